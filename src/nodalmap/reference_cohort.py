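"""Published reference cohort: level involvement and expert review outcomes.

Worked-example data from a published definitive-chemoradiation
head-and-neck cohort of 193 patients with 449 lymph node metastases, whose
level involvement was determined by the automated containment/nearest-level
method and then reviewed independently by three board-certified radiation
oncologists.  The tables here encode the printed results: the automated
per-level counts, each expert's corrections relative to the automated
assignment, and each expert's resulting per-level column.

These data serve as a fixture for the review/aggregation stages and as the
package's worked example; they are counts and correction lists only (no
imaging data are included or required).
"""

from __future__ import annotations

import pandas as pd

from .levels import LEVEL_NAMES

N_NODES = 449
N_PATIENTS = 193

#: Automated (autosegmentation-based) per-level counts, n = 449.
AUTOMATED_COUNTS: dict[str, int] = {
    "2_R": 137, "2_L": 128,
    "3_R": 51, "3_L": 52,
    "1b_L": 17, "1b_R": 17,
    "5_R": 12, "5_L": 11,
    "4a_L": 7, "4a_R": 3,
    "8_L": 6, "8_R": 3,
    "6b": 3, "7a": 1, "7b_R": 1,
    "1a": 0, "4b_L": 0, "4b_R": 0, "6a": 0, "7b_L": 0,
}

#: Each expert's corrections as (automated level, corrected level) pairs;
#: every other node was confirmed.  Expert 1: five corrections; expert 2:
#: none; expert 3: one.  Corrections hit distinct nodes.
EXPERT_CORRECTIONS: dict[str, list[tuple[str, str]]] = {
    "expert1": [
        ("2_R", "3_R"), ("2_R", "3_R"),
        ("8_L", "1b_L"), ("8_R", "2_R"), ("7b_R", "7a"),
    ],
    "expert2": [],
    "expert3": [("2_R", "5_R")],
}

#: Published per-expert corrected columns (consistency check for the
#: correction lists above; each sums to 449).
EXPERT_COLUMNS: dict[str, dict[str, int]] = {
    "expert1": {
        "2_R": 136, "2_L": 128, "3_R": 53, "3_L": 52,
        "1b_L": 18, "1b_R": 17, "5_R": 12, "5_L": 11,
        "4a_L": 7, "4a_R": 3, "8_L": 5, "8_R": 2,
        "6b": 3, "7a": 2, "7b_R": 0,
        "1a": 0, "4b_L": 0, "4b_R": 0, "6a": 0, "7b_L": 0,
    },
    "expert2": dict(AUTOMATED_COUNTS),
    "expert3": {**AUTOMATED_COUNTS, "2_R": 136, "5_R": 13},
}


def automated_counts() -> pd.Series:
    """Automated per-level counts as a Series in canonical level order."""
    return pd.Series(AUTOMATED_COUNTS).reindex(list(LEVEL_NAMES)).astype(int)


def build_assignments() -> pd.DataFrame:
    """Deterministic node-level assignment table realizing the automated counts.

    Nodes get synthetic ids ``N0001..N0449`` under a single cohort-level
    patient id, ordered by canonical level; geometric diagnostics are not
    part of this fixture (inside=True, distance 0).
    """
    rows = []
    i = 0
    for level in LEVEL_NAMES:
        for _ in range(AUTOMATED_COUNTS[level]):
            i += 1
            rows.append(
                {
                    "patient_id": "cohort",
                    "node_id": i,
                    "level": level,
                    "inside": True,
                    "distance_mm": 0.0,
                    "runner_up": "",
                    "runner_up_margin_mm": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def build_votes(assignments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Complete three-reader vote table realizing the published corrections.

    Corrections are applied to distinct nodes of the stated source level,
    in node-id order; each reader's remaining votes are confirms.  Under
    the strict-majority rule the consensus is invariant to which concrete
    nodes within a level carry the corrections, because no node is
    corrected by two readers.
    """
    from .review import votes_from_corrections

    if assignments is None:
        assignments = build_assignments()
    by_level: dict[str, list] = {}
    for rec in assignments.itertuples(index=False):
        by_level.setdefault(rec.level, []).append((rec.patient_id, rec.node_id))
    cursor: dict[str, int] = {}
    corrections: dict[str, list[tuple]] = {}
    for reader, pairs in EXPERT_CORRECTIONS.items():
        corrections[reader] = []
        for src, dst in pairs:
            k = cursor.get(src, 0)
            cursor[src] = k + 1
            pid, nid = by_level[src][k]
            corrections[reader].append((pid, nid, dst))
    return votes_from_corrections(assignments, corrections)
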