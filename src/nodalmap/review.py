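"""Multireader review of automated level assignments.

Each clinical reader either confirms the automated level of a node or
corrects it to another level.  Per node, every reader contributes one label
(a confirm contributes the automated label); the label with a strict
majority wins, and when no label reaches a strict majority the automated
label is kept (logged).  With three readers this means a single dissenting
reader never overrides the automated call, and two readers correcting a
node to different levels cancel out.

Vote tables follow the ``votes.csv`` schema: one row per (node, reader)
with ``verdict`` in {confirm, correct} and ``corrected_level`` set only for
corrections.
"""

from __future__ import annotations

import logging
from collections import Counter

import pandas as pd

from .assignment import CohortDistribution, aggregate
from .errors import ReviewError
from .levels import LEVEL_NAMES

logger = logging.getLogger(__name__)

_NODE_KEY = ["patient_id", "node_id"]


def _validate_votes(assignments: pd.DataFrame, votes: pd.DataFrame) -> pd.DataFrame:
    dup = votes.duplicated(subset=_NODE_KEY + ["reader_id"])
    if dup.any():
        bad = votes.loc[dup, _NODE_KEY + ["reader_id"]].values.tolist()
        raise ReviewError(f"duplicate (node, reader) votes: {bad}")
    merged = votes.merge(
        assignments[_NODE_KEY + ["level"]], on=_NODE_KEY, how="left", validate="m:1"
    )
    if merged["level"].isna().any():
        missing = merged.loc[merged["level"].isna(), _NODE_KEY].values.tolist()
        raise ReviewError(f"votes reference unknown nodes: {missing}")
    corrections = merged["verdict"] == "correct"
    bad_verdicts = ~merged["verdict"].isin(["confirm", "correct"])
    if bad_verdicts.any():
        raise ReviewError(
            f"unknown verdicts: {sorted(merged.loc[bad_verdicts, 'verdict'].unique())}"
        )
    corr_levels = merged.loc[corrections, "corrected_level"]
    unknown = ~corr_levels.isin(LEVEL_NAMES)
    if unknown.any():
        raise ReviewError(f"corrections to unknown levels: {sorted(corr_levels[unknown])}")
    self_corr = corrections & (merged["corrected_level"] == merged["level"])
    if self_corr.any():
        raise ReviewError(
            "corrections must differ from the automated level: "
            f"{merged.loc[self_corr, _NODE_KEY].values.tolist()}"
        )
    return merged


def majority_vote(automated_level: str, vote_labels: list[str]) -> str:
    """Consensus label for one node from per-reader labels.

    *vote_labels* holds each reader's effective label (automated level for
    confirms).  A label needs a strict majority to win; otherwise the
    automated label is kept.
    """
    if not vote_labels:
        raise ReviewError("majority voting requires at least one vote")
    label, count = Counter(vote_labels).most_common(1)[0]
    if count * 2 > len(vote_labels):
        return label
    logger.info(
        "no strict majority among %s; keeping automated label %s",
        vote_labels, automated_level,
    )
    return automated_level


def majority_table(assignments: pd.DataFrame, votes: pd.DataFrame) -> pd.DataFrame:
    """Per-node consensus labels for a cohort.

    Returns the assignment table plus a ``final_level`` column.  Nodes
    without any vote row raise (every node must be reviewed by at least one
    reader).
    """
    merged = _validate_votes(assignments, votes)
    merged["effective"] = merged["corrected_level"].where(
        merged["verdict"] == "correct", merged["level"]
    )
    labels = merged.groupby(_NODE_KEY, sort=False)["effective"].agg(list)
    out = assignments.copy()
    keys = pd.MultiIndex.from_frame(out[_NODE_KEY])
    unvoted = ~keys.isin(labels.index)
    if unvoted.any():
        raise ReviewError(
            f"nodes without votes: {out.loc[unvoted, _NODE_KEY].values.tolist()}"
        )
    out["final_level"] = [
        majority_vote(level, labels[key])
        for level, key in zip(out["level"], keys)
    ]
    return out


def majority_distribution(
    assignments: pd.DataFrame, votes: pd.DataFrame
) -> tuple[CohortDistribution, float]:
    """Consensus cohort distribution and the automated-vs-consensus agreement.

    Agreement is the fraction of nodes whose consensus label equals the
    automated label — the accuracy of the automated method under the
    consensus reference.
    """
    table = majority_table(assignments, votes)
    agreement = float((table["final_level"] == table["level"]).mean())
    return aggregate(table["final_level"]), agreement


def reader_agreement(
    assignments: pd.DataFrame, votes: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-reader agreement fractions and per-reader corrected level counts.

    Returns
    -------
    (agreement, columns)
        ``agreement``: fraction of reviewed nodes each reader confirmed.
        ``columns``: per-level counts (rows = 20 levels, canonical order)
        of each reader's corrected distribution, i.e. the automated counts
        with that reader's corrections applied; each column sums to the
        number of nodes the reader reviewed.
    """
    merged = _validate_votes(assignments, votes)
    merged["effective"] = merged["corrected_level"].where(
        merged["verdict"] == "correct", merged["level"]
    )
    readers = sorted(merged["reader_id"].unique())
    agreement = pd.Series(
        {
            r: float((merged.loc[merged["reader_id"] == r, "verdict"] == "confirm").mean())
            for r in readers
        },
        name="agreement",
    )
    columns = pd.DataFrame(
        {
            r: aggregate(merged.loc[merged["reader_id"] == r, "effective"]).counts
            for r in readers
        }
    )
    return agreement, columns


def votes_from_corrections(
    assignments: pd.DataFrame, corrections: dict[str, list[tuple]]
) -> pd.DataFrame:
    """Build a complete vote table from per-reader correction lists.

    ``corrections`` maps reader id to a list of ``(patient_id, node_id,
    corrected_level)`` triples; every other (node, reader) pair becomes a
    confirm.  Convenience for encoding review outcomes reported as
    correction lists.
    """
    rows = []
    for reader in sorted(corrections):
        corrected = {
            (pid, nid): level for pid, nid, level in corrections[reader]
        }
        unknown = set(corrected) - set(map(tuple, assignments[_NODE_KEY].values))
        if unknown:
            raise ReviewError(f"corrections for unknown nodes: {sorted(unknown)}")
        for rec in assignments.itertuples(index=False):
            key = (rec.patient_id, rec.node_id)
            if key in corrected:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "node_id": rec.node_id,
                        "reader_id": reader,
                        "verdict": "correct",
                        "corrected_level": corrected[key],
                    }
                )
            else:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "node_id": rec.node_id,
                        "reader_id": reader,
                        "verdict": "confirm",
                        "corrected_level": "",
                    }
                )
    return pd.DataFrame(rows)
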