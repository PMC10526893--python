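"""Vocabulary of the 20 cervical nodal levels.

The package classifies lymph node metastases into the consensus cervical
level system used for head-and-neck radiotherapy target volume design:
midline levels 1a, 6a, 6b and 7a plus the bilateral levels 1b, 2, 3, 4a,
4b, 5, 7b and 8 (left/right counted separately), i.e. 20 compartments.

Levels are identified either by their canonical integer code (1..20) or by
their name (``"2_R"``, ``"7a"``, ...).  The canonical ordering below is fixed
and is used throughout the package for deterministic tie-breaking and for
column/row ordering in tables.
"""

from __future__ import annotations

from .errors import NodalMapError

#: Canonical level ordering.  Index + 1 is the integer label code used in
#: level label volumes.  Midline levels have no side suffix; ``_L`` sorts
#: before ``_R`` so left wins canonical ties (e.g. a node exactly on the
#: midline between mirrored levels).
LEVEL_NAMES: tuple[str, ...] = (
    "1a",
    "1b_L", "1b_R",
    "2_L", "2_R",
    "3_L", "3_R",
    "4a_L", "4a_R",
    "4b_L", "4b_R",
    "5_L", "5_R",
    "6a", "6b",
    "7a",
    "7b_L", "7b_R",
    "8_L", "8_R",
)

N_LEVELS = len(LEVEL_NAMES)

NAME_TO_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(LEVEL_NAMES)}
CODE_TO_NAME: dict[int, str] = {i + 1: name for i, name in enumerate(LEVEL_NAMES)}

#: Bilateral base levels, each present as ``<base>_L`` and ``<base>_R``.
BILATERAL_BASES: tuple[str, ...] = ("1b", "2", "3", "4a", "4b", "5", "7b", "8")
#: Midline levels without a side.
MIDLINE_NAMES: tuple[str, ...] = ("1a", "6a", "6b", "7a")


class UnknownLevelError(NodalMapError, KeyError):
    """A name or code outside the 20-level vocabulary."""


def code_for(name: str) -> int:
    """Integer label code for a level name."""
    try:
        return NAME_TO_CODE[name]
    except KeyError:
        raise UnknownLevelError(f"unknown level name {name!r}") from None


def name_for(code: int) -> str:
    """Level name for an integer label code."""
    try:
        return CODE_TO_NAME[int(code)]
    except KeyError:
        raise UnknownLevelError(f"unknown level code {code!r}") from None


def mirror_name(name: str) -> str:
    """Name of the contralateral level (identity for midline levels)."""
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    if name in MIDLINE_NAMES:
        return name
    raise UnknownLevelError(f"unknown level name {name!r}")
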