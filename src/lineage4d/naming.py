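"""Sulston-nomenclature utilities for the early C. elegans lineage.

Somatic cells are named by appending a/p (anterior/posterior), l/r
(left/right) or d/v (dorsal/ventral) to the mother's name.  The germline
(P) lineage uses special names that the suffix rule does not cover; an
explicit table maps each P-lineage mother to its daughter pair:

    P0 -> AB, P1;  P1 -> EMS, P2;  EMS -> MS, E;
    P2 -> C, P3;   P3 -> D, P4;    P4 -> Z2, Z3.

Extra divisions of the quiescent germline precursors Z2/Z3 (observed in
some size-equalized embryos) fall back to the generic a/p rule (Z2a, Z2p,
...).
"""
from __future__ import annotations

from typing import NamedTuple

from .errors import ArgumentError, NamingError

#: daughters of the P (germline) lineage and of the intermediates it produces
P_DAUGHTERS: dict[str, tuple[str, str]] = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
}

_P_PARENT = {d: p for p, pair in P_DAUGHTERS.items() for d in pair}

#: founder cells in the classical sense, plus the germline pair
FOUNDERS = ("AB", "MS", "E", "C", "D", "P4", "Z2", "Z3")

#: bases that accept an a/p/l/r/d/v suffix chain
_SUFFIX_BASES = ("AB", "MS", "Z2", "Z3", "E", "C", "D")

_SUFFIX_CHARS = frozenset("aplrdv")

#: suffix letter pairs by division axis
SUFFIX_PAIRS = {"a": "p", "l": "r", "d": "v"}

#: axis index (A-P, D-V, L-R) probed by each suffix letter
AXIS_OF_SUFFIX = {"a": 0, "p": 0, "d": 1, "v": 1, "l": 2, "r": 2}


class Founder(NamedTuple):
    founder: str
    super_lineage: str  # "AB", "P1", or "P0" for the zygote itself


def split_name(name: str) -> tuple[str, str]:
    """Split ``name`` into (base, suffix chain).

    P-lineage names (P0..P4, EMS) are atomic.  For suffix names the base is
    the longest founder prefix whose remainder is entirely a/p/l/r/d/v.
    """
    if not isinstance(name, str) or not name:
        raise NamingError(f"invalid cell name: {name!r}")
    if name in P_DAUGHTERS or name in _SUFFIX_BASES:
        return name, ""
    for base in sorted(_SUFFIX_BASES, key=len, reverse=True):
        if name.startswith(base):
            suffix = name[len(base):]
            if suffix and all(c in _SUFFIX_CHARS for c in suffix):
                return base, suffix
    raise NamingError(f"cell name {name!r} is not a valid Sulston or P-lineage name")


def is_valid_name(name: str) -> bool:
    try:
        split_name(name)
        return True
    except NamingError:
        return False


def founder_of(name: str) -> Founder:
    """Founder lineage and AB-vs-P1 super-lineage of a cell.

    P-lineage intermediates (P1, EMS, P2, P3) resolve to themselves as the
    "founder" label; everything outside the AB lineage belongs to the P1
    super-lineage except the zygote P0.
    """
    base, _ = split_name(name)
    if name == "P0":
        return Founder("P0", "P0")
    super_lineage = "AB" if base == "AB" else "P1"
    return Founder(base, super_lineage)


def parent_of(name: str) -> str | None:
    """Mother's name, or None for the zygote P0."""
    if name == "P0":
        return None
    if name in _P_PARENT:
        return _P_PARENT[name]
    base, suffix = split_name(name)
    if not suffix:
        # founder reached via the P table above; Z2/Z3 handled there too
        raise NamingError(f"no parent rule for {name!r}")
    return name[:-1]


def daughters_of(name: str, axis_letter: str = "a") -> tuple[str, str]:
    """Daughter pair of ``name``; suffix names need the division axis letter."""
    if name in P_DAUGHTERS:
        return P_DAUGHTERS[name]
    if axis_letter not in SUFFIX_PAIRS:
        raise ArgumentError(f"axis letter must be one of a/l/d, got {axis_letter!r}")
    return name + axis_letter, name + SUFFIX_PAIRS[axis_letter]


def first_daughter(pair: tuple[str, str]) -> str:
    """The daughter that defines the positive end of the division vector.

    By convention this is the a/l/d-suffixed daughter, or the first entry of
    the explicit P-lineage pair.
    """
    a, b = pair
    if a[-1] in ("a", "l", "d") and is_valid_name(a) and a[:-1] == b[:-1]:
        return a
    return a  # P-lineage pairs are already ordered


def generation_index(name: str) -> int:
    """Number of suffix letters (0 for founders and P-lineage names)."""
    _, suffix = split_name(name)
    return len(suffix)


def _expand(cells: tuple[str, ...], letter: str) -> tuple[str, ...]:
    out = []
    for c in cells:
        out.extend(daughters_of(c, letter))
    return tuple(out)


_AB2 = ("ABa", "ABp")
_AB4 = _expand(_AB2, "l")
_AB8 = _expand(_AB4, "a")
_AB16 = _expand(_AB8, "a")

#: cells whose features are attributed to each classifier stage.  A stage's
#: cohort contains the cells newly present at that canonical cell count; the
#: cumulative union over stages defines the classifier's feature universe.
STAGE_COHORTS: dict[int, frozenset[str]] = {
    4: frozenset({"ABa", "ABp", "EMS", "P2"}),
    8: frozenset(set(_AB4) | {"MS", "E", "C", "P3"}),
    15: frozenset(set(_AB8) | {"MSa", "MSp", "Ea", "Ep", "Ca", "Cp"}),
    28: frozenset(
        set(_AB16)
        | {"MSaa", "MSap", "MSpa", "MSpp", "Caa", "Cap", "Cpa", "Cpp", "D", "P4"}
    ),
}

STAGES = tuple(sorted(STAGE_COHORTS))


def generation_cohort(stage_k: int) -> frozenset[str]:
    """Canonical named cells attributed to a 4/8/15/28-cell stage."""
    if stage_k not in STAGE_COHORTS:
        raise ArgumentError(f"unsupported stage {stage_k!r}; expected one of {STAGES}")
    return STAGE_COHORTS[stage_k]


def cumulative_cohort(stage_k: int) -> frozenset[str]:
    """Union of stage cohorts up to and including ``stage_k``."""
    if stage_k not in STAGE_COHORTS:
        raise ArgumentError(f"unsupported stage {stage_k!r}; expected one of {STAGES}")
    cells: set[str] = set()
    for s in STAGES:
        if s <= stage_k:
            cells |= STAGE_COHORTS[s]
    return frozenset(cells)


def canonical_suffix_letter(name: str) -> str | None:
    """Division-axis letter used when naming a cell's daughters.

    None for P-lineage mothers (explicit names).  The AB lineage divides
    along A-P, then L-R, then A-P again, with a D-V round at the fifth
    division; all other somatic lineages divide along A-P.  This is a
    self-consistent scheme for the simulator and cohort tables, not a claim
    about every real division axis.
    """
    if name in P_DAUGHTERS:
        return None
    base, suffix = split_name(name)
    if base == "AB":
        if len(suffix) == 1:
            return "l"
        if len(suffix) == 4:
            return "d"
        return "a"
    return "a"
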