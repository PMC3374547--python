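"""Generalization hierarchies, value coarsening, and the lattice of
generalization states.

Each quasi-identifier has an ordered ladder of *levels*: level 0 is the raw
value and every later level is a strict coarsening of the one before (each
coarser cell is a union of finer cells).  De-identifying a dataset means
picking one level per quasi-identifier — a node of the cross-product
*lattice* — and replacing every QI value by its label at that level.

Default ladders:

* Age: years → 5-year interval, 80+ → 10-year, 80+ → 20-year, 80+
* DaysInHospital (Y2 and Y3 move together): days → days to 2 weeks, >2 weeks
  → days to 1 week, 1–2 weeks, >2 weeks
* LOS: days → days up to 6, week ranges ((1–2], (2–4], (4–8], (8–12],
  (12–26], 26+) → <1 week + same ranges → <4 weeks + coarser ranges
* DSFC: days → weeks → 2-week blocks → months (fixed 28-day blocks, so the
  month level equals a "4 weeks" coarsening)
* Sex: no change (single level)
* Specialty / PlaceOfService / CPTCode / Diagnosis: one predetermined
  grouping level each, driven by configurable two-column tables (the tables
  shipped with the package are small synthetic demonstration groupings, not
  the clinical groupings of any real release); Diagnosis maps ICD-9-CM codes
  to primary condition groups by longest-prefix match.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Callable, Mapping

import pandas as pd

from .claims_model import Dataset
from .exceptions import DomainError
from . import tables

__all__ = [
    "Hierarchy",
    "Lattice",
    "LatticeNode",
    "generalize_value",
    "build_default_hierarchies",
    "build_lattice",
    "apply_node",
]


@dataclass(frozen=True)
class Hierarchy:
    """An ordered ladder of coarsenings for one quasi-identifier.

    ``levels[0]`` is the identity; ``levels[l]`` maps a *raw* value to its
    level-``l`` label.  ``columns`` lists the dataset columns the ladder
    applies to (DaysInHospital Y2/Y3 share one ladder and move together).
    """

    qi_name: str
    levels: tuple[Callable[[Any], Any], ...]
    columns: tuple[str, ...]
    table: str  # "patients" or "claims"

    @property
    def height(self) -> int:
        return len(self.levels)


def generalize_value(h: Hierarchy, value, level: int):
    """Return ``value``'s label at ``level`` of hierarchy ``h``.

    Level 0 returns the value unchanged; missing values pass through.
    """
    if not (0 <= level < h.height):
        raise DomainError(
            f"level {level} outside hierarchy {h.qi_name!r} (height {h.height})"
        )
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return value
    if level == 0:
        return value
    return h.levels[level](value)


# --------------------------------------------------------------------------
# numeric ladders
# --------------------------------------------------------------------------

def _age_interval(width: int):
    def f(v):
        v = int(v)
        if v >= 80:
            return "80+"
        lo = (v // width) * width
        return f"[{lo},{lo + width})"

    return f


def _dih_l1(v):
    v = int(v)
    return str(v) if v <= 14 else ">2 weeks"


def _dih_l2(v):
    v = int(v)
    if v <= 7:
        return str(v)
    if v <= 14:
        return "1-2 weeks"
    return ">2 weeks"


def _los_week(v) -> int:
    # week index of a stay of v days; day 7 counts as the boundary week
    return max(1, -(-int(v) // 7))


_LOS_RANGES = (
    (2, "(1-2] weeks"),
    (4, "(2-4] weeks"),
    (8, "(4-8] weeks"),
    (12, "(8-12] weeks"),
    (26, "(12-26] weeks"),
)


def _los_range_label(week: int) -> str:
    for hi, label in _LOS_RANGES:
        if week <= hi:
            return label
    return "26+ weeks"


def _los_l1(v):
    v = int(v)
    return str(v) if v <= 6 else _los_range_label(_los_week(v))


def _los_l2(v):
    v = int(v)
    return "<1 week" if v <= 6 else _los_range_label(_los_week(v))


def _los_l3(v):
    lab = _los_l2(v)
    return "<4 weeks" if lab in ("<1 week", "(1-2] weeks", "(2-4] weeks") else lab


def _dsfc_block(days: int):
    """dsfc is stored 0-based; blocks are over 1-based days, so block k of
    width w covers stored values [(k-1)w, kw)."""

    def f(v):
        return -(-(int(v) + 1) // days)

    return f


def _dsfc_label(width: int, prefix: str):
    block = _dsfc_block(width)

    def f(v):
        return f"{prefix} {block(v)}"

    return f


# --------------------------------------------------------------------------
# categorical grouping levels
# --------------------------------------------------------------------------

def _grouping_level(mapping: Mapping[str, str], qi_name: str, prefix: bool = False):
    def f(v):
        code = str(v)
        if code in mapping:
            return mapping[code]
        if prefix:
            stripped = code.replace(".", "")
            for n in range(len(stripped), 0, -1):
                if stripped[:n] in mapping:
                    return mapping[stripped[:n]]
        if "*" in mapping:
            return mapping["*"]
        raise DomainError(f"{qi_name} value {code!r} not covered by grouping table")

    return f


def build_default_hierarchies(
    grouping_tables: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, Hierarchy]:
    """Build the full per-QI hierarchy map.

    ``grouping_tables`` may override the demonstration grouping maps; keys
    are ``specialty``, ``place_of_service``, ``cpt_code``, ``diagnosis``.
    """
    gt = dict(tables.default_grouping_tables())
    if grouping_tables:
        gt.update(grouping_tables)

    ident = lambda v: v  # noqa: E731 - level-0 placeholder, never called
    h = {
        "age": Hierarchy(
            "age",
            (ident, _age_interval(5), _age_interval(10), _age_interval(20)),
            ("age",),
            "patients",
        ),
        "sex": Hierarchy("sex", (ident,), ("sex",), "patients"),
        "days_in_hospital": Hierarchy(
            "days_in_hospital",
            (ident, _dih_l1, _dih_l2),
            ("dih_y2", "dih_y3"),
            "patients",
        ),
        "los": Hierarchy(
            "los", (ident, _los_l1, _los_l2, _los_l3), ("los",), "claims"
        ),
        "dsfc": Hierarchy(
            "dsfc",
            (
                ident,
                _dsfc_label(7, "wk"),
                _dsfc_label(14, "2wk"),
                _dsfc_label(28, "mo"),
            ),
            ("dsfc",),
            "claims",
        ),
        "specialty": Hierarchy(
            "specialty",
            (ident, _grouping_level(gt["specialty"], "specialty")),
            ("specialty",),
            "claims",
        ),
        "place_of_service": Hierarchy(
            "place_of_service",
            (ident, _grouping_level(gt["place_of_service"], "place_of_service")),
            ("place_of_service",),
            "claims",
        ),
        "cpt_code": Hierarchy(
            "cpt_code",
            (ident, _grouping_level(gt["cpt_code"], "cpt_code")),
            ("cpt_code",),
            "claims",
        ),
        "diagnosis": Hierarchy(
            "diagnosis",
            (ident, _grouping_level(gt["diagnosis"], "diagnosis", prefix=True)),
            ("diagnosis",),
            "claims",
        ),
    }
    return h


# --------------------------------------------------------------------------
# lattice
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class LatticeNode:
    """One generalization state: a level per quasi-identifier."""

    qi_names: tuple[str, ...]
    levels: tuple[int, ...]

    @property
    def height(self) -> int:
        return sum(self.levels)

    def level_of(self, qi: str) -> int:
        return self.levels[self.qi_names.index(qi)]

    def __le__(self, other: "LatticeNode") -> bool:
        return all(a <= b for a, b in zip(self.levels, other.levels))

    def __ge__(self, other: "LatticeNode") -> bool:
        return other.__le__(self)


@dataclass
class Lattice:
    """The cross product of hierarchy levels over the lattice QIs."""

    qi_names: tuple[str, ...]
    heights: tuple[int, ...]

    def __len__(self) -> int:
        n = 1
        for h in self.heights:
            n *= h
        return n

    def node(self, levels) -> LatticeNode:
        levels = tuple(int(l) for l in levels)
        if len(levels) != len(self.heights) or any(
            not 0 <= l < h for l, h in zip(levels, self.heights)
        ):
            raise DomainError(f"levels {levels} outside lattice {self.heights}")
        return LatticeNode(self.qi_names, levels)

    @property
    def bottom(self) -> LatticeNode:
        return LatticeNode(self.qi_names, (0,) * len(self.heights))

    @property
    def top(self) -> LatticeNode:
        return LatticeNode(self.qi_names, tuple(h - 1 for h in self.heights))

    def nodes(self) -> list[LatticeNode]:
        return [
            LatticeNode(self.qi_names, lv)
            for lv in itertools.product(*(range(h) for h in self.heights))
        ]

    def successors(self, node: LatticeNode) -> list[LatticeNode]:
        out = []
        for i, (l, h) in enumerate(zip(node.levels, self.heights)):
            if l + 1 < h:
                lv = list(node.levels)
                lv[i] = l + 1
                out.append(LatticeNode(self.qi_names, tuple(lv)))
        return out

    def ancestors(self, node: LatticeNode) -> list[LatticeNode]:
        """All nodes strictly above ``node`` (componentwise ≥, not equal)."""
        return [n for n in self.nodes() if node <= n and n != node]

    def descendants(self, node: LatticeNode) -> list[LatticeNode]:
        return [n for n in self.nodes() if n <= node and n != node]


def build_lattice(
    hierarchies: Mapping[str, Hierarchy], qi_names=None
) -> Lattice:
    """Build the lattice over ``qi_names`` (default: every hierarchy given,
    in mapping order)."""
    if qi_names is None:
        qi_names = tuple(hierarchies)
    else:
        qi_names = tuple(qi_names)
    if not qi_names:
        raise DomainError("lattice needs at least one hierarchy")
    heights = tuple(hierarchies[q].height for q in qi_names)
    return Lattice(qi_names, heights)


def apply_node(
    ds: Dataset, node: LatticeNode, hierarchies: Mapping[str, Hierarchy]
) -> Dataset:
    """Generalize every lattice QI column of ``ds`` to its node level.

    Non-QI columns are untouched; the bottom node is the identity.
    """
    out = ds.copy()
    for qi, level in zip(node.qi_names, node.levels):
        if level == 0:
            continue
        h = hierarchies[qi]
        df = out.patients if h.table == "patients" else out.claims
        for col in h.columns:
            df[col] = df[col].map(lambda v: generalize_value(h, v, level))
    return out
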