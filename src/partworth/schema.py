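"""Attribute schemas and part-worth coding for discrete-choice experiments.

An :class:`AttributeSchema` declares the attributes that define a treatment
profile and their levels.  A :class:`CodingMap` translates a profile (one
level index per attribute) into the covariate vector that multiplies the
part-worth vector ``beta``:

* linear attributes contribute one column, ``x = level - center``, so the
  coefficient is a slope per unit of the attribute (here: per percentage
  point);
* categorical attributes with ``L`` levels contribute ``L - 1`` effects-coded
  columns (the last level is ``-1`` on all of them), so level utilities sum
  to zero within the attribute;
* binary attributes contribute a single effects column with the first level
  coded ``+1`` and the second ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Attribute", "AttributeSchema", "CodingMap", "crohn_schema"]

_KINDS = ("linear", "categorical", "binary")


@dataclass(frozen=True)
class Attribute:
    """One attribute of a choice profile.

    Parameters
    ----------
    name
        Identifier used in tables and files.
    kind
        ``"linear"``, ``"categorical"`` or ``"binary"``.
    levels
        Level values: numeric for linear attributes, labels otherwise.
    ordering
        Better-direction for ordered attributes: ``"higher"`` / ``"lower"``
        for linear attributes, a preferred level label for binary ones, or
        ``"none"`` when levels have no natural ranking (e.g. dosing regimen).
    center
        Centering constant for linear attributes (slopes are per unit around
        this value).
    """

    name: str
    kind: str
    levels: tuple = ()
    ordering: str = "none"
    center: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >= 2 levels")
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == "linear":
            if not all(isinstance(v, (int, float)) for v in self.levels):
                raise ValueError(f"linear attribute {self.name!r} needs numeric levels")
            if self.center is None or not np.isfinite(self.center):
                raise ValueError(f"linear attribute {self.name!r} needs a finite center")
            if self.ordering not in ("higher", "lower"):
                raise ValueError(
                    f"linear attribute {self.name!r} needs ordering 'higher' or 'lower'"
                )
        elif self.kind == "binary":
            if len(self.levels) != 2:
                raise ValueError(f"binary attribute {self.name!r} needs exactly 2 levels")
            if self.ordering != "none" and self.ordering not in self.levels:
                raise ValueError(
                    f"binary ordering must be a level label or 'none', got {self.ordering!r}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def is_ordered(self) -> bool:
        """Whether the attribute has a declared better-direction."""
        return self.ordering != "none"

    def level_rank(self, level_index: int) -> float:
        """Rank of a level, larger = better.  Only valid for ordered attributes."""
        if not self.is_ordered:
            raise ValueError(f"attribute {self.name!r} has no ordering")
        if self.kind == "linear":
            v = float(self.levels[level_index])
            return v if self.ordering == "higher" else -v
        # binary: preferred level ranks 1, the other 0
        return 1.0 if self.levels[level_index] == self.ordering else 0.0


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes defining the choice profiles."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, i: int) -> Attribute:
        return self.attributes[i]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(a.n_levels for a in self.attributes)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def ordered_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.attributes) if a.is_ordered]

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    "levels": list(a.levels),
                    "ordering": a.ordering,
                    "center": a.center,
                }
                for a in self.attributes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSchema":
        return cls(
            tuple(
                Attribute(
                    name=a["name"],
                    kind=a["kind"],
                    levels=tuple(a["levels"]),
                    ordering=a.get("ordering", "none"),
                    center=a.get("center"),
                )
                for a in d["attributes"]
            )
        )


@dataclass(frozen=True)
class CodingMap:
    """Maps (attribute, level) pairs to columns of the part-worth vector."""

    schema: AttributeSchema
    columns: tuple[tuple[int, ...], ...] = field(init=False)
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        cols: list[tuple[int, ...]] = []
        start = 0
        for a in self.schema:
            width = 1 if a.kind in ("linear", "binary") else a.n_levels - 1
            cols.append(tuple(range(start, start + width)))
            start += width
        object.__setattr__(self, "columns", tuple(cols))
        object.__setattr__(self, "n_columns", start)

    @classmethod
    def from_schema(cls, schema: AttributeSchema) -> "CodingMap":
        return cls(schema)

    def code_profile(self, level_indices: Sequence[int]) -> np.ndarray:
        """Covariate vector x for a profile given one level index per attribute."""
        if len(level_indices) != len(self.schema):
            raise ValueError("one level index per attribute required")
        x = np.zeros(self.n_columns)
        for a, li, cols in zip(self.schema, level_indices, self.columns):
            self._fill(x, a, int(li), cols)
        return x

    def code_design(self, cells: np.ndarray) -> np.ndarray:
        """Vectorised coding: cells (..., n_attrs) of level indices -> (..., p)."""
        cells = np.asarray(cells)
        out = np.zeros(cells.shape[:-1] + (self.n_columns,))
        for ai, (a, cols) in enumerate(zip(self.schema, self.columns)):
            li = cells[..., ai]
            if a.kind == "linear":
                lv = np.asarray(a.levels, dtype=float)[li]
                out[..., cols[0]] = lv - a.center
            elif a.kind == "binary":
                out[..., cols[0]] = np.where(li == 0, 1.0, -1.0)
            else:
                last = a.n_levels - 1
                for j, c in enumerate(cols):
                    out[..., c] = np.where(li == j, 1.0, np.where(li == last, -1.0, 0.0))
        return out

    def _fill(self, x: np.ndarray, a: Attribute, li: int, cols: tuple[int, ...]) -> None:
        if not 0 <= li < a.n_levels:
            raise ValueError(f"level index {li} out of range for {a.name!r}")
        if a.kind == "linear":
            x[cols[0]] = float(a.levels[li]) - float(a.center)
        elif a.kind == "binary":
            x[cols[0]] = 1.0 if li == 0 else -1.0
        else:
            if li < a.n_levels - 1:
                x[cols[li]] = 1.0
            else:
                for c in cols:
                    x[c] = -1.0

    def level_utilities(self, attr_index: int, beta: np.ndarray) -> np.ndarray:
        """Utility of each level of one attribute under part-worth draws ``beta``.

        ``beta`` may be a single vector (p,) or a stack of draws (..., p); the
        result has the level axis last.  Linear attributes are evaluated at
        their design levels around the center; effects-coded utilities come
        straight from the columns (last level = minus the sum).
        """
        beta = np.asarray(beta, dtype=float)
        a = self.schema[attr_index]
        cols = self.columns[attr_index]
        if a.kind == "linear":
            x = np.asarray(a.levels, dtype=float) - a.center
            return beta[..., cols[0], None] * x
        if a.kind == "binary":
            b = beta[..., cols[0]]
            return np.stack([b, -b], axis=-1)
        b = beta[..., list(cols)]
        return np.concatenate([b, -b.sum(axis=-1, keepdims=True)], axis=-1)


# Table-derived default schema for the Crohn's disease maintenance-therapy DCE.
DOSING_LEVELS = (
    "daily tablets",
    "tablets twice a day",
    "weekly injection",
    "injection every 2 weeks",
    "IV infusion every 8 weeks",
    "daily tablets + IV infusion every 8 weeks",
)


def crohn_schema() -> AttributeSchema:
    """Default six-attribute schema for Crohn's maintenance-therapy choices.

    Chance of remission (20/50/80 per 100, higher better) and chance of a
    side effect requiring stopping the medication (1/15/30 per 100, lower
    better) enter linearly; centers sit at the mid-range so slopes are per
    percentage point.  Dosing has six unordered regimens; the three risk /
    burden attributes are binary with "No" preferred.
    """
    return AttributeSchema(
        (
            Attribute("remission", "linear", (20.0, 50.0, 80.0), "higher", 50.0),
            Attribute("wdae", "linear", (1.0, 15.0, 30.0), "lower", 15.5),
            Attribute("dosing", "categorical", DOSING_LEVELS, "none"),
            Attribute("prednisone", "binary", ("Yes", "No"), "No"),
            Attribute("blood_liver", "binary", ("Yes", "No"), "No"),
            Attribute("infection_cancer", "binary", ("Yes", "No"), "No"),
        )
    )
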