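"""Aitchison-geometry primitives for 4-part daily time-use compositions.

A day is partitioned exhaustively into sleep, sedentary behavior (SED),
light physical activity (LPA) and moderate-to-vigorous physical activity
(MVPA).  Because the four durations are bound to a 1440-minute day they
carry only relative information and live on the simplex; all arithmetic
here is Aitchison geometry: closure, perturbation, the centered log-ratio
(clr), and pivot coordinates — the orthonormal isometric log-ratio (ilr)
basis whose first coordinate contrasts one chosen behavior against the
geometric mean of the remaining three.

Everything downstream (descriptives, the change-on-change regression, the
isotemporal substitution engine, the synthetic cohort generator) is built
on this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical behavior order used throughout the package.
PARTS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")

#: Minutes in one day; the scale constant of the minutes representation.
DAY_MINUTES: float = 1440.0

_D = len(PARTS)
_SUM_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for invalid compositional input (zero/negative parts, shape)."""


def _as_array(values: Iterable[float], n_parts: int = _D) -> np.ndarray:
    arr = np.asarray(tuple(values), dtype=float).reshape(-1)
    if arr.size != n_parts:
        raise CompositionError(
            f"expected {n_parts} parts, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise CompositionError("non-finite part value")
    return arr


@dataclass(frozen=True)
class Composition:
    """A closed 4-part composition in the canonical (sleep, SED, LPA, MVPA) order.

    Internally stored as proportions summing to 1; the minutes/day view is a
    rescaling by ``day_minutes`` (default 1440, exact conversion).

    Parameters
    ----------
    proportions
        Strictly positive 4-vector; closed on construction.
    day_minutes
        Scale constant for the minutes representation.
    """

    proportions: tuple[float, ...]
    day_minutes: float = DAY_MINUTES
    parts: tuple[str, ...] = field(default=PARTS)

    def __post_init__(self) -> None:
        arr = _as_array(self.proportions, len(self.parts))
        for name, v in zip(self.parts, arr):
            if v <= 0:
                raise CompositionError(
                    f"part {name!r} is {v:g}; every behavior duration must be > 0"
                )
        arr = arr / arr.sum()
        object.__setattr__(self, "proportions", tuple(arr))
        if self.day_minutes <= 0:
            raise CompositionError("day_minutes must be positive")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_minutes(
        cls, minutes: Iterable[float], day_minutes: float = DAY_MINUTES
    ) -> "Composition":
        """Build a composition from minutes/day (closed automatically)."""
        return cls(tuple(_as_array(minutes)), day_minutes=day_minutes)

    # -- views ------------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """Closed proportions as an ndarray (sums to 1)."""
        return np.asarray(self.proportions)

    @property
    def minutes(self) -> np.ndarray:
        """Minutes/day view (sums to ``day_minutes``)."""
        return self.values * self.day_minutes

    def __getitem__(self, part: str) -> float:
        return self.values[self.parts.index(part)]

    def as_dict(self, minutes: bool = False) -> dict[str, float]:
        vec = self.minutes if minutes else self.values
        return dict(zip(self.parts, map(float, vec)))


def closure(
    raw: Iterable[float],
    day_minutes: float = DAY_MINUTES,
    zero_replacement: float | None = None,
) -> Composition:
    """Close a positive vector to a :class:`Composition`.

    Zero parts are a hard error by default (the analysis assumes strictly
    positive daily durations).  For synthetic edge studies a multiplicative
    replacement can be enabled: zeros are replaced by ``zero_replacement``
    (on the proportion scale) and the non-zero parts shrunk proportionally.
    """
    arr = _as_array(raw)
    if zero_replacement is not None:
        if zero_replacement <= 0:
            raise CompositionError("zero_replacement must be positive")
        zero = arr == 0
        if zero.any():
            arr = arr / arr.sum()
            arr[zero] = zero_replacement
            arr[~zero] *= 1.0 - zero.sum() * zero_replacement
    for name, v in zip(PARTS, arr):
        if v <= 0:
            raise CompositionError(
                f"part {name!r} is {v:g}; every behavior duration must be > 0"
            )
    return Composition(tuple(arr), day_minutes=day_minutes)


def _check_same_order(x: Composition, y: Composition) -> None:
    if x.parts != y.parts:
        raise CompositionError(
            f"part order mismatch: {x.parts} vs {y.parts}"
        )


def perturb(x: Composition, y: Composition) -> Composition:
    """Aitchison perturbation x ⊕ y: closure of the element-wise product."""
    _check_same_order(x, y)
    return closure(x.values * y.values, day_minutes=x.day_minutes)


def perturbation_difference(post: Composition, pre: Composition) -> Composition:
    """Compositional change post ⊖ pre: closure of element-wise ratios.

    Perturbing ``pre`` by the result recovers ``post``; the neutral element
    (no change) is the equal composition (1/4, 1/4, 1/4, 1/4).
    """
    _check_same_order(post, pre)
    return closure(post.values / pre.values, day_minutes=post.day_minutes)


def compositional_mean(items: Sequence[Composition]) -> Composition:
    """Center of a compositional sample: closure of part-wise geometric means.

    Equals the inverse-ilr of the arithmetic mean of ilr coordinates.
    """
    if len(items) == 0:
        raise CompositionError("compositional_mean of an empty sample")
    logs = np.stack([np.log(c.values) for c in items])
    return closure(np.exp(logs.mean(axis=0)), day_minutes=items[0].day_minutes)


def clr(x: Composition) -> np.ndarray:
    """Centered log-ratio: log parts minus their mean; zero-sum 4-vector."""
    logs = np.log(x.values)
    return logs - logs.mean()


def clr_inverse(vec: Iterable[float], day_minutes: float = DAY_MINUTES) -> Composition:
    """Map a real 4-vector back to the simplex (closure of exp)."""
    return closure(np.exp(_as_array(vec)), day_minutes=day_minutes)


@dataclass(frozen=True)
class PivotBasis:
    """Pivot-coordinate ilr basis with one behavior contrasted first.

    The basis order places ``pivot_part`` first, the remaining behaviors in
    canonical order.  ``contrast_matrix`` is the 4x3 matrix V (rows in
    canonical part order) with orthonormal zero-sum columns such that
    ``z = V.T @ clr(x)``; its first coordinate is

        z1 = sqrt(3/4) * ln( pivot / gmean(others) ),

    the "pivot behavior vs remaining" contrast reported by the regression.
    """

    pivot_part: str
    order: tuple[str, ...] = field(init=False)
    contrast_matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.pivot_part not in PARTS:
            raise CompositionError(
                f"unknown behavior {self.pivot_part!r}; expected one of {PARTS}"
            )
        order = (self.pivot_part,) + tuple(p for p in PARTS if p != self.pivot_part)
        V_ord = np.zeros((_D, _D - 1))
        for k in range(1, _D):
            r = _D - k  # parts remaining after position k
            coef = math.sqrt(r / (r + 1))
            V_ord[k - 1, k - 1] = coef
            V_ord[k:, k - 1] = -coef / r
        V = np.zeros_like(V_ord)
        for pos, part in enumerate(order):
            V[PARTS.index(part)] = V_ord[pos]
        V.setflags(write=False)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "contrast_matrix", V)


#: One basis per behavior, keyed by the behavior pivoted first.
ALL_BASES: dict[str, PivotBasis] = {p: PivotBasis(p) for p in PARTS}


def pivot_coordinates(x: Composition, basis: PivotBasis) -> np.ndarray:
    """ilr coordinates of ``x`` in the given pivot basis (3-vector)."""
    return basis.contrast_matrix.T @ clr(x)


def inverse_pivot(
    z: Iterable[float], basis: PivotBasis, day_minutes: float = DAY_MINUTES
) -> Composition:
    """Back-transform pivot coordinates to a composition in canonical order."""
    z = _as_array(z, _D - 1)
    return clr_inverse(basis.contrast_matrix @ z, day_minutes=day_minutes)


def first_pivot_all_parts(x: Composition) -> np.ndarray:
    """First pivot coordinate of each behavior's own basis, canonical order.

    Entry j is sqrt(3/4)·ln(x_j / gmean(others)) = sqrt(4/3)·clr_j(x); the
    four entries sum to zero.
    """
    return math.sqrt(_D / (_D - 1)) * clr(x)
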