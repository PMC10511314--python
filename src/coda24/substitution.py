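"""Compositional isotemporal substitution.

Translates one-to-one minute reallocations between behaviors, applied at a
reference composition (by default the cohort's pre-retirement
compositional mean), into predicted changes in an obesity indicator.

Because the model is linear in ilr coordinates, the predicted change for a
reallocation is the Δ-coefficient vector dotted with the difference in
pivot coordinates between the reallocated and the reference composition;
intercept, baseline and covariate terms cancel, so the curve passes
through zero at a zero-minute reallocation.  The prediction is
basis-invariant, and equivalently the clr-effect vector dotted with the
clr difference.  In this log-ratio geometry reallocations are not
antisymmetric: removing 60 min of MVPA moves the composition much further
(in Aitchison distance) than adding 60 min, so losses of a small part cost
more than equal-sized gains return.

Confidence intervals use the delta method on the Δ-coefficient covariance
block with a t quantile at the fit's residual degrees of freedom.

Grid caps follow the observed ranges of change: ±60 min for pairs
involving MVPA, ±120 min otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .composition import PARTS, Composition, clr, pivot_coordinates, ALL_BASES
from .change_model import ChangeModelFit, clr_coefficients

#: Per-pair default caps on reallocation size, minutes.
MVPA_CAP = 60.0
OTHER_CAP = 120.0


class ReallocationError(ValueError):
    """Infeasible reallocation (would drive a behavior to zero or below)."""


def default_cap(from_part: str, to_part: str) -> float:
    """±60 min when the pair involves MVPA, ±120 min otherwise."""
    return MVPA_CAP if "mvpa" in (from_part, to_part) else OTHER_CAP


@dataclass(frozen=True)
class ReallocationEstimate:
    """Predicted outcome change for one reallocation, with its 95% CI."""

    from_part: str
    to_part: str
    minutes: float
    estimate: float
    ci_low: float | None
    ci_high: float | None
    outcome: str | None
    reference: Composition

    def as_row(self) -> dict:
        return {
            "from": self.from_part,
            "to": self.to_part,
            "minutes": self.minutes,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "outcome": self.outcome,
        }


def _check_pair(from_part: str, to_part: str) -> None:
    for p in (from_part, to_part):
        if p not in PARTS:
            raise ReallocationError(f"unknown behavior {p!r}; expected one of {PARTS}")
    if from_part == to_part:
        raise ReallocationError("from_part and to_part must differ")


def reallocate(
    reference: Composition, from_part: str, to_part: str, minutes: float
) -> Composition:
    """Move ``minutes`` from one behavior to another, total time fixed."""
    _check_pair(from_part, to_part)
    if minutes < 0:
        return reallocate(reference, to_part, from_part, -minutes)
    mins = reference.minutes.copy()
    i, j = PARTS.index(from_part), PARTS.index(to_part)
    if minutes >= mins[i]:
        raise ReallocationError(
            f"cannot move {minutes:g} min out of {from_part!r}, which has "
            f"only {mins[i]:g} min"
        )
    mins[i] -= minutes
    mins[j] += minutes
    return Composition.from_minutes(mins, day_minutes=reference.day_minutes)


def predict_change_from_fit(
    fit: ChangeModelFit,
    reference: Composition,
    from_part: str,
    to_part: str,
    minutes: float,
) -> ReallocationEstimate:
    """Model-based prediction with a delta-method 95% CI."""
    new = reallocate(reference, from_part, to_part, minutes)
    basis = ALL_BASES[fit.pivot_part]
    dz = pivot_coordinates(new, basis) - pivot_coordinates(reference, basis)
    gamma = fit.delta_coefficients
    est = float(gamma @ dz)
    var = float(dz @ fit.delta_covariance @ dz)
    tq = scipy.stats.t.ppf(0.975, fit.df_resid)
    half = tq * np.sqrt(var)
    return ReallocationEstimate(
        from_part=from_part,
        to_part=to_part,
        minutes=minutes,
        estimate=est,
        ci_low=est - half,
        ci_high=est + half,
        outcome=fit.outcome,
        reference=reference,
    )


def predict_change_from_first_pivot_betas(
    betas: Iterable[float],
    reference: Composition,
    from_part: str,
    to_part: str,
    minutes: float,
) -> float:
    """Point prediction from four published first-pivot coefficients.

    The betas (canonical behavior order) are rotated to a clr-effect
    vector a = (√3/2)·betas and dotted with the clr difference between the
    reallocated and reference compositions.  No CI: the coefficient
    covariance behind published tables is unavailable.  Betas should sum
    to ~0 (exact for betas taken from a fitted model; rounded published
    values may miss by a little — a warning is emitted beyond 0.05).
    """
    betas = np.asarray(tuple(betas), dtype=float)
    a = clr_coefficients(betas)
    if abs(betas.sum()) > 0.05:
        warnings.warn(
            f"first-pivot betas sum to {betas.sum():.3f}, expected ~0; "
            "check order/rounding",
            stacklevel=2,
        )
    new = reallocate(reference, from_part, to_part, minutes)
    return float(a @ (clr(new) - clr(reference)))


def _grid(cap: float, step: float) -> np.ndarray:
    k = int(np.floor(cap / step))
    return np.arange(-k, k + 1) * step


def substitution_table(
    fit_or_betas: ChangeModelFit | Iterable[float],
    reference: Composition,
    pairs: Sequence[tuple[str, str]] | None = None,
    step: float = 10.0,
    caps: dict[tuple[str, str], float] | None = None,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Predictions on a signed reallocation grid for each ordered pair.

    For pair (from, to), grid point +t moves t minutes from ``from`` to
    ``to``; −t moves them back.  Infeasible grid points (reallocation at
    least as large as the donor behavior's minutes) are skipped.  Defaults:
    all 12 ordered pairs, 10-min steps, caps from :func:`default_cap`.
    """
    if pairs is None:
        pairs = list(permutations(PARTS, 2))
    from_fit = isinstance(fit_or_betas, ChangeModelFit)
    rows = []
    for from_part, to_part in pairs:
        _check_pair(from_part, to_part)
        cap = (caps or {}).get((from_part, to_part), default_cap(from_part, to_part))
        for t in _grid(cap, step):
            try:
                if from_fit:
                    est = predict_change_from_fit(
                        fit_or_betas, reference, from_part, to_part, float(t)
                    )
                    row = est.as_row()
                else:
                    if t == 0:
                        val = 0.0
                    else:
                        val = predict_change_from_first_pivot_betas(
                            fit_or_betas, reference, from_part, to_part, float(t)
                        )
                    row = {
                        "from": from_part,
                        "to": to_part,
                        "minutes": float(t),
                        "estimate": val,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "outcome": outcome,
                    }
            except ReallocationError:
                continue
            rows.append(row)
    return pd.DataFrame(rows)
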