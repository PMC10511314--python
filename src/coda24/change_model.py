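"""Change-on-change regression of obesity indicators on time-use change.

The model regresses the one-year change in an obesity indicator (BMI in
kg/m², waist circumference in cm) on the within-person change in the 24-h
movement-behavior composition, expressed as pivot-coordinate (ilr)
differences:

    Δy_i = β0 + γᵀ Δz_i + δᵀ z_i^pre + λ·y_i^pre
           + covariates (age, sex, occupation [, season, follow-up days])
           + ε_i

where z are the three pivot coordinates of the 4-part composition and
Δz_i = z(post_i) − z(pre_i).  The model is refitted once per pivot basis
(sleep-, SED-, LPA- and MVPA-first); the four fits are orthogonal
reparameterizations of one model (identical fitted values, residuals and
R²), and only the first Δ-coordinate of each fit is reported: the effect of
increasing that behavior relative to the geometric mean of the remaining
three.  The four first-pivot coefficients are a rotation of one underlying
clr-effect vector and sum to zero.

Ordinary least squares with classical (homoskedastic) covariance is used;
statsmodels does the numerical work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .composition import (
    ALL_BASES,
    PARTS,
    Composition,
    PivotBasis,
    compositional_mean,
)
from .cohort import SEASONS, validate_participants

DELTA_COLS = ("d_z1", "d_z2", "d_z3")
BASELINE_COLS = ("base_z1", "base_z2", "base_z3")

#: Scaling between a first pivot coordinate and its clr direction, D = 4.
FIRST_PIVOT_TO_CLR = np.sqrt(3.0) / 2.0


class ModelSpecError(ValueError):
    """The data lack a field the requested model specification needs."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, optional adjustments, optional exclusions.

    outcome
        ``"bmi"`` (kg/m²) or ``"wc"`` (waist circumference, cm).
    adjust_season / adjust_followup
        Sensitivity adjustments: pre-wave measurement season (winter as
        reference) and follow-up time in days.
    exclude_long_sleepers
        Drop participants self-reporting more than ``long_sleep_threshold``
        hours of sleep per night before retirement (default 9 h).
    """

    outcome: str = "bmi"
    adjust_season: bool = False
    adjust_followup: bool = False
    exclude_long_sleepers: bool = False
    long_sleep_threshold: float = 9.0

    def __post_init__(self) -> None:
        if self.outcome not in ("bmi", "wc"):
            raise ValueError(f"outcome must be 'bmi' or 'wc', got {self.outcome!r}")
        if self.long_sleep_threshold <= 0:
            raise ValueError("long_sleep_threshold must be positive")


@dataclass(frozen=True)
class ChangeModelFit:
    """One pivot parameterization of the fitted change-on-change model."""

    pivot_part: str
    outcome: str
    n_used: int
    params: pd.Series
    cov_params: pd.DataFrame
    resid_var: float
    df_resid: int
    rsquared: float
    first_pivot_beta: float
    first_pivot_ci: tuple[float, float]
    first_pivot_p: float
    fitted_values: np.ndarray = field(repr=False, compare=False, default=None)
    residuals: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def delta_coefficients(self) -> np.ndarray:
        """Coefficients of the three Δ-pivot-coordinate terms."""
        return self.params[list(DELTA_COLS)].to_numpy()

    @property
    def delta_covariance(self) -> np.ndarray:
        """Covariance block of the Δ-pivot coefficients."""
        return self.cov_params.loc[list(DELTA_COLS), list(DELTA_COLS)].to_numpy()

    def to_dict(self) -> dict:
        return {
            "pivot_part": self.pivot_part,
            "outcome": self.outcome,
            "n_used": self.n_used,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "covariance": self.cov_params.to_numpy().tolist(),
            "covariance_labels": list(self.cov_params.columns),
            "resid_var": self.resid_var,
            "df_resid": self.df_resid,
            "rsquared": self.rsquared,
            "first_pivot": {
                "beta": self.first_pivot_beta,
                "ci_low": self.first_pivot_ci[0],
                "ci_high": self.first_pivot_ci[1],
                "p_value": self.first_pivot_p,
            },
        }


def apply_spec_filters(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    """Apply the spec's exclusions/complete-case rules; report dropped counts."""
    info: dict = {"n_input": len(df)}
    out = df
    if spec.exclude_long_sleepers:
        if "selfreport_sleep_pre" not in out.columns or out["selfreport_sleep_pre"].isna().all():
            raise ModelSpecError(
                "exclude_long_sleepers requires the selfreport_sleep_pre column"
            )
        keep = ~(out["selfreport_sleep_pre"] > spec.long_sleep_threshold)
        info["n_long_sleepers_dropped"] = int((~keep).sum())
        out = out[keep]
    required = []
    if spec.adjust_season:
        if "season_pre" not in out.columns:
            raise ModelSpecError("adjust_season requires the season_pre column")
        required.append("season_pre")
    if spec.adjust_followup:
        if "followup_days" not in out.columns:
            raise ModelSpecError("adjust_followup requires the followup_days column")
        required.append("followup_days")
    if required:
        keep = out[required].notna().all(axis=1)
        info["n_incomplete_dropped"] = int((~keep).sum())
        out = out[keep]
    info["n_used"] = len(out)
    return out.reset_index(drop=True), info


def build_design(
    df: pd.DataFrame, basis: PivotBasis, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Response vector and labeled predictor matrix for one pivot basis.

    Response: outcome_post − outcome_pre.  Predictors: Δ pivot coordinates
    (equivalently the pivot coordinates of post ⊖ pre), baseline pivot
    coordinates, baseline outcome, age, sex (woman = 1), occupation
    (manual = 1), plus optional season dummies (winter reference) and
    follow-up days.  No intercept column; the fitter adds it.
    """
    data, info = apply_spec_filters(df, spec)
    if data.empty:
        raise ModelSpecError("no rows remain after specification filters")
    V = basis.contrast_matrix
    log_pre = np.log(data[[f"{p}_min_pre" for p in PARTS]].to_numpy(dtype=float))
    log_post = np.log(data[[f"{p}_min_post" for p in PARTS]].to_numpy(dtype=float))
    clr_pre = log_pre - log_pre.mean(axis=1, keepdims=True)
    clr_post = log_post - log_post.mean(axis=1, keepdims=True)
    z_pre = clr_pre @ V
    z_post = clr_post @ V
    X = pd.DataFrame(index=data.index)
    for j, col in enumerate(DELTA_COLS):
        X[col] = z_post[:, j] - z_pre[:, j]
    for j, col in enumerate(BASELINE_COLS):
        X[col] = z_pre[:, j]
    X["base_outcome"] = data[f"{spec.outcome}_pre"]
    X["age"] = data["age"]
    X["sex_woman"] = (data["sex"] == "woman").astype(float)
    X["occ_manual"] = (data["occupation"] == "manual").astype(float)
    if spec.adjust_season:
        for season in SEASONS[1:]:  # winter is the reference level
            X[f"season_{season}"] = (data["season_pre"] == season).astype(float)
    if spec.adjust_followup:
        X["followup_days"] = data["followup_days"].astype(float)
    y = (data[f"{spec.outcome}_post"] - data[f"{spec.outcome}_pre"]).rename(
        f"d_{spec.outcome}"
    )
    return y, X, info


def _check_full_rank(X: pd.DataFrame) -> None:
    Xc = sm.add_constant(X, has_constant="add")
    arr = Xc.to_numpy()
    _, R = np.linalg.qr(arr)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps * 100
    bad = [Xc.columns[i] for i in np.where(diag < tol)[0]]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_ols(
    y: pd.Series, X: pd.DataFrame, pivot_part: str, outcome: str
) -> ChangeModelFit:
    """OLS fit with classical covariance; CI/p for the first Δ-pivot term."""
    n, p = X.shape[0], X.shape[1] + 1
    if n <= p:
        raise ModelSpecError(f"n = {n} rows cannot identify {p} coefficients")
    _check_full_rank(X)
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    ci = res.conf_int(alpha=0.05)
    first = DELTA_COLS[0] if DELTA_COLS[0] in X.columns else X.columns[0]
    return ChangeModelFit(
        pivot_part=pivot_part,
        outcome=outcome,
        n_used=int(n),
        params=res.params,
        cov_params=res.cov_params(),
        resid_var=float(res.mse_resid),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        first_pivot_beta=float(res.params[first]),
        first_pivot_ci=(float(ci.loc[first, 0]), float(ci.loc[first, 1])),
        first_pivot_p=float(res.pvalues[first]),
        fitted_values=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def fit_all_pivots(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[dict[str, ChangeModelFit], pd.DataFrame]:
    """Fit the model once per behavior-first pivot basis.

    Returns the four fits keyed by pivot behavior and a summary table with
    one row per behavior: the first-pivot coefficient ("behavior vs
    remaining, difference"), its 95% CI and two-sided p-value.
    """
    fits: dict[str, ChangeModelFit] = {}
    rows = []
    for part in PARTS:
        fit = fit_ols(*(build_design(df, ALL_BASES[part], spec)[:2]),
                      pivot_part=part, outcome=spec.outcome)
        fits[part] = fit
        rows.append(
            {
                "pivot_part": part,
                "contrast": f"{part} vs remaining, difference",
                "outcome": spec.outcome,
                "beta": fit.first_pivot_beta,
                "ci_low": fit.first_pivot_ci[0],
                "ci_high": fit.first_pivot_ci[1],
                "p_value": fit.first_pivot_p,
                "n_used": fit.n_used,
            }
        )
    return fits, pd.DataFrame(rows)


def first_pivot_betas(fits: Mapping[str, ChangeModelFit]) -> np.ndarray:
    """The four first-pivot coefficients in canonical behavior order."""
    return np.array([fits[p].first_pivot_beta for p in PARTS])


def clr_coefficients(
    fits_or_betas: Mapping[str, ChangeModelFit] | Iterable[float],
) -> np.ndarray:
    """Basis-free clr representation of the Δ-composition effect.

    For D = 4, clr effect a_j = (√3/2) · (first-pivot beta of behavior j).
    Accepts the fits from :func:`fit_all_pivots` or four externally
    supplied first-pivot coefficients (e.g. from a published table).
    """
    if isinstance(fits_or_betas, Mapping):
        betas = first_pivot_betas(fits_or_betas)
    else:
        betas = np.asarray(tuple(fits_or_betas), dtype=float)
        if betas.size != 4:
            raise ValueError("expected four first-pivot coefficients")
    return FIRST_PIVOT_TO_CLR * betas


class CompositionalChangeRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style front end to the change-on-change model.

    ``fit`` takes a validated participant table (the DataFrame dialect of
    :mod:`coda24.cohort`) and fits the pivot-coordinate change model for
    one outcome under the requested specification; ``predict`` returns the
    expected outcome change for (new) participants.  Reallocation
    predictions are exposed via :meth:`predict_reallocation` and
    :meth:`substitution_table`.

    Parameters mirror :class:`ModelSpec`.

    Attributes
    ----------
    fits_ : dict[str, ChangeModelFit]
        One fit per behavior-first pivot basis.
    summary_ : pandas.DataFrame
        Table of first-pivot contrasts (beta, 95% CI, p) per behavior.
    clr_effect_ : ndarray of shape (4,)
        The Δ-composition effect rotated to clr space; sums to 0.
    reference_composition_ : Composition
        Compositional mean of the pre-retirement wave of the training data
        (default reference for reallocations).
    n_used_ : int
    """

    def __init__(
        self,
        outcome: str = "bmi",
        adjust_season: bool = False,
        adjust_followup: bool = False,
        exclude_long_sleepers: bool = False,
        long_sleep_threshold: float = 9.0,
    ):
        self.outcome = outcome
        self.adjust_season = adjust_season
        self.adjust_followup = adjust_followup
        self.exclude_long_sleepers = exclude_long_sleepers
        self.long_sleep_threshold = long_sleep_threshold

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            outcome=self.outcome,
            adjust_season=self.adjust_season,
            adjust_followup=self.adjust_followup,
            exclude_long_sleepers=self.exclude_long_sleepers,
            long_sleep_threshold=self.long_sleep_threshold,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "CompositionalChangeRegressor":
        """Fit on a participant table; ``y`` is ignored (derived from X)."""
        X = validate_participants(X.copy())
        spec = self._spec()
        self.fits_, self.summary_ = fit_all_pivots(X, spec)
        self.clr_effect_ = clr_coefficients(self.fits_)
        self.n_used_ = self.fits_[PARTS[0]].n_used
        data, self.filter_info_ = apply_spec_filters(X, spec)
        self.reference_composition_ = compositional_mean(
            [
                Composition.from_minutes(m)
                for m in data[[f"{p}_min_pre" for p in PARTS]].to_numpy(dtype=float)
            ]
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted outcome change for each participant row."""
        self._check_fitted()
        spec = self._spec()
        _, design, _ = build_design(X, ALL_BASES[PARTS[0]], spec)
        fit = self.fits_[PARTS[0]]
        Xc = sm.add_constant(design, has_constant="add")
        return Xc.to_numpy() @ fit.params[Xc.columns].to_numpy()

    def predict_reallocation(self, from_part: str, to_part: str, minutes: float,
                             reference: Composition | None = None):
        """Predicted outcome change (with CI) for a one-to-one reallocation."""
        from .substitution import predict_change_from_fit

        self._check_fitted()
        ref = reference if reference is not None else self.reference_composition_
        return predict_change_from_fit(
            self.fits_[PARTS[0]], ref, from_part, to_part, minutes
        )

    def substitution_table(self, pairs=None, step: float = 10.0,
                           reference: Composition | None = None) -> pd.DataFrame:
        """Signed reallocation grid for the requested behavior pairs."""
        from .substitution import substitution_table

        self._check_fitted()
        ref = reference if reference is not None else self.reference_composition_
        return substitution_table(self.fits_[PARTS[0]], ref, pairs=pairs, step=step)

    def _check_fitted(self) -> None:
        if not hasattr(self, "fits_"):
            raise RuntimeError("this CompositionalChangeRegressor is not fitted yet")
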