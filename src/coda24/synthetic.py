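"""Synthetic two-wave cohort generator.

Emulates a retirement-transition accelerometer cohort: 4-part daily
time-use compositions before and after retirement, concurrent BMI and
waist-circumference measurements, and baseline covariates, with the
statistical structure the change-on-change analysis assumes.

Compositions are logistic-normal: pre-retirement pivot coordinates
(sleep-first basis) are Gaussian around the pivot coordinates of the
target pre-retirement center, and the compositional change is an
independent Gaussian draw in the same coordinates around the difference
between the post- and pre-retirement centers; the post composition is the
perturbation of the two.  This guarantees strictly positive minutes.
Outcome changes are generated from the linear model the analysis fits:

    Δy = β0 + aᵀ(clr(post) − clr(pre)) + δᵀ z_pre + covariate effects + ε

with a known clr-effect vector ``a`` (summing to zero), so parameter
recovery can be checked end to end.  The intercept is solved so the mean
outcome change at the center of the design matches the target drift
(default −0.1 kg/m² for BMI, −0.9 cm for waist circumference).

Default sizes and moments mirror the cohort the analysis was designed
around: n = 213, centers (497, 584, 282, 77) and (520, 572, 272, 76)
minutes, BMI 26.3 (SD 4.8) kg/m², WC 91.4 (SD 13.0) cm, age 63.5 (SD 1.1),
82% women, 31% manual workers, 12% long sleepers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import (
    ALL_BASES,
    DAY_MINUTES,
    PARTS,
    Composition,
    clr,
    inverse_pivot,
    pivot_coordinates,
)
from .cohort import SEASONS

_SLEEP_BASIS = ALL_BASES["sleep"]

# Published first-pivot contrasts used as default effect sizes, rotated to
# clr space; the BMI column's rounded values sum to -0.01, so they are
# centered before scaling to satisfy the zero-sum constraint exactly.
_BMI_BETAS = np.array([1.34, -0.09, -0.66, -0.60])
_WC_BETAS = np.array([1.51, 2.39, -1.76, -2.14])
_S = np.sqrt(3.0) / 2.0
DEFAULT_CLR_EFFECT_BMI = tuple(_S * (_BMI_BETAS - _BMI_BETAS.mean()))
DEFAULT_CLR_EFFECT_WC = tuple(_S * (_WC_BETAS - _WC_BETAS.mean()))


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 213
    seed: int = 0
    pre_mean_minutes: Sequence[float] = (497.0, 584.0, 282.0, 77.0)
    post_mean_minutes: Sequence[float] = (520.0, 572.0, 272.0, 76.0)
    #: SDs of the sleep-first pivot coordinates of the pre composition.
    pre_ilr_sd: Sequence[float] = (0.20, 0.25, 0.35)
    #: SDs of the sleep-first pivot coordinates of the change.
    delta_ilr_sd: Sequence[float] = (0.10, 0.12, 0.20)
    #: Correlation between baseline and change pivot coordinates (per axis).
    baseline_change_corr: float = 0.0
    true_clr_effect: Sequence[float] = DEFAULT_CLR_EFFECT_BMI
    baseline_effect: Sequence[float] = (0.0, 0.0, 0.0)
    outcome_pre_mean: float = 26.3
    outcome_pre_sd: float = 4.8
    outcome_drift: float = -0.1
    residual_sd: float = 1.0
    # waist-circumference channel
    wc_true_clr_effect: Sequence[float] = DEFAULT_CLR_EFFECT_WC
    wc_pre_mean: float = 91.4
    wc_pre_sd: float = 13.0
    wc_drift: float = -0.9
    wc_residual_sd: float = 4.0
    # covariates
    age_mean: float = 63.5
    age_sd: float = 1.1
    p_woman: float = 0.82
    p_manual: float = 0.31
    age_effect: float = 0.0
    sex_effect: float = 0.0
    occupation_effect: float = 0.0
    p_long_sleeper: float = 0.12
    followup_days_mean: float = 365.0
    followup_days_sd: float = 21.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name in ("pre_ilr_sd", "delta_ilr_sd"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} entries must be >= 0")
        for name in ("true_clr_effect", "wc_true_clr_effect"):
            eff = np.asarray(getattr(self, name), dtype=float)
            if eff.size != 4 or abs(eff.sum()) > 1e-10:
                raise ValueError(f"{name} must be a 4-vector summing to 0")
        if not -1.0 < self.baseline_change_corr < 1.0:
            raise ValueError("baseline_change_corr must be in (-1, 1)")
        if self.residual_sd < 0 or self.wc_residual_sd < 0:
            raise ValueError("residual SDs must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in d.items()}


def _clr_matrix(minutes: np.ndarray) -> np.ndarray:
    logs = np.log(minutes)
    return logs - logs.mean(axis=1, keepdims=True)


def generate_cohort(params: GeneratorParams | None = None, **overrides) -> pd.DataFrame:
    """Draw a synthetic participant table (the CSV dialect of cohort I/O).

    Fully reproducible from ``params.seed``; keyword overrides are applied
    on top of ``params`` (or the defaults).
    """
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        params = GeneratorParams(**{**params.to_dict(), **overrides})
    rng = np.random.default_rng(params.seed)
    n = params.n

    z_pre_center = pivot_coordinates(
        Composition.from_minutes(params.pre_mean_minutes), _SLEEP_BASIS
    )
    z_post_center = pivot_coordinates(
        Composition.from_minutes(params.post_mean_minutes), _SLEEP_BASIS
    )
    dz_center = z_post_center - z_pre_center

    eps_pre = rng.standard_normal((n, 3))
    eps_dz = rng.standard_normal((n, 3))
    rho = params.baseline_change_corr
    if rho:
        eps_dz = rho * eps_pre + np.sqrt(1 - rho**2) * eps_dz
    z_pre = z_pre_center + eps_pre * np.asarray(params.pre_ilr_sd)
    dz = dz_center + eps_dz * np.asarray(params.delta_ilr_sd)
    z_post = z_pre + dz

    V = _SLEEP_BASIS.contrast_matrix
    pre_min = np.exp(z_pre @ V.T)
    pre_min = pre_min / pre_min.sum(axis=1, keepdims=True) * DAY_MINUTES
    post_min = np.exp(z_post @ V.T)
    post_min = post_min / post_min.sum(axis=1, keepdims=True) * DAY_MINUTES
    d_clr = _clr_matrix(post_min) - _clr_matrix(pre_min)

    age = rng.normal(params.age_mean, params.age_sd, n)
    woman = rng.random(n) < params.p_woman
    manual = rng.random(n) < params.p_manual
    season = rng.choice(SEASONS, size=n)
    followup = np.maximum(
        np.rint(rng.normal(params.followup_days_mean, params.followup_days_sd, n)), 1
    ).astype(int)
    # self-reported nightly sleep: a p_long_sleeper fraction above 9 h
    sleep_sr = np.minimum(rng.normal(7.4, 0.7, n), 9.0)
    long_ = rng.random(n) < params.p_long_sleeper
    sleep_sr[long_] = rng.uniform(9.1, 10.5, long_.sum())
    sleep_sr = np.round(np.maximum(sleep_sr, 4.0), 1)

    cov_term = (
        params.age_effect * (age - params.age_mean)
        + params.sex_effect * woman
        + params.occupation_effect * manual
    )
    base_term = (z_pre - z_pre_center) @ np.asarray(params.baseline_effect)

    def _outcome(pre_mean, pre_sd, effect, drift, resid_sd):
        pre = rng.normal(pre_mean, pre_sd, n)
        a = np.asarray(effect, dtype=float)
        intercept = drift - a @ (
            clr(Composition.from_minutes(params.post_mean_minutes))
            - clr(Composition.from_minutes(params.pre_mean_minutes))
        )
        delta = intercept + d_clr @ a + base_term + cov_term
        delta = delta + rng.normal(0.0, resid_sd, n)
        return pre, pre + delta

    bmi_pre, bmi_post = _outcome(
        params.outcome_pre_mean, params.outcome_pre_sd,
        params.true_clr_effect, params.outcome_drift, params.residual_sd,
    )
    wc_pre, wc_post = _outcome(
        params.wc_pre_mean, params.wc_pre_sd,
        params.wc_true_clr_effect, params.wc_drift, params.wc_residual_sd,
    )

    df = pd.DataFrame({"id": [f"P{i + 1:04d}" for i in range(n)]})
    for j, p in enumerate(PARTS):
        df[f"{p}_min_pre"] = pre_min[:, j]
    for j, p in enumerate(PARTS):
        df[f"{p}_min_post"] = post_min[:, j]
    df["bmi_pre"] = bmi_pre
    df["bmi_post"] = bmi_post
    df["wc_pre"] = wc_pre
    df["wc_post"] = wc_post
    df["age"] = age
    df["sex"] = np.where(woman, "woman", "man")
    df["occupation"] = np.where(manual, "manual", "non_manual")
    df["season_pre"] = season
    df["followup_days"] = followup
    df["selfreport_sleep_pre"] = sleep_sr
    return df


def make_daily_records(
    participants: pd.DataFrame,
    days_per_wave: int = 4,
    jitter_ilr_sd: float = 0.10,
    wear_mean_hours: float = 15.5,
    wear_sd_hours: float = 0.7,
    fraction_invalid: float = 0.0,
    min_hours: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day wear records around each participant-wave composition.

    Day compositions are jittered in pivot-coordinate space (SD
    ``jitter_ilr_sd``; 0 reproduces the wave composition exactly).  Waking
    wear hours are Gaussian; a ``fraction_invalid`` share of days is
    forced below ``min_hours`` so the validity filter has work to do.
    """
    if days_per_wave < 1:
        raise ValueError("days_per_wave must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in participants.iterrows():
        for wave, start in (("pre", "2018-01-08"), ("post", "2019-01-07")):
            base = Composition.from_minutes(
                [row[f"{p}_min_{wave}"] for p in PARTS]
            )
            z0 = pivot_coordinates(base, _SLEEP_BASIS)
            dates = pd.date_range(start, periods=days_per_wave, freq="D")
            for d in range(days_per_wave):
                z = z0 + rng.normal(0.0, jitter_ilr_sd, 3)
                day = inverse_pivot(z, _SLEEP_BASIS)
                wear = rng.normal(wear_mean_hours, wear_sd_hours)
                wear = float(np.clip(wear, min_hours, 20.0))
                if rng.random() < fraction_invalid:
                    wear = float(rng.uniform(6.0, min_hours - 0.1))
                rec = {
                    "id": row["id"],
                    "wave": wave,
                    "date": dates[d].date().isoformat(),
                    "wear_hours_waking": round(wear, 2),
                }
                rec.update(
                    {f"{p}_min": m for p, m in zip(PARTS, day.minutes)}
                )
                rows.append(rec)
    return pd.DataFrame(rows)
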