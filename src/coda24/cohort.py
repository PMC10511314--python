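"""Participant-table I/O, valid-day filtering, change groups and descriptives.

The cohort is a two-wave (pre/post retirement) panel: each participant has
an accelerometer-derived 4-part time-use composition, measured BMI and
waist circumference at both waves, and baseline covariates.  This module
reads and validates that table, applies the wear-time validity rules
(a measurement day counts if waking wear time is at least 10 h; a
participant is analyzable only with at least 3 valid days in both waves),
classifies participants into obesity-indicator change groups, and computes
the descriptive summary and ternary-plot coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .composition import (
    PARTS,
    Composition,
    CompositionError,
    closure,
    compositional_mean,
    perturbation_difference,
)

# -- table schemas ---------------------------------------------------------

SEXES = ("woman", "man")
OCCUPATIONS = ("manual", "non_manual")
SEASONS = ("winter", "spring", "summer", "autumn")
WAVES = ("pre", "post")

#: Outcome-change cutpoints delimiting the "no change" band.
CHANGE_CUTPOINTS = {"bmi": 0.5, "wc": 3.0}
CHANGE_LABELS = ("decrease", "no_change", "increase")

_BEHAVIOR_COLS = {
    wave: [f"{p}_min_{wave}" for p in PARTS] for wave in WAVES
}
MANDATORY_COLUMNS = (
    ["id"]
    + _BEHAVIOR_COLS["pre"]
    + _BEHAVIOR_COLS["post"]
    + ["bmi_pre", "bmi_post", "wc_pre", "wc_post", "age", "sex", "occupation"]
)
OPTIONAL_COLUMNS = ("season_pre", "followup_days", "selfreport_sleep_pre")

DAYS_COLUMNS = (
    ["id", "wave", "date", "wear_hours_waking"]
    + [f"{p}_min" for p in PARTS]
)


class CohortValidationError(ValueError):
    """Participant-table validation failure; message lists row and field."""


@dataclass(frozen=True)
class ParticipantRecord:
    """Typed view of one participant row."""

    id: str
    pre_composition: Composition
    post_composition: Composition
    bmi_pre: float
    bmi_post: float
    wc_pre: float
    wc_post: float
    age: float
    sex: str
    occupation: str
    season_pre: str | None = None
    followup_days: int | None = None
    selfreport_sleep_pre: float | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "ParticipantRecord":
        def opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        fd = opt("followup_days")
        return cls(
            id=str(row["id"]),
            pre_composition=Composition.from_minutes(
                [row[c] for c in _BEHAVIOR_COLS["pre"]]
            ),
            post_composition=Composition.from_minutes(
                [row[c] for c in _BEHAVIOR_COLS["post"]]
            ),
            bmi_pre=float(row["bmi_pre"]),
            bmi_post=float(row["bmi_post"]),
            wc_pre=float(row["wc_pre"]),
            wc_post=float(row["wc_post"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            occupation=str(row["occupation"]),
            season_pre=opt("season_pre"),
            followup_days=None if fd is None else int(fd),
            selfreport_sleep_pre=opt("selfreport_sleep_pre"),
        )


def validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a participant table in place; return it on success.

    Collects every row-level problem (zero/negative behavior minutes,
    nonpositive BMI/WC, unknown factor levels) and raises one error
    listing all of them with row numbers.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {missing}")
    problems: list[str] = []
    for wave in WAVES:
        for part, col in zip(PARTS, _BEHAVIOR_COLS[wave]):
            bad = df.index[~(df[col] > 0)]
            problems += [
                f"row {i}: {part} ({col}) must be > 0, got {df.at[i, col]!r}"
                for i in bad
            ]
    for col in ("bmi_pre", "bmi_post", "wc_pre", "wc_post"):
        bad = df.index[~(df[col] > 0)]
        problems += [f"row {i}: {col} must be > 0" for i in bad]
    for col, levels in (("sex", SEXES), ("occupation", OCCUPATIONS)):
        bad = df.index[~df[col].isin(levels)]
        problems += [
            f"row {i}: {col}={df.at[i, col]!r} not in allowed levels {levels}"
            for i in bad
        ]
    if "season_pre" in df.columns:
        bad = df.index[df["season_pre"].notna() & ~df["season_pre"].isin(SEASONS)]
        problems += [
            f"row {i}: season_pre={df.at[i, 'season_pre']!r} not in {SEASONS}"
            for i in bad
        ]
    if "followup_days" in df.columns:
        bad = df.index[df["followup_days"].notna() & ~(df["followup_days"] > 0)]
        problems += [f"row {i}: followup_days must be > 0" for i in bad]
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].tolist()
        problems.append(f"duplicate participant ids: {dup}")
    if problems:
        raise CohortValidationError(
            "participant table invalid:\n  " + "\n  ".join(problems)
        )
    return df


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a participants CSV (see docs for the schema)."""
    df = pd.read_csv(path, dtype={"id": str})
    return validate_participants(df)


def iter_records(df: pd.DataFrame) -> Iterator[ParticipantRecord]:
    """Yield typed :class:`ParticipantRecord` views of a validated table."""
    for _, row in df.iterrows():
        yield ParticipantRecord.from_row(row)


def wave_composition(row: pd.Series, wave: str) -> Composition:
    """The 4-part composition of one participant row at one wave."""
    return Composition.from_minutes([row[c] for c in _BEHAVIOR_COLS[wave]])


# -- valid-day filtering ---------------------------------------------------

def read_days(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in DAYS_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"days table missing columns: {missing}")
    bad = df.index[~df["wave"].isin(WAVES)]
    if len(bad):
        raise CohortValidationError(f"rows {list(bad)}: wave must be in {WAVES}")
    return df


def filter_valid_days(
    days: pd.DataFrame, min_hours: float = 10.0, min_days: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the wear-time validity rules.

    A day is valid iff ``wear_hours_waking >= min_hours`` (boundary
    inclusive); a participant is excluded iff either wave has fewer than
    ``min_days`` valid days.

    Returns
    -------
    valid_days
        The valid subset of ``days`` (same columns).
    status
        One row per participant: valid-day counts per wave and an
        ``excluded`` flag.
    """
    if days.empty:
        status = pd.DataFrame(
            columns=["id", "valid_days_pre", "valid_days_post", "excluded"]
        )
        return days.copy(), status
    valid = days[days["wear_hours_waking"] >= min_hours].copy()
    counts = (
        valid.groupby(["id", "wave"]).size().unstack("wave", fill_value=0)
        .reindex(columns=list(WAVES), fill_value=0)
        .reindex(days["id"].unique(), fill_value=0)
    )
    status = pd.DataFrame(
        {
            "id": counts.index,
            "valid_days_pre": counts["pre"].to_numpy(),
            "valid_days_post": counts["post"].to_numpy(),
        }
    ).reset_index(drop=True)
    status["excluded"] = (status["valid_days_pre"] < min_days) | (
        status["valid_days_post"] < min_days
    )
    return valid, status


def average_behaviors(
    valid_days: pd.DataFrame, compositional: bool = False
) -> Composition:
    """Average one participant-wave's valid days into a composition.

    Plain arithmetic mean of each behavior's minutes across days, then
    closure; ``compositional=True`` switches to the geometric
    (compositional-mean) alternative.
    """
    if valid_days.empty:
        raise CohortValidationError("no valid days to average")
    cols = [f"{p}_min" for p in PARTS]
    if compositional:
        return compositional_mean(
            [Composition.from_minutes(r) for r in valid_days[cols].to_numpy()]
        )
    return Composition.from_minutes(valid_days[cols].mean(axis=0).to_numpy())


# -- change groups ---------------------------------------------------------

def classify_change(delta: float, outcome: str) -> str:
    """Label an outcome change as decrease / no_change / increase.

    The no-change band is |Δ| < cutpoint (0.5 kg/m² for BMI, 3.0 cm for
    waist circumference); ties at the cutpoint go to decrease/increase.
    """
    if outcome not in CHANGE_CUTPOINTS:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {tuple(CHANGE_CUTPOINTS)}"
        )
    if not np.isfinite(delta):
        raise ValueError("outcome change must be finite")
    cut = CHANGE_CUTPOINTS[outcome]
    if delta <= -cut:
        return "decrease"
    if delta >= cut:
        return "increase"
    return "no_change"


def change_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant change-group labels for both outcomes."""
    out = pd.DataFrame({"id": df["id"]})
    out["bmi_change"] = df["bmi_post"] - df["bmi_pre"]
    out["wc_change"] = df["wc_post"] - df["wc_pre"]
    out["bmi_group"] = [classify_change(d, "bmi") for d in out["bmi_change"]]
    out["wc_group"] = [classify_change(d, "wc") for d in out["wc_change"]]
    return out


# -- ternary geometry ------------------------------------------------------

def subcomposition(x: Composition, keep: Sequence[str]) -> np.ndarray:
    """Closed 3-part subcomposition of the named behaviors (in given order)."""
    keep = tuple(keep)
    if len(keep) != 3 or len(set(keep)) != 3:
        raise CompositionError(f"keep must name 3 distinct behaviors, got {keep}")
    for name in keep:
        if name not in x.parts:
            raise CompositionError(f"unknown behavior {name!r}")
    sub = np.array([x[name] for name in keep])
    return sub / sub.sum()


def ternary_xy(p: Iterable[float]) -> tuple[float, float]:
    """Map a closed 3-vector onto the unit-side ternary triangle.

    Vertices: part1 at (0, 0), part2 at (1, 0), part3 at (0.5, √3/2).
    """
    p = np.asarray(tuple(p), dtype=float)
    if p.size != 3:
        raise CompositionError("ternary_xy expects a 3-part vector")
    x = p[1] + p[2] / 2.0
    y = p[2] * np.sqrt(3.0) / 2.0
    return float(x), float(y)


def ternary_table(
    df: pd.DataFrame, keep: Sequence[str]
) -> pd.DataFrame:
    """Plot-ready ternary coordinates of per-participant compositional change.

    For each participant the compositional difference post ⊖ pre is reduced
    to the 3-part subcomposition ``keep`` and projected to (x, y), together
    with both change-group labels.  The no-change point (equal change
    composition) maps to the triangle centroid.
    """
    groups = change_groups(df)
    rows = []
    for (_, row), (_, grp) in zip(df.iterrows(), groups.iterrows()):
        diff = perturbation_difference(
            wave_composition(row, "post"), wave_composition(row, "pre")
        )
        sub = subcomposition(diff, keep)
        x, y = ternary_xy(sub)
        rows.append(
            {
                "id": row["id"],
                **{f"change_{k}": v for k, v in zip(keep, sub)},
                "x": x,
                "y": y,
                "bmi_group": grp["bmi_group"],
                "wc_group": grp["wc_group"],
            }
        )
    return pd.DataFrame(rows)


# -- descriptives ----------------------------------------------------------

_BMI_BINS = (
    ("normal_weight", -np.inf, 25.0),  # underweight folded into normal
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, np.inf),
)


def _bmi_category_counts(values: pd.Series) -> dict[str, dict[str, float]]:
    n = len(values)
    out = {}
    for name, lo, hi in _BMI_BINS:
        count = int(((values >= lo) & (values < hi)).sum())
        out[name] = {"n": count, "percent": 100.0 * count / n}
    return out


def describe_cohort(df: pd.DataFrame) -> dict:
    """Descriptive summary of the cohort (means/SDs, categories, centers).

    Continuous characteristics as mean (SD); BMI categories in the
    half-open bins [<25, 25–30, ≥30) with underweight tallied inside the
    normal-weight row; the per-wave compositional mean reported in
    minutes/day.
    """
    if df.empty:
        raise CohortValidationError("cannot describe an empty cohort")
    n = len(df)
    summary: dict = {"n": n}
    summary["age"] = {"mean": float(df["age"].mean()), "sd": float(df["age"].std(ddof=1)) if n > 1 else 0.0}
    summary["sex"] = {
        s: {"n": int((df["sex"] == s).sum()), "percent": 100.0 * float((df["sex"] == s).mean())}
        for s in SEXES
    }
    summary["occupation"] = {
        o: {"n": int((df["occupation"] == o).sum()), "percent": 100.0 * float((df["occupation"] == o).mean())}
        for o in OCCUPATIONS
    }
    for wave in WAVES:
        block: dict = {}
        for var, col in (("bmi", f"bmi_{wave}"), ("wc", f"wc_{wave}")):
            block[var] = {
                "mean": float(df[col].mean()),
                "sd": float(df[col].std(ddof=1)) if n > 1 else 0.0,
            }
        block["bmi_categories"] = _bmi_category_counts(df[f"bmi_{wave}"])
        center = compositional_mean(
            [wave_composition(row, wave) for _, row in df.iterrows()]
        )
        block["compositional_mean_min"] = center.as_dict(minutes=True)
        summary[wave] = block
    return summary


def summary_to_text(summary: dict) -> str:
    """Aligned-text rendering of :func:`describe_cohort` output."""
    lines = [f"Cohort summary (n = {summary['n']})", ""]
    lines.append(f"{'Age, mean (SD)':<38}{summary['age']['mean']:.1f} ({summary['age']['sd']:.1f})")
    for s, d in summary["sex"].items():
        lines.append(f"{s.capitalize() + ', n (%)':<38}{d['n']} ({d['percent']:.0f})")
    for o, d in summary["occupation"].items():
        lines.append(f"{o.replace('_', '-').capitalize() + ', n (%)':<38}{d['n']} ({d['percent']:.0f})")
    for wave in WAVES:
        blk = summary[wave]
        lines.append("")
        lines.append(f"{wave.capitalize()}-retirement wave")
        lines.append(f"{'  BMI, mean (SD), kg/m2':<38}{blk['bmi']['mean']:.1f} ({blk['bmi']['sd']:.1f})")
        for name, d in blk["bmi_categories"].items():
            lines.append(f"{'    ' + name.replace('_', ' '):<38}{d['n']} ({d['percent']:.0f}%)")
        lines.append(f"{'  Waist circumference, mean (SD), cm':<38}{blk['wc']['mean']:.1f} ({blk['wc']['sd']:.1f})")
        mins = blk["compositional_mean_min"]
        comp = ", ".join(f"{mins[p]:.0f}" for p in PARTS)
        lines.append(f"{'  Compositional mean (sleep/SED/LPA/MVPA), min':<38}{comp}")
    return "\n".join(lines)


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2)
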