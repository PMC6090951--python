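"""BMI, LMS growth-reference Z-scores, and conditional relative weight gain.

Conditional relative weight gain for a growth period is the standardized
residual (SR) from a sex-specific OLS regression of the period-end weight
on all earlier anchor weights, earlier anchor heights, and period-end
height. By construction SR is uncorrelated with earlier size and with
linear growth, which removes the overestimation that correlated repeated
weight measures would otherwise induce.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthPeriod",
    "default_periods",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "add_bmi_zscores",
    "select_period_measurements",
    "conditional_weight_gain",
    "cohort_summary",
]


def compute_bmi(weight_kg, height_cm):
    """BMI in kg/m^2 from weight (kg) and height (cm)."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if (w <= 0).any() or (h <= 0).any():
        raise ValueError("weight and height must be positive")
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def _interp_lms(ref: pd.DataFrame, sex: str, age: np.ndarray):
    sub = ref[ref["sex"] == sex].sort_values("age")
    if sub.empty:
        raise ValueError(f"no LMS rows for sex {sex!r}")
    ages = sub["age"].to_numpy(dtype=float)
    if (age < ages[0] - 1e-9).any() or (age > ages[-1] + 1e-9).any():
        raise ValueError(
            f"age outside LMS reference range [{ages[0]}, {ages[-1]}] for sex {sex}"
        )
    L = np.interp(age, ages, sub["L"].to_numpy(dtype=float))
    M = np.interp(age, ages, sub["M"].to_numpy(dtype=float))
    S = np.interp(age, ages, sub["S"].to_numpy(dtype=float))
    return L, M, S


def lms_zscore(x, sex: str, age, ref: pd.DataFrame):
    """LMS (Box-Cox) Z-score of measurement `x` at `age` for `sex`.

    Z = ((x/M)^L - 1) / (L*S) for L != 0, else ln(x/M)/S, with (L, M, S)
    linearly interpolated in age from the reference.
    """
    x = np.asarray(x, dtype=float)
    age = np.asarray(age, dtype=float)
    if (x <= 0).any():
        raise ValueError("measurement must be positive")
    L, M, S = _interp_lms(ref, sex, age)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) > 1e-12,
            ((x / M) ** L - 1.0) / (L * S),
            np.log(x / M) / S,
        )
    return float(z) if z.ndim == 0 else z


def lms_inverse(z, sex: str, age, ref: pd.DataFrame):
    """Measurement value whose LMS Z-score is `z` (inverse transform)."""
    z = np.asarray(z, dtype=float)
    age = np.asarray(age, dtype=float)
    L, M, S = _interp_lms(ref, sex, age)
    x = np.where(
        np.abs(L) > 1e-12,
        M * (1.0 + L * S * z) ** (1.0 / np.where(np.abs(L) > 1e-12, L, 1.0)),
        M * np.exp(S * z),
    )
    return float(x) if x.ndim == 0 else x


def add_bmi_zscores(
    anthro: pd.DataFrame, ref: pd.DataFrame, implausible_z: float = 5.0
) -> pd.DataFrame:
    """Return a copy of the anthro table with bmi, bmi_z and a flag column.

    |Z| > `implausible_z` records are flagged implausible but kept.
    """
    out = anthro.copy()
    out["bmi"] = compute_bmi(out["weight_kg"], out["height_cm"])
    z = np.empty(len(out))
    for sex in out["sex"].unique():
        m = (out["sex"] == sex).to_numpy()
        z[m] = lms_zscore(out.loc[m, "bmi"], sex, out.loc[m, "age_years"], ref)
    out["bmi_z"] = z
    out["implausible"] = np.abs(z) > implausible_z
    return out


@dataclass(frozen=True)
class GrowthPeriod:
    """One conditional-growth period with its regression anchors."""

    name: str
    start_age: float
    end_age: float
    prior_weight_ages: tuple = ()
    prior_height_ages: tuple = ()

    def __post_init__(self) -> None:
        if not self.start_age < self.end_age:
            raise ValueError("start_age must precede end_age")
        for a in self.prior_weight_ages + self.prior_height_ages:
            if a > self.start_age:
                raise ValueError("anchor ages must not exceed the period start")

    @property
    def anchor_ages(self) -> tuple:
        """All distinct ages whose measurements the regression needs."""
        return tuple(sorted(set(self.prior_weight_ages)
                            | set(self.prior_height_ages) | {self.end_age}))


def default_periods(include_birth_length: bool = False) -> list[GrowthPeriod]:
    """Infancy 0-2, early childhood 2-5, mid-childhood 5-8, adolescence 8-15.

    Prior predictors are the weights at all earlier period boundaries and
    the heights at earlier boundaries from age 2 on (birth length excluded
    by default, as its missingness is typically high); the period-end height
    enters every regression.
    """
    bounds = [0.0, 2.0, 5.0, 8.0, 15.0]
    names = ["infancy", "early_childhood", "mid_childhood", "adolescence"]
    periods = []
    for k, name in enumerate(names):
        start, end = bounds[k], bounds[k + 1]
        priors_w = tuple(bounds[: k + 1])
        priors_h = tuple(b for b in bounds[: k + 1] if include_birth_length or b > 0.0)
        periods.append(GrowthPeriod(name, start, end, priors_w, priors_h))
    return periods


def select_period_measurements(
    anthro: pd.DataFrame,
    anchor_ages,
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Wide table of per-subject weight/height at each anchor age.

    For each subject and anchor, the record closest in age within
    +/- tolerance is chosen (ties go to the earlier record); absent anchors
    are left NaN. Columns are ``weight_<age>`` / ``height_<age>`` plus sex.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    anchor_ages = sorted(set(float(a) for a in anchor_ages))
    subjects = anthro[["subject_id", "sex"]].drop_duplicates("subject_id")
    out = subjects.set_index("subject_id")
    for a in anchor_ages:
        d = anthro.assign(_dist=(anthro["age_years"] - a).abs())
        d = d[d["_dist"] <= tolerance + 1e-12]
        # ties in distance resolve to the earlier record
        d = d.sort_values(["subject_id", "_dist", "age_years"])
        pick = d.groupby("subject_id").first()
        out[f"weight_{a:g}"] = pick["weight_kg"]
        out[f"height_{a:g}"] = pick["height_cm"]
    return out.reset_index()


def conditional_weight_gain(
    wide: pd.DataFrame, period: GrowthPeriod
) -> pd.DataFrame:
    """Standardized residuals of period-end weight per sex, pooled.

    Runs, separately within each sex, OLS of ``weight_<end>`` on the prior
    anchor weights, prior anchor heights and ``height_<end>``; residuals are
    divided by their sample SD so each sex contributes mean 0, SD 1. Returns
    columns (subject_id, period, sr, n_used).
    """
    ycol = f"weight_{period.end_age:g}"
    xcols = (
        [f"weight_{a:g}" for a in period.prior_weight_ages]
        + [f"height_{a:g}" for a in period.prior_height_ages]
        + [f"height_{period.end_age:g}"]
    )
    for c in [ycol] + xcols:
        if c not in wide.columns:
            raise ValueError(f"column {c!r} missing from wide table")
    frames = []
    for sex, sub in wide.groupby("sex"):
        cc = sub.dropna(subset=[ycol] + xcols)
        p = len(xcols)
        if len(cc) < p + 2:
            raise ValueError(
                f"period {period.name!r}, sex {sex}: only {len(cc)} complete "
                f"cases for {p} predictors"
            )
        X = np.column_stack([np.ones(len(cc))] + [cc[c].to_numpy(float) for c in xcols])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify the first column that adds no rank
            bad = []
            for k in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, : k + 1]) <= np.linalg.matrix_rank(X[:, :k]):
                    bad.append((["intercept"] + xcols)[k])
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        y = cc[ycol].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sr = resid / resid.std(ddof=1)
        frames.append(pd.DataFrame({
            "subject_id": cc["subject_id"].to_numpy(),
            "period": period.name,
            "sr": sr,
            "n_used": len(cc),
            "sex": sex,
        }))
    return pd.concat(frames, ignore_index=True)


def cohort_summary(
    anthro: pd.DataFrame, ref: pd.DataFrame | None = None, ages=None, tolerance: float = 0.5
) -> pd.DataFrame:
    """Per sex x age descriptive table (mean, SD, n) with M-vs-F p-values.

    Summarizes height, weight, BMI and (when a reference is given) BMI
    Z-score at each requested age; p-values are Welch two-sample t-tests.
    """
    df = anthro.copy()
    df["bmi"] = compute_bmi(df["weight_kg"], df["height_cm"])
    variables = {"height_cm": "height", "weight_kg": "weight", "bmi": "bmi"}
    if ref is not None:
        df = add_bmi_zscores(df, ref)
        variables["bmi_z"] = "bmi_z"
    if ages is None:
        ages = sorted(df["age_years"].round().unique())
    rows = []
    for a in ages:
        at = df[(df["age_years"] - a).abs() <= tolerance]
        for col, label in variables.items():
            m = at.loc[at["sex"] == "M", col].dropna()
            f = at.loc[at["sex"] == "F", col].dropna()
            if len(m) > 1 and len(f) > 1 and (m.std() > 0 or f.std() > 0):
                p = float(stats.ttest_ind(m, f, equal_var=False).pvalue)
            else:
                p = np.nan
            rows.append({
                "age": a, "variable": label,
                "mean_M": m.mean(), "sd_M": m.std(), "n_M": len(m),
                "mean_F": f.mean(), "sd_F": f.std(), "n_F": len(f),
                "p_MF": p,
            })
    return pd.DataFrame(rows)
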