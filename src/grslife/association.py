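"""GRS-phenotype association models.

Cross-sectional per-age OLS of BMI Z-score on the standardized score
(sex-adjusted), a random-intercept linear mixed model with score-by-age
polynomial interactions for the longitudinal profile, a multinomial logit
of trajectory-class membership, and per-variant additive regressions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssocResult",
    "per_age_assoc",
    "age_profile",
    "mixed_longitudinal",
    "trajectory_multinomial",
    "per_snp_assoc",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class AssocResult:
    """One estimated coefficient with Wald inference."""

    term: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int

    @classmethod
    def from_wald(cls, term: str, est: float, se: float, n: int) -> "AssocResult":
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = 2.0 * float(stats.norm.sf(abs(z)))
        return cls(term, float(est), float(se),
                   float(est - _Z975 * se), float(est + _Z975 * se), p, int(n))


def _sex_indicator(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        return (s == "M").astype(float)
    return s.astype(float)


def per_age_assoc(bmi_z, grsz, sex=None, min_n: int = 10) -> AssocResult:
    """OLS of BMI Z-score on wGRSz (plus a sex indicator); wGRSz coefficient."""
    y = np.asarray(bmi_z, dtype=float)
    g = np.asarray(grsz, dtype=float)
    cols = {"grsz": g}
    if sex is not None:
        cols["sex"] = _sex_indicator(sex)
    X = pd.DataFrame(cols)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    if ok.sum() < min_n:
        raise ValueError(f"only {int(ok.sum())} complete cases (need {min_n})")
    X = sm.add_constant(X[ok])
    fit = sm.OLS(y[ok], X).fit()
    return AssocResult.from_wald("grsz", fit.params["grsz"], fit.bse["grsz"], int(ok.sum()))


def age_profile(
    long_table: pd.DataFrame, ages=None, tolerance: float = 0.5
) -> pd.DataFrame:
    """Per-age cross-sectional estimates over a list of assessment ages.

    `long_table` needs columns (subject_id, sex, age_years, bmi_z, grsz).
    Returns one row per age with the wGRSz coefficient and Wald CI — the
    age-resolved association profile.
    """
    if ages is None:
        ages = sorted(long_table["age_years"].round().unique())
    rows = []
    for a in ages:
        at = long_table[(long_table["age_years"] - a).abs() <= tolerance]
        at = at.drop_duplicates("subject_id")
        try:
            r = per_age_assoc(at["bmi_z"], at["grsz"], at["sex"])
        except ValueError:
            continue
        rows.append({"age": a, "estimate": r.estimate, "se": r.se,
                     "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "p": r.p, "n": r.n})
    return pd.DataFrame(rows)


def mixed_longitudinal(
    long_table: pd.DataFrame,
    reml: bool = True,
    center_age: bool = True,
) -> list[AssocResult]:
    """Random-intercept mixed model with wGRSz-by-age polynomial interactions.

    Fits BMI-SDS ~ wGRSz + age + age^2 + age^3 + sex + wGRSz:age +
    wGRSz:age^2 + wGRSz:age^3 with a subject random intercept, by REML
    (``reml=False`` for ML). Age is centered at its sample mean before the
    polynomial and interaction terms are formed, purely for numerical
    conditioning; the linear-interaction coefficient is unchanged by the
    shift and is reported per year of age.
    """
    need = {"subject_id", "age_years", "bmi_z", "grsz", "sex"}
    if not need.issubset(long_table.columns):
        raise ValueError(f"long table needs columns {sorted(need)}")
    df = long_table.dropna(subset=["bmi_z", "grsz", "age_years"]).copy()
    counts = df.groupby("subject_id").size()
    if (counts >= 2).mean() < 0.5:
        raise ValueError("fewer than half of subjects have >= 2 observations")
    a = df["age_years"].to_numpy(float)
    ac = a - a.mean() if center_age else a
    g = df["grsz"].to_numpy(float)
    X = pd.DataFrame({
        "grsz": g,
        "age": ac,
        "age2": ac**2,
        "age3": ac**3,
        "sex": _sex_indicator(df["sex"]),
        "grsz:age": g * ac,
        "grsz:age2": g * ac**2,
        "grsz:age3": g * ac**3,
    }, index=df.index)
    X = sm.add_constant(X)
    model = sm.MixedLM(df["bmi_z"].to_numpy(float), X, groups=df["subject_id"])
    fit = model.fit(reml=reml)
    if not fit.converged:
        raise RuntimeError(f"mixed model did not converge: {fit.summary()}")
    n = int(len(df))
    return [
        AssocResult.from_wald(term, fit.params[term], fit.bse[term], n)
        for term in X.columns
    ]


def trajectory_multinomial(
    labels,
    grsz,
    sex=None,
    class_names=None,
    min_class_n: int = 10,
) -> pd.DataFrame:
    """Multinomial logit of trajectory class on wGRSz (+ sex).

    The first class (index 0 / first of `class_names`) is the reference;
    returns one row per non-reference class with the wGRSz coefficient
    exponentiated to a relative risk ratio per SD of genetic risk, with a
    Wald CI on the ratio scale.
    """
    lab = pd.Series(np.asarray(labels))
    if class_names is None:
        class_names = sorted(lab.unique())
    lab = pd.Categorical(lab, categories=class_names, ordered=True)
    if pd.isna(lab).any():
        raise ValueError("labels outside the declared class set")
    counts = pd.Series(lab).value_counts()
    if (counts < min_class_n).any():
        small = counts[counts < min_class_n].index.tolist()
        raise ValueError(f"classes with < {min_class_n} members: {small}")
    cols = {"grsz": np.asarray(grsz, dtype=float)}
    if sex is not None:
        cols["sex"] = _sex_indicator(sex)
    X = sm.add_constant(pd.DataFrame(cols))
    try:
        fit = sm.MNLogit(lab.codes, X).fit(disp=False, maxiter=200)
    except np.linalg.LinAlgError as e:
        raise RuntimeError(
            "multinomial fit failed (possible separation); consider a "
            "penalized fit or pooling classes"
        ) from e
    params = fit.params  # columns: one per non-reference class
    bse = fit.bse
    rows = []
    for k in range(params.shape[1]):
        est, se = float(params.loc["grsz", k]), float(bse.loc["grsz", k])
        r = AssocResult.from_wald("grsz", est, se, len(lab))
        rows.append({
            "class": class_names[k + 1],
            "log_rrr": r.estimate, "se": r.se,
            "rrr": float(np.exp(r.estimate)),
            "rrr_ci_lo": float(np.exp(r.ci_lo)),
            "rrr_ci_hi": float(np.exp(r.ci_hi)),
            "p": r.p, "n": r.n,
        })
    return pd.DataFrame(rows)


def per_snp_assoc(g, outcome, sex=None) -> pd.DataFrame:
    """Independent additive-dosage OLS per variant with multiplicity columns.

    Monomorphic or all-missing variants are skipped with a notice column.
    Returns per-variant estimate/se/p plus Holm- and Bonferroni-adjusted
    p-values over the tested variants.
    """
    y = np.asarray(outcome, dtype=float)
    s = None if sex is None else _sex_indicator(sex)
    rows = []
    for j, vid in enumerate(g.variant_ids):
        d = g.dosages[:, j]
        ok = np.isfinite(d) & np.isfinite(y)
        if s is not None:
            ok &= np.isfinite(s)
        if ok.sum() < 3 or np.nanstd(d[ok]) == 0:
            rows.append({"snp": vid, "estimate": np.nan, "se": np.nan,
                         "p": np.nan, "n": int(ok.sum()), "note": "monomorphic_or_empty"})
            continue
        cols = {"dosage": d[ok]}
        if s is not None:
            cols["sex"] = s[ok]
        X = sm.add_constant(pd.DataFrame(cols))
        fit = sm.OLS(y[ok], X).fit()
        rows.append({"snp": vid, "estimate": float(fit.params["dosage"]),
                     "se": float(fit.bse["dosage"]),
                     "p": float(fit.pvalues["dosage"]), "n": int(ok.sum()),
                     "note": ""})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_holm"] = np.nan
    out["p_bonferroni"] = np.nan
    if tested.any():
        p = out.loc[tested, "p"].to_numpy()
        out.loc[tested, "p_holm"] = multipletests(p, method="holm")[1]
        out.loc[tested, "p_bonferroni"] = np.minimum(p * tested.sum(), 1.0)
    return out


def plot_age_profile(profile: pd.DataFrame, path=None):
    """Plot the per-age wGRSz effect with 95% CI error bars.

    Matplotlib is imported lazily so the plotting extra is optional at
    run time.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(profile["age"], profile["estimate"],
                yerr=[profile["estimate"] - profile["ci_lo"],
                      profile["ci_hi"] - profile["estimate"]],
                fmt="o", capsize=3)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("BMI Z-score per SD of wGRS")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
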