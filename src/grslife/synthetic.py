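"""Synthetic cohort generator.

Emulates a birth cohort followed annually from birth to age 18 with
genotypes at ~71 BMI risk loci, sex-specific BMI growth, a genetic effect
on BMI standard-deviation scores (SDS) that increases linearly with age,
latent BMI-trajectory classes whose membership odds depend on the genetic
risk score, and a mediation path from the score through adolescent weight
gain to BMI at 18. Every generator is deterministic given its seed, so the
downstream estimators can be tested against known truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, VariantWeight

__all__ = [
    "GrowthParams",
    "ClassParams",
    "MediationSimParams",
    "SimConfig",
    "default_variant_weights",
    "synthetic_lms_reference",
    "median_bmi",
    "median_height",
    "simulate_genotypes",
    "simulate_trajectory_labels",
    "simulate_longitudinal_anthro",
    "simulate_mediation_triples",
]

# Descriptive anchors (ages 0,2,5,8,15,18) for the median BMI and height
# curves, by sex; values chosen to track an urban African birth cohort's
# printed sex-specific means. Interpolated linearly in between.
_ANCHOR_AGES = np.array([0.0, 2.0, 5.0, 8.0, 15.0, 18.0])
_BMI_ANCHORS = {
    "M": np.array([17.7, 16.4, 15.8, 16.0, 19.5, 20.3]),
    "F": np.array([17.4, 16.3, 15.6, 16.1, 22.3, 23.3]),
}
_HEIGHT_ANCHORS = {
    "M": np.array([50.0, 83.7, 107.6, 125.1, 165.5, 170.8]),
    "F": np.array([50.0, 82.9, 107.2, 124.3, 158.7, 159.7]),
}

CLASS_NAMES = ("normal", "late_onset", "early_onset")


def median_bmi(age, sex: str) -> np.ndarray:
    """Sex-specific median BMI (kg/m^2) at `age` years."""
    return np.interp(np.asarray(age, dtype=float), _ANCHOR_AGES, _BMI_ANCHORS[sex])


def median_height(age, sex: str) -> np.ndarray:
    """Sex-specific median height (cm) at `age` years; monotone in age."""
    return np.interp(np.asarray(age, dtype=float), _ANCHOR_AGES, _HEIGHT_ANCHORS[sex])


@dataclass
class GrowthParams:
    """Generative parameters of the longitudinal BMI-SDS model.

    BMI-SDS(i, t) = curve_sex(t) + class_offset + u_i
                    + (grs_slope_base + grs_slope_age * t) * grsz_i + eps,
    with u_i ~ N(0, random_intercept_sd^2), eps ~ N(0, residual_sd^2).
    Curve coefficients are (c0, c1, c2, c3) of a cubic in age (years).
    """

    curve_male: tuple = (0.40, -0.12, 0.004, 0.0)
    curve_female: tuple = (0.50, -0.13, 0.0075, 0.0)
    random_intercept_sd: float = 0.8
    residual_sd: float = 0.5
    grs_slope_base: float = 0.0
    grs_slope_age: float = 0.01  # SDS per GRS-SD per year
    class_offsets: tuple = (0.0, 0.4, 1.0)
    height_scale_sd: float = 0.03  # subject-level multiplicative height noise
    height_noise_sd: float = 0.01  # per-visit multiplicative measurement noise

    def __post_init__(self) -> None:
        for name in ("random_intercept_sd", "residual_sd", "height_scale_sd",
                     "height_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mean_sds(self, age, sex: str) -> np.ndarray:
        c = self.curve_male if sex == "M" else self.curve_female
        a = np.asarray(age, dtype=float)
        return c[0] + c[1] * a + c[2] * a**2 + c[3] * a**3


@dataclass
class ClassParams:
    """Multinomial-logit membership model for latent BMI-trajectory classes.

    Class 0 is the reference ("normal"); `intercepts` and `grs_log_rrr` give
    the log-odds intercept and log relative-risk-ratio per GRS-SD for each
    non-reference class, in order.
    """

    n_classes: int = 3
    intercepts: tuple = (-1.5, -2.0)
    grs_log_rrr: tuple = (0.0, float(np.log(1.88)))

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.intercepts) != self.n_classes - 1:
            raise ValueError("need one intercept per non-reference class")
        if len(self.grs_log_rrr) != self.n_classes - 1:
            raise ValueError("need one log-RRR per non-reference class")


@dataclass
class MediationSimParams:
    """Path-model generator: exposure -> mediator -> outcome.

    exposure ~ N(0,1); mediator = a*exposure + N(0, sd_m);
    outcome = c_prime*exposure + b*mediator + N(0, sd_y).
    True proportion mediated is a*b / (a*b + c_prime).
    """

    a: float = 0.4
    b: float = 0.7
    c_prime: float = 0.22
    sd_m: float = 1.0
    sd_y: float = 1.0
    n: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_m <= 0 or self.sd_y <= 0:
            raise ValueError("residual SDs must be positive")
        if self.n < 10:
            raise ValueError("need n >= 10")

    @property
    def true_proportion_mediated(self) -> float:
        return 100.0 * self.a * self.b / (self.a * self.b + self.c_prime)


@dataclass
class SimConfig:
    """Full cohort-simulation configuration."""

    n_subjects: int = 971
    seed: int = 13
    variant_weights: list = field(default_factory=lambda: default_variant_weights())
    ages: np.ndarray = field(default_factory=lambda: np.arange(0.0, 19.0))
    missing_rate: float = 0.15
    sex_ratio: float = 0.5  # fraction male
    growth: GrowthParams = field(default_factory=GrowthParams)
    classes: ClassParams = field(default_factory=ClassParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        self.ages = np.asarray(self.ages, dtype=float)
        if not (np.diff(self.ages) > 0).all():
            raise ValueError("ages must be strictly increasing")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


def default_variant_weights(n: int = 71, seed: int = 2018) -> list[VariantWeight]:
    """A deterministic synthetic 71-locus weight table.

    Betas (kg/m^2 per allele) and effect-allele frequencies are drawn once
    from ranges typical of published adult-BMI loci; the table stands in for
    a user-supplied published weight file and is labelled synthetic.
    """
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]
    weights = []
    for j in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        beta = float(np.clip(abs(rng.normal(0.03, 0.02)), 0.005, 0.12))
        eaf = float(rng.uniform(0.05, 0.95))
        weights.append(
            VariantWeight(f"rs{1000001 + j}", ea, oa, beta=beta, eaf=eaf)
        )
    return weights


def synthetic_lms_reference(
    growth: GrowthParams | None = None,
    ages: np.ndarray | None = None,
    L: float = 1.0,
    S: float = 0.12,
) -> pd.DataFrame:
    """LMS reference (sex, age, L, M, S) matching the generator's median curves.

    With L=1 the z-score transform is linear in BMI, so SDS round-trips
    through the reference are exact and no external growth standard is needed.
    """
    if ages is None:
        ages = np.arange(0.0, 19.5, 0.5)
    rows = []
    for sex in ("M", "F"):
        for age in ages:
            rows.append((sex, float(age), L, float(median_bmi(age, sex)), S))
    return pd.DataFrame(rows, columns=["sex", "age", "L", "M", "S"])


def simulate_genotypes(
    n_subjects: int, weights: list[VariantWeight], seed: int
) -> GenotypeMatrix:
    """Draw Binomial(2, eaf) effect-allele dosages, independent across loci.

    Genotypes are therefore in Hardy-Weinberg equilibrium by construction,
    giving the QC filters a calibrated null.
    """
    for w in weights:
        if w.eaf is None or not 0.0 <= w.eaf <= 1.0:
            raise ValueError(f"{w.snp_id}: effect-allele frequency required in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([w.eaf for w in weights])
    dosages = rng.binomial(2, p, size=(n_subjects, len(weights))).astype(float)
    return GenotypeMatrix(
        subject_ids=np.array([f"S{i:05d}" for i in range(n_subjects)], dtype=object),
        variant_ids=np.array([w.snp_id for w in weights], dtype=object),
        dosages=dosages,
        counted_alleles=np.array([w.effect_allele for w in weights], dtype=object),
        other_alleles=np.array([w.other_allele for w in weights], dtype=object),
    )


def class_probabilities(grsz: np.ndarray, params: ClassParams) -> np.ndarray:
    """Multinomial-logit membership probabilities, reference class first."""
    grsz = np.asarray(grsz, dtype=float)
    if not np.isfinite(grsz).all():
        raise ValueError("grsz must be finite")
    eta = np.zeros((grsz.size, params.n_classes))
    for k in range(1, params.n_classes):
        eta[:, k] = params.intercepts[k - 1] + params.grs_log_rrr[k - 1] * grsz
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def simulate_trajectory_labels(
    grsz: np.ndarray, params: ClassParams, seed: int
) -> np.ndarray:
    """Draw a latent trajectory-class index per subject (0 = reference)."""
    p = class_probabilities(grsz, params)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=p.shape[0])
    return (u[:, None] >= p.cumsum(axis=1)).sum(axis=1)


def simulate_longitudinal_anthro(
    grsz: np.ndarray,
    labels: np.ndarray,
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate long-format anthropometry with a known BMI-SDS truth.

    Returns ``(anthro, truth, lms)`` where `anthro` has columns
    (subject_id, sex, age_years, weight_kg, height_cm) after missing-at-random
    record deletion, `truth` keeps every record with its true SDS, and `lms`
    is the matching synthetic reference. Only weight carries the genetic
    signal; height is a deterministic sex curve with subject-level scale
    noise plus small per-visit measurement noise, so conditional weight gain
    is identifiable independent of linear growth.
    """
    grsz = np.asarray(grsz, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = config.n_subjects
    if grsz.size != n or labels.size != n:
        raise ValueError("grsz and labels must have length n_subjects")
    g = config.growth
    lms = synthetic_lms_reference(g)
    if config.ages.min() < lms["age"].min() or config.ages.max() > lms["age"].max():
        raise ValueError("assessment ages outside the LMS reference range")
    offsets = np.asarray(g.class_offsets, dtype=float)
    if labels.max() >= offsets.size:
        raise ValueError("class label without a class offset")

    rng = np.random.default_rng(seed)
    sex = np.where(rng.uniform(size=n) < config.sex_ratio, "M", "F")
    u = rng.normal(0.0, g.random_intercept_sd, size=n)
    hscale = 1.0 + rng.normal(0.0, g.height_scale_sd, size=n)

    S = 0.12
    recs = []
    for i in range(n):
        ages = config.ages
        eps = rng.normal(0.0, g.residual_sd, size=ages.size)
        z = (
            g.mean_sds(ages, sex[i])
            + offsets[labels[i]]
            + u[i]
            + (g.grs_slope_base + g.grs_slope_age * ages) * grsz[i]
            + eps
        )
        m = median_bmi(ages, sex[i])
        bmi = m * (1.0 + S * z)  # L = 1 back-transform
        height = (
            median_height(ages, sex[i])
            * hscale[i]
            * (1.0 + rng.normal(0.0, g.height_noise_sd, size=ages.size))
        )
        weight = bmi * (height / 100.0) ** 2
        for t, a in enumerate(ages):
            recs.append(
                (f"S{i:05d}", sex[i], float(a), float(weight[t]), float(height[t]), float(z[t]))
            )
    truth = pd.DataFrame(
        recs, columns=["subject_id", "sex", "age_years", "weight_kg", "height_cm", "true_sds"]
    )
    keep = rng.uniform(size=len(truth)) >= config.missing_rate
    anthro = truth.loc[keep, ["subject_id", "sex", "age_years", "weight_kg", "height_cm"]]
    return anthro.reset_index(drop=True), truth, lms


def simulate_mediation_triples(params: MediationSimParams) -> pd.DataFrame:
    """Draw (exposure, mediator, outcome) from the linear path model."""
    rng = np.random.default_rng(params.seed)
    x = rng.standard_normal(params.n)
    m = params.a * x + rng.normal(0.0, params.sd_m, size=params.n)
    y = params.c_prime * x + params.b * m + rng.normal(0.0, params.sd_y, size=params.n)
    return pd.DataFrame({"exposure": x, "mediator": m, "outcome": y})
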