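"""Variant- and sample-level genotype quality control.

Reproduces the standard PLINK-style filter chain on a dosage matrix:
variant missingness, minor-allele frequency, Hardy-Weinberg exact test;
then sample missingness and heterozygosity outliers; then method-of-moments
relatedness (PI_HAT) with greedy removal of one member per related pair.
Sex-discordance and PCA population-outlier stages require X-chromosome and
reference-panel data and are recorded in the report as skipped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcEntry",
    "QcReport",
    "hwe_exact_pvalue",
    "variant_qc",
    "sample_qc",
    "estimate_pi_hat",
    "relatedness_filter",
    "run_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    variant_missing_max: float = 0.02
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    sample_missing_max: float = 0.03
    het_sd_band: float = 3.0
    pi_hat_max: float = 0.1875
    # moment-based IBD needs many independent markers to be informative;
    # below this count run_qc records the relatedness stage as skipped
    min_variants_for_ibd: int = 200

    def __post_init__(self) -> None:
        for name in ("variant_missing_max", "maf_min", "hwe_p_min",
                     "sample_missing_max", "pi_hat_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.het_sd_band <= 0:
            raise ValueError("het_sd_band must be positive")
        if self.min_variants_for_ibd < 2:
            raise ValueError("min_variants_for_ibd must be >= 2")


@dataclass
class QcEntry:
    filter_name: str
    axis: str  # "variant" or "sample"
    threshold: float | None
    removed_ids: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


@dataclass
class QcReport:
    entries: list = field(default_factory=list)
    variants_before: int = 0
    variants_after: int = 0
    samples_before: int = 0
    samples_after: int = 0
    skipped_stages: tuple = ("sex_discordance", "pca_population_outliers")

    def removed(self, axis: str) -> int:
        return sum(e.n_removed for e in self.entries if e.axis == axis)

    def check_bookkeeping(self) -> None:
        if self.variants_before - self.removed("variant") != self.variants_after:
            raise AssertionError("variant bookkeeping identity violated")
        if self.samples_before - self.removed("sample") != self.samples_after:
            raise AssertionError("sample bookkeeping identity violated")


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test probability.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (the Wigginton-Cutler-Abecasis exact test).
    Probabilities are built by recurrence from the modal heterozygote count
    for numerical stability far into the tail.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    # rare-allele count; symmetric in allele labels
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0  # monomorphic: no variation to test

    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(hets.size)
    # start at the modal het count (approx. expectation under HWE)
    mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mode % 2 != n_rare % 2:
        mode += 1 if mode < n_rare else -1
    mode = int(np.clip(mode, hets[0], hets[-1]))
    i_mode = int(np.searchsorted(hets, mode))
    probs[i_mode] = 1.0

    def homs(het: int) -> tuple[float, float]:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        return rare_hom, common_hom

    # downward recurrence: P(het-2)/P(het) = het*(het-1) / (4*(r+1)*(c+1))
    for i in range(i_mode, 0, -1):
        het = hets[i]
        r, c = homs(het)
        probs[i - 1] = probs[i] * het * (het - 1) / (4.0 * (r + 1) * (c + 1))
    # upward recurrence: P(het+2)/P(het) = 4*r*c / ((het+2)*(het+1))
    for i in range(i_mode, hets.size - 1):
        het = hets[i]
        r, c = homs(het)
        probs[i + 1] = probs[i] * 4.0 * r * c / ((het + 2.0) * (het + 1.0))

    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, n_Aa))]
    # tolerance guards against ties broken by floating-point rounding
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def variant_qc(
    g: GenotypeMatrix, t: QcThresholds | None = None
) -> tuple[GenotypeMatrix, list[QcEntry]]:
    """Drop variants failing missingness, then MAF, then HWE.

    Each variant is reported under the first filter it fails; MAF and HWE are
    computed from non-missing calls only.
    """
    t = t or QcThresholds()
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    miss = g.variant_missingness()
    eaf = g.effect_allele_freq()
    maf = np.minimum(eaf, 1.0 - eaf)

    fail_miss = miss > t.variant_missing_max
    fail_maf = (~fail_miss) & (maf < t.maf_min)
    fail_hwe = np.zeros(g.n_variants, dtype=bool)
    for j in np.flatnonzero(~fail_miss & ~fail_maf):
        counts = _genotype_counts(g.dosages[:, j])
        if sum(counts) >= 1 and hwe_exact_pvalue(*counts) < t.hwe_p_min:
            fail_hwe[j] = True

    entries = [
        QcEntry("variant_missingness", "variant", t.variant_missing_max,
                list(g.variant_ids[fail_miss])),
        QcEntry("minor_allele_frequency", "variant", t.maf_min,
                list(g.variant_ids[fail_maf])),
        QcEntry("hardy_weinberg", "variant", t.hwe_p_min,
                list(g.variant_ids[fail_hwe])),
    ]
    keep = ~(fail_miss | fail_maf | fail_hwe)
    return g.subset(variants=np.flatnonzero(keep)), entries


def sample_qc(
    g: GenotypeMatrix, t: QcThresholds | None = None
) -> tuple[GenotypeMatrix, list[QcEntry]]:
    """Drop samples by missingness, then heterozygosity-rate outliers.

    The heterozygosity band (mean +/- het_sd_band * SD) is computed over the
    samples remaining after the missingness filter; a zero-SD band removes
    nobody.
    """
    t = t or QcThresholds()
    if g.n_subjects < 3:
        raise ValueError("need at least 3 samples for the heterozygosity filter")
    miss = g.sample_missingness()
    no_calls = miss >= 1.0
    if no_calls.any():
        warnings.warn(
            f"{int(no_calls.sum())} sample(s) with zero non-missing calls removed "
            "under the missingness filter"
        )
    fail_miss = miss > t.sample_missing_max
    entries = [
        QcEntry("sample_missingness", "sample", t.sample_missing_max,
                list(g.subject_ids[fail_miss])),
    ]
    kept = g.subset(subjects=np.flatnonzero(~fail_miss))

    obs = ~np.isnan(kept.dosages)
    with np.errstate(invalid="ignore"):
        het = np.where(obs.sum(axis=1) > 0,
                       (kept.dosages == 1).sum(axis=1) / np.maximum(obs.sum(axis=1), 1),
                       np.nan)
    mu, sd = np.nanmean(het), np.nanstd(het, ddof=1)
    if sd > 0:
        fail_het = (het < mu - t.het_sd_band * sd) | (het > mu + t.het_sd_band * sd)
    else:
        fail_het = np.zeros(kept.n_subjects, dtype=bool)
    entries.append(
        QcEntry("heterozygosity", "sample", t.het_sd_band,
                list(kept.subject_ids[fail_het]))
    )
    return kept.subset(subjects=np.flatnonzero(~fail_het)), entries


def estimate_pi_hat(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments pairwise IBD-sharing estimate (PLINK PI_HAT).

    For each sample pair, identity-by-state counts across non-missing loci
    are compared with their expectations under IBD states 0/1/2 given sample
    allele frequencies; the moment estimates of P(IBD=k) are clamped to the
    simplex and PI_HAT = P(IBD=2) + P(IBD=1)/2. Diagonal is 1.
    """
    if g.n_subjects < 2:
        raise ValueError("need at least 2 samples")
    p = g.effect_allele_freq()
    informative = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not informative.any():
        raise ValueError("no polymorphic variants; allele frequencies uninformative")
    X = g.dosages[:, informative]
    p = p[informative]
    q = 1.0 - p

    # per-locus IBS-class probabilities under each IBD state
    e0_ibs0 = 2.0 * p**2 * q**2
    e0_ibs1 = 4.0 * p**3 * q + 4.0 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibs1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    n = g.n_subjects
    out = np.eye(n)
    obs = ~np.isnan(X)
    if obs.all():
        # fully observed: IBS class counts for all pairs via one-hot products
        A = [(X == k).astype(float) for k in (0.0, 1.0, 2.0)]
        N2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T   # IBS2
        N0 = A[0] @ A[2].T + A[2] @ A[0].T                   # IBS0
        m = float(X.shape[1])
        N1 = m - N0 - N2
        E0_0, E0_1, E0_2 = e0_ibs0.sum(), e0_ibs1.sum(), e0_ibs2.sum()
        E1_1, E1_2 = e1_ibs1.sum(), e1_ibs2.sum()
        P0 = N0 / E0_0
        P1 = (N1 - P0 * E0_1) / E1_1
        P2 = (N2 - P0 * E0_2 - P1 * E1_2) / m
        P0, P1, P2 = (np.maximum(v, 0.0) for v in (P0, P1, P2))
        s = P0 + P1 + P2
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.clip((P2 + 0.5 * P1) / np.where(s > 0, s, 1.0), 0.0, 1.0)
        iu = np.triu_indices(n, 1)
        out[iu] = pi[iu]
        out.T[iu] = pi[iu]
        return out
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if both.sum() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            d = np.abs(X[i, both] - X[j, both])
            n_ibs0 = float((d == 2).sum())
            n_ibs1 = float((d == 1).sum())
            n_ibs2 = float((d == 0).sum())
            E0_0, E0_1, E0_2 = e0_ibs0[both].sum(), e0_ibs1[both].sum(), e0_ibs2[both].sum()
            E1_1, E1_2 = e1_ibs1[both].sum(), e1_ibs2[both].sum()
            m = float(both.sum())
            P0 = n_ibs0 / E0_0 if E0_0 > 0 else 0.0
            P1 = (n_ibs1 - P0 * E0_1) / E1_1 if E1_1 > 0 else 0.0
            P2 = (n_ibs2 - P0 * E0_2 - P1 * E1_2) / m
            P0, P1, P2 = (max(0.0, v) for v in (P0, P1, P2))
            s = P0 + P1 + P2
            if s > 0:
                P0, P1, P2 = P0 / s, P1 / s, P2 / s
            pi = np.clip(P2 + 0.5 * P1, 0.0, 1.0)
            out[i, j] = out[j, i] = pi
    return out


def relatedness_filter(
    pi_hat: np.ndarray, g: GenotypeMatrix, t: QcThresholds | None = None
) -> tuple[GenotypeMatrix, list[QcEntry]]:
    """Greedily drop one member of each pair with PI_HAT above threshold.

    The member with the lower genotype call rate is removed (ties break to
    the later subject id); pairs at exactly the threshold are kept.
    """
    t = t or QcThresholds()
    if pi_hat.shape != (g.n_subjects, g.n_subjects):
        raise ValueError("pi_hat not conformable with genotype matrix")
    call = g.sample_call_rate()
    alive = np.ones(g.n_subjects, dtype=bool)
    removed: list = []
    ii, jj = np.where(np.triu(np.nan_to_num(pi_hat, nan=0.0), k=1) > t.pi_hat_max)
    order = np.argsort(-pi_hat[ii, jj])  # most related pairs first
    for k in order:
        i, j = ii[k], jj[k]
        if not (alive[i] and alive[j]):
            continue
        if call[i] < call[j]:
            drop = i
        elif call[j] < call[i]:
            drop = j
        else:
            drop = i if str(g.subject_ids[i]) > str(g.subject_ids[j]) else j
        alive[drop] = False
        removed.append(g.subject_ids[drop])
    entries = [QcEntry("relatedness_pi_hat", "sample", t.pi_hat_max, removed)]
    return g.subset(subjects=np.flatnonzero(alive)), entries


def run_qc(
    g: GenotypeMatrix, t: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Full single-pass QC chain: variants, then samples, then relatedness."""
    t = t or QcThresholds()
    if g.n_subjects == 0 or g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(
        variants_before=g.n_variants, samples_before=g.n_subjects
    )
    g1, ev = variant_qc(g, t)
    report.entries.extend(ev)
    if g1.n_variants == 0:
        raise ValueError("no variants remain after variant QC")
    g2, es = sample_qc(g1, t)
    report.entries.extend(es)
    if g2.n_subjects == 0:
        raise ValueError("no samples remain after sample QC")
    if g2.n_variants < t.min_variants_for_ibd:
        warnings.warn(
            f"only {g2.n_variants} variants: too few for moment-based IBD; "
            "relatedness stage skipped"
        )
        report.skipped_stages = report.skipped_stages + ("relatedness_pi_hat",)
        g3 = g2
        report.entries.append(
            QcEntry("relatedness_pi_hat", "sample", t.pi_hat_max, [])
        )
    else:
        pi = estimate_pi_hat(g2)
        g3, er = relatedness_filter(pi, g2, t)
        report.entries.extend(er)
    if g3.n_subjects == 0:
        raise ValueError("no samples remain after relatedness filtering")
    report.variants_after = g3.n_variants
    report.samples_after = g3.n_subjects
    report.check_bookkeeping()
    return g3, report
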