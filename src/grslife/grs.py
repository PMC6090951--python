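"""Weighted genetic risk score (wGRS) construction and Z-standardization.

The score sums, over risk loci, the count of BMI-increasing alleles (0, 1
or 2) times the published per-allele effect size in kg/m^2; the Z-scored
form (wGRSz) subtracts the analysis-sample mean and divides by its SD so
effects are per SD of genetic risk.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, VariantWeight, complement_allele

__all__ = ["GrsResult", "AlignmentReport", "align_weights", "compute_wgrs", "standardize"]


@dataclass
class AlignmentReport:
    kept: list = field(default_factory=list)
    flipped_dosage: list = field(default_factory=list)  # counted the other allele
    strand_flipped: list = field(default_factory=list)  # alleles on opposite strand
    dropped: list = field(default_factory=list)  # (snp_id, reason)
    palindromic: list = field(default_factory=list)


@dataclass
class GrsResult:
    subject_ids: np.ndarray
    wgrs: np.ndarray
    n_used: np.ndarray
    n_imputed: np.ndarray
    wgrsz: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "wgrs": self.wgrs,
                "wgrsz": np.nan if self.wgrsz is None else self.wgrsz,
                "n_used": self.n_used,
                "n_imputed": self.n_imputed,
            }
        )
        return df


def align_weights(
    g: GenotypeMatrix,
    weights: list[VariantWeight],
    drop_palindromic: bool = False,
) -> tuple[GenotypeMatrix, list[VariantWeight], AlignmentReport]:
    """Recode dosages so each kept column counts its weight's effect allele.

    Resolution per overlapping variant, comparing the matrix's counted/other
    alleles with the weight's effect/other alleles:

    - same pair, counted == effect: unchanged;
    - same pair, counted == other: dosage d -> 2 - d;
    - pair matches only after complementing both matrix alleles: strand
      flip, orientation then resolved as above;
    - anything else: dropped and reported.

    Palindromic (A/T, C/G) variants are strand-ambiguous; they are flagged
    and kept by default (``drop_palindromic=True`` removes them).
    """
    wmap = {w.snp_id: w for w in weights}
    overlap = [j for j, v in enumerate(g.variant_ids) if v in wmap]
    if not overlap:
        sample = [str(v) for v in g.variant_ids[:5]]
        raise ValueError(
            "no overlap between genotype variants and weight table; "
            f"first matrix ids: {sample}"
        )
    rep = AlignmentReport()
    keep_idx: list[int] = []
    kept_weights: list[VariantWeight] = []
    new_dosages = []
    for j in overlap:
        snp = g.variant_ids[j]
        w = wmap[snp]
        ca, oa = str(g.counted_alleles[j]), str(g.other_alleles[j])
        col = g.dosages[:, j].copy()
        pair = frozenset((ca, oa))
        wpair = frozenset((w.effect_allele, w.other_allele))
        cpair = frozenset((complement_allele(ca), complement_allele(oa)))
        if pair == wpair:
            counted = ca
        elif cpair == wpair:
            rep.strand_flipped.append(snp)
            counted = complement_allele(ca)
        else:
            rep.dropped.append((snp, f"alleles {ca}/{oa} vs weight "
                                     f"{w.effect_allele}/{w.other_allele}"))
            continue
        if counted == w.other_allele:
            col = 2.0 - col
            rep.flipped_dosage.append(snp)
        if w.is_palindromic:
            rep.palindromic.append(snp)
            if drop_palindromic:
                rep.dropped.append((snp, "palindromic"))
                continue
        keep_idx.append(j)
        kept_weights.append(w)
        new_dosages.append(col)
        rep.kept.append(snp)
    if not keep_idx:
        raise ValueError("no variants reconcilable with the weight table")
    if rep.palindromic and not drop_palindromic:
        warnings.warn(
            f"{len(rep.palindromic)} palindromic variant(s) kept; strand "
            "orientation cannot be verified"
        )
    aligned = GenotypeMatrix(
        subject_ids=g.subject_ids.copy(),
        variant_ids=np.array([w.snp_id for w in kept_weights], dtype=object),
        dosages=np.column_stack(new_dosages),
        counted_alleles=np.array([w.effect_allele for w in kept_weights], dtype=object),
        other_alleles=np.array([w.other_allele for w in kept_weights], dtype=object),
        sex=None if g.sex is None else g.sex.copy(),
    )
    return aligned, kept_weights, rep


def compute_wgrs(
    g: GenotypeMatrix,
    weights: list[VariantWeight],
    missing_policy: str = "impute",
) -> GrsResult:
    """Raw weighted score: wGRS_i = sum_j dosage_ij * beta_j.

    ``missing_policy`` controls missing calls: ``"impute"`` substitutes the
    Hardy-Weinberg expectation 2*eaf (requires eaf for every variant with a
    missing call); ``"rescale"`` sums observed terms and rescales by
    n_variants / n_observed per subject.
    """
    if missing_policy not in ("impute", "rescale"):
        raise ValueError("missing_policy must be 'impute' or 'rescale'")
    wmap = {w.snp_id: w for w in weights}
    try:
        beta = np.array([wmap[v].beta for v in g.variant_ids])
    except KeyError as e:
        raise ValueError(f"variant {e} has no weight") from None
    D = g.dosages
    missing = np.isnan(D)
    n_imputed = missing.sum(axis=1)
    n_used = np.full(g.n_subjects, g.n_variants)
    if missing_policy == "impute":
        eaf = np.array(
            [np.nan if wmap[v].eaf is None else wmap[v].eaf for v in g.variant_ids]
        )
        need = missing.any(axis=0) & np.isnan(eaf)
        if need.any():
            bad = g.variant_ids[need][0]
            raise ValueError(f"missing dosage at {bad} but no eaf to impute from")
        Dw = np.where(missing, 2.0 * eaf, D)
        wgrs = Dw @ beta
    else:
        wgrs = np.nansum(D * beta, axis=1)
        n_obs = (~missing).sum(axis=1)
        if (n_obs == 0).any():
            raise ValueError("subject with zero observed dosages under rescale policy")
        wgrs = wgrs * (g.n_variants / n_obs)
        n_used = n_obs
        n_imputed = np.zeros_like(n_imputed)
    return GrsResult(
        subject_ids=g.subject_ids.copy(),
        wgrs=np.asarray(wgrs, dtype=float),
        n_used=np.asarray(n_used),
        n_imputed=np.asarray(n_imputed),
    )


def standardize(raw: GrsResult, ddof: int = 1) -> GrsResult:
    """Z-score the raw wGRS on the analysis sample.

    Default uses the sample SD (n-1 denominator); ``ddof=0`` switches to the
    population convention.
    """
    if raw.wgrs.size < 2:
        raise ValueError("need at least 2 subjects to standardize")
    mu = raw.wgrs.mean()
    sd = raw.wgrs.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero wGRS standard deviation; cannot Z-score")
    return GrsResult(
        subject_ids=raw.subject_ids,
        wgrs=raw.wgrs,
        n_used=raw.n_used,
        n_imputed=raw.n_imputed,
        wgrsz=(raw.wgrs - mu) / sd,
    )
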