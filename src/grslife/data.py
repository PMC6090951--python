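"""Core in-memory containers shared across the pipeline.

Genotypes are held as an effect-allele dosage matrix (subjects x variants)
with values in {0, 1, 2} and NaN for missing calls, alongside the allele
pair each column's dosage counts. Anthropometry and growth references are
plain pandas DataFrames with validated schemas (see :mod:`grslife.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["VariantWeight", "GenotypeMatrix"]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantWeight:
    """One risk locus: the allele whose count carries the published effect.

    Parameters
    ----------
    snp_id : str
        Variant identifier (e.g. an rsID).
    effect_allele : str
        Allele whose per-copy count is multiplied by ``beta``.
    other_allele : str
        The non-effect allele.
    beta : float
        Per-allele effect size in kg/m^2 on adult BMI.
    eaf : float, optional
        Effect-allele frequency; used to impute missing dosages and to
        simulate genotypes.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, where strand is ambiguous."""
        a, b = self.effect_allele, self.other_allele
        return a in _COMPLEMENT and _COMPLEMENT[a] == b


def complement_allele(a: str) -> str:
    return _COMPLEMENT.get(a, a)


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix counting one declared allele per column.

    ``dosages`` is float with NaN encoding a missing call; non-missing entries
    must be 0, 1 or 2.
    """

    subject_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray
    counted_alleles: np.ndarray
    other_alleles: np.ndarray
    sex: np.ndarray | None = None  # optional per-subject 'M'/'F'

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.counted_alleles = np.asarray(self.counted_alleles, dtype=object)
        self.other_alleles = np.asarray(self.other_alleles, dtype=object)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n or len(self.variant_ids) != m:
            raise ValueError("id lengths do not match dosage matrix shape")
        if len(self.counted_alleles) != m or len(self.other_alleles) != m:
            raise ValueError("allele arrays do not match number of variants")
        for name, ids in (("subject", self.subject_ids), ("variant", self.variant_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} outside {{0, 1, 2, missing}}")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=object)
            if len(self.sex) != n:
                raise ValueError("sex array does not match number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.sample_missingness()

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant counted-allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(
        self,
        subjects: Sequence[int] | np.ndarray | None = None,
        variants: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset along either axis; returns a copy."""
        si = np.arange(self.n_subjects) if subjects is None else np.asarray(subjects)
        vi = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            subject_ids=self.subject_ids[si].copy(),
            variant_ids=self.variant_ids[vi].copy(),
            dosages=self.dosages[np.ix_(si, vi)].copy(),
            counted_alleles=self.counted_alleles[vi].copy(),
            other_alleles=self.other_alleles[vi].copy(),
            sex=None if self.sex is None else self.sex[si].copy(),
        )

    def drop_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        keep = ~np.isin(self.subject_ids.astype(str), list(map(str, ids)))
        return self.subset(subjects=np.flatnonzero(keep))

    def drop_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        keep = ~np.isin(self.variant_ids.astype(str), list(map(str, ids)))
        return self.subset(variants=np.flatnonzero(keep))

    def copy(self) -> "GenotypeMatrix":
        return self.subset()
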