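"""Genotype QC: HWE exact test, filter chain, relatedness."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln

from grslife.data import GenotypeMatrix
from grslife.qc import (
    QcThresholds,
    estimate_pi_hat,
    hwe_exact_pvalue,
    relatedness_filter,
    run_qc,
    sample_qc,
    variant_qc,
)
from grslife.synthetic import default_variant_weights, simulate_genotypes

from conftest import make_matrix


def hwe_pvalue_enumeration(n_AA, n_Aa, n_aa):
    """Independent oracle: direct enumeration with log-factorial weights."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    rare_hom = (n_a - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1) - gammaln(common_hom + 1) - gammaln(hets + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, min(n_Aa, n_a))]
    return min(1.0, p[p <= p_obs * (1 + 1e-12)].sum())


class TestHweExact:
    def test_perfect_equilibrium_is_modal(self):
        assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_total_heterozygote_deficit_fails_threshold(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-5
        assert hwe_exact_pvalue(50, 0, 50) == pytest.approx(
            hwe_pvalue_enumeration(50, 0, 50), abs=1e-10
        )

    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(100, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 0)

    def test_matches_enumeration_exhaustively_small_n(self):
        """All genotype configurations with total <= 40 agree to 1e-10."""
        for n in range(1, 41):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_het
                    assert hwe_exact_pvalue(n_AA, n_het, n_aa) == pytest.approx(
                        hwe_pvalue_enumeration(n_AA, n_het, n_aa), abs=1e-10
                    ), (n_AA, n_het, n_aa)

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_matches_enumeration_random_up_to_200(self, a, h, b):
        total = a + h + b
        if total == 0 or total > 200:
            return
        assert hwe_exact_pvalue(a, h, b) == pytest.approx(
            hwe_pvalue_enumeration(a, h, b), abs=1e-10
        )

    def test_symmetric_in_allele_labels(self):
        assert hwe_exact_pvalue(12, 30, 58) == hwe_exact_pvalue(58, 30, 12)


class TestVariantQc:
    def test_first_failing_filter_claims_the_variant(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        base[:3, 0] = np.nan          # 3% missing at threshold 2% -> removed
        base[:, 1] = 0.0
        base[0, 1] = 1.0              # MAF 0.005 < 1% -> removed
        base[:, 2] = np.r_[np.zeros(50), 2 * np.ones(50)]  # HWE failure
        g = make_matrix(base)
        kept, entries = variant_qc(g, QcThresholds())
        by_name = {e.filter_name: e.removed_ids for e in entries}
        assert by_name["variant_missingness"] == ["rs0"]
        assert by_name["minor_allele_frequency"] == ["rs1"]
        assert by_name["hardy_weinberg"] == ["rs2"]
        assert kept.n_variants == 2

    def test_maf_exactly_at_threshold_kept(self):
        # 100 subjects, 2 copies of the rare allele: MAF exactly 0.01
        col = np.zeros((100, 1))
        col[0, 0] = 2.0
        # companion common variant so the matrix is non-trivial
        g = make_matrix(np.hstack([col, np.ones((100, 1))]))
        kept, _ = variant_qc(g, QcThresholds())
        assert "rs0" in list(kept.variant_ids)

    def test_null_simulation_hwe_false_positive_rate_tiny(self):
        w = default_variant_weights(n=400, seed=5)
        g = simulate_genotypes(1000, w, seed=6)
        _, entries = variant_qc(g, QcThresholds(maf_min=1e-6))
        hwe = [e for e in entries if e.filter_name == "hardy_weinberg"][0]
        assert hwe.n_removed / g.n_variants < 0.001


class TestSampleQc:
    def test_high_missingness_sample_removed(self):
        d = np.ones((10, 100))
        d[0, :5] = np.nan  # 5% missing > 3%
        g = make_matrix(d)
        kept, entries = sample_qc(g, QcThresholds())
        assert entries[0].removed_ids == ["S000"]
        assert kept.n_subjects == 9

    def test_zero_variance_het_band_removes_nobody(self):
        d = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (5, 25))
        kept, entries = sample_qc(make_matrix(d), QcThresholds())
        assert kept.n_subjects == 5
        het = [e for e in entries if e.filter_name == "heterozygosity"][0]
        assert het.n_removed == 0

    def test_planted_zero_het_outlier_removed(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.5, size=(60, 2000)).astype(float)
        d[0] = np.where(d[0] == 1.0, 0.0, d[0])  # het rate 0 among ~0.5
        kept, entries = sample_qc(make_matrix(d), QcThresholds())
        het = [e for e in entries if e.filter_name == "heterozygosity"][0]
        assert het.removed_ids == ["S000"]
        assert kept.n_subjects == 59


class TestRelatedness:
    @staticmethod
    def _hwe_matrix(n, m, seed, p=0.5):
        rng = np.random.default_rng(seed)
        return rng.binomial(2, p, size=(n, m)).astype(float)

    def test_duplicate_sample_pi_hat_near_one(self):
        d = self._hwe_matrix(12, 2000, 1)
        d[1] = d[0]
        pi = estimate_pi_hat(make_matrix(d))
        assert pi[0, 1] > 0.95
        assert np.allclose(np.diag(pi), 1.0)

    def test_unrelated_pairs_pi_hat_near_zero(self):
        d = self._hwe_matrix(20, 5000, 2)
        pi = estimate_pi_hat(make_matrix(d))
        off = pi[np.triu_indices(20, 1)]
        assert abs(off.mean()) < 0.02

    def test_parent_offspring_pi_hat_half(self):
        rng = np.random.default_rng(4)
        m = 5000
        p = rng.uniform(0.2, 0.8, size=m)
        parent = rng.binomial(2, p, size=m).astype(float)
        child = (rng.uniform(size=m) < parent / 2.0) + rng.binomial(1, p)
        others = rng.binomial(2, p, size=(8, m)).astype(float)
        d = np.vstack([parent, child.astype(float), others])
        pi = estimate_pi_hat(make_matrix(d))
        assert pi[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_monomorphic_only_errors(self):
        with pytest.raises(ValueError):
            estimate_pi_hat(make_matrix(np.zeros((5, 10))))

    def test_pair_above_threshold_one_removed_boundary_kept(self):
        d = self._hwe_matrix(6, 50, 5)
        pi = np.eye(6)
        pi[0, 1] = pi[1, 0] = 0.20    # above 0.1875 -> one removed
        pi[2, 3] = pi[3, 2] = 0.1875  # exactly at threshold -> both kept
        kept, entries = relatedness_filter(pi, make_matrix(d))
        assert entries[0].n_removed == 1
        assert entries[0].removed_ids[0] in ("S000", "S001")
        assert {"S002", "S003"} <= set(kept.subject_ids)

    def test_fully_related_triple_loses_exactly_two(self):
        d = self._hwe_matrix(5, 50, 6)
        pi = np.eye(5)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            pi[i, j] = pi[j, i] = 0.5
        kept, entries = relatedness_filter(pi, make_matrix(d))
        assert entries[0].n_removed == 2
        assert kept.n_subjects == 3

    def test_lower_call_rate_member_dropped(self):
        d = self._hwe_matrix(4, 100, 7)
        d[1, :10] = np.nan  # S001 has the lower call rate
        pi = np.eye(4)
        pi[0, 1] = pi[1, 0] = 0.9
        _, entries = relatedness_filter(pi, make_matrix(d))
        assert entries[0].removed_ids == ["S001"]


class TestRunQc:
    def test_clean_cohort_unchanged_and_idempotent(self):
        w = default_variant_weights(n=2000, seed=8)
        g = simulate_genotypes(150, w, seed=9)
        clean, report = run_qc(g)
        assert report.variants_after == report.variants_before
        assert report.samples_after == report.samples_before
        again, report2 = run_qc(clean)
        assert report2.removed("variant") == 0
        assert report2.removed("sample") == 0

    def test_planted_failures_reported_under_right_filters(self):
        w = default_variant_weights(n=2000, seed=8)
        g = simulate_genotypes(150, w, seed=10)
        d = g.dosages.copy()
        d[:20, 0] = np.nan  # two high-missing variants
        d[:20, 1] = np.nan
        d[:, 2] = 0.0       # one rare (here monomorphic) variant
        d[1] = d[0]         # one duplicated sample
        g2 = make_matrix(d)
        _, report = run_qc(g2)
        by_name = {e.filter_name: e.n_removed for e in report.entries}
        assert by_name["variant_missingness"] == 2
        assert by_name["minor_allele_frequency"] == 1
        assert by_name["relatedness_pi_hat"] == 1
        report.check_bookkeeping()

    def test_bookkeeping_identity(self, genotypes):
        # 71 score variants: too few for moment-based IBD, stage is skipped
        with pytest.warns(UserWarning, match="too few"):
            _, report = run_qc(genotypes)
        report.check_bookkeeping()
        assert {"sex_discordance", "pca_population_outliers",
                "relatedness_pi_hat"} == set(report.skipped_stages)
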