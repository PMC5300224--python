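"""Heterozygosity, exact HWE testing against a rational-arithmetic
enumeration oracle, F_st boundary/hand cases, GRM and PCA contracts."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from introgress import genotype_core as gc
from introgress import popgen_stats as ps
from introgress import synthetic_data as sd
from introgress.errors import ParameterError, UndefinedStatisticError

from conftest import make_matrix


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact-rational full enumeration of the conditional HWE test."""
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    rare = min(n1, 2 * n - n1)

    def weight(h: int) -> Fraction:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # multinomial coefficient x 2^h (unnormalized conditional weight)
        import math

        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        )

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= p_obs) / total


class TestHeterozygosity:
    def test_half_frequency_maximizes_expected_het(self):
        g = make_matrix([[0], [1], [2], [1]])  # p = 0.5
        het = ps.heterozygosity(g, by_group=False)
        assert het.per_snp["ALL"]["exp_het"].iat[0] == pytest.approx(0.5)

    def test_monomorphic_snp_has_zero_het(self):
        g = make_matrix([[0], [0], [0]])
        het = ps.heterozygosity(g, by_group=False)
        assert het.per_snp["ALL"]["exp_het"].iat[0] == 0.0
        assert het.per_snp["ALL"]["obs_het"].iat[0] == 0.0

    def test_observed_het_matches_binomial_oracle(self):
        rng = np.random.default_rng(0)
        g = make_matrix(rng.binomial(2, 0.3, size=(500, 200)).astype(np.int8))
        het = ps.heterozygosity(g, by_group=False)
        target = 2 * 0.3 * 0.7  # 0.42
        se = np.sqrt(target * (1 - target) / 500)
        mean_obs = het.per_snp["ALL"]["obs_het"].mean()
        assert abs(mean_obs - target) < 3 * se / np.sqrt(200) + 1e-3

    def test_summary_matches_per_snp_vectors(self, recovery_cohort):
        g, _ = recovery_cohort
        het = ps.heterozygosity(g)
        for _, row in het.summary.iterrows():
            df = het.per_snp[row["group"]]
            assert row["exp_mean"] == pytest.approx(
                np.nanmean(df["exp_het"]), abs=1e-12
            )
            assert row["obs_median"] == pytest.approx(
                np.nanmedian(df["obs_het"]), abs=1e-12
            )


class TestHweExactTest:
    @pytest.mark.parametrize(
        "counts",
        [(1, 0, 1), (25, 50, 25), (5, 0, 5), (0, 2, 0), (3, 7, 2),
         (12, 3, 40), (0, 100, 0), (60, 35, 5)],
    )
    def test_matches_rational_enumeration_oracle(self, counts):
        expected = float(hwe_enumeration_oracle(*counts))
        assert ps.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_counts_give_p_one(self):
        assert ps.hwe_exact_test(50, 0, 0) == 1.0

    def test_perfect_proportions_near_one(self):
        assert ps.hwe_exact_test(25, 50, 25) > 0.9

    def test_all_zero_counts_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ps.hwe_exact_test(0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ps.hwe_exact_test(-1, 2, 3)

    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
    )
    def test_enumeration_agreement_on_random_counts(self, a, h, b):
        if a + h + b == 0:
            return
        expected = float(hwe_enumeration_oracle(a, h, b))
        assert ps.hwe_exact_test(a, h, b) == pytest.approx(expected, abs=1e-12)


class TestPairwiseFst:
    def test_identical_frequencies_give_zero(self):
        f = np.array([0.1, 0.4, 0.7])
        assert ps.pairwise_fst(f, f) == 0.0

    def test_fixed_differences_give_one(self):
        assert ps.pairwise_fst([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_hand_arithmetic_single_locus(self):
        assert ps.pairwise_fst([0.2], [0.8]) == pytest.approx(0.36)

    def test_no_polymorphic_loci_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ps.pairwise_fst([0.0], [0.0])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=2, max_size=20),
        st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=2, max_size=20),
    )
    def test_symmetry_and_bounds(self, fa, fb):
        m = min(len(fa), len(fb))
        fa, fb = fa[:m], fb[:m]
        v = ps.pairwise_fst(fa, fb)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(ps.pairwise_fst(fb, fa))

    def test_balding_nichols_recovery_at_table_scale(self):
        fr = sd.simulate_breed_frequencies(10_000, 2, 0.1, seed=30)
        est = ps.pairwise_fst(fr.freqs[0], fr.freqs[1])
        assert abs(est - sd.expected_pairwise_fst(0.1, 0.1)) < 0.02


class TestGrm:
    def test_duplicated_sample_matches_diagonal(self):
        rng = np.random.default_rng(1)
        row = rng.binomial(2, 0.4, size=300).astype(np.int8)
        other = rng.binomial(2, 0.4, size=(3, 300)).astype(np.int8)
        g = make_matrix(np.vstack([row, row, other]))
        G = ps.grm(g)
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-10)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-10)

    def test_exact_symmetry(self, recovery_cohort):
        g, _ = recovery_cohort
        G = ps.grm(g)
        assert np.array_equal(G, G.T)

    def test_within_breed_relationship_exceeds_between(self, two_breed_freqs):
        q = np.vstack([np.tile([1.0, 0.0], (30, 1)), np.tile([0.0, 1.0], (30, 1))])
        g, _ = sd.simulate_admixed_cohort(two_breed_freqs, q, seed=31)
        G = ps.grm(g)
        within = (G[:30, :30].sum() - np.trace(G[:30, :30])) / (30 * 29)
        between = G[:30, 30:].mean()
        assert within > between

    def test_no_polymorphic_snps_rejected(self):
        g = make_matrix([[0, 2], [0, 2]])
        with pytest.raises(UndefinedStatisticError):
            ps.grm(g)


class TestPca:
    def test_two_breeds_separate_on_pc1(self, two_breed_freqs):
        q = np.vstack([np.tile([1.0, 0.0], (40, 1)), np.tile([0.0, 1.0], (40, 1))])
        g, _ = sd.simulate_admixed_cohort(two_breed_freqs, q, seed=32)
        res = ps.pca_project(ps.grm(g), 2)
        pc1 = res.coords[:, 0]
        assert max(pc1[:40]) < min(pc1[40:]) or max(pc1[40:]) < min(pc1[:40])

    def test_rank_one_matrix_has_single_nonzero_eigenvalue(self):
        G = np.ones((5, 5))
        res = ps.pca_project(G, 5)
        assert res.eigenvalues[0] == pytest.approx(5.0)
        assert np.allclose(res.eigenvalues[1:], 0.0, atol=1e-10)

    def test_eigenvalues_ordered_and_near_psd(self, recovery_cohort):
        g, _ = recovery_cohort
        res = ps.pca_project(ps.grm(g), 10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= -1e-8)

    def test_nonsymmetric_input_rejected(self):
        with pytest.raises(ParameterError):
            ps.pca_project(np.array([[1.0, 0.5], [0.2, 1.0]]), 1)

    def test_two_lineage_fixture_orders_centroids_on_pc1(self):
        # taurine and indicine lineages diverge from a common pool; NE and
        # IB sit within the indicine lineage; CAN is 5/8 CH + 3/8 indicine.
        J = 3000
        pool = sd.simulate_breed_frequencies(J, 2, 0.08, seed=33)
        ch = sd.simulate_breed_frequencies(
            J, 1, 0.04, seed=34, ancestral_freqs=pool.freqs[0]
        )
        ne_ib = sd.simulate_breed_frequencies(
            J, 2, 0.04, seed=35, ancestral_freqs=pool.freqs[1]
        )
        freqs = gc.AlleleFrequencySet(
            np.vstack([ch.freqs, ne_ib.freqs]),
            ["CH", "NE", "IB"],
            pool.snp_ids,
        )
        q = np.vstack(
            [
                np.tile([1, 0, 0], (25, 1)),
                np.tile([0, 1, 0], (25, 1)),
                np.tile([0, 0, 1], (25, 1)),
                np.tile([0.625, 0.375, 0.0], (25, 1)),
            ]
        ).astype(float)
        labels = ["CH"] * 25 + ["NE"] * 25 + ["IB"] * 25 + ["CAN"] * 25
        g, _ = sd.simulate_admixed_cohort(freqs, q, seed=36, group_labels=labels)
        res = ps.pca_project(ps.grm(g), 2)
        cent = {
            lab: res.coords[np.array(labels) == lab, 0].mean()
            for lab in ("CH", "NE", "IB", "CAN")
        }
        # composite lies between its parental breeds on PC1
        lo, hi = sorted([cent["CH"], cent["NE"]])
        assert lo < cent["CAN"] < hi
        # the two indicine breeds are adjacent: both on the far side of CAN
        assert abs(cent["NE"] - cent["IB"]) < abs(cent["NE"] - cent["CH"])


class TestOutlierFilter:
    def test_planted_outlier_removed_exactly(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 1, size=(50, 2))
        coords[7] = [30.0, -30.0]  # far beyond 10 robust SDs
        kept, removed = ps.pca_outlier_filter(coords, ["A"] * 50, n_sd=6.0)
        assert list(removed) == [7]

    def test_homogeneous_cluster_mostly_retained(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1, size=(400, 2))
        kept, removed = ps.pca_outlier_filter(coords, ["A"] * 400, n_sd=3.0)
        assert len(removed) <= 0.05 * 400

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 1, size=(20, 2))
        kept, removed = ps.pca_outlier_filter(coords, ["A"] * 20, n_sd=np.inf)
        assert len(removed) == 0

    def test_small_group_skipped_with_warning(self):
        coords = np.zeros((2, 2))
        with pytest.warns(UserWarning):
            kept, removed = ps.pca_outlier_filter(coords, ["A", "A"], n_sd=3.0)
        assert len(kept) == 2
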