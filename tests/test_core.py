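import itertools

import numpy as np
import pytest

from liquidassoc import (
    ExpressionMatrix,
    assign_scouting_gene,
    conditional_correlations,
    la_scan_for_pair,
    la_score,
    mla,
    normal_quantile_transform,
)
from liquidassoc.core import partition_by_rank, pearson

from conftest import planted_profiles


class TestLaScore:
    def test_two_aligned_products(self):
        # m >= 3 required, so embed the 2-sample idea at m = 3 directly
        assert la_score([2, 0, -2], [1, -1, 0], [0.5, 1, -1]) == pytest.approx(1 / 3)

    def test_zero_conditioner_annihilates(self, rng):
        x, y = rng.standard_normal((2, 10))
        assert la_score(x, y, np.zeros(10)) == 0.0

    def test_symmetric_in_all_six_orderings(self, rng):
        x, y, z = rng.standard_normal((3, 25))
        ref = la_score(x, y, z)
        for a, b, c in itertools.permutations((x, y, z)):
            assert la_score(a, b, c) == ref

    def test_input_validation(self):
        with pytest.raises(ValueError):
            la_score([1, 2], [1, 2], [1, 2])
        with pytest.raises(ValueError):
            la_score([1, 2, 3], [1, 2], [1, 2, 3])

    def test_null_mean_and_scale(self):
        # independent standard-normal profiles: mean ~ 0, SD ~ 1/sqrt(m)
        m, reps = 368, 2000
        gen = np.random.default_rng(3)
        scores = np.array([
            la_score(*gen.standard_normal((3, m))) for _ in range(reps)
        ])
        assert abs(scores.mean()) < 3 * scores.std(ddof=1) / np.sqrt(reps)
        assert scores.std(ddof=1) == pytest.approx(1 / np.sqrt(m), rel=0.10)

    def test_trivariate_normal_mean_vanishes(self):
        # constant-correlation Gaussian triplets have no third-moment signal
        m, reps = 368, 2000
        gen = np.random.default_rng(4)
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        L = np.linalg.cholesky(cov)
        scores = np.array([
            la_score(*(L @ gen.standard_normal((3, m)))) for _ in range(reps)
        ])
        assert abs(scores.mean()) < 3 * scores.std(ddof=1) / np.sqrt(reps)

    def test_planted_sign_semantics(self):
        # increasing corr(x, y | z) in z gives LA > 0 and corr_high > corr_low
        gen = np.random.default_rng(5)
        for _ in range(50):
            x, y, z = planted_profiles(0.5, 368, gen)
            assert la_score(x, y, z) > 0
            corrs, _ = conditional_correlations(x, y, z)
            assert corrs[-1] > corrs[0]


class TestLaScanForPair:
    def test_output_excludes_the_pair(self, noise_matrix):
        small = noise_matrix.subset_genes(np.arange(4))
        z_idx, scores = la_scan_for_pair(small, 0, 2)
        assert list(z_idx) == [1, 3]
        assert scores.shape == (2,)

    def test_matches_scalar_loop_bitwise(self, rng):
        mat = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(10)],
            sample_ids=[f"s{j}" for j in range(20)],
            values=rng.standard_normal((10, 20)),
        )
        z_idx, scores = la_scan_for_pair(mat, 2, 7)
        for k, j in enumerate(z_idx):
            assert scores[k] == la_score(mat.values[2], mat.values[7], mat.values[j])

    def test_index_errors(self, noise_matrix):
        with pytest.raises(IndexError):
            la_scan_for_pair(noise_matrix, 0, 99)
        with pytest.raises(ValueError):
            la_scan_for_pair(noise_matrix, 3, 3)


class TestPartitionByRank:
    def test_remainder_goes_to_lower_groups(self):
        labels = partition_by_rank(np.arange(8.0), 3)
        # sizes 3, 3, 2 from low to high
        assert [int((labels == g).sum()) for g in range(3)] == [3, 3, 2]
        assert labels[0] == 0 and labels[-1] == 2

    def test_ties_broken_by_input_order(self):
        labels = partition_by_rank(np.zeros(6), 3)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1, 2, 2])


class TestConditionalCorrelations:
    def test_perfect_correlation_in_high_group(self, rng):
        z = np.arange(1.0, 10.0)
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        y[6:] = x[6:]          # samples 7-9: x == y
        y[:3] = -x[:3]         # samples 1-3: x == -y
        corrs, labels = conditional_correlations(x, y, z)
        assert corrs[-1] == pytest.approx(1.0)
        assert corrs[0] == pytest.approx(-1.0)
        assert [int((labels == g).sum()) for g in range(3)] == [3, 3, 3]

    def test_matches_explicit_slicing_oracle(self, rng):
        x, y, z = rng.standard_normal((3, 30))
        corrs, labels = conditional_correlations(x, y, z)
        order = np.argsort(z, kind="stable")
        for g, sl in enumerate((order[:10], order[10:20], order[20:])):
            expected = np.corrcoef(x[sl], y[sl])[0, 1]
            assert corrs[g] == pytest.approx(expected, abs=1e-12)

    def test_tiny_group_warns_and_reports_nan(self, rng):
        x, y, z = rng.standard_normal((3, 5))
        with pytest.warns(UserWarning, match="fewer than 3"):
            corrs, _ = conditional_correlations(x, y, z, n_groups=2)
        assert np.isnan(corrs[1])


class TestMla:
    def test_exact_value_on_constructed_bins(self):
        # three bins with x3 means (-1, 0, 1) and in-bin correlations
        # (-0.6, 0, 0.6): MLA = (0.6 + 0 + 0.6)/3 = 0.4 exactly
        b = np.array([-1.0, -1.0, 1.0, 1.0])
        o = np.array([-1.0, 1.0, -1.0, 1.0])
        x3 = np.repeat([-1.0, 0.0, 1.0], 4)
        x1 = np.tile(b, 3)
        x2 = np.concatenate([-0.6 * b + 0.8 * o, o, 0.6 * b + 0.8 * o])
        assert mla(x1, x2, x3) == pytest.approx(0.4, abs=1e-12)

    def test_equal_correlations_with_balanced_bins_cancel(self):
        b = np.array([-1.0, -1.0, 1.0, 1.0])
        x3 = np.repeat([-2.0, 0.0, 2.0], 4)  # bin means sum to 0
        assert mla(np.tile(b, 3), np.tile(b, 3), x3) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x1, x2, x3 = rng.standard_normal((3, 31))
            order = np.argsort(x3, kind="stable")
            bins = (order[:11], order[11:21], order[21:])
            expected = sum(
                np.corrcoef(x1[s], x2[s])[0, 1] * x3[s].mean() for s in bins
            ) / 3
            assert mla(x1, x2, x3) == pytest.approx(expected, abs=1e-12)

    def test_constant_bin_is_an_error(self):
        x1 = np.tile([1.0, 1.0, 1.0], 3)  # constant everywhere
        x2 = np.arange(9.0)
        with pytest.raises(ValueError, match="bin 0"):
            mla(x1, x2, np.arange(9.0))


class TestAssignScoutingGene:
    @staticmethod
    def _flip_triplet(rng, m=368):
        # corr(x, y) flips sign exactly at the median of c; pairs near-orthogonal
        c = rng.standard_normal(m)
        x = rng.standard_normal(m)
        y = np.sign(c - np.median(c)) * x + 0.3 * rng.standard_normal(m)
        return x, y, c

    def test_flip_conditioner_is_scout(self, rng):
        x, y, c = self._flip_triplet(rng)
        xt, yt, ct = map(normal_quantile_transform, (x, y, c))
        scout, by_role = assign_scouting_gene(xt, yt, ct, ("x", "y", "c"))
        assert scout == "c"
        # oracle: brute-force MLA for all three roles
        assert by_role["c"] == pytest.approx(mla(xt, yt, ct), abs=1e-12)
        assert by_role["x"] == pytest.approx(mla(yt, ct, xt), abs=1e-12)
        assert by_role["y"] == pytest.approx(mla(xt, ct, yt), abs=1e-12)

    def test_total_on_independent_noise(self, rng):
        x, y, z = rng.standard_normal((3, 60))
        scout, by_role = assign_scouting_gene(x, y, z, ("a", "b", "c"))
        assert scout in ("a", "b", "c")
        assert len(by_role) == 3

    def test_order_invariant_away_from_ties(self, rng):
        x, y, c = self._flip_triplet(rng)
        s1, _ = assign_scouting_gene(x, y, c, ("x", "y", "c"))
        s2, _ = assign_scouting_gene(c, x, y, ("c", "x", "y"))
        s3, _ = assign_scouting_gene(y, c, x, ("y", "c", "x"))
        assert s1 == s2 == s3 == "c"


def test_pearson_constant_vector_is_nan():
    assert np.isnan(pearson(np.ones(5), np.arange(5.0)))
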