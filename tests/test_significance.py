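import numpy as np
import pytest

from liquidassoc import (
    ExpressionMatrix,
    ReferenceDistribution,
    build_reference_distribution,
    estimate_fdr,
    la_score,
    la_threshold,
    local_permutation_p,
    normal_quantile_transform,
    permutation_p_value,
    transform_matrix,
)

from conftest import planted_profiles


def make_ref(pos, neg, seed=0):
    pos = np.asarray(pos, dtype=float)
    return ReferenceDistribution(pos, np.asarray(neg, dtype=float), len(pos), seed)


class TestReferenceDistribution:
    def test_vectors_sorted_on_construction(self):
        ref = make_ref([0.3, 0.1, 0.2], [-0.2, -0.3, -0.1])
        assert list(ref.pos_extremes) == [0.1, 0.2, 0.3]
        assert list(ref.neg_extremes) == [-0.3, -0.2, -0.1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReferenceDistribution(np.zeros(3), np.zeros(2), 3, 0)


class TestBuildReferenceDistribution:
    def test_count_contract_and_signs(self, noise_matrix):
        ref = build_reference_distribution(noise_matrix, 100, seed=1)
        assert len(ref.pos_extremes) == 100
        assert len(ref.neg_extremes) == 100
        assert (ref.pos_extremes > 0).all()
        assert (ref.neg_extremes < 0).all()

    def test_deterministic_given_seed(self, noise_matrix):
        a = build_reference_distribution(noise_matrix, 20, seed=7)
        b = build_reference_distribution(noise_matrix, 20, seed=7)
        np.testing.assert_array_equal(a.pos_extremes, b.pos_extremes)
        np.testing.assert_array_equal(a.neg_extremes, b.neg_extremes)

    def test_extremes_match_brute_force_with_stubbed_sampler(self, rng):
        mat = transform_matrix(ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(5)],
            sample_ids=[f"s{j}" for j in range(6)],
            values=rng.standard_normal((5, 6)),
        ))
        fixed = (rng.standard_normal(6), rng.standard_normal(6))

        def stub(_rng, _matrix):
            return fixed

        ref = build_reference_distribution(mat, 3, seed=0, sampler=stub)
        x = normal_quantile_transform(fixed[0])
        y = normal_quantile_transform(fixed[1])
        scores = [la_score(x, y, mat.values[j]) for j in range(5)]
        assert ref.pos_extremes == pytest.approx([max(scores)] * 3)
        assert ref.neg_extremes == pytest.approx([min(scores)] * 3)

    def test_rejects_bad_permutation_count(self, noise_matrix):
        with pytest.raises(ValueError):
            build_reference_distribution(noise_matrix, 0, seed=0)


class TestLaThreshold:
    def test_ten_percent_tail_of_ten_values(self):
        ref = make_ref(np.arange(0.1, 1.05, 0.1), -np.arange(0.1, 1.05, 0.1))
        pos, neg = la_threshold(ref, 0.1)
        assert pos == pytest.approx(1.0)
        assert neg == pytest.approx(-1.0)

    def test_median_tail(self):
        ref = make_ref(np.arange(0.1, 1.05, 0.1), -np.arange(0.1, 1.05, 0.1))
        pos, neg = la_threshold(ref, 0.5)
        # inverse-ECDF order statistics around the median of 10 values
        assert pos == pytest.approx(0.6)
        assert neg == pytest.approx(-0.6)

    def test_matches_sort_and_index_oracle(self, rng):
        pos = rng.standard_normal(1000) + 3
        neg = rng.standard_normal(1000) - 3
        ref = make_ref(pos, neg)
        got_pos, got_neg = la_threshold(ref, 0.01)
        assert got_pos == np.sort(pos)[990]   # floor(1000 * 0.99)
        assert got_neg == np.sort(neg)[9]     # ceil(1000 * 0.01) - 1

    def test_warns_when_tail_unresolvable(self):
        ref = make_ref([0.5, 0.6], [-0.5, -0.6])
        with pytest.warns(UserWarning, match="cannot resolve"):
            la_threshold(ref, 1e-3)

    def test_invalid_tail(self):
        ref = make_ref([0.5], [-0.5])
        with pytest.raises(ValueError):
            la_threshold(ref, 0.0)


class TestPermutationPValue:
    def test_add_one_floor(self, rng):
        ref = make_ref(rng.random(999), -rng.random(999))
        assert permutation_p_value(2.0, ref) == pytest.approx(1 / 1000)

    def test_tie_counts_as_exceedance(self, rng):
        pos = np.sort(rng.random(999))
        ref = make_ref(pos, -pos)
        assert permutation_p_value(float(pos[-1]), ref) == pytest.approx(2 / 1000)

    def test_matches_counting_oracle(self, rng):
        ref = make_ref(rng.standard_normal(200), rng.standard_normal(200) - 1)
        for score in rng.standard_normal(50) * 2:
            if score >= 0:
                expected = (1 + int((ref.pos_extremes >= score).sum())) / 201
            else:
                expected = (1 + int((ref.neg_extremes <= score).sum())) / 201
            assert permutation_p_value(float(score), ref) == pytest.approx(expected)

    def test_monotone_in_magnitude(self, rng):
        ref = make_ref(rng.standard_normal(500), rng.standard_normal(500))
        grid = np.linspace(0, 3, 40)
        p_pos = [permutation_p_value(s, ref) for s in grid]
        p_neg = [permutation_p_value(-s, ref) for s in grid]
        assert all(a >= b for a, b in zip(p_pos, p_pos[1:]))
        assert all(a >= b for a, b in zip(p_neg, p_neg[1:]))

    def test_threshold_p_consistency(self, rng):
        ref = make_ref(rng.standard_normal(1000) + 3, rng.standard_normal(1000) - 3)
        for tail in (0.01, 0.05, 0.2):
            pos_thr, neg_thr = la_threshold(ref, tail)
            bound = tail * (1 + 1 / 1000) + 1 / 1001
            assert permutation_p_value(pos_thr, ref) <= bound
            assert permutation_p_value(neg_thr, ref) <= bound


class TestEstimateFdr:
    @pytest.mark.parametrize(
        "n, p, d, expected",
        [
            (10**6, 1e-5, 100, 0.1),
            (1000, 0.01, 10, 1.0),   # D = N*p exactly
            (1000, 0.01, 40, 0.25),
        ],
    )
    def test_plug_in_formula(self, n, p, d, expected):
        assert estimate_fdr(n, p, d) == pytest.approx(expected)

    def test_no_discoveries_is_undefined(self):
        assert estimate_fdr(100, 0.01, 0) is None

    @pytest.mark.parametrize("args", [(0, 0.1, 1), (10, 0.0, 1), (10, 0.1, -1)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            estimate_fdr(*args)


class TestLocalPermutationP:
    def test_add_one_bound_when_observed_dominates(self):
        # theta = 2 puts the observed score ~10 null SDs out: no permutation
        # can reach it, so p hits the add-one floor 1/(B + 1)
        gen = np.random.default_rng(12)
        x, y, z = planted_profiles(2.0, 368, gen)
        x, y, z = map(normal_quantile_transform, (x, y, z))
        assert local_permutation_p(x, y, z, n_perm=999, seed=5) == pytest.approx(1 / 1000)

    def test_power_on_planted_triplet(self):
        gen = np.random.default_rng(13)
        hits = 0
        for _ in range(20):
            x, y, z = planted_profiles(0.5, 368, gen)
            x, y, z = map(normal_quantile_transform, (x, y, z))
            hits += local_permutation_p(x, y, z, n_perm=2000, seed=1) < 0.01
        assert hits >= 19

    def test_deterministic_and_valid_range(self, rng):
        x, y, z = rng.standard_normal((3, 50))
        p1 = local_permutation_p(x, y, z, n_perm=500, seed=3)
        p2 = local_permutation_p(x, y, z, n_perm=500, seed=3)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_rejects_bad_n_perm(self, rng):
        x, y, z = rng.standard_normal((3, 10))
        with pytest.raises(ValueError):
            local_permutation_p(x, y, z, n_perm=0, seed=0)
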