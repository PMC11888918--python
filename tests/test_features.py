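"""MC features: CCC oracle, copula-MI estimator, normalization, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgmc import (
    MultiChannelRecording,
    apply_normalizer,
    ccc,
    copula_mi,
    fit_normalizer,
    mc_features,
    pairwise_ccc,
    pairwise_mi,
    pseudo_observations,
    time_domain_features,
)
from emgmc.features import pair_order


def lin_ccc_reference(x, y):
    """Independent brute-force Lin's concordance (explicit sums)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestCCC:
    def test_matches_independent_reference_on_random_pairs(self, rng):
        worst = 0.0
        for _ in range(100):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50) + rng.uniform(-2, 2)
            worst = max(worst, abs(ccc(x, y) - lin_ccc_reference(x, y)))
        assert worst < 1e-12

    def test_self_concordance_is_one(self, rng):
        x = rng.standard_normal(100)
        assert ccc(x, x) == pytest.approx(1.0)

    def test_negated_zero_mean_series_is_minus_one(self, rng):
        x = rng.standard_normal(100)
        x -= x.mean()
        assert ccc(x, -x) == pytest.approx(-1.0)

    def test_mean_shift_formula(self, rng):
        # y = x + c with zero-mean x: ccc = 2 s^2 / (2 s^2 + c^2)
        x = rng.standard_normal(2000)
        x -= x.mean()
        s2 = np.mean(x**2)
        assert ccc(x, x + 1.0) == pytest.approx(2 * s2 / (2 * s2 + 1.0), abs=1e-12)

    def test_degenerate_equal_constants_return_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert ccc(np.ones(10), np.ones(10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ccc(np.ones(5), np.ones(6))

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_bounded_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(30), r.standard_normal(30) * r.uniform(0.1, 3)
        v = ccc(x, y)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(ccc(y, x), abs=1e-15)


class TestPseudoObservations:
    def test_rank_example(self):
        np.testing.assert_allclose(
            pseudo_observations([5.0, 1.0, 3.0]), [0.75, 0.25, 0.5]
        )

    def test_ties_get_average_ranks(self):
        np.testing.assert_allclose(pseudo_observations([2.0, 2.0]), [0.5, 0.5])

    def test_invariant_under_monotone_map(self, rng):
        x = rng.standard_normal(200)
        np.testing.assert_array_equal(
            pseudo_observations(x), pseudo_observations(np.exp(x))
        )

    def test_strictly_inside_unit_interval(self, rng):
        u = pseudo_observations(rng.standard_normal(500))
        assert np.all(u > 0) and np.all(u < 1)


class TestCopulaMI:
    def test_independent_series_near_zero(self):
        vals = []
        for s in range(5):
            r = np.random.default_rng(900 + s)
            vals.append(copula_mi(r.standard_normal(2000), r.standard_normal(2000)))
        assert abs(np.mean(vals)) < 0.05

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.6, 0.9])
    def test_gaussian_closed_form(self, r):
        true_mi = -0.5 * np.log(1 - r * r) if r else 0.0
        errs = []
        for s in range(10):
            g = np.random.default_rng(200 + s)
            x = g.standard_normal(2000)
            y = r * x + np.sqrt(1 - r * r) * g.standard_normal(2000)
            errs.append(abs(copula_mi(x, y) - true_mi))
        assert np.mean(errs) < 0.1

    def test_monotone_transform_invariance_exact(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        assert copula_mi(x, y) == copula_mi(np.exp(x), y**3)

    def test_deterministic_dependence_is_strong(self, rng):
        x = rng.standard_normal(2000)
        mi_cubic = copula_mi(x, x**3)
        assert mi_cubic > 1.0
        assert mi_cubic == copula_mi(x, x)  # same copula

    def test_symmetry_within_noise(self, rng):
        x = rng.standard_normal(1000)
        y = 0.5 * x + rng.standard_normal(1000)
        assert copula_mi(x, y) == pytest.approx(copula_mi(y, x), abs=0.05)

    def test_short_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            copula_mi(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            copula_mi(np.ones(50), np.arange(50.0))


class TestMCVector:
    @pytest.mark.parametrize("m", range(2, 9))
    def test_length_is_m_times_m_minus_one(self, rng, m):
        rec = MultiChannelRecording(rng.standard_normal((200, m)), 1000.0)
        fv = mc_features(rec)
        assert len(fv.values) == m * (m - 1)
        assert len(pairwise_ccc(rec)) == m * (m - 1) // 2
        assert len(pairwise_mi(rec)) == m * (m - 1) // 2

    def test_pair_order_is_row_major(self):
        assert pair_order(4) == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_ccc_entries_bounded_and_mi_entries_nearly_nonnegative(self, rng):
        rec = MultiChannelRecording(rng.standard_normal((2000, 4)), 1000.0)
        fv = mc_features(rec)
        assert np.all(np.abs(fv.ccc_values) <= 1.0)
        # independent channels: the k-NN estimator's boundary bias keeps
        # small negative values possible, but never far below zero
        assert np.all(fv.mi_values >= -0.1)

    def test_channel_permutation_permutes_entries(self, rng):
        v = rng.standard_normal((300, 4))
        rec = MultiChannelRecording(v, 1000.0)
        perm = MultiChannelRecording(v[:, [2, 0, 3, 1]], 1000.0)
        a = mc_features(rec).values
        b = mc_features(perm).values
        assert sorted(np.round(a, 10)) == sorted(np.round(b, 10))

    def test_dependent_pair_dominates_mi_vector(self, rng):
        v = rng.standard_normal((1000, 3))
        v[:, 2] = np.tanh(v[:, 0])  # monotone function of channel 0
        mi = pairwise_mi(MultiChannelRecording(v, 1000.0))
        # pair (0,2) is index 1 in row-major order for M=3
        assert np.argmax(mi) == 1


class TestNormalizer:
    def test_two_sample_population_std(self):
        stats = fit_normalizer(np.array([[0.0], [2.0]]))
        assert stats.means[0] == 1.0 and stats.stds[0] == 1.0

    def test_fit_set_normalizes_to_zero_mean_unit_std(self, rng):
        f = rng.standard_normal((40, 6)) * 5 + 3
        out = apply_normalizer(f, fit_normalizer(f))
        assert np.max(np.abs(out.mean(axis=0))) < 1e-12
        assert np.max(np.abs(out.std(axis=0) - 1)) < 1e-12

    def test_constant_dimension_flagged_and_zeroed(self, rng):
        f = np.column_stack([rng.standard_normal(10), np.full(10, 2.0)])
        stats = fit_normalizer(f)
        assert stats.zero_variance.tolist() == [False, True]
        assert np.all(apply_normalizer(f, stats)[:, 1] == 0.0)

    def test_scale_invariance_of_zscores(self, rng):
        f = rng.standard_normal((30, 3))
        g = f.copy()
        g[:, 1] *= 10
        a = apply_normalizer(f, fit_normalizer(f))
        b = apply_normalizer(g, fit_normalizer(g))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        stats = fit_normalizer(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError):
            apply_normalizer(rng.standard_normal((5, 3)), stats)

    def test_sample_at_fit_mean_maps_to_zero(self, rng):
        f = rng.standard_normal((20, 4))
        stats = fit_normalizer(f)
        np.testing.assert_allclose(
            apply_normalizer(stats.means, stats), 0.0, atol=1e-12
        )


class TestTimeDomain:
    def test_hand_counted_square_wave(self):
        rec = MultiChannelRecording(
            np.array([[1.0], [-1.0], [1.0], [-1.0]]), 1000.0
        )
        mav, zc, wl, ssc = time_domain_features(rec)
        assert (mav, zc, wl, ssc) == (1.0, 3.0, 6.0, 2.0)

    def test_constant_signal(self):
        rec = MultiChannelRecording(np.full((50, 1), 2.5), 1000.0)
        mav, zc, wl, ssc = time_domain_features(rec)
        assert (mav, zc, wl, ssc) == (2.5, 0.0, 0.0, 0.0)

    def test_amplitude_homogeneity(self, rng):
        v = rng.standard_normal((100, 2))
        r1 = MultiChannelRecording(v, 1000.0)
        r2 = MultiChannelRecording(2 * v, 1000.0)
        f1 = time_domain_features(r1)
        f2 = time_domain_features(r2)
        m = 2
        np.testing.assert_allclose(f2[:m], 2 * f1[:m])          # MAV doubles
        np.testing.assert_allclose(f2[m:2*m], f1[m:2*m])        # ZC unchanged
        np.testing.assert_allclose(f2[2*m:3*m], 2 * f1[2*m:3*m])  # WL doubles
        np.testing.assert_allclose(f2[3*m:], f1[3*m:])          # SSC unchanged
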