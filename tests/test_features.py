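import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from zonegrade.features import (FEATURE_NAMES, GLRL_NAMES, HARALICK_NAMES,
                                HISTOGRAM_NAMES, OFFSETS, cooccurrence,
                                extract_features, glrl_features,
                                haralick_features, histogram_features,
                                quantize, run_length_matrix)
from zonegrade.io_preprocess import ROIFragment


def frag(px):
    return ROIFragment(np.asarray(px, float))


class TestQuantize:
    def test_constant_maps_to_level_one(self):
        q = quantize(np.full((61, 61), 5.0), G=128)
        assert set(q.levels.ravel()) == {1}

    def test_endpoints_hit_extreme_levels(self, rng):
        px = rng.uniform(0, 1, size=(8, 8))
        px[0, 0], px[-1, -1] = 0.0, 1.0
        q = quantize(px, G=16)
        assert q.levels[0, 0] == 1 and q.levels[-1, -1] == 16

    def test_derived_example_g4(self):
        q = quantize(np.array([[0.0, 0.5, 1.0]]), G=4)
        assert q.levels.tolist() == [[1, 3, 4]]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, seed):
        px = np.random.default_rng(seed).normal(size=(8, 8))
        q1 = quantize(px, G=32)
        q2 = quantize(2.5 * px + 17.0, G=32)
        np.testing.assert_array_equal(q1.levels, q2.levels)


class TestCooccurrence:
    def test_constant_single_entry(self):
        q = quantize(np.ones((4, 4)), G=4)
        P = cooccurrence(q, (0, 1)).P
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_opposite_offsets_are_transposes(self, rng):
        q = quantize(rng.normal(size=(9, 9)), G=5)
        P_fwd = cooccurrence(q, (0, 1)).P
        P_bwd = cooccurrence(q, (0, -1)).P
        np.testing.assert_allclose(P_bwd, P_fwd.T)
        np.testing.assert_allclose(cooccurrence(q, (1, 0)).P,
                                   cooccurrence(q, (-1, 0)).P.T)

    def test_two_by_two_example(self):
        q = quantize(np.array([[1.0, 2.0], [1.0, 2.0]]), G=2)
        P = cooccurrence(q, (0, 1)).P
        assert P[0, 1] == 1.0 and P.sum() == 1.0

    def test_is_probability_distribution(self, rng):
        q = quantize(rng.normal(size=(12, 12)), G=7)
        for off in OFFSETS:
            P = cooccurrence(q, off).P
            assert np.all(P >= 0)
            assert abs(P.sum() - 1) < 1e-12

    def test_thin_axis_rejected(self):
        q = quantize(np.array([[1.0, 2.0, 3.0]]), G=3)
        with pytest.raises(ValueError):
            cooccurrence(q, (1, 0))


class TestHaralick:
    def test_stripe_contrast(self):
        # alternating column stripes: every horizontal pair differs by 1 level
        px = np.tile([1.0, 2.0], (4, 2))
        q = quantize(px, G=2)
        P = cooccurrence(q, (0, 1)).P
        i = np.arange(1, 3)
        contrast = sum((a - b) ** 2 * P[a - 1, b - 1] for a in i for b in i)
        assert contrast == pytest.approx(1.0)

    def test_transpose_invariance_and_symmetrization(self, rng):
        # ASM, Contrast, IDM and Entropy are invariant under transposing
        # the matrix, so opposite offsets agree exactly; for the statistics
        # that are additionally *linear* in P (Contrast, IDM) the two-offset
        # mean equals the statistic of the symmetrized matrix
        q = quantize(rng.normal(size=(8, 8)), G=4)
        P1 = cooccurrence(q, (0, 1)).P
        P2 = cooccurrence(q, (0, -1)).P
        sym = (P1 + P2) / 2
        for name in ("angular_second_moment", "contrast",
                     "inverse_difference_moment", "entropy"):
            a = oracles.haralick_brute(P1)[name]
            b = oracles.haralick_brute(P2)[name]
            assert a == pytest.approx(b, abs=1e-12)
        for name in ("contrast", "inverse_difference_moment"):
            a = oracles.haralick_brute(P1)[name]
            b = oracles.haralick_brute(P2)[name]
            c = oracles.haralick_brute(sym)[name]
            assert (a + b) / 2 == pytest.approx(c, abs=1e-10)

    def test_matches_brute_force_on_random_fragments(self, rng):
        for _ in range(10):
            px = rng.normal(size=(8, 8))
            q = quantize(px, G=4)
            got = dict(zip(HARALICK_NAMES, haralick_features(q)))
            want = oracles.haralick_brute_mean(q.levels, 4)
            for name in HARALICK_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-8), name


class TestRunLength:
    def test_constant_rows(self):
        q = quantize(np.ones((4, 4)), G=4)
        rl = run_length_matrix(q, (0, 1))
        assert rl.R[0, 3] == 4 and rl.R.sum() == 4

    def test_alternating_all_unit_runs(self):
        px = np.tile([1.0, 2.0], (4, 2))
        q = quantize(px, G=2)
        rl = run_length_matrix(q, (0, 1))
        assert rl.R[:, 0].sum() == 16 and rl.R[:, 1:].sum() == 0

    def test_hand_enumerated_row(self):
        px = np.array([[1, 1, 2, 3], [9, 9, 9, 9], [9, 9, 9, 9], [9, 9, 9, 9]],
                      dtype=float)
        q = quantize(px, G=9)
        rl = run_length_matrix(q, (0, 1))
        # first row: runs (level1, len2), (level2, len1), (level3, len1)
        assert rl.R[0, 1] == 1 and rl.R[1, 0] == 1 and rl.R[2, 0] == 1

    def test_opposite_directions_identical(self, rng):
        q = quantize(rng.normal(size=(9, 9)), G=4)
        np.testing.assert_array_equal(run_length_matrix(q, (0, 1)).R,
                                      run_length_matrix(q, (0, -1)).R)
        np.testing.assert_array_equal(run_length_matrix(q, (-1, 0)).R,
                                      run_length_matrix(q, (1, 0)).R)

    def test_pixel_conservation(self, rng):
        q = quantize(rng.normal(size=(11, 11)), G=6)
        for d in OFFSETS:
            R = run_length_matrix(q, d).R
            j = np.arange(1, R.shape[1] + 1)
            assert (R * j).sum() == 121


class TestGLRLFeatures:
    def test_constant_fragment_values(self):
        q = quantize(np.ones((4, 4)), G=4)
        got = dict(zip(GLRL_NAMES, glrl_features(q)))
        assert got["run_percentage"] == pytest.approx(0.25)
        assert got["long_run_emphasis"] == pytest.approx(16.0)

    def test_all_unit_runs(self):
        px = np.indices((4, 4)).sum(0) % 2 + 1.0  # checkerboard
        q = quantize(px, G=2)
        got = dict(zip(GLRL_NAMES, glrl_features(q)))
        assert got["short_run_emphasis"] == pytest.approx(1.0)
        assert got["run_percentage"] == pytest.approx(1.0)

    def test_sre_bounded_by_one(self, rng):
        for _ in range(5):
            q = quantize(rng.normal(size=(8, 8)), G=4)
            sre = dict(zip(GLRL_NAMES, glrl_features(q)))["short_run_emphasis"]
            assert sre <= 1.0 + 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            q = quantize(rng.normal(size=(8, 8)), G=4)
            got = dict(zip(GLRL_NAMES, glrl_features(q)))
            want = oracles.glrl_brute_mean(q.levels, 4)
            for name in GLRL_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-8), name


class TestHistogram:
    def test_basic_statistics(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, quantize(x, 4))))
        assert got["hist_mean"] == 2.5
        assert got["hist_median"] == 2.5
        assert got["hist_min"] == 1 and got["hist_max"] == 4
        # population variance of {1,2,3,4} is 1.25
        assert got["hist_variance"] == pytest.approx(1.25)
        # 10th percentile with linear interpolation: 1 + 0.3*(2-1)
        assert got["hist_p10"] == pytest.approx(1.3)

    def test_two_point_variance(self):
        x = np.array([[0.0, 2.0]])
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, quantize(x, 4))))
        assert got["hist_variance"] == pytest.approx(1.0)

    def test_uniform_quantized_energy(self):
        x = np.arange(16, dtype=float).reshape(4, 4)
        q = quantize(x, G=16)
        assert len(set(q.levels.ravel())) == 16
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, q)))
        assert got["hist_energy"] == pytest.approx(1 / 16)

    def test_moments_against_brute_force(self, rng):
        x = rng.normal(size=(8, 8))
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, quantize(x, 4))))
        s = np.sort(x.ravel())
        n = s.size
        mean = s.sum() / n
        m2 = sum((v - mean) ** 2 for v in s) / n
        m3 = sum((v - mean) ** 3 for v in s) / n
        m4 = sum((v - mean) ** 4 for v in s) / n
        assert got["hist_mean"] == pytest.approx(mean, abs=1e-10)
        assert got["hist_variance"] == pytest.approx(m2, abs=1e-10)
        assert got["hist_skewness"] == pytest.approx(m3 / m2 ** 1.5, abs=1e-10)
        assert got["hist_kurtosis"] == pytest.approx(m4 / m2 ** 2, abs=1e-10)

    def test_percentiles_monotone(self, rng):
        x = rng.normal(size=(61, 61))
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, quantize(x, 128))))
        p = [got[k] for k in ("hist_p10", "hist_p20", "hist_p30", "hist_p40",
                              "hist_p75")]
        assert all(a <= b for a, b in zip(p, p[1:]))

    def test_constant_fragment_conventions(self):
        x = np.full((4, 4), 2.0)
        got = dict(zip(HISTOGRAM_NAMES, histogram_features(x, quantize(x, 4))))
        assert got["hist_variance"] == 0.0
        assert got["hist_skewness"] == 0.0
        assert got["hist_kurtosis"] == 0.0
        assert got["hist_energy"] == 1.0  # all mass in level 1


class TestExtractFeatures:
    def test_panel_length_and_order(self, random_fragment):
        fv = extract_features(random_fragment)
        assert fv.values.shape == (38,)
        assert FEATURE_NAMES[:2] == ("short_run_emphasis", "long_run_emphasis")
        assert FEATURE_NAMES[11] == "angular_second_moment"
        assert FEATURE_NAMES[25] == "hist_mean"

    def test_constant_fragment_is_finite_with_conventions(self):
        fv = extract_features(frag(np.full((61, 61), 9.0)))
        d = fv.as_dict()
        assert np.all(np.isfinite(fv.values))
        assert d["hist_variance"] == 0.0
        assert d["contrast"] == 0.0
        assert d["angular_second_moment"] == 1.0

    def test_texture_affine_invariance(self, rng):
        px = rng.normal(100, 15, size=(61, 61))
        a = extract_features(frag(px)).values
        b = extract_features(frag(0.3 * px + 40.0)).values
        np.testing.assert_allclose(a[:25], b[:25], rtol=1e-9)

    def test_deterministic(self, random_fragment):
        a = extract_features(random_fragment).values
        b = extract_features(random_fragment).values
        assert np.array_equal(a, b)
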