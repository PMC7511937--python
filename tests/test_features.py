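import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from thermoliver.features import (
    CooccurrenceMatrix,
    cooccurrence,
    entropy,
    extract_features,
    glcm_stats,
    moments,
    quantize,
    rebin,
    shape_moments,
)
from thermoliver.io import FEATURE_NAMES, ROI


def small_map(rng, rows=None, cols=None, span=2.0):
    rows = rows or rng.integers(2, 10)
    cols = cols or rng.integers(21, 30)
    return 30.0 + span * rng.random((rows, cols))


class TestQuantize:
    def test_worked_example(self):
        q = quantize(np.array([[30.0, 30.1], [30.5, 30.0]]))
        assert q.levels.tolist() == [[0, 1], [5, 0]]

    def test_constant_map(self):
        q = quantize(np.full((3, 3), 31.7))
        assert q.levels.tolist() == [[0, 0, 0]] * 3
        assert q.n_levels == 1

    def test_half_away_rounding(self):
        q = quantize(np.array([[29.96, 30.04, 30.25]]))
        assert q.levels.tolist() == [[0, 0, 3]]

    @given(st.lists(st.lists(st.integers(-200, 1200), min_size=2, max_size=6),
                    min_size=2, max_size=6).filter(lambda rows: len({len(r) for r in rows}) == 1))
    def test_invariants_and_reconstruction(self, deci_rows):
        values = np.array(deci_rows, dtype=float) / 10.0
        q = quantize(values)
        assert q.levels.min() == 0
        assert np.issubdtype(q.levels.dtype, np.integer)
        # level · 0.1 + rounded ROI minimum recovers each rounded pixel
        recon = q.levels + int(round(q.offset_c * 10))
        np.testing.assert_array_equal(recon, np.array(deci_rows))


class TestMoments:
    def test_constant_roi(self):
        assert moments(np.full((4, 4), 37.0)) == (37.0, 0.0)

    def test_two_point(self):
        mean, var = moments(np.array([[30.0, 30.2]]))
        assert mean == pytest.approx(30.1)
        assert var == pytest.approx(0.01)

    def test_roi_restriction(self, ramp_map):
        mean, var = moments(ramp_map, ROI(0, 1, 0, 2))
        assert (mean, var) == (0.5, 0.25)

    def test_matches_two_pass_oracle(self, rng):
        arr = small_map(rng)
        mean, var = moments(arr)
        o_mean, o_var = oracles.brute_mean_var(arr.tolist())
        assert mean == pytest.approx(o_mean, rel=1e-12)
        assert var == pytest.approx(o_var, rel=1e-12)


class TestShapeMoments:
    def test_constant_roi_defined_as_zero(self):
        assert shape_moments(quantize(np.full((3, 3), 30.0))) == (0.0, 0.0)

    def test_symmetric_two_level(self):
        # equal counts of levels {0, 2}: m2 = 1, m3 = 0, m4 = 1
        skew, kurt = shape_moments(quantize(np.array([[30.0, 30.2], [30.2, 30.0]])))
        assert skew == pytest.approx(0.0)
        assert kurt == pytest.approx(1.0)

    def test_matches_central_moment_oracle(self, rng):
        arr = small_map(rng)
        skew, kurt = shape_moments(quantize(arr))
        o_skew, o_kurt = oracles.brute_shape_moments(oracles.brute_levels(arr.tolist()))
        assert skew == pytest.approx(o_skew, rel=1e-9)
        assert kurt == pytest.approx(o_kurt, rel=1e-9)


class TestEntropy:
    def test_constant_roi_zero_bits(self):
        assert entropy(quantize(np.full((5, 5), 30.0))) == 0.0

    def test_uniform_binary_one_bit(self):
        assert entropy(quantize(np.array([[30.0, 30.1]]))) == pytest.approx(1.0)

    def test_dyadic_distribution(self):
        # frequencies 1/2, 1/4, 1/8, 1/8 → 1.75 bits
        vals = [30.0] * 4 + [30.1] * 2 + [30.2] + [30.3]
        assert entropy(quantize(np.array([vals]))) == pytest.approx(1.75)

    def test_bounded_by_log2_levels(self, rng):
        arr = small_map(rng)
        q = quantize(arr)
        assert 0.0 <= entropy(q) <= np.log2(q.n_levels) + 1e-12


class TestCooccurrence:
    def test_hand_enumerated_pairs(self):
        # 1×22 row: only columns 0, 1 pair with 20, 21
        vals = 30.0 + 0.1 * np.array([[0, 1] + [5] * 18 + [0, 1]], dtype=float)
        q = quantize(vals)
        P = cooccurrence(q, offset=(0, 20))
        assert P.n_pairs == 2
        assert P.p[0, 0] == pytest.approx(0.5)
        assert P.p[1, 1] == pytest.approx(0.5)
        assert P.p.sum() == pytest.approx(1.0)

    def test_constant_roi(self):
        P = cooccurrence(quantize(np.full((3, 25), 30.0)))
        assert P.p.tolist() == [[1.0]]

    def test_narrow_roi_raises(self):
        with pytest.raises(ValueError, match="larger ROI or a smaller offset"):
            cooccurrence(quantize(np.full((3, 20), 30.0)), offset=(0, 20))

    def test_matches_pair_enumeration_oracle(self, rng):
        arr = small_map(rng)
        q = quantize(arr)
        P = cooccurrence(q, offset=(0, 20))
        o_p, o_pairs = oracles.brute_glcm(q.levels.tolist(), (0, 20))
        assert P.n_pairs == o_pairs
        np.testing.assert_allclose(P.p, o_p, atol=1e-12)

    def test_matches_skimage_graycomatrix(self, rng):
        from skimage.feature import graycomatrix

        arr = small_map(rng, rows=8, cols=25, span=1.0)
        q = quantize(arr)
        P = cooccurrence(q, offset=(0, 20))
        ref = graycomatrix(
            q.levels.astype(np.uint8), distances=[20], angles=[0],
            levels=q.n_levels, symmetric=False, normed=True,
        )[:, :, 0, 0]
        np.testing.assert_allclose(P.p, ref, atol=1e-12)


class TestGlcmStats:
    def test_degenerate_single_cell(self):
        P = CooccurrenceMatrix(np.array([[1.0]]), (0, 20), 10)
        assert glcm_stats(P) == (0.0, 1.0, 1.0, 0.0)

    def test_perfectly_correlated_diagonal(self):
        P = CooccurrenceMatrix(np.array([[0.5, 0.0], [0.0, 0.5]]), (0, 20), 2)
        contrast, homog, energy, corr = glcm_stats(P)
        assert (contrast, homog, energy) == (0.0, 1.0, 0.5)
        assert corr == pytest.approx(1.0)

    def test_perfectly_anticorrelated(self):
        P = CooccurrenceMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), (0, 20), 2)
        contrast, homog, energy, corr = glcm_stats(P)
        assert (contrast, homog, energy) == (1.0, 0.5, 0.5)
        assert corr == pytest.approx(-1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            glcm_stats(CooccurrenceMatrix(np.array([[0.7, 0.0], [0.0, 0.7]]), (0, 20), 2))


class TestExtractFeatures:
    def test_nine_finite_values(self, rng):
        fv = extract_features(small_map(rng))
        arr = fv.to_array()
        assert arr.shape == (9,)
        assert np.all(np.isfinite(arr))
        assert len(FEATURE_NAMES) == 9

    def test_constant_roi_composition(self):
        fv = extract_features(np.full((4, 30), 36.5))
        assert fv.to_array().tolist() == [36.5, 0, 0, 0, 0, 0, 1, 1, 0]

    def test_ranges(self, rng):
        fv = extract_features(small_map(rng))
        assert 0.0 <= fv.homogeneity <= 1.0
        assert 0.0 < fv.energy <= 1.0
        assert -1.0 <= fv.correlation <= 1.0
        assert fv.variance >= 0.0 and fv.entropy >= 0.0

    @given(st.integers(-50, 50), st.integers(0, 400))
    @settings(max_examples=40)
    def test_translation_invariance(self, shift_deci, seed_offset):
        # shift by an exact multiple of 0.1 °C: only the mean moves
        rng = np.random.default_rng(900 + seed_offset)
        base = np.round(30.0 + rng.random((4, 25)), 1)
        shifted = (base * 10 + shift_deci) / 10.0
        a = extract_features(base).to_array()
        b = extract_features(shifted).to_array()
        assert b[0] == pytest.approx(a[0] + shift_deci / 10.0, abs=1e-9)
        np.testing.assert_allclose(b[1:], a[1:], rtol=1e-9, atol=1e-12)

    def test_rebin_coarsens_levels(self, rng):
        q = quantize(small_map(rng, span=4.0))
        q8 = rebin(q, 8)
        assert q8.n_levels <= 8
        assert q8.levels.min() == 0
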