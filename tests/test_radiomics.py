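import numpy as np
import pytest

from oracles import (
    brute_glcm_features,
    brute_glcm_matrix,
    brute_glrlm_features,
    brute_glrlm_matrix,
)

from ocpam.config import RadiomicsParams
from ocpam.core import LabelMask, Volume3D
from ocpam.radiomics import (
    DIRECTIONS_3D,
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    TextureFeatureVector,
    _glcm_matrix,
    discretize,
    extract_feature_vector,
    first_order_features,
    glcm_features,
    glrlm_features,
)

TOP9 = (
    "Sum Entropy", "Run Percentage", "Joint Entropy", "Difference Entropy",
    "Run Length Non-Uniformity Normalized", "Autocorrelation", "Joint Average",
    "Gray Level Variance", "Run Entropy",
)


def _random_roi(seed, shape=(6, 6, 6), n_levels=8, holes=0.15):
    rng = np.random.default_rng(seed)
    vol = rng.random(shape)
    roi = np.ones(shape, bool)
    roi[rng.random(shape) < holes] = False
    return discretize(vol, roi, n_levels)


class TestDiscretize:
    def test_identity_mapping_plus_one(self):
        vals = np.arange(32, dtype=float).reshape(2, 4, 4)
        d = discretize(vals, np.ones(vals.shape, bool), 32)
        assert np.array_equal(d.levels[d.mask], vals.ravel().astype(int) + 1)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random((4, 4, 4))
        roi = np.ones(vals.shape, bool)
        a = discretize(vals, roi, 16)
        b = discretize(3.5 * vals + 11.0, roi, 16)
        assert np.array_equal(a.levels, b.levels)

    def test_constant_roi_single_level(self):
        d = discretize(np.full((3, 3, 3), 5.0), np.ones((3, 3, 3), bool), 8)
        assert set(d.levels[d.mask]) == {1}

    def test_out_of_roi_excluded(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0] = 100.0  # extreme value outside the ROI
        roi = np.ones((3, 3, 3), bool)
        roi[0, 0, 0] = False
        d = discretize(vals, roi, 8)
        assert d.raw.max() == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), 8)


class TestFirstOrder:
    def test_constant_roi(self):
        d = discretize(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool), 8)
        f = first_order_features(d)
        assert f["Variance"] == 0.0 and f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0 and f["Range"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_two_equiprobable_levels(self):
        vals = np.array([0.0, 1.0] * 8).reshape(1, 4, 4)
        d = discretize(vals, np.ones(vals.shape, bool), 2)
        f = first_order_features(d)
        assert f["Entropy"] == pytest.approx(1.0)  # one bit
        assert f["Uniformity"] == pytest.approx(0.5)

    def test_moments_match_direct_formula(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(0.0, 0.8, (5, 5, 5))  # skewed sample
        d = discretize(vals, np.ones(vals.shape, bool), 32)
        f = first_order_features(d)
        x = vals.ravel()
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert f["Mean"] == pytest.approx(m, abs=1e-10)
        assert f["Variance"] == pytest.approx(m2, abs=1e-10)
        assert f["Skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-10)
        assert f["Kurtosis"] == pytest.approx(m4 / m2**2, abs=1e-10)
        assert f["Energy"] == pytest.approx((x**2).sum(), rel=1e-12)


class TestGlcm:
    @pytest.mark.parametrize("seed", [42, 43, 44])
    def test_matches_brute_force_enumeration(self, seed):
        d = _random_roi(seed)
        per_dir = []
        for off in DIRECTIONS_3D:
            p = brute_glcm_matrix(d.levels, d.mask, off, d.n_levels)
            if p is not None:
                per_dir.append(brute_glcm_features(p))
        expected = {k: np.mean([f[k] for f in per_dir]) for k in GLCM_NAMES}
        got = glcm_features(d)
        for k in GLCM_NAMES:
            assert got[k] == pytest.approx(expected[k], abs=1e-8), k

    def test_alternating_sequence_closed_form(self):
        seq = np.array([0.0, 1.0] * 8).reshape(1, 1, 16)
        d = discretize(seq, np.ones(seq.shape, bool), 2)
        f = glcm_features(d, 1, [(0, 0, 1)])
        # P(1,2)=P(2,1)=0.5 exactly
        assert f["Joint Entropy"] == pytest.approx(1.0)
        assert f["Joint Energy"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(1.0)

    def test_constant_roi(self):
        d = discretize(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool), 8)
        f = glcm_features(d)
        assert f["Joint Entropy"] == 0.0 and f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0  # degenerate-variance convention

    def test_matrix_symmetric_normalised(self):
        d = _random_roi(3)
        for off in DIRECTIONS_3D:
            p = _glcm_matrix(d, off)
            if p is None:
                continue
            assert p.sum() == pytest.approx(1.0)
            assert np.allclose(p, p.T)
            assert np.all(p >= 0)

    def test_rotation_robustness(self):
        d0 = _random_roi(11, shape=(7, 7, 7), holes=0.0)
        vol = np.random.default_rng(11).random((7, 7, 7))
        roi = np.ones((7, 7, 7), bool)
        a = glcm_features(discretize(vol, roi, 8))
        b = glcm_features(discretize(vol.transpose(2, 0, 1), roi, 8))
        for k in GLCM_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-8), k


class TestGlrlm:
    @pytest.mark.parametrize("seed", [42, 43, 44])
    def test_matches_brute_force_run_scan(self, seed):
        d = _random_roi(seed)
        per_dir = [
            brute_glrlm_features(
                brute_glrlm_matrix(d.levels, d.mask, off, d.n_levels), d.n_voxels
            )
            for off in DIRECTIONS_3D
        ]
        expected = {k: np.mean([f[k] for f in per_dir]) for k in GLRLM_NAMES}
        got = glrlm_features(d)
        for k in GLRLM_NAMES:
            assert got[k] == pytest.approx(expected[k], abs=1e-8), k

    def test_row_run_percentage_closed_form(self):
        row = np.array([1.0, 1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 5)
        d = discretize(row, np.ones(row.shape, bool), 2)
        f = glrlm_features(d, [(0, 0, 1)])
        assert f["Run Percentage"] == pytest.approx(0.4)  # 2 runs / 5 voxels

    def test_constant_line_closed_form(self):
        n = 10
        const = np.zeros((1, 1, n))
        d = discretize(const, np.ones(const.shape, bool), 8)
        f = glrlm_features(d, [(0, 0, 1)])
        assert f["Run Percentage"] == pytest.approx(1.0 / n)
        assert f["Long Run Emphasis"] == pytest.approx(n**2)

    def test_rotation_robustness(self):
        vol = np.random.default_rng(12).random((7, 7, 7))
        roi = np.ones((7, 7, 7), bool)
        a = glrlm_features(discretize(vol, roi, 8))
        b = glrlm_features(discretize(vol.transpose(2, 0, 1), roi, 8))
        for k in GLRLM_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-8), k


class TestFeatureVector:
    def test_exactly_32_partitioned_9_13_10(self):
        assert len(FEATURE_NAMES) == 32
        assert len(FIRST_ORDER_NAMES) == 9
        assert len(GLCM_NAMES) == 13
        assert len(GLRLM_NAMES) == 10
        assert FEATURE_NAMES == FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES

    def _volume_and_mask(self, seed=0, constant=None):
        rng = np.random.default_rng(seed)
        data = rng.random((8, 8, 8)) if constant is None else np.full((8, 8, 8),
                                                                      constant)
        labels = np.zeros((8, 8, 8), np.int32)
        labels[1:7, 1:7, 1:7] = 1
        return (Volume3D(data, (1, 1, 1)), LabelMask(labels, (1, 1, 1)))

    def test_vector_length_and_order(self):
        vol, mask = self._volume_and_mask()
        fv = extract_feature_vector(vol, mask, 1)
        assert tuple(fv.values) == FEATURE_NAMES
        assert fv.as_array().shape == (32,)
        assert np.all(np.isfinite(fv.as_array()))

    def test_constant_roi_degenerate_values(self):
        vol, mask = self._volume_and_mask(constant=3.0)
        fv = extract_feature_vector(vol, mask, 1)
        assert fv.values["Entropy"] == 0.0
        assert fv.values["Joint Entropy"] == 0.0
        assert fv.values["Uniformity"] == 1.0
        assert fv.values["Joint Energy"] == 1.0
        assert fv.values["Variance"] == 0.0
        assert fv.values["Sum of Squares"] == 0.0

    def test_small_roi_rejected(self):
        vol, mask = self._volume_and_mask()
        small = mask.labels.copy()
        small[:] = 0
        small[2, 2, 2:4] = 1
        with pytest.raises(ValueError, match="below the minimum"):
            extract_feature_vector(vol, LabelMask(small, (1, 1, 1)), 1)

    def test_missing_label_rejected(self):
        vol, mask = self._volume_and_mask()
        with pytest.raises(ValueError, match="not present"):
            extract_feature_vector(vol, mask, 9)

    def test_level_based_features_affine_invariant(self):
        vol, mask = self._volume_and_mask(seed=5)
        fv1 = extract_feature_vector(vol, mask, 1)
        fv2 = extract_feature_vector(vol.with_data(4.0 * vol.data + 7.0), mask, 1)
        invariant = list(GLCM_NAMES) + list(GLRLM_NAMES) + ["Entropy", "Uniformity"]
        for k in invariant:
            assert fv1.values[k] == pytest.approx(fv2.values[k], rel=1e-9), k

    def test_wrong_names_rejected(self):
        with pytest.raises(ValueError, match="32 named"):
            TextureFeatureVector(label=1, values={"Mean": 1.0})


class TestSeparability:
    def test_top_feature_effect_size(self, feature_dataset):
        # at least one of the nine headline features separates the HIGH and
        # LOW texture regimes with |d| > 1 at n = 50+/class
        X, y = feature_dataset
        names = list(FEATURE_NAMES)
        best = 0.0
        for f in TOP9:
            i = names.index(f)
            a, b = X[y == "HIGH", i], X[y == "LOW", i]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            if pooled > 0:
                best = max(best, abs(a.mean() - b.mean()) / pooled)
        assert best > 1.0
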