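"""Feature battery: counts, hand-computed oracles, invariances."""

import numpy as np
import pytest

from synthrad import radiomics as rad
from synthrad.data_io import Modality
from synthrad.radiomics import (
    DegenerateMaskError, EmptyMaskError, FEATURE_NAMES, discretize,
    extract_features, glcm_matrix, glrlm_features, intensity_features,
    shape_features, texture_features, wavelet_features, wavelet_subbands,
)


class TestBatteryContract:
    def test_526_features_with_family_partition(self, small_case):
        vec = extract_features(small_case.dwi_b0, small_case.mask)
        assert len(vec) == 526
        fams = {"shape_": 0, "intensity_": 0, "glcm_": 0, "glrlm_": 0,
                "ngtdm_": 0, "wavelet_": 0}
        for name in vec.index:
            for fam in fams:
                if name.startswith(fam):
                    fams[fam] += 1
                    break
        assert fams == {"shape_": 13, "intensity_": 18, "glcm_": 22,
                        "glrlm_": 13, "ngtdm_": 4, "wavelet_": 456}
        assert np.isfinite(vec.to_numpy()).all()

    def test_registry_is_stable_and_ordered(self, small_case):
        vec = extract_features(small_case.t2, small_case.mask)
        assert list(vec.index) == FEATURE_NAMES

    def test_deterministic_bit_identical(self, small_case):
        a = extract_features(small_case.adc, small_case.mask)
        b = extract_features(small_case.adc, small_case.mask)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_empty_mask_raises(self, small_case):
        with pytest.raises(EmptyMaskError):
            extract_features(small_case.t2, np.zeros_like(small_case.mask))

    def test_single_voxel_mask_shape_ok_texture_fails(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        vol = np.random.default_rng(0).uniform(size=(8, 8, 8))
        sf = shape_features(mask, (1, 1, 1))
        assert sf["shape_volume"] == pytest.approx(1.0)
        with pytest.raises(DegenerateMaskError):
            texture_features(vol, mask)


class TestIntensity:
    def test_simple_sample(self):
        f = intensity_features([1, 2, 3, 4, 5])
        assert f["intensity_mean"] == pytest.approx(3.0)
        assert f["intensity_range"] == pytest.approx(4.0)
        assert f["intensity_median"] == pytest.approx(3.0)

    def test_constant_sample_degenerate_histogram(self):
        f = intensity_features(np.full(20, 42.0))
        assert f["intensity_mean"] == 42.0
        assert f["intensity_variance"] == 0.0
        assert f["intensity_entropy"] == 0.0
        assert f["intensity_uniformity"] == 1.0

    def test_gaussian_moments(self):
        x = np.random.default_rng(7).standard_normal(1000)
        f = intensity_features(x)
        assert abs(f["intensity_skewness"]) < 0.25
        assert abs(f["intensity_kurtosis"]) < 0.25


class TestGLCM:
    def test_two_level_block_contrast_hand_computed(self):
        """4x4x1 half-and-half block: hand-enumerated co-occurrences."""
        vol = np.zeros((4, 4, 1))
        vol[2:, :, :] = 1.0  # two x-slabs of levels 1 and 2
        mask = np.ones((4, 4, 1), bool)
        levels = discretize(vol, mask, 2)
        M = glcm_matrix(levels, mask, 2)
        P = M / M.sum()
        contrast = float(((np.subtract.outer([1, 2], [1, 2])) ** 2 * P).sum())
        # hand enumeration over the 13 offsets within the 4x4 plane:
        # unequal pairs occur only across the x=1/x=2 boundary:
        # dx=1,dy=0: 4 pairs; dx=1,dy=+-1: 3+3 pairs -> 10 ordered*2 = 20
        # total pairs: x-dir 12, y-dir 12, two diagonals 9+9 -> 42 *2 = 84
        assert M.sum() == 84.0
        assert contrast == pytest.approx(20.0 / 84.0)

    def test_matrix_matches_bruteforce_pair_count(self, rng):
        """3x3x2 random levels against a triple-loop enumeration."""
        vol = rng.integers(0, 3, size=(3, 3, 2)).astype(float)
        mask = rng.uniform(size=(3, 3, 2)) > 0.2
        mask[0, 0, 0] = True  # guarantee non-empty
        levels = np.where(mask, vol.astype(int) + 1, 0)
        M = glcm_matrix(levels, mask, 3)
        brute = np.zeros((3, 3))
        shape = levels.shape
        for d in rad.DIRECTIONS_13:
            for x in range(shape[0]):
                for y in range(shape[1]):
                    for z in range(shape[2]):
                        u, v, w = x + d[0], y + d[1], z + d[2]
                        if not (0 <= u < shape[0] and 0 <= v < shape[1]
                                and 0 <= w < shape[2]):
                            continue
                        if mask[x, y, z] and mask[u, v, w]:
                            a, b = levels[x, y, z] - 1, levels[u, v, w] - 1
                            brute[a, b] += 1
                            brute[b, a] += 1
        assert np.array_equal(M, brute)

    def test_symmetry_and_normalization(self, small_case):
        vol = small_case.t2.voxels
        levels = discretize(vol, small_case.mask, 16)
        M = glcm_matrix(levels, small_case.mask, 16)
        assert np.array_equal(M, M.T)


class TestGLRLM:
    def test_alternating_levels_run_percentage_one(self):
        """A pattern alternating along every one of the 13 directions has
        only length-1 runs."""
        x, y, z = np.indices((6, 6, 6))
        vol = ((x + 2 * y + 4 * z) % 8).astype(float)
        mask = np.ones((6, 6, 6), bool)
        levels = discretize(vol, mask, 8)
        f = glrlm_features(levels, mask, 8)
        assert f["glrlm_run_percentage"] == pytest.approx(1.0)

    def test_constant_volume_single_long_runs(self):
        mask = np.ones((5, 1, 1), bool)
        levels = np.ones((5, 1, 1), dtype=np.int64)
        f = glrlm_features(levels, mask, 1)
        # along x: one run of length 5; the other 12 directions see
        # length-1 runs (5 each)
        assert f["glrlm_long_run_emphasis"] == pytest.approx(
            (1 * 25 + 60 * 1) / 61)


class TestShape:
    def test_digital_ball(self):
        x, y, z = np.ogrid[-15:16, -15:16, -15:16]
        ball = (x * x + y * y + z * z) <= 100.0
        f = shape_features(ball, (1.0, 1.0, 1.0))
        true_volume = 4.0 / 3.0 * np.pi * 1000.0
        assert f["shape_volume"] == pytest.approx(true_volume, rel=0.05)
        assert 0.95 <= f["shape_sphericity"] <= 1.0
        assert f["shape_max_3d_diameter"] == pytest.approx(20.0, rel=0.05)

    def test_box_volume_and_axis_ratios(self):
        """20x10x5 voxel box: exact volume; elongation/flatness match the
        discrete-uniform principal moments (n^2 - 1)/12."""
        box = np.zeros((26, 16, 11), bool)
        box[3:23, 3:13, 3:8] = True
        f = shape_features(box, (1.0, 1.0, 1.0))
        assert f["shape_volume"] == pytest.approx(1000.0)
        lam = sorted([(20 ** 2 - 1) / 12, (10 ** 2 - 1) / 12,
                      (5 ** 2 - 1) / 12], reverse=True)
        assert f["shape_elongation"] == pytest.approx(
            np.sqrt(lam[1] / lam[0]), rel=1e-6)
        assert f["shape_flatness"] == pytest.approx(
            np.sqrt(lam[2] / lam[0]), rel=1e-6)
        assert f["shape_major_axis_length"] == pytest.approx(
            4 * np.sqrt(lam[0] * 1000 / 999), rel=1e-6)  # ddof-1 covariance

    def test_intensity_invariance(self, small_case):
        a = shape_features(small_case.mask, small_case.t2.spacing)
        b = shape_features(small_case.mask, small_case.t2.spacing)
        assert a == b  # shape never sees intensities by signature


class TestWavelet:
    def test_456_features_eight_subbands(self, small_case):
        f = wavelet_features(small_case.dwi_b0.voxels, small_case.mask)
        assert len(f) == 456
        subbands = {n.split("_")[1] for n in f}
        assert subbands == set(rad.SUBBANDS)

    def test_lll_of_constant_volume_is_constant(self):
        bands = wavelet_subbands(np.full((8, 8, 8), 3.0))
        lll = bands["LLL"]
        assert np.allclose(lll, lll.ravel()[0])  # constant up to filter norm
        for name in ("LLH", "HHH"):
            assert np.allclose(bands[name], 0.0)

    def test_lll_mean_tracks_original_mean(self, cohort50):
        """Across the cohort, the low-pass sub-band mean stays highly
        correlated with the original in-mask mean."""
        cases = cohort50[:30]
        orig = [float(c.dwi_b0.voxels[c.mask].mean()) for c in cases]
        lll = [float(wavelet_subbands(c.dwi_b0.voxels)["LLL"][c.mask].mean())
               for c in cases]
        assert np.corrcoef(orig, lll)[0, 1] > 0.95

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            wavelet_subbands(np.zeros((4, 4, 4)))


class TestInvariances:
    def test_out_of_mask_changes_do_not_leak(self, small_case):
        """Intensity and texture features depend only on in-mask voxels
        (wavelet features are excluded: their filters straddle the mask
        boundary by construction)."""
        vol = small_case.t2.voxels.copy()
        mask = small_case.mask
        vol2 = vol.copy()
        vol2[~mask] = vol2[~mask] * 3.0 + 17.0
        a = intensity_features(vol[mask])
        b = intensity_features(vol2[mask])
        assert a == b
        ta = texture_features(vol, mask)
        tb = texture_features(vol2, mask)
        assert ta == tb

    def test_class_signal_exists_for_downstream(self, cohort50_features_b0):
        """At least one texture feature separates fibrous from soft with
        AUC > 0.7 on a noisy 50-case cohort."""
        from synthrad.evalstats import mann_whitney_auc

        tab = cohort50_features_b0
        y = (tab["label"] == "fibrous").to_numpy().astype(int)
        best = 0.0
        for col in tab.columns:
            if col.startswith(("glcm_", "glrlm_", "ngtdm_")):
                a = mann_whitney_auc(tab[col].to_numpy(), y)
                best = max(best, a, 1 - a)
        assert best > 0.7
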