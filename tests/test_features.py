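import numpy as np
import pytest

from repeatomics import extract_features, quantize
from repeatomics.features.filters import (LAWS_KERNELS, laws3d_features,
                                          laws_response, wavelet3d_features,
                                          wavelet_subbands)
from repeatomics.features.firstorder import (inthist_features, locint_features,
                                             stat_features)
from repeatomics.features.shape import shape_features
from repeatomics.features.texture import (QuantizedROI, glcm3d_features,
                                          glrlm3d_features, glszm_features,
                                          ngtdm_features)

import oracles
from conftest import make_mask, make_volume, random_quantized_roi


def _roi_from_values(values, spacing=(1.0, 1.0, 1.0)):
    """Embed a 1D list of intensities as a 1xNx1 full-foreground ROI."""
    arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
    return make_volume(arr, spacing), make_mask(np.ones_like(arr), spacing)


def _q(levels, Ng, spacing=(1.0, 1.0, 1.0)):
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedROI(levels, Ng, make_mask(levels > 0, spacing), spacing)


class TestQuantize:
    def test_bin_edges(self):
        vol, roi = _roi_from_values([0.0, 0.5, 1.0])
        q = quantize(vol, roi, Ng=2)
        np.testing.assert_array_equal(q.roi_levels(), [1, 1, 2])

    def test_constant_roi(self):
        vol, roi = _roi_from_values([3.0, 3.0, 3.0])
        q = quantize(vol, roi, Ng=8)
        assert set(q.roi_levels()) == {1}

    def test_affine_invariance(self, rng):
        vals = rng.normal(size=50)
        vol1, roi = _roi_from_values(vals)
        vol2, _ = _roi_from_values(4.2 * vals + 17.0)
        np.testing.assert_array_equal(quantize(vol1, roi, 16).levels,
                                      quantize(vol2, roi, 16).levels)

    def test_levels_span_full_range(self, rng):
        vol, roi = _roi_from_values(rng.normal(size=200))
        lv = quantize(vol, roi, 32).roi_levels()
        assert lv.min() == 1 and lv.max() == 32


class TestStatFeatures:
    def test_hand_arithmetic(self):
        vol, roi = _roi_from_values([1.0, 2.0, 3.0, 4.0])
        f = stat_features(vol, roi)
        assert f["Stat-Max-gray-level"] == 4.0
        assert f["Stat-range"] == 3.0
        assert f["Stat-Root-Mn-Sq"] == pytest.approx(np.sqrt(7.5))
        assert f["Stat-ENERGY"] == pytest.approx(30.0)

    def test_percentile_convention(self):
        vol, roi = _roi_from_values(list(range(1, 11)))
        f = stat_features(vol, roi)
        assert f["Stat-10th-percentile"] == pytest.approx(1.9)

    def test_constant_roi(self):
        vol, roi = _roi_from_values([-2.5] * 6)
        f = stat_features(vol, roi)
        assert f["Stat-SD"] == 0.0
        assert f["Stat-range"] == 0.0
        assert f["Stat-Root-Mn-Sq"] == pytest.approx(2.5)
        assert np.isfinite(list(f.values())).all()


class TestIntHistFeatures:
    def test_gradient_convention(self):
        # counts [5, 1, 5] over levels 1..3: gradient [-4, +4]
        levels = [1] * 5 + [2] + [3] * 5
        q = _q(np.array(levels).reshape(1, -1, 1), Ng=3)
        f = inthist_features(q)
        assert f["Max-hist-Gradient"] == 4.0
        assert f["Max-hist-Gradient-gray-level"] == 3.0
        assert f["Min-hist-Gradient"] == -4.0
        assert f["Min-hist-Gradient-gray-level"] == 2.0

    def test_uniform_histogram_entropy(self):
        q = _q(np.array([1, 2, 3, 4] * 4).reshape(1, -1, 1), Ng=4)
        f = inthist_features(q)
        assert f["Int-hist-entropy"] == pytest.approx(2.0)  # log2(4)
        assert f["Int-hist-uniformity"] == pytest.approx(0.25)

    def test_single_level(self):
        q = _q(np.ones((1, 6, 1)), Ng=1)
        f = inthist_features(q)
        assert f["Int-hist-mode"] == 1.0
        assert f["Int-hist-interquartile-range"] == 0.0
        assert f["Max-hist-Gradient"] == 0.0


class TestShapeFeatures:
    def test_cube_geometry(self):
        mask = np.zeros((14, 14, 14))
        mask[2:12, 2:12, 2:12] = 1
        vol = make_volume(np.random.default_rng(0).normal(size=(14, 14, 14)))
        f = shape_features(make_mask(mask), vol)
        assert f["Vol-(mm^3)"] == pytest.approx(1000.0)
        assert f["Surface-area-(mm^2)"] == pytest.approx(600.0)
        assert f["Num-slices"] == 10.0

    def test_uniform_intensity_zero_com_shift(self):
        mask = np.zeros((8, 8, 8))
        mask[2:6, 2:6, 2:6] = 1
        vol = make_volume(np.full((8, 8, 8), 5.0))
        f = shape_features(make_mask(mask), vol)
        assert f["Center-of-mass-shift-(mm)"] == 0.0

    def test_vif_single_bright_voxel(self):
        mask = np.zeros((1, 10, 1))
        mask[0, :, 0] = 1
        vox = np.zeros((1, 10, 1))
        vox[0, -1, 0] = 100.0
        f = shape_features(make_mask(mask), make_volume(vox))
        # threshold at min + 10% range = 10: exactly one voxel above
        assert f["Vol-at-Int-Fraction-10"] == pytest.approx(0.1)
        assert f["Vol-at-Int-Fraction-90"] == pytest.approx(0.1)
        assert f["Vol-at-Int-fraction-diff"] == pytest.approx(0.0)

    def test_anisotropic_spacing_aware(self):
        mask = np.zeros((6, 6, 6))
        mask[1:5, 1:5, 1:3] = 1  # 4x4x2 voxels at (1,1,3) mm
        vol = make_volume(np.ones((6, 6, 6)), spacing=(1, 1, 3))
        f = shape_features(make_mask(mask, spacing=(1, 1, 3)), vol)
        assert f["Vol-(mm^3)"] == pytest.approx(4 * 4 * 2 * 3.0)
        assert f["Bounding-box-z-(mm)"] == pytest.approx(6.0)


class TestGLCM:
    def test_constant_roi(self):
        q = _q(np.ones((3, 3, 3)), Ng=4)
        f = glcm3d_features(q)
        assert f["Joint-var"] == 0.0
        assert f["Cluster-prominence"] == 0.0
        assert f["Inv-diff-mom-norm"] == 1.0

    def test_2x2_hand_case_matches_oracle(self):
        levels = np.array([[1, 2], [2, 1]], dtype=np.int32).reshape(2, 2, 1)
        q = _q(levels, Ng=2)
        got = glcm3d_features(q)
        want = oracles.glcm_avg_oracle(levels, Ng=2)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k

    def test_gray_level_swap_preserves_entropy(self, rng):
        lv = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)
        swapped = (5 - lv).astype(np.int32)
        e1 = glcm3d_features(_q(lv, 4))["Joint-entropy"]
        e2 = glcm3d_features(_q(swapped, 4))["Joint-entropy"]
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestGLRLM:
    def test_run_enumeration(self):
        lv = np.array([1, 1, 2, 2], dtype=np.int32).reshape(1, 4, 1)
        runs = oracles.runs_oracle(lv, (0, 1, 0))
        assert sorted(runs) == [(1, 2), (2, 2)]

    def test_single_run_closed_form(self):
        n = 7
        lv = np.ones((1, n, 1), dtype=np.int32)
        q = _q(lv, Ng=1)
        f = glrlm3d_features(q)
        # along the run axis, one run of length N contributes LRE = N^2;
        # check via the direction-resolved oracle average
        want = oracles.glrlm_avg_oracle(lv)
        assert f["LRE-(Long-runs-emphasis)"] == pytest.approx(
            want["LE"], rel=1e-12)

    def test_all_distinct_levels_sre_one(self):
        lv = np.arange(1, 9, dtype=np.int32).reshape(1, 8, 1)
        f = glrlm3d_features(_q(lv, Ng=8))
        assert f["SRE-(Short-runs-emphasis)"] == pytest.approx(1.0)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        n = 27
        q = _q(np.ones((3, 3, 3), dtype=np.int32), Ng=1)
        f = glszm_features(q)
        assert f["Zone-percentage"] == pytest.approx(1.0 / n)
        assert f["Large-zone-emphasis"] == pytest.approx(n ** 2)

    def test_alternating_strip_all_singletons(self):
        lv = np.array([1, 2] * 5, dtype=np.int32).reshape(1, 10, 1)
        f = glszm_features(_q(lv, Ng=2))
        assert f["Zone-percentage"] == pytest.approx(1.0)

    def test_single_gray_level_gln_normalized(self):
        # zones of sizes {1, 3} with the same level -> GLN normalized = 1
        lv = np.zeros((1, 6, 1), dtype=np.int32)
        lv[0, 0, 0] = 1
        lv[0, 2:5, 0] = 1
        f = glszm_features(_q(lv, Ng=1))
        assert f["Gray-level-non-uniformity-normalized"] == pytest.approx(1.0)


class TestNGTDM:
    def test_constant_roi_guards(self):
        f = ngtdm_features(_q(np.ones((3, 3, 3)), Ng=4))
        assert f["Contrast"] == 0.0
        assert f["Busyness"] == 0.0
        assert f["Coarseness"] == pytest.approx(1e12)

    def test_center_voxel_hand_case(self):
        lv = np.ones((3, 3, 1), dtype=np.int32)
        lv[1, 1, 0] = 2
        got = ngtdm_features(_q(lv, Ng=2))
        want = oracles.ngtdm_oracle(lv, Ng=2)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k

    def test_empty_levels_do_not_change_present_level_features(self, rng):
        lv = rng.integers(1, 3, size=(4, 4, 4)).astype(np.int32)
        f1 = ngtdm_features(_q(lv, Ng=2))
        f2 = ngtdm_features(_q(lv, Ng=4))  # empty levels 3, 4
        assert f1["Contrast"] == pytest.approx(f2["Contrast"], rel=1e-12)


@pytest.mark.parametrize("family,impl,oracle,keymap", [
    ("glcm", glcm3d_features, oracles.glcm_avg_oracle, None),
    ("glrlm", glrlm3d_features, oracles.glrlm_avg_oracle,
     oracles._GLRLM_ORACLE_TO_IMPL),
    ("glszm", glszm_features, oracles.glszm_oracle, oracles._GLSZM_ORACLE_TO_IMPL),
    ("ngtdm", ngtdm_features, oracles.ngtdm_oracle, None),
])
def test_texture_matches_bruteforce_oracle(family, impl, oracle, keymap, rng):
    """Vectorized texture features agree with exhaustive enumeration."""
    for _ in range(5):
        q = random_quantized_roi(rng, shape=(4, 4, 4), Ng=4)
        got = impl(q)
        want = oracle(q.levels, 4) if family in ("glcm", "ngtdm") else oracle(q.levels)
        for k, v in want.items():
            kk = keymap[k] if keymap else k
            assert got[kk] == pytest.approx(v, rel=1e-9, abs=1e-12), (family, k)


class TestLaws:
    def test_zero_sum_kernels_on_constant(self):
        vol = make_volume(np.full((10, 10, 10), 3.0))
        roi = make_mask(np.ones((10, 10, 10)))
        f = laws3d_features(vol, roi)
        for name, v in f.items():
            if any(k in name.split("LawsF-")[1] for k in ("E5", "S5", "R5", "W5")):
                assert v == pytest.approx(0.0, abs=1e-9), name
        assert f["3D-LawsF-L5-L5-L5"] == pytest.approx(3.0 * 16 ** 3)

    def test_impulse_response_is_kernel_outer_product(self):
        from scipy.signal import convolve
        vol = np.zeros((11, 11, 11))
        vol[5, 5, 5] = 1.0
        for triple in (("L5", "E5", "S5"), ("R5", "W5", "L5")):
            resp = laws_response(vol, triple)
            k3d = (LAWS_KERNELS[triple[0]][:, None, None]
                   * LAWS_KERNELS[triple[1]][None, :, None]
                   * LAWS_KERNELS[triple[2]][None, None, :])
            want = convolve(vol, k3d, mode="same")
            np.testing.assert_allclose(resp, want, atol=1e-10)


class TestWavelet:
    def test_constant_input_detail_subbands_vanish(self):
        vol = make_volume(np.full((8, 8, 8), 4.0))
        roi = make_mask(np.ones((8, 8, 8)))
        f = wavelet3d_features(vol, roi)
        for c in range(1, 15):  # C1..C14 are detail subbands
            assert f[f"3D-Wave-P1-L2-C{c}"] == pytest.approx(0.0, abs=1e-9)
        assert f["3D-Wave-P1-L2-C15"] > 0  # approximation keeps the DC level

    def test_linearity_of_mean_abs(self, rng):
        vox = rng.normal(size=(8, 8, 8))
        roi = make_mask(np.ones((8, 8, 8)))
        f1 = wavelet3d_features(make_volume(vox), roi)
        f2 = wavelet3d_features(make_volume(2.0 * vox), roi)
        for c in range(1, 16):
            assert f2[f"3D-Wave-P1-L2-C{c}"] == pytest.approx(
                2.0 * f1[f"3D-Wave-P1-L2-C{c}"], rel=1e-9)

    def test_subband_count_and_shapes(self, rng):
        bands = wavelet_subbands(rng.normal(size=(6, 7, 9)))
        assert len(bands) == 15
        assert all(b.shape == (6, 7, 9) for b in bands)


class TestLocalIntensity:
    def test_constant_volume_peaks(self):
        vol = make_volume(np.full((20, 20, 20), 7.0))
        mask = np.zeros((20, 20, 20))
        mask[8:12, 8:12, 8:12] = 1
        f = locint_features(vol, make_mask(mask))
        assert f["Local-intensity-peak"] == pytest.approx(7.0)
        assert f["Global-intensity-peak"] == pytest.approx(7.0)
        assert f["Total-energy"] == pytest.approx(49.0 * 64)


class TestExtractAll:
    def test_full_vector_and_invariances(self, catalog, rng):
        vox = rng.normal(100, 15, size=(20, 20, 12))
        mask = np.zeros((20, 20, 12))
        mask[6:14, 6:14, 3:9] = 1
        vol, roi = make_volume(vox), make_mask(mask)
        feats = extract_features(vol, roi, catalog)
        assert len(feats) == 307
        assert not any(np.isnan(v) for v in feats.values())

    def test_translation_invariance(self, catalog, rng):
        # two crops of one larger scene: the ROI covers the same absolute
        # voxels at different array offsets, with identical surroundings
        big = rng.normal(size=(32, 32, 26))
        big_mask = np.zeros((32, 32, 26))
        big_mask[14:20, 14:20, 10:15] = 1
        crop1 = (slice(4, 28), slice(4, 28), slice(4, 24))
        crop2 = (slice(2, 26), slice(2, 26), slice(3, 23))
        f1 = extract_features(make_volume(big[crop1]), make_mask(big_mask[crop1]),
                              catalog)
        f2 = extract_features(make_volume(big[crop2]), make_mask(big_mask[crop2]),
                              catalog)
        centroid_feats = {f"F{k}" for k in range(82, 88)}
        for fid, v in f1.items():
            if fid.split(":")[0] in centroid_feats:
                continue
            assert f2[fid] == pytest.approx(v, rel=1e-9, abs=1e-9), fid

    def test_intensity_shift_invariance_of_quantized_families(self, catalog, rng):
        vox = rng.normal(size=(16, 16, 8))
        mask = np.zeros((16, 16, 8))
        mask[4:12, 4:12, 2:6] = 1
        f1 = extract_features(make_volume(vox), make_mask(mask), catalog)
        f2 = extract_features(make_volume(2.0 * vox + 30.0), make_mask(mask), catalog)
        quantized_families = {"INTHIST", "GLCM3D", "GLRLM3D", "GLSZM", "NGTDM"}
        for d in catalog:
            if d.family in quantized_families:
                assert f2[d.feature_id] == pytest.approx(
                    f1[d.feature_id], rel=1e-9, abs=1e-12), d.feature_id

    def test_constant_roi_defined_everywhere(self, catalog):
        vox = np.full((12, 12, 8), 5.0)
        mask = np.zeros((12, 12, 8))
        mask[4:8, 4:8, 2:6] = 1
        feats = extract_features(make_volume(vox), make_mask(mask), catalog)
        nan_feats = [k for k, v in feats.items() if np.isnan(v)]
        assert nan_feats == []
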