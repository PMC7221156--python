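import numpy as np
import pytest

from repeatomics import HabitatConfig, habitat_sphere, habitat_within_lesion

from conftest import make_mask, make_volume


class TestHabitatWithinLesion:
    def test_median_threshold_single_block(self):
        # lesion ADC {1..5} in one connected 1x5x1 block: median 3 -> {1,2,3}
        adc = np.zeros((1, 7, 1))
        adc[0, 1:6, 0] = [1, 2, 3, 4, 5]
        lesion = np.zeros((1, 7, 1))
        lesion[0, 1:6, 0] = 1
        # pad lesion to satisfy the >= 8 voxel precondition
        adc3 = np.tile(adc, (2, 1, 1))
        lesion3 = np.tile(lesion, (2, 1, 1))
        hab = habitat_within_lesion(make_volume(adc3), make_mask(lesion3))
        got = set(map(tuple, np.argwhere(hab.voxels)))
        expected = {(i, j, 0) for i in (0, 1) for j in (1, 2, 3)}
        assert got == expected

    def test_largest_component_wins(self):
        # two equal-ADC low components of sizes 30 and 12 -> keep the 30
        adc = np.full((4, 20, 2), 100.0)
        lesion = np.zeros((4, 20, 2))
        lesion[:3, :5, :] = 1    # component A: 30 voxels at low ADC
        lesion[:3, 14:16, :] = 1  # component B: 12 voxels at low ADC
        lesion[3, :, 0] = 1      # 20 high-ADC voxels keep the lesion whole-ish
        adc[:3, :5, :] = 1.0
        adc[:3, 14:16, :] = 1.0
        # 42 low of 62 lesion voxels: the median is the low value
        hab = habitat_within_lesion(make_volume(adc), make_mask(lesion))
        assert hab.n_voxels == 30
        assert hab.voxels[:3, :5, :].all()

    def test_constant_lesion_gives_entire_lesion(self):
        adc = np.full((4, 4, 4), 7.0)
        lesion = np.zeros((4, 4, 4))
        lesion[1:3, 1:3, 1:3] = 1
        hab = habitat_within_lesion(make_volume(adc), make_mask(lesion))
        np.testing.assert_array_equal(hab.voxels, lesion.astype(bool))

    def test_subset_and_connected(self, rng):
        adc = rng.normal(size=(10, 10, 6))
        lesion = np.zeros((10, 10, 6))
        lesion[2:8, 2:8, 1:5] = 1
        hab = habitat_within_lesion(make_volume(adc), make_mask(lesion))
        assert not (hab.voxels & ~lesion.astype(bool)).any()
        assert 1 <= hab.n_voxels <= lesion.sum()
        from scipy import ndimage
        _, n = ndimage.label(hab.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_tiny_lesion_rejected(self):
        adc = np.zeros((4, 4, 4))
        lesion = np.zeros((4, 4, 4))
        lesion[0, 0, :3] = 1
        with pytest.raises(ValueError, match="8 voxels"):
            habitat_within_lesion(make_volume(adc), make_mask(lesion))


class TestHabitatSphere:
    def _setting(self):
        gland = np.ones((40, 40, 20))
        lesion = np.zeros((40, 40, 20))
        lesion[18:23, 18:23, 9:12] = 1
        return gland, lesion

    def test_low_blob_recovered(self):
        # uniform ADC except one contiguous low blob at half background
        gland, lesion = self._setting()
        adc = np.full((40, 40, 20), 100.0)
        blob = np.zeros_like(adc, dtype=bool)
        blob[19:24, 19:23, 10] = True  # 20 voxels near the centroid
        adc[blob] = 50.0
        hab = habitat_sphere(make_volume(adc), make_mask(lesion),
                             make_mask(gland, label="GLAND"))
        np.testing.assert_array_equal(hab.voxels, blob)

    def test_sphere_membership_in_world_mm(self):
        # spacing (1,1,3): a voxel 3 slices away axially is 9 mm > 7.5 mm radius
        gland = np.ones((41, 41, 21))
        lesion = np.zeros((41, 41, 21))
        lesion[20, 20, 10] = 1
        lesion[19:22, 19:22, 10] = 1  # centroid at voxel (20,20,10)
        adc = np.full((41, 41, 21), 100.0)
        adc[20, 20, 13] = 1.0   # 9 mm away axially: outside sphere
        adc[20, 26, 10] = 1.0   # 6 mm away in-plane: inside sphere
        hab = habitat_sphere(make_volume(adc, spacing=(1, 1, 3)),
                             make_mask(lesion, spacing=(1, 1, 3)),
                             make_mask(gland, spacing=(1, 1, 3), label="GLAND"))
        assert hab.voxels[20, 26, 10]
        assert not hab.voxels[20, 20, 13]

    def test_uniform_adc_fallback(self):
        # sigma = 0 -> strict threshold set empty -> fallback ADC <= mu
        gland, lesion = self._setting()
        adc = np.full((40, 40, 20), 100.0)
        hab = habitat_sphere(make_volume(adc), make_mask(lesion),
                             make_mask(gland, label="GLAND"))
        # fallback keeps the whole sphere-and-gland region (all values <= mu)
        assert hab.n_voxels > lesion.sum()

    def test_subset_of_gland(self, rng):
        gland = np.zeros((40, 40, 20))
        gland[5:35, 5:35, 3:17] = 1
        lesion = np.zeros((40, 40, 20))
        lesion[18:23, 18:23, 8:12] = 1
        adc = rng.normal(100, 20, size=(40, 40, 20))
        hab = habitat_sphere(make_volume(adc), make_mask(lesion),
                             make_mask(gland, label="GLAND"))
        assert not (hab.voxels & ~gland.astype(bool)).any()

    def test_determinism(self, rng):
        gland, lesion = self._setting()
        adc = rng.normal(100, 20, size=(40, 40, 20))
        args = (make_volume(adc), make_mask(lesion), make_mask(gland, label="GLAND"))
        h1 = habitat_sphere(*args)
        h2 = habitat_sphere(*args)
        np.testing.assert_array_equal(h1.voxels, h2.voxels)

    def test_centroid_outside_gland_rejected(self):
        gland = np.zeros((40, 40, 20))
        gland[:5, :5, :2] = 1
        lesion = np.zeros((40, 40, 20))
        lesion[30:35, 30:35, 15:18] = 1
        adc = np.full((40, 40, 20), 100.0)
        with pytest.raises(ValueError, match="centroid outside gland"):
            habitat_sphere(make_volume(adc), make_mask(lesion),
                           make_mask(gland, label="GLAND"))


def test_config_validation():
    with pytest.raises(ValueError):
        HabitatConfig(sphere_diameter_mm=-1)
    with pytest.raises(ValueError):
        HabitatConfig(median_fraction=1.5)
    with pytest.raises(ValueError):
        HabitatConfig(connectivity=4)
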