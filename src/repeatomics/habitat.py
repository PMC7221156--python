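"""Habitat regions: low-ADC sub-regions converged from a marked lesion.

A habitat is a contiguous restricted-diffusion region whose low ADC resembles
aggressive tumor. Two convergence rules are provided:

* :func:`habitat_sphere` — grow the search space to a 15-mm-diameter sphere
  around the lesion centroid, clip it to the prostate gland, and keep the
  largest connected component of voxels at least ``k`` standard deviations
  below the local mean ADC. The result may extend beyond the marked lesion.
* :func:`habitat_within_lesion` — keep the largest connected component of
  lesion voxels at or below the median lesion ADC. The result is always a
  subset of the lesion.

Habitats are converged once per timepoint from that timepoint's (raw) ADC map
and then applied to both modalities. The threshold multiplier ``k`` for the
sphere rule is an exposed parameter (default 1.0): the underlying deviation
rule is a convention of this package, not a published constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import RegionMask, ScanVolume

__all__ = ["HabitatConfig", "habitat_sphere", "habitat_within_lesion"]


@dataclass(frozen=True)
class HabitatConfig:
    sphere_diameter_mm: float = 15.0
    deviation_k: float = 1.0
    connectivity: int = 26
    median_fraction: float = 0.5

    def __post_init__(self):
        if self.sphere_diameter_mm <= 0:
            raise ValueError("sphere_diameter_mm must be positive")
        if not 0 < self.median_fraction < 1:
            raise ValueError("median_fraction must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest connected component; size ties broken by smallest linear index."""
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        first_idx = [np.flatnonzero(labels.ravel() == b)[0] for b in best]
        best = [best[int(np.argmin(first_idx))]]
    return labels == best[0]


def habitat_within_lesion(adc: ScanVolume, lesion: RegionMask,
                          cfg: HabitatConfig = HabitatConfig()) -> RegionMask:
    """Largest contiguous lesion sub-region at or below the lesion-median ADC.

    The median uses midpoint interpolation over in-lesion ADC values and ties
    at the median are included, so the output is never empty and always a
    subset of the lesion.
    """
    lesion.check_same_grid(adc)
    if lesion.n_voxels < 8:
        raise ValueError("lesion must contain at least 8 voxels")
    values = adc.voxels[lesion.voxels]
    cutoff = float(np.quantile(values, cfg.median_fraction))
    low = lesion.voxels & (adc.voxels <= cutoff)
    comp = _largest_component(low, cfg.connectivity)
    return RegionMask(comp, adc.spacing, adc.origin, label="HABITAT_MEDIAN",
                      lesion_id=lesion.lesion_id)


def habitat_sphere(adc: ScanVolume, lesion: RegionMask, gland: RegionMask,
                   cfg: HabitatConfig = HabitatConfig()) -> RegionMask:
    """Low-ADC component inside a fixed-diameter sphere around the lesion.

    The sphere (default diameter 15 mm) is centered at the lesion's unweighted
    geometric centroid in world mm and clipped to the gland; voxel membership
    is tested at voxel centers. Within sphere-and-gland the threshold is
    mu - k*sigma of the local ADC distribution; if no voxel passes (e.g. a
    uniform-ADC neighborhood), the rule falls back to ADC <= mu. The largest
    connected component under ``cfg.connectivity`` is returned. It may extend
    beyond the lesion but never beyond the gland.
    """
    lesion.check_same_grid(adc)
    gland.check_same_grid(adc)
    if lesion.n_voxels == 0 or gland.n_voxels == 0:
        raise ValueError("lesion and gland must be non-empty")

    idx = np.argwhere(lesion.voxels)
    centroid_mm = adc.world_coordinates(idx).mean(axis=0)

    grids = np.indices(adc.shape, dtype=np.float64)
    spacing = np.asarray(adc.spacing)
    origin = np.asarray(adc.origin)
    d2 = np.zeros(adc.shape)
    for ax in range(3):
        d2 += (origin[ax] + grids[ax] * spacing[ax] - centroid_mm[ax]) ** 2
    sphere = d2 <= (cfg.sphere_diameter_mm / 2.0) ** 2

    search = sphere & gland.voxels
    if not search.any():
        raise ValueError("lesion centroid outside gland neighborhood: "
                         "sphere does not intersect the gland")
    vals = adc.voxels[search]
    mu, sigma = float(vals.mean()), float(vals.std())
    thresholded = search & (adc.voxels <= mu - cfg.deviation_k * sigma)
    if not thresholded.any():
        thresholded = search & (adc.voxels <= mu)
    comp = _largest_component(thresholded, cfg.connectivity)
    return RegionMask(comp, adc.spacing, adc.origin, label="HABITAT_SPHERE",
                      lesion_id=lesion.lesion_id)
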