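"""Filter-bank textures: 3D Laws texture energy and undecimated wavelet subbands.

Laws features convolve the volume with every ordered separable triple of the
five classic 1D kernels (Level, Edge, Spot, Ripple, Wave) and reduce the
response to its mean absolute value over ROI voxels — the usual "texture
energy" statistic. Wavelet features use a two-level undecimated (stationary)
Haar decomposition of the ROI bounding box; the 15 subbands through level 2
are indexed C1..C15 (level-1 details LLH..HHH, level-2 details in the same
order, then the level-2 approximation), each contributing a mean-absolute-
coefficient and an energy feature over ROI voxels.

Filtering happens on the voxel grid (spacing is ignored); volumes are
extended by mirror reflection at their edges.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import convolve1d

from ..io import RegionMask, ScanVolume

__all__ = ["LAWS_KERNELS", "laws3d_features", "wavelet3d_features",
           "laws_response", "wavelet_subbands"]

LAWS_KERNELS: dict[str, np.ndarray] = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

_KERNEL_ORDER = ("L5", "E5", "S5", "R5", "W5")

#: subband key per axis-letter code, axis order (0, 1, 2); 'a' = low, 'd' = high
_DETAIL_KEYS = ("aad", "ada", "add", "daa", "dad", "dda", "ddd")


def _roi_box(vol: ScanVolume, roi: RegionMask, margin: int):
    """Crop volume to the ROI bounding box plus margin, mirror-padding any
    shortfall at the volume edge. Returns (data, roi-in-box)."""
    idx = np.argwhere(roi.voxels)
    lo_want = idx.min(axis=0) - margin
    hi_want = idx.max(axis=0) + 1 + margin
    lo = np.maximum(lo_want, 0)
    hi = np.minimum(hi_want, vol.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    data = vol.voxels[box]
    mask = roi.voxels[box]
    pad = [(int(lo[ax] - lo_want[ax]), int(hi_want[ax] - hi[ax])) for ax in range(3)]
    if any(p != (0, 0) for p in pad):
        data = np.pad(data, pad, mode="symmetric")
        mask = np.pad(mask, pad, mode="constant")
    return data, mask


def laws_response(volume: np.ndarray, kernels: tuple[str, str, str]) -> np.ndarray:
    """Separable 3D convolution with K1 (axis 0) x K2 (axis 1) x K3 (axis 2)."""
    out = volume.astype(np.float64)
    for ax, k in enumerate(kernels):
        out = convolve1d(out, LAWS_KERNELS[k], axis=ax, mode="mirror")
    return out


def laws3d_features(vol: ScanVolume, roi: RegionMask) -> dict[str, float]:
    """125 Laws texture-energy features (mean |response| over ROI voxels).

    The separable structure is exploited: 1D passes are shared across triples
    (5 + 25 + 125 one-dimensional convolutions on the ROI bounding box).
    """
    roi.check_same_grid(vol)
    data, mask = _roi_box(vol, roi, margin=2)
    ax0 = {k: convolve1d(data, LAWS_KERNELS[k], axis=0, mode="mirror")
           for k in _KERNEL_ORDER}
    out: dict[str, float] = {}
    for k1 in _KERNEL_ORDER:
        for k2 in _KERNEL_ORDER:
            ax01 = convolve1d(ax0[k1], LAWS_KERNELS[k2], axis=1, mode="mirror")
            for k3 in _KERNEL_ORDER:
                resp = convolve1d(ax01, LAWS_KERNELS[k3], axis=2, mode="mirror")
                out[f"3D-LawsF-{k1}-{k2}-{k3}"] = float(np.abs(resp[mask]).mean())
    return out


def wavelet_subbands(volume: np.ndarray) -> list[np.ndarray]:
    """The 15 undecimated Haar subbands C1..C15 of a 3D array.

    The array is padded (symmetric, appended) to a multiple of 4 per axis as
    required by the stationary transform; returned coefficient arrays are
    trimmed back to the input shape.
    """
    shape = volume.shape
    pad = [(0, (-s) % 4) for s in shape]
    data = np.pad(volume, pad, mode="symmetric") if any(p[1] for p in pad) else volume
    coeffs = pywt.swtn(data, "haar", level=2)
    # pywt orders levels coarsest-first: coeffs[0] is level 2, coeffs[-1] level 1
    level2, level1 = coeffs[0], coeffs[-1]
    trim = tuple(slice(0, s) for s in shape)
    bands = [level1[k][trim] for k in _DETAIL_KEYS]
    bands += [level2[k][trim] for k in _DETAIL_KEYS]
    bands.append(level2["aaa"][trim])
    return bands


def wavelet3d_features(vol: ScanVolume, roi: RegionMask) -> dict[str, float]:
    """30 wavelet features: per subband C1..C15, mean |coefficient| and energy
    (sum of squared coefficients) over ROI voxels."""
    roi.check_same_grid(vol)
    data, mask = _roi_box(vol, roi, margin=0)
    out: dict[str, float] = {}
    for c, band in enumerate(wavelet_subbands(data), start=1):
        in_roi = band[mask]
        out[f"3D-Wave-P1-L2-C{c}"] = float(np.abs(in_roi).mean())
        out[f"3D-Wave-P1-L2-C{c}-Energy"] = float((in_roi ** 2).sum())
    return out
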