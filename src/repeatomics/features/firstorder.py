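"""First-order intensity statistics, intensity-histogram and local-intensity features."""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from ..io import RegionMask, ScanVolume
from .texture import QuantizedROI

__all__ = ["stat_features", "inthist_features", "locint_features"]

#: radius (mm) of the 1 cm^3 sphere used for intensity-peak features
_PEAK_RADIUS_MM = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)


def _distribution_stats(v: np.ndarray) -> dict[str, float]:
    """The shared 17-statistic block (population moments, linear percentiles)."""
    mean = float(v.mean())
    var = float(v.var())
    sd = float(np.sqrt(var))
    p10, p25, median, p75, p90 = (float(np.percentile(v, q)) for q in (10, 25, 50, 75, 90))
    inner = v[(v >= p10) & (v <= p90)]
    qcd_den = p75 + p25
    return {
        "mean": mean,
        "var": var,
        "sd": sd,
        "skewness": float(stats.skew(v)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v)) if sd > 0 else 0.0,
        "median": median,
        "min": float(v.min()),
        "p10": p10,
        "p90": p90,
        "max": float(v.max()),
        "iqr": p75 - p25,
        "range": float(v.max() - v.min()),
        "mad": float(np.abs(v - mean).mean()),
        "rmad": float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0,
        "medad": float(np.abs(v - median).mean()),
        "cov": sd / abs(mean) if mean != 0 else 0.0,
        "qcd": (p75 - p25) / qcd_den if qcd_den != 0 else 0.0,
    }


def stat_features(vol: ScanVolume, roi: RegionMask) -> dict[str, float]:
    """19 first-order statistics over in-ROI intensities."""
    roi.check_same_grid(vol)
    if roi.n_voxels < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    v = vol.voxels[roi.voxels].astype(np.float64)
    d = _distribution_stats(v)
    return {
        "Stat-Mean": d["mean"], "Stat-Var": d["var"], "Stat-SD": d["sd"],
        "Stat-Skewness": d["skewness"], "Stat-Kurtosis": d["kurtosis"],
        "Stat-Median": d["median"], "Stat-Min-gray-level": d["min"],
        "Stat-10th-percentile": d["p10"], "Stat-90th-percentile": d["p90"],
        "Stat-Max-gray-level": d["max"], "Stat-Interquartile-range": d["iqr"],
        "Stat-range": d["range"], "Stat-Mean-abs-deviation": d["mad"],
        "Stat-Robust-mean-abs-deviation": d["rmad"],
        "Stat-Median-abs-deviation": d["medad"],
        "Stat-Coeff-of-variation": d["cov"],
        "Stat-Quartile-coeff-of-dispersion": d["qcd"],
        "Stat-ENERGY": float((v ** 2).sum()),
        "Stat-Root-Mn-Sq": float(np.sqrt((v ** 2).mean())),
    }


def inthist_features(q: QuantizedROI) -> dict[str, float]:
    """23 histogram-domain statistics on quantized levels 1..Ng.

    The histogram gradient is the discrete first difference of bin counts,
    h(k+1) - h(k), located at level k+1; its extrema and their levels form
    the last four features. A single-level histogram has zero gradient by
    convention.
    """
    lv = q.roi_levels().astype(np.float64)
    d = _distribution_stats(lv)
    counts = np.bincount(lv.astype(int), minlength=q.Ng + 1)[1:].astype(np.float64)
    p = counts / counts.sum()
    nz = p[p > 0]
    mode_level = float(np.argmax(counts) + 1)  # smallest level on ties

    if q.Ng > 1:
        grad = np.diff(counts)  # grad[k-1] = h(k+1) - h(k)
        gmax, gmin = int(np.argmax(grad)), int(np.argmin(grad))
        max_grad, max_grad_level = float(grad[gmax]), float(gmax + 2)
        min_grad, min_grad_level = float(grad[gmin]), float(gmin + 2)
    else:
        max_grad = min_grad = 0.0
        max_grad_level = min_grad_level = 1.0

    return {
        "Int-hist-mean": d["mean"], "Int-hist-var": d["var"],
        "Int-hist-skewness": d["skewness"], "Int-hist-kurtosis": d["kurtosis"],
        "Int-hist-median": d["median"], "Int-hist-min-gray-level": d["min"],
        "Int-hist-10th-percentile": d["p10"], "Int-hist-90th-percentile": d["p90"],
        "Int-hist-max-gray-level": d["max"], "Int-hist-mode": mode_level,
        "Int-hist-interquartile-range": d["iqr"], "Int-hist-range": d["range"],
        "Int-hist-mean-abs-deviation": d["mad"],
        "Int-hist-robust-mean-abs-deviation": d["rmad"],
        "Int-hist-median-abs-deviation": d["medad"],
        "Int-hist-coeff-of-variation": d["cov"],
        "Int-hist-quartile-coeff-of-dispersion": d["qcd"],
        "Int-hist-entropy": float(-(nz * np.log2(nz)).sum()),
        "Int-hist-uniformity": float((p ** 2).sum()),
        "Max-hist-Gradient": max_grad,
        "Max-hist-Gradient-gray-level": max_grad_level,
        "Min-hist-Gradient": min_grad,
        "Min-hist-Gradient-gray-level": min_grad_level,
    }


def _sphere_footprint(spacing) -> np.ndarray:
    r = _PEAK_RADIUS_MM
    half = [int(np.floor(r / s)) for s in spacing]
    grids = np.indices([2 * h + 1 for h in half], dtype=np.float64)
    d2 = np.zeros(grids.shape[1:])
    for ax in range(3):
        d2 += ((grids[ax] - half[ax]) * spacing[ax]) ** 2
    return d2 <= r ** 2


def locint_features(vol: ScanVolume, roi: RegionMask) -> dict[str, float]:
    """Local / global intensity peak (1 cm^3 spherical mean) and total energy.

    The spherical mean at a voxel averages volume intensities whose centers
    lie within a 6.2 mm radius, restricted to the volume. The local peak is
    the spherical mean at the ROI's maximum-intensity voxel (largest mean on
    ties); the global peak is the maximum spherical mean over all ROI voxels.
    """
    roi.check_same_grid(vol)
    fp = _sphere_footprint(vol.spacing)
    margin = [s // 2 for s in fp.shape]
    idx = np.argwhere(roi.voxels)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, vol.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    data = vol.voxels[box]
    num = ndimage.correlate(data, fp.astype(np.float64), mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(data), fp.astype(np.float64),
                            mode="constant", cval=0.0)
    sphere_mean = num / den
    roi_box = roi.voxels[box]
    means_in_roi = sphere_mean[roi_box]
    vals_in_roi = data[roi_box]
    at_max = means_in_roi[vals_in_roi == vals_in_roi.max()]
    return {
        "Local-intensity-peak": float(at_max.max()),
        "Global-intensity-peak": float(means_in_roi.max()),
        "Total-energy": float((vol.voxels[roi.voxels] ** 2).sum() * vol.voxel_volume_mm3),
    }
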