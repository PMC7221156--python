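"""The 307-feature extraction engine.

:func:`extract_features` runs every feature family on one (volume, ROI) pair
and returns ``{feature_id: value}`` ordered as the catalog. Families raising
on degenerate ROIs smaller than their preconditions propagate their errors;
undefined values within a family are emitted as NaN.
"""

from __future__ import annotations

import logging

import numpy as np

from ..catalog import FeatureCatalog, build_catalog
from ..io import RegionMask, ScanVolume
from .filters import laws3d_features, wavelet3d_features
from .firstorder import inthist_features, locint_features, stat_features
from .shape import shape_features
from .texture import (QuantizedROI, glcm3d_features, glrlm3d_features,
                      glszm_features, ngtdm_features, quantize)

__all__ = ["extract_features", "quantize", "QuantizedROI",
           "stat_features", "inthist_features", "locint_features",
           "shape_features", "glcm3d_features", "glrlm3d_features",
           "glszm_features", "ngtdm_features", "laws3d_features",
           "wavelet3d_features"]

logger = logging.getLogger(__name__)

DEFAULT_NG = 32


def extract_features(vol: ScanVolume, roi: RegionMask,
                     catalog: FeatureCatalog | None = None,
                     Ng: int = DEFAULT_NG) -> dict[str, float]:
    """Extract all 307 features of ``catalog`` from one volume and ROI."""
    if catalog is None:
        catalog = build_catalog()
    roi.check_same_grid(vol)

    q = quantize(vol, roi, Ng)
    by_name: dict[str, float] = {}
    by_name.update(stat_features(vol, roi))
    by_name.update(inthist_features(q))
    by_name.update(shape_features(roi, vol))
    by_name.update(locint_features(vol, roi))
    for fam, vals in (("GLCM3D", glcm3d_features(q)),
                      ("GLRLM3D", glrlm3d_features(q)),
                      ("GLSZM", glszm_features(q)),
                      ("NGTDM", ngtdm_features(q))):
        prefix = {"GLCM3D": "avgCooc_3D_", "GLRLM3D": "avg_3D_",
                  "GLSZM": "GLSZM_", "NGTDM": "NGTDM_"}[fam]
        by_name.update({f"{prefix}{k}": v for k, v in vals.items()})
    by_name.update(laws3d_features(vol, roi))
    by_name.update(wavelet3d_features(vol, roi))

    out: dict[str, float] = {}
    for d in catalog:
        value = by_name[d.name]
        if not np.isfinite(value) and not np.isnan(value):
            value = float("nan")
        if np.isnan(value):
            logger.warning("feature %s undefined for ROI (%d voxels); emitting NaN",
                           d.feature_id, roi.n_voxels)
        out[d.feature_id] = float(value)
    return out
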