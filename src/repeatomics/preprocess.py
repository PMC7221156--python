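"""Gland-level z-score standardization.

MR intensities have no biological reference scale (T2w especially), so each
modality of each scan is standardized against the whole prostate gland:
subtract the gland mean and divide by the gland standard deviation, then
apply the same affine transform to every voxel of the volume. Each timepoint
uses its own gland statistics, independently per modality and per patient.

"Deviation" is read as the population standard deviation (divide by N); at
gland voxel counts the distinction is immaterial but it is fixed here for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionMask, ScanVolume

__all__ = ["StandardizationParams", "zscore_standardize"]


@dataclass(frozen=True)
class StandardizationParams:
    mean: float
    sd: float
    modality: str
    timepoint: str
    patient_id: str

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "modality": self.modality,
                "timepoint": self.timepoint, "patient_id": self.patient_id}


def zscore_standardize(vol: ScanVolume, gland: RegionMask) -> tuple[ScanVolume, StandardizationParams]:
    """Standardize ``vol`` by its gland mean/SD; returns (volume, params).

    The statistics come from gland voxels only; the transform is applied to
    the whole volume so that lesion and habitat regions inherit intensities
    relative to the gland. Raises on a constant gland (zero variance).
    """
    gland.check_same_grid(vol)
    gv = vol.voxels[gland.voxels]
    if gv.size < 2:
        raise ValueError("gland must contain at least 2 voxels")
    mean = float(gv.mean())
    sd = float(gv.std())  # population SD
    if sd == 0.0:
        raise ValueError("zero gland variance: cannot z-score a constant gland")
    out = vol.with_voxels((vol.voxels - mean) / sd)
    params = StandardizationParams(mean=mean, sd=sd, modality=vol.modality,
                                   timepoint=vol.timepoint, patient_id=vol.patient_id)
    return out, params
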