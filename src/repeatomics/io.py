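"""Volumes, masks and feature tables: on-disk formats and in-memory containers.

Volumes and masks travel as NIfTI-1 (read/written through nibabel); feature
values travel as long-format CSV. Both modalities of a patient scan are
assumed pre-resampled to a single axis-aligned grid — this package does not
register T2w to ADC, it requires coregistered inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScanVolume",
    "RegionMask",
    "FeatureMatrix",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "GridMismatchError",
]

#: tolerated voxel-spacing disagreement between a mask and its volume (mm)
SPACING_TOL_MM = 1e-3
#: tolerated origin disagreement (mm)
ORIGIN_TOL_MM = 1e-2

MODALITIES = ("T2W", "ADC")
TIMEPOINTS = ("TEST", "RETEST")
MASK_LABELS = ("GLAND", "LESION", "HABITAT_SPHERE", "HABITAT_MEDIAN")

ROW_KEYS = ["patient_id", "lesion_id", "timepoint", "region_variant", "modality"]


class GridMismatchError(ValueError):
    """Mask and volume do not live on the same voxel grid."""


@dataclass
class ScanVolume:
    """A single-modality, single-timepoint 3D scalar image.

    Intensities are arbitrary units for T2w and 1e-6 mm^2/s-scaled units for
    ADC. ``spacing`` and ``origin`` are in mm; voxel index (0, 0, 0) is the
    first voxel and world position = origin + index * spacing (axis-aligned
    grids only).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "T2W"
    timepoint: str = "TEST"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_voxels(self, voxels: np.ndarray) -> "ScanVolume":
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World-mm positions (N, 3) of voxel indices (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class RegionMask:
    """A binary mask on the grid of a parent :class:`ScanVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "LESION"
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; expected one of {MASK_LABELS}")
        if self.label in ("GLAND", "LESION") and not self.voxels.any():
            raise ValueError(f"{self.label} mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_same_grid(self, other: "ScanVolume | RegionMask") -> None:
        if self.shape != other.shape:
            raise GridMismatchError(f"shape mismatch: {self.shape} vs {other.shape}")
        if np.max(np.abs(np.subtract(self.spacing, other.spacing))) > SPACING_TOL_MM:
            raise GridMismatchError(f"spacing mismatch: {self.spacing} vs {other.spacing}")
        if np.max(np.abs(np.subtract(self.origin, other.origin))) > ORIGIN_TOL_MM:
            raise GridMismatchError(f"origin mismatch: {self.origin} vs {other.origin}")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from_nifti(img) -> tuple[tuple, tuple]:
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def read_volume(path: str | Path, modality: str, timepoint: str, patient_id: str = "") -> ScanVolume:
    """Load a NIfTI volume; rejects non-3D data and non-finite voxels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN/Inf voxels")
    spacing, origin = _grid_from_nifti(img)
    return ScanVolume(data, spacing, origin, modality=modality, timepoint=timepoint,
                      patient_id=patient_id)


def write_volume(vol: ScanVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.voxels, _affine(vol.spacing, vol.origin)), str(path))
    return path


def read_mask(path: str | Path, reference: ScanVolume, label: str = "LESION",
              lesion_id: str = "") -> RegionMask:
    """Load a NIfTI mask on the grid of ``reference``; any nonzero voxel -> 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, got {data.ndim}D")
    spacing, origin = _grid_from_nifti(img)
    mask = RegionMask(data, spacing, origin, label=label, lesion_id=lesion_id)
    mask.check_same_grid(reference)
    return mask


def write_mask(mask: RegionMask, path: str | Path, label_value: int = 1) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = mask.voxels.astype(np.uint8) * np.uint8(label_value)
    nib.save(nib.Nifti1Image(data, _affine(mask.spacing, mask.origin)), str(path))
    return path


class FeatureMatrix:
    """Feature values keyed by (patient, lesion, timepoint, region variant, modality).

    Internally a wide pandas DataFrame: one row per key tuple, one column per
    feature id. Written to disk as long-format CSV with 12 significant digits
    (lossless round-trip at that precision).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.nlevels != len(ROW_KEYS):
            raise ValueError(f"row index must have levels {ROW_KEYS}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate row key {dup}")
        data = data.sort_index()
        self.data = data.astype(np.float64)

    @classmethod
    def from_records(cls, records: list[dict]) -> "FeatureMatrix":
        """Build from dicts with the five key fields plus feature_id/value."""
        long = pd.DataFrame.from_records(records)
        if long.duplicated(subset=ROW_KEYS + ["feature_id"]).any():
            raise ValueError("duplicate (row key, feature_id) entries")
        wide = long.pivot(index=ROW_KEYS, columns="feature_id", values="value")
        wide.columns.name = None
        return cls(wide)

    @classmethod
    def from_rows(cls, rows: dict[tuple, dict[str, float]]) -> "FeatureMatrix":
        """Build from {key tuple: {feature_id: value}}."""
        idx = pd.MultiIndex.from_tuples(rows.keys(), names=ROW_KEYS)
        return cls(pd.DataFrame(list(rows.values()), index=idx))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, region_variant: str | None = None, modality: str | None = None) -> "FeatureMatrix":
        df = self.data
        if region_variant is not None:
            df = df.xs(region_variant, level="region_variant", drop_level=False)
        if modality is not None:
            df = df.xs(modality, level="modality", drop_level=False)
        return FeatureMatrix(df)

    def paired(self, feature_id: str) -> tuple[np.ndarray, np.ndarray, list]:
        """Align TEST and RETEST values of one feature by (patient, lesion).

        Returns (test, retest, subject_keys) restricted to complete pairs
        (both timepoints present); NaN values are kept — downstream statistics
        drop NaN pairs themselves.
        """
        col = self.data[feature_id]
        by_tp = col.unstack(level="timepoint")
        if "TEST" not in by_tp.columns or "RETEST" not in by_tp.columns:
            raise ValueError("matrix must contain both TEST and RETEST rows")
        both = by_tp.dropna(how="any", subset=["TEST", "RETEST"])
        return both["TEST"].to_numpy(), both["RETEST"].to_numpy(), list(both.index)

    def check_paired(self) -> None:
        """Every (patient, lesion, variant, modality) must appear at both timepoints."""
        counts = self.data.groupby(
            level=["patient_id", "lesion_id", "region_variant", "modality"]
        ).size()
        incomplete = counts[counts != 2]
        if len(incomplete):
            raise ValueError(f"unpaired rows for keys: {list(incomplete.index[:5])}")

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(future_stack=True).rename("value").reset_index()
        long = long.rename(columns={"level_5": "feature_id"})
        if "feature_id" not in long.columns:  # unnamed column level
            long.columns = ROW_KEYS + ["feature_id", "value"]
        return long

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_long().to_csv(path, index=False, float_format="%.12g")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        # key columns are plain strings: "NA" is a legal modality label, so
        # default NA parsing is disabled and only the value column is numeric
        long = pd.read_csv(path, dtype=str, keep_default_na=False)
        long["value"] = pd.to_numeric(long["value"], errors="coerce")
        return cls.from_records(long.to_dict("records"))

    def equals(self, other: "FeatureMatrix", rtol: float = 1e-11) -> bool:
        a, b = self.data.sort_index(), other.data.sort_index()
        if not a.index.equals(b.index) or set(a.columns) != set(b.columns):
            return False
        b = b[a.columns]
        return np.allclose(a.to_numpy(), b.to_numpy(), rtol=rtol, atol=0, equal_nan=True)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2))
    return path
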