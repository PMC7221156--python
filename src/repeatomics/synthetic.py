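"""Synthetic paired test-retest data: phantom mpMRI cohorts and designed matrices.

Two generators support the pipeline end to end without any external data:

* :func:`generate_phantom_cohort` builds per-patient paired (test/retest)
  T2w + ADC volumes with a gland and lesion mask. Anatomy is an ellipsoidal
  gland containing a spherical lesion whose ADC is strongly reduced in an
  inner core and moderately reduced in the rim (restricted diffusion, the
  premise of habitat convergence). Frozen per-patient Gaussian texture plays
  the role of tissue heterogeneity; the retest scan differs only by fresh
  Gaussian voxel noise and by an independently jittered lesion boundary
  (emulating independent delineation at the two timepoints).
* :func:`generate_designed_features` draws paired feature matrices with a
  known population concordance per feature: Test = mu + e1, Retest = mu + e2
  with mu ~ N(0, between^2) and within-noise chosen so that
  CCC = between^2 / (between^2 + within^2) equals the target. Duplicate
  blocks force exact affine copies (population R^2 = 1) to exercise
  redundancy reduction.

Gaussian (not Rician) noise is used: at phantom SNR the difference is
immaterial and Gaussian keeps the designed-CCC algebra exact. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import FeatureMatrix, RegionMask, ScanVolume

__all__ = ["PhantomConfig", "PhantomCase", "generate_phantom_cohort",
           "DesignedFeatureConfig", "generate_designed_features"]

# background (non-gland) tissue means, per modality
_ADC_BACKGROUND = 800.0
_T2_BACKGROUND = 120.0


@dataclass(frozen=True)
class PhantomConfig:
    n_patients: int = 10
    grid: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    gland_semiaxes_mm: tuple[float, float, float] = (18.0, 14.0, 12.0)
    lesions_per_patient: int = 1
    lesion_radius_mm: float = 6.0
    #: fraction of the lesion radius occupied by the strongly low-ADC core
    lesion_core_fraction: float = 0.8
    adc_gland_mean: float = 1400.0
    adc_lesion_mean: float = 750.0
    adc_sd: float = 150.0
    t2_gland_mean: float = 400.0
    t2_lesion_mean: float = 250.0
    t2_sd: float = 60.0
    #: fresh per-timepoint noise, as a fraction of each modality's texture SD
    retest_noise_sd: float = 0.3
    boundary_jitter_mm: float = 1.0
    #: coefficient of variation of per-patient tissue means
    between_patient_cv: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.adc_lesion_mean >= self.adc_gland_mean:
            raise ValueError("lesions must be restricted-diffusion: "
                             "adc_lesion_mean < adc_gland_mean")
        if not 0 < self.lesion_core_fraction <= 1:
            raise ValueError("lesion_core_fraction must be in (0, 1]")


@dataclass
class PhantomCase:
    """One synthetic patient: paired volumes, gland mask, lesion masks, truth."""

    patient_id: str
    volumes: dict  # (modality, timepoint) -> ScanVolume
    gland: RegionMask
    lesions: dict  # timepoint -> list[RegionMask]
    core_truth: list = field(default_factory=list)  # planted low-ADC cores (bool arrays)


def _world_grids(grid, spacing):
    g = np.indices(grid, dtype=np.float64)
    return [g[ax] * spacing[ax] for ax in range(3)]


def _ellipsoid(world, center, semiaxes) -> np.ndarray:
    d = np.zeros(world[0].shape)
    for ax in range(3):
        d += ((world[ax] - center[ax]) / semiaxes[ax]) ** 2
    return d <= 1.0


def _jitter_footprint(jitter_mm: float, spacing) -> np.ndarray | None:
    half = [int(np.floor(jitter_mm / s)) for s in spacing]
    if not any(half):
        return None
    g = np.indices([2 * h + 1 for h in half], dtype=np.float64)
    d2 = np.zeros(g.shape[1:])
    for ax in range(3):
        d2 += ((g[ax] - half[ax]) * spacing[ax]) ** 2
    return d2 <= jitter_mm ** 2


def _jitter_mask(mask: np.ndarray, fp: np.ndarray | None, rng) -> np.ndarray:
    """Random dilation / erosion / identity emulating delineation variability."""
    if fp is None:
        return mask
    op = rng.integers(0, 3)
    if op == 0:
        return mask
    if op == 1:
        return ndimage.binary_dilation(mask, structure=fp)
    eroded = ndimage.binary_erosion(mask, structure=fp)
    return eroded if eroded.sum() >= 8 else mask


def generate_phantom_cohort(cfg: PhantomConfig = PhantomConfig()) -> list[PhantomCase]:
    """Generate the paired phantom cohort; deterministic given ``cfg.seed``."""
    master = np.random.SeedSequence(cfg.seed)
    cases = []
    for p, ss in enumerate(master.spawn(cfg.n_patients)):
        rng = np.random.default_rng(ss)
        pid = f"P{p + 1:03d}"
        world = _world_grids(cfg.grid, cfg.spacing)
        extent = [cfg.grid[ax] * cfg.spacing[ax] for ax in range(3)]
        gcenter = [e / 2.0 for e in extent]
        gland_mask = _ellipsoid(world, gcenter, cfg.gland_semiaxes_mm)

        scale = 1.0 + cfg.between_patient_cv * rng.standard_normal(4)
        adc_gland = cfg.adc_gland_mean * scale[0]
        adc_core = cfg.adc_lesion_mean * scale[1]
        t2_gland = cfg.t2_gland_mean * scale[2]
        t2_lesion = cfg.t2_lesion_mean * scale[3]
        adc_rim = 0.5 * (adc_gland + adc_core)

        adc = np.full(cfg.grid, _ADC_BACKGROUND)
        t2 = np.full(cfg.grid, _T2_BACKGROUND)
        adc[gland_mask] = adc_gland
        t2[gland_mask] = t2_gland

        lesion_masks, core_masks = [], []
        semi = np.asarray(cfg.gland_semiaxes_mm)
        for _ in range(cfg.lesions_per_patient):
            radius = cfg.lesion_radius_mm * rng.uniform(0.85, 1.15)
            for _attempt in range(100):
                offset = rng.uniform(-0.35, 0.35, size=3) * semi
                if np.sum(((np.abs(offset) + radius) / semi) ** 2) <= 1.0:
                    break
            else:
                raise ValueError("lesion outside gland: could not place lesion "
                                 "inside the gland ellipsoid")
            center = np.asarray(gcenter) + offset
            lesion = _ellipsoid(world, center, [radius] * 3)
            core = _ellipsoid(world, center, [radius * cfg.lesion_core_fraction] * 3)
            if not np.all(gland_mask[lesion]):
                raise ValueError("lesion outside gland")
            adc[core] = adc_core
            adc[lesion & ~core] = adc_rim
            t2[lesion] = t2_lesion
            lesion_masks.append(lesion)
            core_masks.append(core)

        # frozen anatomy texture, then fresh per-timepoint scanner noise
        adc_tex = adc + cfg.adc_sd * rng.standard_normal(cfg.grid)
        t2_tex = t2 + cfg.t2_sd * rng.standard_normal(cfg.grid)

        volumes, lesions = {}, {}
        fp = _jitter_footprint(cfg.boundary_jitter_mm, cfg.spacing)
        for tp in ("TEST", "RETEST"):
            adc_vox = adc_tex + cfg.retest_noise_sd * cfg.adc_sd * rng.standard_normal(cfg.grid)
            t2_vox = t2_tex + cfg.retest_noise_sd * cfg.t2_sd * rng.standard_normal(cfg.grid)
            volumes[("ADC", tp)] = ScanVolume(adc_vox, cfg.spacing, modality="ADC",
                                              timepoint=tp, patient_id=pid)
            volumes[("T2W", tp)] = ScanVolume(t2_vox, cfg.spacing, modality="T2W",
                                              timepoint=tp, patient_id=pid)
            tp_lesions = []
            for li, lm in enumerate(lesion_masks):
                jm = _jitter_mask(lm, fp, rng) & gland_mask if cfg.boundary_jitter_mm > 0 \
                    else lm
                tp_lesions.append(RegionMask(jm, cfg.spacing, label="LESION",
                                             lesion_id=f"L{li + 1}"))
            lesions[tp] = tp_lesions

        gland = RegionMask(gland_mask, cfg.spacing, label="GLAND")
        cases.append(PhantomCase(patient_id=pid, volumes=volumes, gland=gland,
                                 lesions=lesions, core_truth=core_masks))
    return cases


@dataclass(frozen=True)
class DesignedFeatureConfig:
    n_subjects: int = 200
    n_features: int = 10
    #: scalar or per-feature sequence of population CCC targets in [0, 1]
    target_ccc: float | tuple = 0.65
    between_sd: float | tuple = 1.0
    #: groups of 0-based feature indices forced to be exact affine copies
    duplicate_blocks: tuple = ()
    seed: int = 0


def generate_designed_features(cfg: DesignedFeatureConfig) -> FeatureMatrix:
    """Paired feature matrix with designed population CCC per feature."""
    rng = np.random.default_rng(cfg.seed)
    targets = np.broadcast_to(np.asarray(cfg.target_ccc, dtype=float),
                              (cfg.n_features,)).copy()
    between = np.broadcast_to(np.asarray(cfg.between_sd, dtype=float),
                              (cfg.n_features,)).copy()
    if np.any((targets < 0) | (targets > 1)):
        raise ValueError("target_ccc must be in [0, 1]")

    copies = {}  # feature index -> (source index, a, b)
    for block in cfg.duplicate_blocks:
        src = block[0]
        for pos, j in enumerate(block[1:], start=1):
            copies[j] = (src, 1.0 + 0.5 * pos, 0.3 * pos)

    test = np.empty((cfg.n_subjects, cfg.n_features))
    retest = np.empty_like(test)
    for j in range(cfg.n_features):
        if j in copies:
            continue
        t = targets[j]
        if t == 0.0:
            mu = np.zeros(cfg.n_subjects)
            within = between[j]
        else:
            mu = between[j] * rng.standard_normal(cfg.n_subjects)
            within = between[j] * np.sqrt((1.0 - t) / t)
        test[:, j] = mu + within * rng.standard_normal(cfg.n_subjects)
        retest[:, j] = mu + within * rng.standard_normal(cfg.n_subjects)
    for j, (src, a, b) in copies.items():
        test[:, j] = a * test[:, src] + b
        retest[:, j] = a * retest[:, src] + b

    rows = {}
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:04d}"
        for tp, arr in (("TEST", test), ("RETEST", retest)):
            rows[(sid, "L1", tp, "designed", "NA")] = {
                f"F{j + 1}:Designed-{j + 1}": arr[i, j] for j in range(cfg.n_features)
            }
    return FeatureMatrix.from_rows(rows)
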