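"""End-to-end orchestration over region variants and modalities.

For every patient-lesion and timepoint the pipeline (1) optionally z-scores
each modality against the gland, (2) converges habitat regions from the raw
ADC map of that timepoint, (3) extracts the 307-feature signature per region
variant and modality, then (4) screens features by CCC and dynamic range and
(5) reduces redundancy at each R^2 cutoff, emitting a summary count table
(rows = joint cutoffs, columns = variant x modality).

The four default region variants are radiologist-drawn and sphere-habitat
regions, each on raw and z-scored intensities; the two within-lesion
(median) habitat variants are opt-in. Habitats are always converged on raw
ADC — z-scoring is monotone, so thresholds would pick the same voxels — and
z-scoring applies only to the intensities feeding feature extraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_catalog
from .features import DEFAULT_NG, extract_features
from .habitat import HabitatConfig, habitat_sphere, habitat_within_lesion
from .io import (FeatureMatrix, RegionMask, ScanVolume, read_mask, read_volume,
                 write_json, write_mask, write_volume)
from .preprocess import zscore_standardize
from .repeatability import (DEFAULT_CUTOFFS, DEFAULT_RSQ_CUTOFFS,
                            RepeatabilityModel, RepeatabilityResults)
from .synthetic import PhantomCase, PhantomConfig, generate_phantom_cohort

__all__ = ["RunConfig", "PipelineError", "ALL_VARIANTS", "DEFAULT_VARIANTS",
           "extract_cohort_features", "run_pipeline", "write_cohort", "load_cohort"]

logger = logging.getLogger(__name__)

ALL_VARIANTS = ("radiologist_raw", "radiologist_z",
                "habitat_sphere_raw", "habitat_sphere_z",
                "habitat_median_raw", "habitat_median_z")
DEFAULT_VARIANTS = ALL_VARIANTS[:4]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    manifest: str | None = None
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    modalities: tuple[str, ...] = ("T2W", "ADC")
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    rsq_cutoffs: tuple[float, ...] = DEFAULT_RSQ_CUTOFFS
    habitat: HabitatConfig = field(default_factory=HabitatConfig)
    Ng: int = DEFAULT_NG
    outdir: str = "repeatomics_out"
    seed: int = 0

    def __post_init__(self):
        for v in self.variants:
            if v not in ALL_VARIANTS:
                raise ValueError(f"unknown variant {v!r}; valid: {ALL_VARIANTS}")
        for m in self.modalities:
            if m not in ("T2W", "ADC"):
                raise ValueError(f"unknown modality {m!r}; valid: ('T2W', 'ADC')")
        if not (self.variants and self.modalities and self.cutoffs):
            raise ValueError("need at least one variant, modality and cutoff")


def _variant_region(variant: str) -> str:
    if variant.startswith("radiologist"):
        return "radiologist"
    return "habitat_sphere" if variant.startswith("habitat_sphere") else "habitat_median"


def extract_cohort_features(cases: list[PhantomCase],
                            variants=DEFAULT_VARIANTS,
                            modalities=("T2W", "ADC"),
                            habitat_cfg: HabitatConfig = HabitatConfig(),
                            Ng: int = DEFAULT_NG,
                            catalog: FeatureCatalog | None = None,
                            ) -> tuple[FeatureMatrix, list[dict]]:
    """Extract the full feature matrix for a cohort.

    Returns (matrix, standardization-parameter log). Habitat regions are
    converged per timepoint from that timepoint's raw ADC and shared by both
    modalities.
    """
    if catalog is None:
        catalog = build_catalog()
    need_z = any(v.endswith("_z") for v in variants)
    regions_needed = {_variant_region(v) for v in variants}
    rows: dict[tuple, dict[str, float]] = {}
    zparams: list[dict] = []

    for case in cases:
        for tp in ("TEST", "RETEST"):
            vols = {m: case.volumes[(m, tp)] for m in modalities}
            adc_raw = case.volumes[("ADC", tp)]
            zvols = {}
            if need_z:
                for m, v in vols.items():
                    zv, params = zscore_standardize(v, case.gland)
                    zvols[m] = zv
                    zparams.append(params.as_dict())
            for lesion in case.lesions[tp]:
                regions: dict[str, RegionMask] = {}
                if "radiologist" in regions_needed:
                    regions["radiologist"] = lesion
                if "habitat_sphere" in regions_needed:
                    regions["habitat_sphere"] = habitat_sphere(
                        adc_raw, lesion, case.gland, habitat_cfg)
                if "habitat_median" in regions_needed:
                    regions["habitat_median"] = habitat_within_lesion(
                        adc_raw, lesion, habitat_cfg)
                for variant in variants:
                    roi = regions[_variant_region(variant)]
                    source = zvols if variant.endswith("_z") else vols
                    for m in modalities:
                        key = (case.patient_id, lesion.lesion_id, tp, variant, m)
                        rows[key] = extract_features(source[m], roi, catalog, Ng)
    return FeatureMatrix.from_rows(rows), zparams


def run_pipeline(cfg: RunConfig,
                 cases: list[PhantomCase] | None = None,
                 fm: FeatureMatrix | None = None,
                 ) -> tuple[RepeatabilityResults, FeatureMatrix]:
    """Run the full analysis and write the report bundle to ``cfg.outdir``.

    Inputs come from (in order of precedence) an injected feature matrix
    ``fm``, an in-memory cohort ``cases``, or the NIfTI cohort listed in
    ``cfg.manifest``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status = {"stages": {}}

    def _stage(name):
        def deco(fn):
            try:
                result = fn()
                status["stages"][name] = "ok"
                return result
            except Exception as exc:
                status["stages"][name] = f"failed: {exc}"
                write_json(status, outdir / "MANIFEST.status")
                raise PipelineError(name, str(exc)) from exc
        return deco

    if fm is None:
        if cases is None:
            if cfg.manifest is None:
                raise PipelineError("input", "no manifest, cohort or matrix given")
            cases = _stage("load")(lambda: load_cohort(cfg.manifest))
        zparams_box: list = []

        def _extract():
            m, zp = extract_cohort_features(cases, cfg.variants, cfg.modalities,
                                            cfg.habitat, cfg.Ng)
            zparams_box.extend(zp)
            return m

        fm = _stage("extract")(_extract)
        fm.write_csv(outdir / "features.csv")
    else:
        zparams_box = []
        status["stages"]["extract"] = "injected matrix"
        fm.write_csv(outdir / "features.csv")

    model = RepeatabilityModel(fm, cutoffs=cfg.cutoffs, rsq_cutoffs=cfg.rsq_cutoffs)
    results = _stage("screen_reduce")(model.fit)

    results.records.to_csv(outdir / "repeatability.csv", index=False,
                           float_format="%.12g")
    rec = results.records.set_index(["region_variant", "modality", "feature_id"])
    for r in cfg.rsq_cutoffs:
        rows = []
        for (v, m, rc), kept in results.survivors.items():
            if rc != r:
                continue
            for rank, fid in enumerate(kept, start=1):
                stats = rec.loc[(v, m, fid)]
                rows.append({"region_variant": v, "modality": m,
                             "cutoff_ccc_dr": results.base_cutoff,
                             "rsq_cutoff": r, "rank": rank, "feature_id": fid,
                             "ccc": stats["ccc"], "dr": stats["dr"]})
        pd.DataFrame(rows).to_csv(outdir / f"selected_rsq{r:g}.csv", index=False,
                                  float_format="%.12g")
        results.summary(r).to_csv(outdir / f"summary_rsq{r:g}.csv",
                                  float_format="%.12g")

    report = {
        "config": {
            "variants": list(cfg.variants), "modalities": list(cfg.modalities),
            "cutoffs": list(cfg.cutoffs), "rsq_cutoffs": list(cfg.rsq_cutoffs),
            "Ng": cfg.Ng, "seed": cfg.seed,
            "habitat": {"sphere_diameter_mm": cfg.habitat.sphere_diameter_mm,
                        "deviation_k": cfg.habitat.deviation_k,
                        "connectivity": cfg.habitat.connectivity,
                        "median_fraction": cfg.habitat.median_fraction},
        },
        "standardization_params": zparams_box,
        "n_rows": len(fm),
        "survivor_counts": {f"{v}/{m}/rsq{r:g}": len(kept)
                            for (v, m, r), kept in results.survivors.items()},
    }
    write_json(report, outdir / "run_report.json")
    write_json(status, outdir / "MANIFEST.status")
    return results, fm


# ---------------------------------------------------------------- cohort IO

def write_cohort(cases: list[PhantomCase], outdir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes/masks plus a manifest.json index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for case in cases:
        pdir = outdir / case.patient_id
        entry = {"patient_id": case.patient_id, "volumes": {}, "gland": None,
                 "lesions": {}}
        for (m, tp), vol in case.volumes.items():
            p = write_volume(vol, pdir / f"{m.lower()}_{tp.lower()}.nii.gz")
            entry["volumes"][f"{m}_{tp}"] = str(p.relative_to(outdir))
        p = write_mask(case.gland, pdir / "gland.nii.gz")
        entry["gland"] = str(p.relative_to(outdir))
        for tp, lesions in case.lesions.items():
            for lm in lesions:
                p = write_mask(lm, pdir / f"lesion_{lm.lesion_id}_{tp.lower()}.nii.gz")
                entry["lesions"].setdefault(lm.lesion_id, {})[tp] = \
                    str(p.relative_to(outdir))
        manifest["patients"].append(entry)
    path = outdir / "manifest.json"
    write_json(manifest, path)
    return path


def load_cohort(manifest_path: str | Path) -> list[PhantomCase]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cases = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        volumes = {}
        for key, rel in entry["volumes"].items():
            m, tp = key.split("_")
            volumes[(m, tp)] = read_volume(root / rel, modality=m, timepoint=tp,
                                           patient_id=pid)
        ref = volumes[("ADC", "TEST")]
        gland = read_mask(root / entry["gland"], ref, label="GLAND")
        lesions = {"TEST": [], "RETEST": []}
        for lid, tps in entry["lesions"].items():
            for tp, rel in tps.items():
                lesions[tp].append(read_mask(root / rel, ref, label="LESION",
                                             lesion_id=lid))
        cases.append(PhantomCase(patient_id=pid, volumes=volumes, gland=gland,
                                 lesions=lesions))
    return cases
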