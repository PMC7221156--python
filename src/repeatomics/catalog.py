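"""The 307-feature catalog.

Features are identified as ``F<k>:<name>`` with k = 1..307 and grouped into
three broad categories: C1 size and shape (45), C2 intensity, histogram and
texture-matrix features (107), C3 filter-bank textures — Laws and wavelets
(155). Within each family the ordering follows the IBSI reference feature
order, which is what pins the printed indices (e.g. F107 is the seventeenth
co-occurrence feature, inverse difference moment normalized).

Index layout::

    F1   - F19   STAT      first-order intensity statistics      (C2)
    F20  - F42   INTHIST   intensity-histogram features          (C2)
    F43  - F90   SHAPE     size/shape incl. the VIF curve        (C1, 45)
      F55 - F57  LOCINT    local-intensity features              (C2, 3)
    F91  - F115  GLCM3D    co-occurrence, averaged over 13 dirs  (C2, 25)
    F116 - F131  GLRLM3D   run length, averaged over 13 dirs     (C2, 16)
    F132 - F147  GLSZM     size zone (single 3D matrix)          (C2, 16)
    F148 - F152  NGTDM     neighborhood gray tone difference     (C2, 5)
    F153 - F277  LAWS3D    Laws texture energy, 5^3 kernels      (C3, 125)
    F278 - F307  WAVELET3D undecimated Haar subbands C1..C15     (C3, 30)
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FeatureDefinition", "FeatureCatalog", "build_catalog",
           "LAWS_KERNEL_NAMES", "VIF_FRACTIONS", "WAVELET_SUBBANDS"]

LAWS_KERNEL_NAMES = ("L5", "E5", "S5", "R5", "W5")

#: intensity fractions (percent) of the volume-at-intensity-fraction curve
VIF_FRACTIONS = (10, 20, 30, 40, 50, 60, 70, 90)

#: number of undecimated wavelet subbands through level 2 (7 + 7 + 1)
WAVELET_SUBBANDS = 15


@dataclass(frozen=True)
class FeatureDefinition:
    index: int                    # 1-based catalog position
    name: str
    family: str
    category: str
    params: dict = field(default_factory=dict)

    @property
    def feature_id(self) -> str:
        return f"F{self.index}:{self.name}"


class FeatureCatalog:
    def __init__(self, definitions: list[FeatureDefinition]):
        ids = [d.feature_id for d in definitions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in catalog")
        if [d.index for d in definitions] != list(range(1, len(definitions) + 1)):
            raise ValueError("catalog indices must be contiguous from 1")
        self.definitions = definitions
        self._by_id = {d.feature_id: d for d in definitions}

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def __getitem__(self, feature_id: str) -> FeatureDefinition:
        return self._by_id[feature_id]

    @property
    def feature_ids(self) -> list[str]:
        return [d.feature_id for d in self.definitions]

    def family(self, family: str) -> list[FeatureDefinition]:
        return [d for d in self.definitions if d.family == family]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.definitions:
            counts[d.category] = counts.get(d.category, 0) + 1
        return counts

    def to_json(self) -> list[dict]:
        return [{"feature_id": d.feature_id, "index": d.index, "name": d.name,
                 "family": d.family, "category": d.category, "params": d.params}
                for d in self.definitions]


_STAT_NAMES = [
    "Stat-Mean", "Stat-Var", "Stat-SD", "Stat-Skewness", "Stat-Kurtosis",
    "Stat-Median", "Stat-Min-gray-level", "Stat-10th-percentile",
    "Stat-90th-percentile", "Stat-Max-gray-level", "Stat-Interquartile-range",
    "Stat-range", "Stat-Mean-abs-deviation", "Stat-Robust-mean-abs-deviation",
    "Stat-Median-abs-deviation", "Stat-Coeff-of-variation",
    "Stat-Quartile-coeff-of-dispersion", "Stat-ENERGY", "Stat-Root-Mn-Sq",
]

_INTHIST_NAMES = [
    "Int-hist-mean", "Int-hist-var", "Int-hist-skewness", "Int-hist-kurtosis",
    "Int-hist-median", "Int-hist-min-gray-level", "Int-hist-10th-percentile",
    "Int-hist-90th-percentile", "Int-hist-max-gray-level", "Int-hist-mode",
    "Int-hist-interquartile-range", "Int-hist-range",
    "Int-hist-mean-abs-deviation", "Int-hist-robust-mean-abs-deviation",
    "Int-hist-median-abs-deviation", "Int-hist-coeff-of-variation",
    "Int-hist-quartile-coeff-of-dispersion", "Int-hist-entropy",
    "Int-hist-uniformity", "Max-hist-Gradient", "Max-hist-Gradient-gray-level",
    "Min-hist-Gradient", "Min-hist-Gradient-gray-level",
]

# F43..F90; positions 55-57 are the C2 local-intensity features.
_SHAPE_BLOCK = [
    "Vol-at-Int-Fraction-10", "Vol-at-Int-Fraction-20", "Vol-at-Int-Fraction-30",
    "Vol-at-Int-Fraction-40", "Vol-at-Int-fraction-diff", "Vol-at-Int-Fraction-50",
    "Vol-at-Int-Fraction-60", "Vol-at-Int-Fraction-70", "Vol-at-Int-Fraction-90",
    "Vol-(mm^3)", "Vol-(voxel-count)", "Surface-area-(mm^2)",
    "Local-intensity-peak", "Global-intensity-peak", "Total-energy",
    "Surface-to-volume-ratio-(1/mm)", "Compactness-1", "Compactness-2",
    "Spherical-disproportion", "Sphericity", "Asphericity", "Elongation",
    "Flatness", "Major-axis-length-(mm)", "Minor-axis-length-(mm)",
    "Least-axis-length-(mm)", "Max-3D-diameter-(mm)", "Bounding-box-x-(mm)",
    "Bounding-box-y-(mm)", "Bounding-box-z-(mm)", "Bounding-box-vol-(mm^3)",
    "Extent", "Max-2D-diameter-axial-(mm)", "Max-2D-diameter-coronal-(mm)",
    "Max-2D-diameter-sagittal-(mm)", "Num-slices", "Max-slice-area-(mm^2)",
    "Equiv-sphere-diameter-(mm)", "Equiv-sphere-surface-(mm^2)",
    "CoM_x-(mm)", "CoM_y-(mm)", "CoM_z-(mm)", "Weighted-CoM_x-(mm)",
    "Weighted-CoM_y-(mm)", "Weighted-CoM_z-(mm)", "Center-of-mass-shift-(mm)",
    "Border-length-max-slice-(mm)", "Border-length-(mm)",
]
_LOCINT_NAMES = {"Local-intensity-peak", "Global-intensity-peak", "Total-energy"}

_GLCM_NAMES = [
    "Joint-max", "Joint-avg", "Joint-var", "Joint-entropy", "Difference-avg",
    "Difference-var", "Difference-entropy", "Sum-avg", "Sum-var", "Sum-entropy",
    "Angular-second-moment", "Contrast", "Dissimilarity", "Inv-diff",
    "Inv-diff-norm", "Inv-diff-mom", "Inv-diff-mom-norm", "Inv-var",
    "Correlation", "Autocorrelation", "Cluster-tendency", "Cluster-shade",
    "Cluster-prominence", "First-measure-of-information-correlation",
    "Second-measure-of-information-correlation",
]

_GLRLM_NAMES = [
    "SRE-(Short-runs-emphasis)", "LRE-(Long-runs-emphasis)",
    "LGRE-(Low-gray-level-run-emphasis)", "HGRE-(High-gray-level-run-emphasis)",
    "SRLGE-(Short-run-low-gray-level-emphasis)",
    "SRHGE-(Short-run-high-gray-level-emphasis)",
    "LRLGE-(Long-run-low-gray-level-emphasis)",
    "LRHGE-(Long-run-high-gray-level-emphasis)",
    "GLN-(Gray-level-non-uniformity)", "GLNN-(Gray-level-non-uniformity-normalized)",
    "RLN-(Run-length-non-uniformity)", "RLNN-(Run-length-non-uniformity-normalized)",
    "RP-(Run-percentage)", "GLV-(Gray-level-variance)",
    "RLV-(Run-length-variance)", "RE-(Run-entropy)",
]

_GLSZM_NAMES = [
    "Small-zone-emphasis", "Large-zone-emphasis", "Low-gray-level-zone-emphasis",
    "High-gray-level-zone-emphasis", "Small-zone-low-gray-level-emphasis",
    "Small-zone-high-gray-level-emphasis", "Large-zone-low-gray-level-emphasis",
    "Large-zone-high-gray-level-emphasis", "Gray-level-non-uniformity",
    "Gray-level-non-uniformity-normalized", "Zone-size-non-uniformity",
    "Zone-size-non-uniformity-normalized", "Zone-percentage",
    "Gray-level-variance", "Zone-size-variance", "Zone-size-entropy",
]

_NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def build_catalog() -> FeatureCatalog:
    """Build the ordered 307-feature catalog (45 C1 + 107 C2 + 155 C3)."""
    defs: list[FeatureDefinition] = []
    k = 1

    for name in _STAT_NAMES:
        defs.append(FeatureDefinition(k, name, "STAT", "C2")); k += 1
    for name in _INTHIST_NAMES:
        defs.append(FeatureDefinition(k, name, "INTHIST", "C2")); k += 1
    for name in _SHAPE_BLOCK:
        if name in _LOCINT_NAMES:
            defs.append(FeatureDefinition(k, name, "LOCINT", "C2"))
        else:
            defs.append(FeatureDefinition(k, name, "SHAPE", "C1"))
        k += 1
    for name in _GLCM_NAMES:
        defs.append(FeatureDefinition(k, f"avgCooc_3D_{name}", "GLCM3D", "C2")); k += 1
    for name in _GLRLM_NAMES:
        defs.append(FeatureDefinition(k, f"avg_3D_{name}", "GLRLM3D", "C2")); k += 1
    for name in _GLSZM_NAMES:
        defs.append(FeatureDefinition(k, f"GLSZM_{name}", "GLSZM", "C2")); k += 1
    for name in _NGTDM_NAMES:
        defs.append(FeatureDefinition(k, f"NGTDM_{name}", "NGTDM", "C2")); k += 1
    for k1 in LAWS_KERNEL_NAMES:
        for k2 in LAWS_KERNEL_NAMES:
            for k3 in LAWS_KERNEL_NAMES:
                defs.append(FeatureDefinition(
                    k, f"3D-LawsF-{k1}-{k2}-{k3}", "LAWS3D", "C3",
                    params={"kernels": (k1, k2, k3)}))
                k += 1
    for c in range(1, WAVELET_SUBBANDS + 1):
        defs.append(FeatureDefinition(k, f"3D-Wave-P1-L2-C{c}", "WAVELET3D", "C3",
                                      params={"subband": c, "statistic": "mean_abs"}))
        k += 1
        defs.append(FeatureDefinition(k, f"3D-Wave-P1-L2-C{c}-Energy", "WAVELET3D", "C3",
                                      params={"subband": c, "statistic": "energy"}))
        k += 1

    assert k - 1 == 307
    return FeatureCatalog(defs)
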