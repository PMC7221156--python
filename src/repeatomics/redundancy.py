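"""Redundancy reduction among reproducible features.

Reproducible features are often near-collinear (e.g. volume in mm^3 vs voxel
count). Features are grouped by the coefficient of determination R^2 — the
squared Pearson correlation of their subject-wise values, with test and
retest averaged per subject first — and each group keeps a single
representative: the feature with the highest dynamic range. The grouping is
applied greedily in descending-DR order and repeated recursively on the
remainder, which makes the selection deterministic. The step eliminates
redundancy; it does not certify pairwise independence of the survivors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix

__all__ = ["RedundancyConfig", "rsq", "reduce_features", "subject_averaged"]


@dataclass(frozen=True)
class RedundancyConfig:
    rsq_cutoff: float = 0.99

    def __post_init__(self):
        if not 0 < self.rsq_cutoff <= 1:
            raise ValueError("rsq_cutoff must be in (0, 1]")


def rsq(x, y) -> float:
    """Squared Pearson correlation on complete pairs; 0 if either is constant."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(min(r * r, 1.0))


def subject_averaged(fm: FeatureMatrix) -> pd.DataFrame:
    """Per-subject (test + retest)/2 feature values: subjects x features.

    ``fm`` must hold a single (region variant, modality) slice; subjects are
    (patient, lesion) pairs present at both timepoints.
    """
    df = fm.data.droplevel(["region_variant", "modality"])
    test = df.xs("TEST", level="timepoint")
    retest = df.xs("RETEST", level="timepoint")
    common = test.index.intersection(retest.index)
    return (test.loc[common] + retest.loc[common]) / 2.0


def _catalog_index(feature_id: str) -> int:
    m = re.match(r"F(\d+):", feature_id)
    return int(m.group(1)) if m else 10 ** 9


def reduce_features(records: pd.DataFrame, averaged: pd.DataFrame,
                    rsq_cutoff: float = 0.99) -> list[str]:
    """Greedy recursive representative selection.

    Parameters
    ----------
    records : DataFrame with columns feature_id, dr
        The features that passed the repeatability cutoff, with their dynamic
        range.
    averaged : DataFrame (subjects x features)
        Subject-wise test/retest-averaged values (see :func:`subject_averaged`).
    rsq_cutoff : float
        Features with R^2 >= cutoff against the current representative are
        grouped with (and eliminated by) it.

    Returns the representatives in selection order. Every eliminated feature
    has R^2 >= cutoff with at least one representative. Constant feature
    vectors have R^2 = 0 against everything and survive on their own merits.
    """
    RedundancyConfig(rsq_cutoff)  # validate
    remaining = records[["feature_id", "dr"]].dropna().copy()
    remaining["order"] = remaining["feature_id"].map(_catalog_index)
    # highest DR first; catalog order breaks ties deterministically
    remaining = remaining.sort_values(["dr", "order"], ascending=[False, True])
    pool = list(remaining["feature_id"])
    if not pool:
        return []

    # standardized column matrix: R^2 against a representative is then a
    # single matrix-vector product; constant columns get R^2 = 0 by zeroing
    X = averaged[pool].to_numpy(dtype=np.float64)
    n = X.shape[0]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    Z = np.where(nonconst, X / np.where(nonconst, sd, 1.0), 0.0)

    selected: list[str] = []
    idx = list(range(len(pool)))
    while idx:
        rep = idx.pop(0)
        selected.append(pool[rep])
        if not idx:
            break
        r = Z[:, idx].T @ Z[:, rep] / n
        r2 = np.minimum(r * r, 1.0)
        if not nonconst[rep]:
            r2[:] = 0.0
        idx = [j for j, v in zip(idx, r2) if v < rsq_cutoff]
    return selected
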