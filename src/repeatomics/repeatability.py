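"""Test-retest repeatability: concordance, dynamic range, and joint screening.

For each feature, Lin's concordance correlation coefficient (CCC) measures
agreement between test and retest values across the cohort — it penalizes
both poor correlation and systematic deviation from the identity line:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

with population (1/n) moments. The dynamic range (DR) compares the mean
absolute test-retest difference to the observed biological range of the
feature (pooled over both timepoints):

    DR = 1 - mean|Test_i - Retest_i| / (Max - Min)

DR lies in [0, 1]; values near 1 mean repeat error is small relative to
interpatient spread. A feature passes a cutoff c when both CCC >= c and
DR >= c ("CCC and DR" jointly).

:class:`RepeatabilityModel` packages the full analysis: screening each
feature per (region variant, modality), then redundancy reduction of the
passing set, with a Table-2-style summary of survivor counts per cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .redundancy import reduce_features, subject_averaged

__all__ = ["ccc", "dynamic_range", "screen", "RepeatabilityModel",
           "RepeatabilityResults", "DEFAULT_CUTOFFS", "DEFAULT_RSQ_CUTOFFS"]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
DEFAULT_RSQ_CUTOFFS = (0.99, 0.95)


def _complete_pairs(test, retest) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(test, dtype=np.float64).ravel()
    y = np.asarray(retest, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("test and retest must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def ccc(test, retest) -> float:
    """Lin's concordance correlation coefficient (population moments).

    Degenerate conventions: both vectors constant and equal -> 1; constant
    but unequal -> 0 (the formula's limit). Requires >= 3 complete pairs.
    """
    x, y = _complete_pairs(test, retest)
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = x.var() + y.var() + (mx - my) ** 2
    if denom == 0.0:
        return 1.0
    return float(2.0 * sxy / denom)


def dynamic_range(test, retest) -> float:
    """Eq.-style dynamic range with the pooled test+retest Max-Min denominator.

    Clipped to [0, 1]; a degenerate pooled range (all values identical)
    yields 0. Requires >= 2 complete pairs.
    """
    x, y = _complete_pairs(test, retest)
    if len(x) < 2:
        raise ValueError(f"need at least 2 complete pairs, got {len(x)}")
    pooled = np.concatenate([x, y])
    rng = pooled.max() - pooled.min()
    if rng == 0.0:
        return 0.0
    dr = 1.0 - np.abs(x - y).mean() / rng
    return float(np.clip(dr, 0.0, 1.0))


def screen(fm: FeatureMatrix, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Per-feature CCC/DR and joint pass flags, per (region variant, modality).

    Returns a long DataFrame with columns (region_variant, modality,
    feature_id, n_pairs, ccc, dr, pass_<c>...). Features with fewer than 3
    complete pairs get NaN statistics and fail every cutoff (logged).
    """
    fm.check_paired()
    cutoffs = tuple(sorted(cutoffs))
    groups = fm.data.groupby(level=["region_variant", "modality"], sort=True)
    rows = []
    for (variant, modality), df in groups:
        sub = FeatureMatrix(df)
        for fid in sub.feature_ids:
            test, retest, _ = sub.paired(fid)
            x, y = _complete_pairs(test, retest)
            if len(x) < 3:
                logger.warning("feature %s (%s/%s): only %d complete pairs; excluded",
                               fid, variant, modality, len(x))
                c = d = float("nan")
            else:
                c, d = ccc(x, y), dynamic_range(x, y)
            row = {"region_variant": variant, "modality": modality,
                   "feature_id": fid, "n_pairs": len(x), "ccc": c, "dr": d}
            for cut in cutoffs:
                row[f"pass_{cut:.2f}"] = bool(np.isfinite(c) and np.isfinite(d)
                                              and c >= cut and d >= cut)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RepeatabilityResults:
    """Fit results: per-feature records, survivors, and summary counts."""

    records: pd.DataFrame
    survivors: dict[tuple[str, str, float], list[str]]
    cutoffs: tuple[float, ...]
    rsq_cutoffs: tuple[float, ...]
    base_cutoff: float

    def summary(self, rsq_cutoff: float | None = None) -> pd.DataFrame:
        """Counts of reproducible, non-redundant features at each cutoff row.

        Rows are CCC-and-DR cutoffs (descending); columns are
        (region_variant, modality) pairs. A feature is counted at row c if it
        survived redundancy reduction of the base-cutoff passing set and its
        CCC and DR both reach c — so columns are monotone non-increasing
        upward, mirroring the nested structure of per-cutoff counts.
        """
        if rsq_cutoff is None:
            rsq_cutoff = self.rsq_cutoffs[0]
        combos = sorted({(v, m) for (v, m, r) in self.survivors if r == rsq_cutoff})
        rows = sorted(self.cutoffs, reverse=True)
        rec = self.records.set_index(["region_variant", "modality", "feature_id"])
        table = {}
        for v, m in combos:
            kept = self.survivors[(v, m, rsq_cutoff)]
            counts = []
            for c in rows:
                n = 0
                for fid in kept:
                    r = rec.loc[(v, m, fid)]
                    if np.isfinite(r["ccc"]) and r["ccc"] >= c and r["dr"] >= c:
                        n += 1
                counts.append(n)
            table[(v, m)] = counts
        out = pd.DataFrame(table, index=[f">={c:.2f}" for c in rows])
        out.index.name = "ccc_and_dr"
        out.columns = pd.MultiIndex.from_tuples(out.columns,
                                                names=["region_variant", "modality"])
        return out

    def selected(self, region_variant: str, modality: str,
                 rsq_cutoff: float | None = None) -> list[str]:
        if rsq_cutoff is None:
            rsq_cutoff = self.rsq_cutoffs[0]
        return list(self.survivors.get((region_variant, modality, rsq_cutoff), []))

    def __str__(self) -> str:
        lines = ["Test-retest repeatability summary "
                 f"(joint CCC and DR cutoffs; base >= {self.base_cutoff:.2f})"]
        for r in self.rsq_cutoffs:
            lines.append(f"\nRedundancy R^2 >= {r:.2f}:")
            lines.append(self.summary(r).to_string())
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of per-feature CCC vs DR, one marker per variant/modality."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (v, m), df in self.records.groupby(["region_variant", "modality"]):
            ax.scatter(df["ccc"], df["dr"], s=8, alpha=0.6, label=f"{v}/{m}")
        ax.set_xlabel("CCC")
        ax.set_ylabel("dynamic range")
        ax.legend(fontsize=7)
        return ax


class RepeatabilityModel:
    """Repeatability analysis of a paired test-retest feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
        Feature values at both timepoints (any number of region variants and
        modalities; each is analyzed independently).
    cutoffs : sequence of float
        Joint CCC-and-DR cutoffs for the summary rows.
    rsq_cutoffs : sequence of float
        R-squared levels for redundancy reduction.
    """

    def __init__(self, fm: FeatureMatrix, cutoffs=DEFAULT_CUTOFFS,
                 rsq_cutoffs=DEFAULT_RSQ_CUTOFFS):
        if not len(cutoffs) or not len(rsq_cutoffs):
            raise ValueError("need at least one cutoff and one rsq_cutoff")
        self.fm = fm
        self.cutoffs = tuple(sorted(cutoffs))
        self.rsq_cutoffs = tuple(rsq_cutoffs)
        self.base_cutoff = self.cutoffs[0]

    def fit(self) -> RepeatabilityResults:
        records = screen(self.fm, self.cutoffs)
        survivors: dict[tuple[str, str, float], list[str]] = {}
        base_col = f"pass_{self.base_cutoff:.2f}"
        for (variant, modality), rec in records.groupby(["region_variant", "modality"]):
            passing = rec.loc[rec[base_col], ["feature_id", "dr"]]
            sub = self.fm.subset(region_variant=variant, modality=modality)
            averaged = subject_averaged(sub)
            for r in self.rsq_cutoffs:
                kept = reduce_features(passing, averaged, rsq_cutoff=r)
                survivors[(variant, modality, r)] = kept
        return RepeatabilityResults(records=records, survivors=survivors,
                                    cutoffs=self.cutoffs,
                                    rsq_cutoffs=self.rsq_cutoffs,
                                    base_cutoff=self.base_cutoff)
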