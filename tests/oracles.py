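"""Independent brute-force oracles for the texture matrices and statistics.

Everything here is written as plain loops over voxels, pairs, runs, zones and
neighborhoods — deliberately naive, sharing no code with the package — so the
vectorized implementations can be checked against exhaustive enumeration.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def _inb(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------- GLCM

def glcm_matrix_oracle(levels: np.ndarray, d) -> dict:
    """Symmetric co-occurrence counts by listing every in-ROI voxel pair."""
    counts: dict = defaultdict(float)
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        if _inb(shape, q) and levels[q] != 0:
            counts[(int(levels[p]), int(levels[q]))] += 1.0
            counts[(int(levels[q]), int(levels[p]))] += 1.0
    return dict(counts)


def glcm_features_oracle(counts: dict, Ng: int) -> dict:
    s = sum(counts.values())
    p = {ij: c / s for ij, c in counts.items()}
    px = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    jvar = sum((i - mu) ** 2 * v for (i, j), v in p.items())
    pd_, ps_ = defaultdict(float), defaultdict(float)
    for (i, j), v in p.items():
        pd_[abs(i - j)] += v
        ps_[i + j] += v
    davg = sum(k * v for k, v in pd_.items())
    savg = sum(k * v for k, v in ps_.items())
    hxy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    hx = -sum(v * math.log2(v) for v in px.values() if v > 0)
    hxy1 = -sum(v * math.log2(px[i] * px[j]) for (i, j), v in p.items())
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in px for j in px)
    corr_num = sum(i * j * v for (i, j), v in p.items()) - mu * mu
    return {
        "Joint-max": max(p.values()),
        "Joint-avg": mu,
        "Joint-var": jvar,
        "Joint-entropy": hxy,
        "Difference-avg": davg,
        "Difference-var": sum((k - davg) ** 2 * v for k, v in pd_.items()),
        "Difference-entropy": -sum(v * math.log2(v) for v in pd_.values() if v > 0),
        "Sum-avg": savg,
        "Sum-var": sum((k - savg) ** 2 * v for k, v in ps_.items()),
        "Sum-entropy": -sum(v * math.log2(v) for v in ps_.values() if v > 0),
        "Angular-second-moment": sum(v ** 2 for v in p.values()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "Inv-diff": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "Inv-diff-norm": sum(v / (1 + abs(i - j) / Ng) for (i, j), v in p.items()),
        "Inv-diff-mom": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "Inv-diff-mom-norm": sum(v / (1 + (i - j) ** 2 / Ng ** 2)
                                 for (i, j), v in p.items()),
        "Inv-var": sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j),
        "Correlation": corr_num / jvar if jvar > 0 else 1.0,
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "Cluster-tendency": sum((i + j - 2 * mu) ** 2 * v for (i, j), v in p.items()),
        "Cluster-shade": sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items()),
        "Cluster-prominence": sum((i + j - 2 * mu) ** 4 * v for (i, j), v in p.items()),
        "First-measure-of-information-correlation":
            (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Second-measure-of-information-correlation":
            math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
    }


def glcm_avg_oracle(levels: np.ndarray, Ng: int) -> dict:
    per_dir = []
    for d in DIRECTIONS_13:
        counts = glcm_matrix_oracle(levels, d)
        if counts:
            per_dir.append(glcm_features_oracle(counts, Ng))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ---------------------------------------------------------------- GLRLM

def runs_oracle(levels: np.ndarray, d) -> list[tuple[int, int]]:
    """Enumerate maximal same-level runs along direction d by walking voxels."""
    shape = levels.shape
    runs = []
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
        if _inb(shape, prev) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        while _inb(shape, q) and levels[q] == levels[p]:
            length += 1
            q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
        runs.append((int(levels[p]), length))
    return runs


def _sz_features_oracle(entries: list[tuple[int, int]], Nv: int) -> dict:
    Ns = float(len(entries))
    ri, rj, pij = defaultdict(float), defaultdict(float), defaultdict(float)
    for i, j in entries:
        ri[i] += 1
        rj[j] += 1
        pij[(i, j)] += 1
    mu_i = sum(i for i, j in entries) / Ns
    mu_j = sum(j for i, j in entries) / Ns
    return {
        "SE": sum(1.0 / j ** 2 for i, j in entries) / Ns,
        "LE": sum(j ** 2 for i, j in entries) / Ns,
        "LG": sum(1.0 / i ** 2 for i, j in entries) / Ns,
        "HG": sum(i ** 2 for i, j in entries) / Ns,
        "SLG": sum(1.0 / (i * j) ** 2 for i, j in entries) / Ns,
        "SHG": sum(i ** 2 / j ** 2 for i, j in entries) / Ns,
        "LLG": sum(j ** 2 / i ** 2 for i, j in entries) / Ns,
        "LHG": sum((i * j) ** 2 for i, j in entries) / Ns,
        "GLN": sum(v ** 2 for v in ri.values()) / Ns,
        "GLNN": sum(v ** 2 for v in ri.values()) / Ns ** 2,
        "SN": sum(v ** 2 for v in rj.values()) / Ns,
        "SNN": sum(v ** 2 for v in rj.values()) / Ns ** 2,
        "PCT": Ns / Nv,
        "GLV": sum((i - mu_i) ** 2 for i, j in entries) / Ns,
        "SV": sum((j - mu_j) ** 2 for i, j in entries) / Ns,
        "ENT": -sum((v / Ns) * math.log2(v / Ns) for v in pij.values()),
    }


def glrlm_avg_oracle(levels: np.ndarray) -> dict:
    Nv = int((levels > 0).sum())
    per_dir = []
    for d in DIRECTIONS_13:
        runs = runs_oracle(levels, d)
        if runs:
            per_dir.append(_sz_features_oracle(runs, Nv))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ---------------------------------------------------------------- GLSZM

def zones_oracle(levels: np.ndarray) -> list[tuple[int, int]]:
    """26-connected same-level zones by flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                q = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if _inb(shape, q) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(g), size))
    return zones


def glszm_oracle(levels: np.ndarray) -> dict:
    Nv = int((levels > 0).sum())
    return _sz_features_oracle(zones_oracle(levels), Nv)


# ---------------------------------------------------------------- NGTDM

def ngtdm_oracle(levels: np.ndarray, Ng: int, eps: float = 1e-12) -> dict:
    shape = levels.shape
    n = defaultdict(float)
    s = defaultdict(float)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        nb = [levels[(p[0] + o[0], p[1] + o[1], p[2] + o[2])]
              for o in offsets
              if _inb(shape, (p[0] + o[0], p[1] + o[1], p[2] + o[2]))
              and levels[(p[0] + o[0], p[1] + o[1], p[2] + o[2])] != 0]
        if not nb:
            continue
        i = int(levels[p])
        n[i] += 1
        s[i] += abs(i - sum(nb) / len(nb))
    Nvc = sum(n.values())
    pres = sorted(n)
    p = {i: n[i] / Nvc for i in pres}
    Np = len(pres)
    coarse_den = sum(p[i] * s[i] for i in pres)
    out = {"Coarseness": 1.0 / max(coarse_den, eps)}
    if Np > 1:
        out["Contrast"] = (sum(p[i] * p[j] * (i - j) ** 2 for i in pres for j in pres)
                           / (Np * (Np - 1))) * (sum(s.values()) / Nvc)
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in pres for j in pres)
        out["Busyness"] = coarse_den / busy_den if busy_den > 0 else 0.0
        out["Complexity"] = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                                for i in pres for j in pres) / Nvc
        stot = sum(s.values())
        out["Strength"] = (sum((p[i] + p[j]) * (i - j) ** 2 for i in pres for j in pres)
                           / stot) if stot > 0 else 0.0
    else:
        out.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0,
                    "Strength": 0.0})
    return out


# ---------------------------------------------------------------- statistics

def ccc_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    den = sx2 + sy2 + (mx - my) ** 2
    return 1.0 if den == 0 else 2.0 * sxy / den


def dr_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = list(x) + list(y)
    rng = max(pooled) - min(pooled)
    if rng == 0:
        return 0.0
    val = 1.0 - (sum(abs(a - b) for a, b in zip(x, y)) / len(x)) / rng
    return min(1.0, max(0.0, val))


def rsq_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    if sx == 0 or sy == 0:
        return 0.0
    r = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n / (sx * sy)
    return min(r * r, 1.0)


_GLRLM_ORACLE_TO_IMPL = {
    "SE": "SRE-(Short-runs-emphasis)", "LE": "LRE-(Long-runs-emphasis)",
    "LG": "LGRE-(Low-gray-level-run-emphasis)", "HG": "HGRE-(High-gray-level-run-emphasis)",
    "SLG": "SRLGE-(Short-run-low-gray-level-emphasis)",
    "SHG": "SRHGE-(Short-run-high-gray-level-emphasis)",
    "LLG": "LRLGE-(Long-run-low-gray-level-emphasis)",
    "LHG": "LRHGE-(Long-run-high-gray-level-emphasis)",
    "GLN": "GLN-(Gray-level-non-uniformity)",
    "GLNN": "GLNN-(Gray-level-non-uniformity-normalized)",
    "SN": "RLN-(Run-length-non-uniformity)",
    "SNN": "RLNN-(Run-length-non-uniformity-normalized)",
    "PCT": "RP-(Run-percentage)", "GLV": "GLV-(Gray-level-variance)",
    "SV": "RLV-(Run-length-variance)", "ENT": "RE-(Run-entropy)",
}

_GLSZM_ORACLE_TO_IMPL = {
    "SE": "Small-zone-emphasis", "LE": "Large-zone-emphasis",
    "LG": "Low-gray-level-zone-emphasis", "HG": "High-gray-level-zone-emphasis",
    "SLG": "Small-zone-low-gray-level-emphasis",
    "SHG": "Small-zone-high-gray-level-emphasis",
    "LLG": "Large-zone-low-gray-level-emphasis",
    "LHG": "Large-zone-high-gray-level-emphasis",
    "GLN": "Gray-level-non-uniformity",
    "GLNN": "Gray-level-non-uniformity-normalized",
    "SN": "Zone-size-non-uniformity", "SNN": "Zone-size-non-uniformity-normalized",
    "PCT": "Zone-percentage", "GLV": "Gray-level-variance",
    "SV": "Zone-size-variance", "ENT": "Zone-size-entropy",
}
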