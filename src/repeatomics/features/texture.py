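"""Gray-level texture matrices: GLCM, GLRLM, GLSZM, NGTDM.

All four families operate on a quantized ROI (fixed bin number over the
in-ROI intensity range, default Ng = 32). Co-occurrence and run-length
matrices are computed per direction over the 13 unique 3D offsets at
Chebyshev distance 1, features are computed per direction and then averaged
(the "avgCooc_3D" / "avg_3D" catalog prefixes). The size-zone matrix uses
26-connected zones and a single matrix; the NGTDM uses the 26-neighborhood
restricted to in-ROI voxels. Texture is computed on the voxel grid ignoring
spacing anisotropy.

Degenerate ROIs (e.g. constant intensity) produce defined values throughout,
with the IBSI epsilon guard for NGTDM coarseness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..io import RegionMask, ScanVolume

__all__ = ["QuantizedROI", "quantize", "glcm3d_features", "glrlm3d_features",
           "glszm_features", "ngtdm_features", "DIRECTIONS_13"]

#: the 13 unique 3D direction offsets at Chebyshev distance 1
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

_EPS = 1e-12


@dataclass
class QuantizedROI:
    """Integer gray levels 1..Ng on ROI voxels; 0 outside the ROI."""

    levels: np.ndarray
    Ng: int
    roi: RegionMask
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())

    def roi_levels(self) -> np.ndarray:
        return self.levels[self.levels > 0]


def quantize(vol: ScanVolume, roi: RegionMask, Ng: int = 32) -> QuantizedROI:
    """Fixed-bin-number quantization over the in-ROI [min, max] range.

    Bins are right-closed: level = ceil((v - min) / width) with the minimum
    assigned level 1 and the maximum level Ng. A constant ROI maps every
    voxel to level 1.
    """
    roi.check_same_grid(vol)
    if roi.n_voxels < 2:
        raise ValueError("ROI must contain at least 2 voxels for quantization")
    if Ng < 1:
        raise ValueError("Ng must be >= 1")
    vals = vol.voxels[roi.voxels]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if vmax == vmin:
        levels[roi.voxels] = 1
    else:
        width = (vmax - vmin) / Ng
        lv = np.ceil((vol.voxels[roi.voxels] - vmin) / width)
        levels[roi.voxels] = np.clip(lv, 1, Ng).astype(np.int32)
    return QuantizedROI(levels, Ng, roi, vol.spacing)


def _bbox_levels(q: QuantizedROI) -> np.ndarray:
    """Crop the level array to the ROI bounding box (levels are 0 outside ROI)."""
    idx = np.argwhere(q.levels > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return q.levels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _pair_slices(shape, d):
    """Slices (src, dst) such that src voxel + d == dst voxel."""
    src, dst = [], []
    for ax in range(3):
        o = d[ax]
        n = shape[ax]
        if o >= 0:
            src.append(slice(0, n - o)); dst.append(slice(o, n))
        else:
            src.append(slice(-o, n)); dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM

def _glcm_matrix(L: np.ndarray, Ng: int, d) -> np.ndarray:
    src, dst = _pair_slices(L.shape, d)
    a, b = L[src].ravel(), L[dst].ravel()
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return np.zeros((Ng, Ng))
    counts = np.bincount((a[ok] - 1) * Ng + (b[ok] - 1), minlength=Ng * Ng)
    P = counts.reshape(Ng, Ng).astype(np.float64)
    return P + P.T  # symmetric co-occurrence


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    s = P.sum()
    p = P / s
    i = np.arange(1, Ng + 1, dtype=np.float64)
    I = i[:, None] * np.ones((1, Ng))
    J = I.T
    px = p.sum(axis=1)

    mu = float((i * px).sum())
    joint_var = float((((I - mu) ** 2) * p).sum())

    # difference |i-j| and sum i+j marginal distributions
    k_diff = np.abs(I - J).astype(int)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=Ng)
    kd = np.arange(len(p_diff), dtype=np.float64)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float((((kd - diff_avg) ** 2) * p_diff).sum())
    k_sum = (I + J).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * Ng + 1)
    ks = np.arange(len(p_sum), dtype=np.float64)
    sum_avg = float((ks * p_sum).sum())
    sum_var = float((((ks - sum_avg) ** 2) * p_sum).sum())

    absdiff = np.abs(I - J)
    sqdiff = (I - J) ** 2
    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    pxy = px[:, None] * px[None, :]
    nz = pxy > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    hxy2 = float(-(pxy[nz] * np.log2(pxy[nz])).sum())
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    corr = ((I * J * p).sum() - mu * mu) / joint_var if joint_var > 0 else 1.0

    off = I + J - 2 * mu
    with np.errstate(divide="ignore"):
        inv_var = float((p[absdiff > 0] / sqdiff[absdiff > 0]).sum())

    return {
        "Joint-max": float(p.max()),
        "Joint-avg": mu,
        "Joint-var": joint_var,
        "Joint-entropy": hxy,
        "Difference-avg": diff_avg,
        "Difference-var": diff_var,
        "Difference-entropy": _entropy2(p_diff),
        "Sum-avg": sum_avg,
        "Sum-var": sum_var,
        "Sum-entropy": _entropy2(p_sum),
        "Angular-second-moment": float((p ** 2).sum()),
        "Contrast": float((sqdiff * p).sum()),
        "Dissimilarity": float((absdiff * p).sum()),
        "Inv-diff": float((p / (1.0 + absdiff)).sum()),
        "Inv-diff-norm": float((p / (1.0 + absdiff / Ng)).sum()),
        "Inv-diff-mom": float((p / (1.0 + sqdiff)).sum()),
        "Inv-diff-mom-norm": float((p / (1.0 + sqdiff / Ng ** 2)).sum()),
        "Inv-var": inv_var,
        "Correlation": float(corr),
        "Autocorrelation": float((I * J * p).sum()),
        "Cluster-tendency": float(((off ** 2) * p).sum()),
        "Cluster-shade": float(((off ** 3) * p).sum()),
        "Cluster-prominence": float(((off ** 4) * p).sum()),
        "First-measure-of-information-correlation": ic1,
        "Second-measure-of-information-correlation": ic2,
    }


def glcm3d_features(q: QuantizedROI) -> dict[str, float]:
    """25 co-occurrence features, averaged over the 13 directions."""
    L = _bbox_levels(q)
    per_dir = []
    for d in DIRECTIONS_13:
        P = _glcm_matrix(L, q.Ng, d)
        if P.sum() > 0:
            per_dir.append(_glcm_features_one(P))
    if not per_dir:
        return {k: float("nan") for k in _glcm_features_one(np.array([[2.0]]))}
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ---------------------------------------------------------------- GLRLM

def _runs_in_direction(L: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """(run levels, run lengths) of maximal same-level streaks along d."""
    shape = L.shape
    # a run starts where the predecessor (v - d) is outside the box/ROI or differs
    prev = np.zeros(shape, dtype=L.dtype)
    src, dst = _pair_slices(shape, d)
    prev[dst] = L[src]
    starts = (L > 0) & (prev != L)
    pos = np.argwhere(starts)
    if len(pos) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    levels = L[tuple(pos.T)]
    lengths = np.ones(len(pos), dtype=np.int64)
    step = np.asarray(d)
    alive = np.ones(len(pos), dtype=bool)
    cur = pos.copy()
    while alive.any():
        cur[alive] += step
        inb = alive.copy()
        inb[alive] = np.all((cur[alive] >= 0) & (cur[alive] < shape), axis=1)
        cont = inb.copy()
        if inb.any():
            cont[inb] = L[tuple(cur[inb].T)] == levels[inb]
        lengths[cont] += 1
        alive = cont
    return levels, lengths


def _rl_features_one(levels: np.ndarray, lengths: np.ndarray, Nv: int,
                     prefix_small: str, prefix_large: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``levels``/``lengths`` enumerate runs (or zones) with their gray level i
    and length (or size) j; each entry counts one run.
    """
    Ns = float(len(levels))
    i = levels.astype(np.float64)
    j = lengths.astype(np.float64)
    ri = np.bincount(levels)  # runs per gray level
    rj = np.bincount(lengths)  # runs per length
    mu_i = float(i.sum() / Ns)
    mu_j = float(j.sum() / Ns)
    return {
        f"S{prefix_small}": float((1.0 / j ** 2).sum() / Ns),
        f"L{prefix_large}": float((j ** 2).sum() / Ns),
        "LG": float((1.0 / i ** 2).sum() / Ns),
        "HG": float((i ** 2).sum() / Ns),
        "SLG": float((1.0 / (i ** 2 * j ** 2)).sum() / Ns),
        "SHG": float((i ** 2 / j ** 2).sum() / Ns),
        "LLG": float((j ** 2 / i ** 2).sum() / Ns),
        "LHG": float((i ** 2 * j ** 2).sum() / Ns),
        "GLN": float((ri.astype(np.float64) ** 2).sum() / Ns),
        "GLNN": float((ri.astype(np.float64) ** 2).sum() / Ns ** 2),
        "RLN": float((rj.astype(np.float64) ** 2).sum() / Ns),
        "RLNN": float((rj.astype(np.float64) ** 2).sum() / Ns ** 2),
        "PCT": Ns / float(Nv),
        "GLV": float(((i - mu_i) ** 2).sum() / Ns),
        "RLV": float(((j - mu_j) ** 2).sum() / Ns),
        "ENT": _entropy2(np.bincount((levels - 1) * (int(lengths.max())) + (lengths - 1)).astype(np.float64) / Ns),
    }


_GLRLM_KEYMAP = {
    "SSmall": "SRE-(Short-runs-emphasis)", "LLarge": "LRE-(Long-runs-emphasis)",
    "LG": "LGRE-(Low-gray-level-run-emphasis)", "HG": "HGRE-(High-gray-level-run-emphasis)",
    "SLG": "SRLGE-(Short-run-low-gray-level-emphasis)",
    "SHG": "SRHGE-(Short-run-high-gray-level-emphasis)",
    "LLG": "LRLGE-(Long-run-low-gray-level-emphasis)",
    "LHG": "LRHGE-(Long-run-high-gray-level-emphasis)",
    "GLN": "GLN-(Gray-level-non-uniformity)", "GLNN": "GLNN-(Gray-level-non-uniformity-normalized)",
    "RLN": "RLN-(Run-length-non-uniformity)", "RLNN": "RLNN-(Run-length-non-uniformity-normalized)",
    "PCT": "RP-(Run-percentage)", "GLV": "GLV-(Gray-level-variance)",
    "RLV": "RLV-(Run-length-variance)", "ENT": "RE-(Run-entropy)",
}

_GLSZM_KEYMAP = {
    "SSmall": "Small-zone-emphasis", "LLarge": "Large-zone-emphasis",
    "LG": "Low-gray-level-zone-emphasis", "HG": "High-gray-level-zone-emphasis",
    "SLG": "Small-zone-low-gray-level-emphasis", "SHG": "Small-zone-high-gray-level-emphasis",
    "LLG": "Large-zone-low-gray-level-emphasis", "LHG": "Large-zone-high-gray-level-emphasis",
    "GLN": "Gray-level-non-uniformity", "GLNN": "Gray-level-non-uniformity-normalized",
    "RLN": "Zone-size-non-uniformity", "RLNN": "Zone-size-non-uniformity-normalized",
    "PCT": "Zone-percentage", "GLV": "Gray-level-variance",
    "RLV": "Zone-size-variance", "ENT": "Zone-size-entropy",
}


def glrlm3d_features(q: QuantizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    L = _bbox_levels(q)
    Nv = q.n_voxels
    per_dir = []
    for d in DIRECTIONS_13:
        levels, lengths = _runs_in_direction(L, d)
        if len(levels):
            raw = _rl_features_one(levels, lengths, Nv, "Small", "Large")
            per_dir.append({_GLRLM_KEYMAP[k]: v for k, v in raw.items()})
    if not per_dir:
        return {v: float("nan") for v in _GLRLM_KEYMAP.values()}
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    """16 size-zone features from a single 3D matrix (26-connected zones)."""
    L = _bbox_levels(q)
    Nv = q.n_voxels
    structure = ndimage.generate_binary_structure(3, 3)
    levels, sizes = [], []
    for g in np.unique(L[L > 0]):
        lab, n = ndimage.label(L == g, structure=structure)
        if n:
            zs = np.bincount(lab.ravel())[1:]
            levels.extend([int(g)] * n)
            sizes.extend(zs.tolist())
    if not levels:
        return {v: float("nan") for v in _GLSZM_KEYMAP.values()}
    raw = _rl_features_one(np.asarray(levels), np.asarray(sizes), Nv, "Small", "Large")
    return {_GLSZM_KEYMAP[k]: v for k, v in raw.items()}


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """The five neighborhood gray tone difference features.

    Neighborhood = 26 surrounding voxels restricted to the ROI; voxels with
    no in-ROI neighbor are excluded. Coarseness uses the IBSI epsilon guard
    (1e-12), so a constant ROI yields coarseness 1e12 and zero for the other
    contrast-type features.
    """
    L = _bbox_levels(q).astype(np.float64)
    inroi = L > 0
    nb_sum = np.zeros_like(L)
    nb_cnt = np.zeros_like(L)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                src, dst = _pair_slices(L.shape, (dz, dy, dx))
                nb_sum[dst] += np.where(inroi[src], L[src], 0.0)
                nb_cnt[dst] += inroi[src]
    valid = inroi & (nb_cnt > 0)
    lev = L[valid].astype(int)
    abar = nb_sum[valid] / nb_cnt[valid]
    diffs = np.abs(L[valid] - abar)

    Ng = q.Ng
    n_i = np.bincount(lev, minlength=Ng + 1)[1:].astype(np.float64)
    s_i = np.bincount(lev, weights=diffs, minlength=Ng + 1)[1:]
    Nvc = n_i.sum()
    if Nvc == 0:
        return {k: float("nan")
                for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p_i = n_i / Nvc
    present = np.flatnonzero(n_i > 0)
    ivals = (present + 1).astype(np.float64)
    pi, si = p_i[present], s_i[present]
    Np = len(present)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / max(coarse_den, _EPS)

    if Np > 1:
        dij2 = (ivals[:, None] - ivals[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * dij2).sum()
                         / (Np * (Np - 1)) * (s_i.sum() / Nvc))
        ipd = np.abs(ivals[:, None] * pi[:, None] - ivals[None, :] * pi[None, :])
        busy_den = float(ipd.sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        psum = pi[:, None] + pi[None, :]
        complexity = float((np.abs(ivals[:, None] - ivals[None, :])
                            * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                            / psum).sum() / Nvc)
        strength = float((psum * dij2).sum()) / max(float(s_i.sum()), _EPS) \
            if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
            "Complexity": complexity, "Strength": strength}
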