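"""Computation of the 107-feature radiomic vector.

Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) are computed in 3-D over
the 13 unique voxel offsets (26-connectivity), with per-offset features
averaged where the matrix is directional.  Shape features come from the mask
geometry alone; first-order features from the normalised intensities, with
entropy/uniformity on the discretized grey levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .manifest import FEATURE_NAMES

__all__ = ["RadiomicVector", "extract_features"]

_EPS = np.finfo(float).eps

# the 13 unique 3-D direction vectors (half of the 26-neighbourhood)
_OFFSETS = [(0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
            (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0),
            (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1)]


@dataclass
class RadiomicVector:
    """Ordered, named 107-feature vector extracted from one map."""

    values: np.ndarray
    source_map: str
    names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (107,):
            raise ValueError(f"a radiomic vector has exactly 107 entries, got {self.values.shape}")

    def as_dict(self) -> dict:
        return {f"{self.source_map}_{n}": v for n, v in zip(self.names, self.values)}


# ---------------------------------------------------------------------------
# shape

def _bbox(mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl


def _max_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    try:
        from scipy.spatial import ConvexHull
        if len(coords) > 10 and np.linalg.matrix_rank(coords - coords.mean(0)) == coords.shape[1]:
            coords = coords[ConvexHull(coords).vertices]
    except Exception:
        pass
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _shape_features(mask: np.ndarray, spacing) -> dict:
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    voxel_vol = float(np.prod(spacing))
    voxvol = n * voxel_vol

    padded = np.pad(mask[_bbox(mask)], 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    meshvol = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                                  np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.maximum(eig, 0.0)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    # boundary voxels suffice for the diameters
    eroded = ndimage.binary_erosion(mask)
    surf = np.argwhere(mask & ~eroded) * spacing
    d3 = _max_pairwise(surf)

    def plane_diameter(fixed_axis: int) -> float:
        keep = [a for a in range(3) if a != fixed_axis]
        best = 0.0
        vals = np.unique(surf[:, fixed_axis])
        for v in vals:
            pts = surf[surf[:, fixed_axis] == v][:, keep]
            best = max(best, _max_pairwise(pts))
        return best

    sphericity = (36.0 * np.pi * meshvol**2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    return {
        "shape_MeshVolume": meshvol,
        "shape_VoxelVolume": voxvol,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / meshvol if meshvol > 0 else 0.0,
        "shape_Sphericity": sphericity,
        "shape_Maximum3DDiameter": d3,
        "shape_Maximum2DDiameterSlice": plane_diameter(2),
        "shape_Maximum2DDiameterColumn": plane_diameter(1),
        "shape_Maximum2DDiameterRow": plane_diameter(0),
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_LeastAxisLength": least,
        "shape_Elongation": np.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 0.0,
        "shape_Flatness": np.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# first order

def _firstorder_features(values: np.ndarray, disc: np.ndarray, voxel_vol: float) -> dict:
    v = values
    n = v.size
    mean = v.mean()
    var = v.var()
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    m2 = var
    m3 = np.mean((v - mean) ** 3)
    m4 = np.mean((v - mean) ** 4)
    counts = np.bincount(disc)[1:]
    p = counts[counts > 0] / n
    energy = float(np.sum(v**2))
    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": energy * voxel_vol,
        "firstorder_Entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_Minimum": float(v.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(v.max()),
        "firstorder_Mean": float(mean),
        "firstorder_Median": float(p50),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(v.max() - v.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(v - mean))),
        "firstorder_RobustMeanAbsoluteDeviation":
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "firstorder_Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "firstorder_Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "firstorder_Variance": float(var),
        "firstorder_Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM

def _offset_pairs(disc, mask, offset):
    """Grey-level pairs (a, b) across one offset, both endpoints in-mask."""
    sl1, sl2 = [], []
    for d in offset:
        if d >= 0:
            sl1.append(slice(None, disc.shape[len(sl1)] - d if d else None))
            sl2.append(slice(d, None))
        else:
            sl1.append(slice(-d, None))
            sl2.append(slice(None, d))
    sl1, sl2 = tuple(sl1), tuple(sl2)
    m = mask[sl1] & mask[sl2]
    return disc[sl1][m], disc[sl2][m]


def _glcm_single(P: np.ndarray, ng: int) -> dict:
    p = P / P.sum()
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    pxy = np.outer(px, px)
    nz = (pxy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxy[nz])))
    hxy2 = float(-np.sum(pxy[nz] * np.log2(pxy[nz])))

    # MCC via the Q matrix restricted to occupied grey levels
    occ = px > 0
    if occ.sum() > 1:
        psub = p[np.ix_(occ, occ)]
        pxs = px[occ]
        Q = (psub / pxs[:, None]) @ (psub / pxs[:, None]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    autoc = float((p * ii * jj).sum())
    return {
        "glcm_Autocorrelation": autoc,
        "glcm_JointAverage": mu,
        "glcm_ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "glcm_ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "glcm_ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "glcm_Contrast": float((p * (ii - jj) ** 2).sum()),
        "glcm_Correlation": (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))),
        "glcm_DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_Id": float((p_diff / (1.0 + k_diff)).sum()),
        "glcm_Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "glcm_Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "glcm_Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "glcm_Imc1": (hxy - hxy1) / max(hx, _EPS) if hx > 0 else 0.0,
        "glcm_Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "glcm_InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0,
        "glcm_JointEnergy": float((p**2).sum()),
        "glcm_JointEntropy": hxy,
        "glcm_MCC": mcc,
        "glcm_MaximumProbability": float(p.max()),
        "glcm_SumAverage": float((k_sum * p_sum).sum()),
        "glcm_SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "glcm_SumSquares": sigma2,
    }


def _glcm_features(disc, mask, ng: int) -> dict:
    acc: dict[str, list] = {}
    for off in _OFFSETS:
        a, b = _offset_pairs(disc, mask, off)
        if a.size == 0:
            continue
        P = np.zeros((ng, ng))
        np.add.at(P, (a - 1, b - 1), 1.0)
        P = P + P.T  # symmetric GLCM
        feats = _glcm_single(P, ng)
        for k, v in feats.items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM

def _glrlm_matrix(disc, mask, offset, ng: int, max_len: int) -> np.ndarray:
    coords = np.argwhere(mask)
    levels = disc[mask]
    d = np.asarray(offset)
    step = int(d @ d)
    t = coords @ d
    key = coords * step - np.outer(t, d)
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_s, lev_s, key_s = t[order], levels[order], key[order]
    new_line = np.any(np.diff(key_s, axis=0) != 0, axis=1) | (np.diff(t_s) != step)
    brk = new_line | (np.diff(lev_s) != 0)
    run_start = np.concatenate([[0], np.flatnonzero(brk) + 1])
    run_end = np.concatenate([np.flatnonzero(brk) + 1, [len(lev_s)]])
    run_len = run_end - run_start
    run_lev = lev_s[run_start]
    R = np.zeros((ng, max_len))
    np.add.at(R, (run_lev - 1, np.minimum(run_len, max_len) - 1), 1.0)
    return R


def _rl_style_features(M: np.ndarray, n_vox: int, prefix: str, size_word: str) -> dict:
    """Shared feature body of the run-length and size-zone families."""
    Ns = M.sum()
    p = M / Ns
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    s = np.arange(1, M.shape[1] + 1, dtype=float)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = (pg * i).sum()
    mu_s = (ps * s).sum()
    pe = p[p > 0]
    short = {"run": ("ShortRun", "LongRun", "Run"), "zone": ("SmallArea", "LargeArea", "Zone")}[size_word]
    sm, lg, word = short
    out = {
        f"{prefix}_GrayLevelNonUniformity": float((M.sum(axis=1) ** 2).sum() / Ns),
        f"{prefix}_GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        f"{prefix}_GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        f"{prefix}_{sm}Emphasis": float((p / ss**2).sum()),
        f"{prefix}_{lg}Emphasis": float((p * ss**2).sum()),
        f"{prefix}_LowGrayLevel{word}Emphasis": float((p / ii**2).sum()),
        f"{prefix}_HighGrayLevel{word}Emphasis": float((p * ii**2).sum()),
        f"{prefix}_{sm}LowGrayLevelEmphasis": float((p / (ii**2 * ss**2)).sum()),
        f"{prefix}_{sm}HighGrayLevelEmphasis": float((p * ii**2 / ss**2).sum()),
        f"{prefix}_{lg}LowGrayLevelEmphasis": float((p * ss**2 / ii**2).sum()),
        f"{prefix}_{lg}HighGrayLevelEmphasis": float((p * ii**2 * ss**2).sum()),
        f"{prefix}_{word}Variance": float((p * (ss - mu_s) ** 2).sum()),
        f"{prefix}_{word}Entropy": float(-np.sum(pe * np.log2(pe))),
        f"{prefix}_{word}Percentage": float(Ns / n_vox),
    }
    if size_word == "run":
        out["glrlm_RunLengthNonUniformity"] = float((M.sum(axis=0) ** 2).sum() / Ns)
        out["glrlm_RunLengthNonUniformityNormalized"] = float((ps**2).sum())
    else:
        out["glszm_SizeZoneNonUniformity"] = float((M.sum(axis=0) ** 2).sum() / Ns)
        out["glszm_SizeZoneNonUniformityNormalized"] = float((ps**2).sum())
    return out


def _glrlm_features(disc, mask, ng: int) -> dict:
    n_vox = int(mask.sum())
    max_len = max(mask.shape)
    acc: dict[str, list] = {}
    for off in _OFFSETS:
        R = _glrlm_matrix(disc, mask, off, ng, max_len)
        if R.sum() == 0:
            continue
        for k, v in _rl_style_features(R, n_vox, "glrlm", "run").items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM

def _glszm_features(disc, mask, ng: int) -> dict:
    structure = np.ones((3, 3, 3), dtype=int)
    n_vox = int(mask.sum())
    sizes_by_level: list[tuple[int, int]] = []
    for g in np.unique(disc[mask]):
        lab, nlab = ndimage.label((disc == g) & mask, structure=structure)
        if nlab == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        sizes_by_level.extend((int(g), int(c)) for c in counts)
    max_size = max(c for _, c in sizes_by_level)
    Z = np.zeros((ng, max_size))
    for g, c in sizes_by_level:
        Z[g - 1, c - 1] += 1.0
    return _rl_style_features(Z, n_vox, "glszm", "zone")


# ---------------------------------------------------------------------------
# GLDM and NGTDM share the 26-neighbourhood scan

def _neighbour_stats(disc, mask):
    """Per-voxel count of equal-level neighbours, neighbour sum and count."""
    eq = np.zeros(disc.shape, dtype=np.int32)
    nsum = np.zeros(disc.shape, dtype=np.float64)
    ncnt = np.zeros(disc.shape, dtype=np.int32)
    for off in _OFFSETS:
        for d in (off, tuple(-o for o in off)):
            sl1, sl2 = [], []
            for axis, dd in enumerate(d):
                if dd >= 0:
                    sl1.append(slice(None, disc.shape[axis] - dd if dd else None))
                    sl2.append(slice(dd, None))
                else:
                    sl1.append(slice(-dd, None))
                    sl2.append(slice(None, dd))
            sl1, sl2 = tuple(sl1), tuple(sl2)
            both = mask[sl1] & mask[sl2]
            eq[sl1] += both & (disc[sl1] == disc[sl2])
            nsum[sl1] += np.where(both, disc[sl2], 0)
            ncnt[sl1] += both
    return eq, nsum, ncnt


def _gldm_features(disc, mask, ng: int, eq: np.ndarray) -> dict:
    dep = eq[mask] + 1  # dependence size includes the centre voxel
    lev = disc[mask]
    nd = dep.max()
    D = np.zeros((ng, nd))
    np.add.at(D, (lev - 1, dep - 1), 1.0)
    Ns = D.sum()
    p = D / Ns
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg, pd = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = (pg * i).sum(), (pd * j).sum()
    pe = p[p > 0]
    return {
        "gldm_DependenceEntropy": float(-np.sum(pe * np.log2(pe))),
        "gldm_DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / Ns),
        "gldm_DependenceNonUniformityNormalized": float((pd**2).sum()),
        "gldm_DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "gldm_GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / Ns),
        "gldm_GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "gldm_HighGrayLevelEmphasis": float((p * ii**2).sum()),
        "gldm_LargeDependenceEmphasis": float((p * jj**2).sum()),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float((p * ii**2 * jj**2).sum()),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float((p * jj**2 / ii**2).sum()),
        "gldm_LowGrayLevelEmphasis": float((p / ii**2).sum()),
        "gldm_SmallDependenceEmphasis": float((p / jj**2).sum()),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float((p * ii**2 / jj**2).sum()),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float((p / (ii**2 * jj**2)).sum()),
    }


def _ngtdm_features(disc, mask, ng: int, nsum, ncnt) -> dict:
    lev = disc[mask].astype(float)
    has_nb = ncnt[mask] > 0
    abar = np.zeros(lev.shape)
    abar[has_nb] = nsum[mask][has_nb] / ncnt[mask][has_nb]
    diff = np.where(has_nb, np.abs(lev - abar), 0.0)
    n_vox = lev.size
    s = np.zeros(ng)
    np.add.at(s, disc[mask] - 1, diff)
    cnt = np.bincount(disc[mask] - 1, minlength=ng).astype(float)
    p = cnt / n_vox
    occ = p > 0
    i = np.arange(1, ng + 1, dtype=float)
    ngp = int(occ.sum())

    ps_sum = float((p * s).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        ii, jj = np.meshgrid(i[occ], i[occ], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) \
            * float(s.sum()) / n_vox
        denom = float(np.abs(i[occ] * p[occ] - (i[occ] * p[occ])[:, None]).sum())
        busyness = ps_sum / denom if denom > 0 else 0.0
        si, sj = np.meshgrid(s[occ], s[occ], indexing="ij")
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / n_vox
        s_tot = float(s.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_Busyness": busyness,
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------

def extract_features(disc: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                     values: np.ndarray | None = None,
                     source_map: str = "map") -> RadiomicVector:
    """Extract the full 107-feature vector from one preprocessed map.

    Parameters
    ----------
    disc
        Discretized grey levels (1-based inside the mask).
    mask
        Binary tumor mask; must contain at least 8 voxels.
    spacing
        Voxel spacing in mm after resampling.
    values
        Normalised floating-point intensities for the first-order features;
        defaults to the grey levels themselves.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 8:
        raise ValueError("mask smaller than 8 voxels: texture undefined")
    disc = np.asarray(disc)
    if values is None:
        values = disc.astype(float)

    sl = _bbox(mask)
    disc_c, mask_c = disc[sl], mask[sl]
    ng = int(disc_c[mask_c].max())

    feats = {}
    feats.update(_shape_features(mask, spacing))
    feats.update(_firstorder_features(values[mask], disc[mask], float(np.prod(spacing))))
    feats.update(_glcm_features(disc_c, mask_c, ng))
    feats.update(_glrlm_features(disc_c, mask_c, ng))
    feats.update(_glszm_features(disc_c, mask_c, ng))
    eq, nsum, ncnt = _neighbour_stats(disc_c, mask_c)
    feats.update(_gldm_features(disc_c, mask_c, ng, eq))
    feats.update(_ngtdm_features(disc_c, mask_c, ng, nsum, ncnt))

    vec = np.array([feats[name] for name in FEATURE_NAMES], dtype=float)
    return RadiomicVector(vec, source_map)
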