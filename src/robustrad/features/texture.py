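"""Gray-level texture matrices and their feature families.

All matrices are built in 3-D on the discretized region.  Pairwise families
(GLCM, GLRLM) use the 13 unique direction pairs at distance 1 and average
the per-direction matrices; GLSZM, NGTDM and GLDM are direction-free with a
26-connected neighbourhood.  Feature formulas follow the standard radiomics
reference definitions; counts are GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5,
GLDM 14.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from scipy import ndimage

from ..core import RegionError, VolumeGrid
from .discretize import DiscretizationSpec, discretize

#: the 13 unique direction pairs at Chebyshev distance 1 (first non-zero
#: component positive; the opposite directions are covered by symmetry)
OFFSETS_13 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)
)
OFFSETS_26 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

GLCM_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "id", "idm", "idmn", "idn", "imc1", "imc2",
    "inverse_variance", "joint_average", "joint_energy", "joint_entropy",
    "maximum_probability", "mcc", "sum_average", "sum_entropy", "sum_squares",
)
GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")
GLDM_NAMES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

FAMILY_NAMES = {
    "GLCM": GLCM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSZM": GLSZM_NAMES,
    "NGTDM": NGTDM_NAMES,
    "GLDM": GLDM_NAMES,
}

_COARSENESS_CAP = 1e6  # degenerate cap when sum(p_i s_i) == 0


def _crop_to_bbox(levels: np.ndarray) -> np.ndarray:
    idx = np.argwhere(levels > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return levels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _shifted(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[x] = arr[x + d], with ``fill`` outside the array."""
    out = np.full_like(arr, fill)
    dst, src = [], []
    for n, di in zip(arr.shape, d):
        if di >= 0:
            dst.append(slice(0, n - di))
            src.append(slice(di, n))
        else:
            dst.append(slice(-di, n))
            src.append(slice(0, n + di))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# --------------------------------------------------------------------------
# matrices
# --------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Average of per-direction symmetric normalized co-occurrence matrices."""
    g = n_levels
    acc = np.zeros((g, g))
    n_dir = 0
    for d in OFFSETS_13:
        b = _shifted(levels, d)
        valid = (levels > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (levels[valid] - 1) * g + (b[valid] - 1)
        m = np.bincount(idx, minlength=g * g).reshape(g, g).astype(float)
        m = m + m.T
        acc += m / m.sum()
        n_dir += 1
    if n_dir == 0:
        raise RegionError("no voxel pairs: region too small for GLCM")
    return acc / n_dir


def glrlm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Average of per-direction run-length count matrices R[gray, length]."""
    g = n_levels
    max_len = max(levels.shape)
    acc = np.zeros((g, max_len))
    for d in OFFSETS_13:
        axis = next(i for i, di in enumerate(d) if di != 0)
        nxt = _shifted(levels, d)
        cont = (levels > 0) & (nxt == levels)
        # T[x] = number of continuation steps from x along d
        t = np.zeros(levels.shape, dtype=np.int32)
        d_rest = tuple(0 if i == axis else di for i, di in enumerate(d))
        planes = [slice(None)] * 3
        for i in range(levels.shape[axis] - 1, -1, -1):
            planes[axis] = i
            if i + 1 < levels.shape[axis]:
                nxt_plane = [slice(None)] * 3
                nxt_plane[axis] = i + 1
                rest2 = tuple(di for j, di in enumerate(d_rest) if j != axis)
                shifted_next = _shifted(t[tuple(nxt_plane)], rest2)
            else:
                shifted_next = 0
            t[tuple(planes)] = np.where(cont[tuple(planes)], shifted_next + 1, 0)
        prev = _shifted(levels, tuple(-di for di in d))
        start = (levels > 0) & (prev != levels)
        grays = levels[start] - 1
        lengths = t[start]  # length - 1
        idx = grays * max_len + lengths
        acc += np.bincount(idx, minlength=g * max_len).reshape(g, max_len)
    return acc / len(OFFSETS_13)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts S[gray, zone_size] with 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for gl in np.unique(levels[levels > 0]):
        lab, nz = ndimage.label(levels == gl, structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((int(gl), int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((n_levels, max_size))
    for gl, s in zones:
        mat[gl - 1, s - 1] += 1
    return mat


def gldm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts D[gray, k]: k = 1 + #26-neighbours with equal level."""
    dep = np.zeros(levels.shape, dtype=np.int32)
    inside = levels > 0
    for d in OFFSETS_26:
        dep += inside & (_shifted(levels, d) == levels)
    max_dep = int(dep[inside].max()) + 1
    idx = (levels[inside] - 1) * max_dep + dep[inside]
    return np.bincount(idx, minlength=n_levels * max_dep).reshape(
        n_levels, max_dep
    ).astype(float)


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) per gray level i for the neighbourhood-difference family."""
    inside = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int32)
    for d in OFFSETS_26:
        nb = _shifted(levels, d)
        has = nb > 0
        nb_sum += np.where(has, nb, 0)
        nb_cnt += has
    valid = inside & (nb_cnt > 0)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(
        levels[valid] - nb_sum[valid] / nb_cnt[valid]
    )
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for gl in range(1, n_levels + 1):
        sel = valid & (levels == gl)
        n_i[gl - 1] = sel.sum()
        s_i[gl - 1] = diff[sel].sum()
    return n_i, s_i


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def _glcm_features(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    i = np.arange(1, g + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    ng = int((px + py > 0).sum())

    # diagonal distributions p_{x+y}, p_{x-y}
    k_sum = np.arange(2, 2 * g + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, g)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    eps = np.finfo(float).eps
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())

    if sig_x > 0 and sig_y > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sig_x * sig_y))
    else:
        correlation = float("nan")  # single gray level: undefined, flagged

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inverse_variance = float((p[off] / (ii - jj)[off] ** 2).sum())

    # maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q
    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.einsum(
                "ik,jk->ij", p / np.where(px[:, None] > 0, px[:, None], 1.0),
                p / np.where(py[None, :] > 0, py[None, :], 1.0),
            )
        ev = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1].real))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + (ii - jj) ** 2 / max(ng, 1) ** 2)).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / max(ng, 1))).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_variance": inverse_variance,
        "joint_average": mu_x,
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "maximum_probability": float(p.max()),
        "mcc": mcc,
        "sum_average": sa,
        "sum_entropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "sum_squares": float(((ii - mu_x) ** 2 * p).sum()),
    }


def _run_zone_features(mat: np.ndarray, n_voxels: int, names: tuple[str, ...]) -> dict[str, float]:
    """Shared formulas of the GLRLM and GLSZM families (mat[gray, size])."""
    nr = mat.sum()
    if nr == 0:
        return {n: float("nan") for n in names}
    g = mat.shape[0]
    i = np.arange(1, g + 1)
    l = np.arange(1, mat.shape[1] + 1)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    p = mat / nr
    pg = mat.sum(axis=1)
    pl = mat.sum(axis=0)
    mu_g = float((i * pg / nr).sum())
    mu_l = float((l * pl / nr).sum())
    pe = p[p > 0]
    vals = {
        "sre": float((mat / ll**2).sum() / nr),
        "lre": float((mat * ll**2).sum() / nr),
        "gln": float((pg**2).sum() / nr),
        "glnn": float((pg**2).sum() / nr**2),
        "rln": float((pl**2).sum() / nr),
        "rlnn": float((pl**2).sum() / nr**2),
        "rp": float(nr / n_voxels),
        "glv": float(((ii - mu_g) ** 2 * p).sum()),
        "rv": float(((ll - mu_l) ** 2 * p).sum()),
        "re": float(-(pe * np.log2(pe)).sum()),
        "lglre": float((mat / ii**2).sum() / nr),
        "hglre": float((mat * ii**2).sum() / nr),
        "srlgle": float((mat / (ii**2 * ll**2)).sum() / nr),
        "srhgle": float((mat * ii**2 / ll**2).sum() / nr),
        "lrlgle": float((mat * ll**2 / ii**2).sum() / nr),
        "lrhgle": float((mat * ii**2 * ll**2).sum() / nr),
    }
    return dict(zip(names, vals.values()))


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nv = n_i.sum()
    if nv == 0:
        return {n: float("nan") for n in NGTDM_NAMES}
    p_i = n_i / nv
    present = p_i > 0
    i = np.arange(1, len(n_i) + 1).astype(float)
    ngp = int(present.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP

    ip, pp, sp = i[present], p_i[present], s_i[present]
    if ngp > 1:
        di2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(
            (pp[:, None] * pp[None, :] * di2).sum()
            / (ngp * (ngp - 1))
            * s_i.sum()
            / nv
        )
        denom = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        pair_sum = pp[:, None] + pp[None, :]
        complexity = float(
            (
                np.abs(ip[:, None] - ip[None, :])
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / pair_sum
            ).sum()
            / nv
        )
        s_tot = float(s_i.sum())
        strength = float((pair_sum * di2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def _gldm_features(mat: np.ndarray) -> dict[str, float]:
    nz = mat.sum()
    g = mat.shape[0]
    i = np.arange(1, g + 1)
    k = np.arange(1, mat.shape[1] + 1)
    ii, kk = np.meshgrid(i, k, indexing="ij")
    p = mat / nz
    pg = mat.sum(axis=1)
    pk = mat.sum(axis=0)
    mu_g = float((p * ii).sum())
    mu_k = float((p * kk).sum())
    pe = p[p > 0]
    return {
        "small_dependence_emphasis": float((mat / kk**2).sum() / nz),
        "large_dependence_emphasis": float((mat * kk**2).sum() / nz),
        "gray_level_nonuniformity": float((pg**2).sum() / nz),
        "dependence_nonuniformity": float((pk**2).sum() / nz),
        "dependence_nonuniformity_normalized": float((pk**2).sum() / nz**2),
        "gray_level_variance": float(((ii - mu_g) ** 2 * p).sum()),
        "dependence_variance": float(((kk - mu_k) ** 2 * p).sum()),
        "dependence_entropy": float(-(pe * np.log2(pe)).sum()),
        "low_gray_level_emphasis": float((mat / ii**2).sum() / nz),
        "high_gray_level_emphasis": float((mat * ii**2).sum() / nz),
        "small_dependence_low_gray_level_emphasis": float(
            (mat / (ii**2 * kk**2)).sum() / nz
        ),
        "small_dependence_high_gray_level_emphasis": float(
            (mat * ii**2 / kk**2).sum() / nz
        ),
        "large_dependence_low_gray_level_emphasis": float(
            (mat * kk**2 / ii**2).sum() / nz
        ),
        "large_dependence_high_gray_level_emphasis": float(
            (mat * ii**2 * kk**2).sum() / nz
        ),
    }


def texture_features_from_levels(
    levels: np.ndarray, n_levels: int, family: str
) -> dict[str, float]:
    """Compute one family from an already-discretized level grid."""
    levels = _crop_to_bbox(levels)
    n_vox = int((levels > 0).sum())
    if family == "GLCM":
        if n_vox < 2:
            warnings.warn("single-voxel region: GLCM degenerate", stacklevel=2)
            return {n: float("nan") for n in GLCM_NAMES}
        return _glcm_features(glcm_matrix(levels, n_levels))
    if family == "GLRLM":
        return _run_zone_features(glrlm_matrix(levels, n_levels), n_vox, GLRLM_NAMES)
    if family == "GLSZM":
        return _run_zone_features(glszm_matrix(levels, n_levels), n_vox, GLSZM_NAMES)
    if family == "NGTDM":
        return _ngtdm_features(*ngtdm_table(levels, n_levels))
    if family == "GLDM":
        return _gldm_features(gldm_matrix(levels, n_levels))
    raise ValueError(f"unknown texture family {family!r}")


def texture_features(
    image: VolumeGrid,
    mask: np.ndarray,
    spec: DiscretizationSpec,
    family: str,
) -> dict[str, float]:
    """Discretize the masked image and compute one texture family."""
    levels, g = discretize(image, mask, spec)
    return texture_features_from_levels(levels, g, family)
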