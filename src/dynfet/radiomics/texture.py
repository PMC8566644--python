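"""Grey-level texture matrices and their features.

Five matrix families, all in 3D at distance 1:

* GLCM  — symmetric co-occurrences over the 13 unique directions, features
  computed per direction and averaged;
* GLRLM — run lengths over the same 13 directions, averaged likewise;
* GLSZM — zone sizes with 26-connected zones;
* GLDM  — dependence counts over the 26-neighbourhood (alpha = 0); the
  dependence size includes the centre voxel, so it is at least 1;
* NGTDM — neighbourhood grey-tone differences over the 26-neighbourhood.

Matrices are indexed by the grey-level *values* actually present in the
ROI (fixed-bin-width discretisation can leave gaps), so intensity-weighted
features use the true bin numbers.  Degenerate conventions: a single grey
level gives GLCM Correlation = 1 and MCC = 1; empty denominators (NGTDM
Busyness/Strength) give 0 and Coarseness returns 1e6.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "texture_matrices",
    "texture_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

#: The 13 unique 3D directions (offsets up to sign) at Chebyshev distance 1.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbour offsets at Chebyshev distance 1.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)
GLRLM_NAMES = (
    "GreyLevelNonUniformity",
    "GreyLevelNonUniformityNormalized",
    "GreyLevelVariance",
    "HighGreyLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGreyLevelEmphasis",
    "LongRunLowGreyLevelEmphasis",
    "LowGreyLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "ShortRunLowGreyLevelEmphasis",
)
GLSZM_NAMES = (
    "GreyLevelNonUniformity",
    "GreyLevelNonUniformityNormalized",
    "GreyLevelVariance",
    "HighGreyLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGreyLevelEmphasis",
    "LargeAreaLowGreyLevelEmphasis",
    "LowGreyLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGreyLevelEmphasis",
    "SmallAreaLowGreyLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GreyLevelNonUniformity",
    "GreyLevelVariance",
    "HighGreyLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGreyLevelEmphasis",
    "LargeDependenceLowGreyLevelEmphasis",
    "LowGreyLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGreyLevelEmphasis",
    "SmallDependenceLowGreyLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_EPS = np.spacing(1.0)


def _shift_slices(shape, d):
    """Slices (src, dst) such that arr[src] aligns with arr shifted by +d at dst."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- matrices


def _glcm_matrices(levels: np.ndarray, mask: np.ndarray, grey: np.ndarray) -> list[np.ndarray]:
    """One symmetric co-occurrence matrix per direction (counts, not normalised)."""
    ng = len(grey)
    index = np.full(int(grey.max()) + 1, -1, dtype=np.int64)
    index[grey] = np.arange(ng)
    lut = np.zeros(levels.shape, dtype=np.int64)
    lut[mask] = index[levels[mask]]
    out = []
    for d in DIRECTIONS_13:
        src, dst = _shift_slices(levels.shape, d)
        valid = mask[src] & mask[dst]
        a = lut[src][valid]
        b = lut[dst][valid]
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        out.append(counts + counts.T)
    return out


def _glrlm_matrices(levels: np.ndarray, mask: np.ndarray, grey: np.ndarray) -> list[np.ndarray]:
    """One run-length count matrix (grey x length) per direction."""
    ng = len(grey)
    index = np.full(int(grey.max()) + 1, -1, dtype=np.int64)
    index[grey] = np.arange(ng)
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum(n**2 for n in shape)))) + 1
    out = []
    for d in DIRECTIONS_13:
        src, dst = _shift_slices(shape, d)
        # same[x] <=> x and x+d are both masked with equal level
        same = np.zeros(shape, dtype=bool)
        same[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
        # a run starts where the predecessor along d does not continue into x
        prev_same = np.zeros(shape, dtype=bool)
        prev_same[dst] = same[src]
        start = mask & ~prev_same

        pos = np.argwhere(start)
        run_grey = index[levels[start]]
        lengths = np.ones(len(pos), dtype=np.int64)
        alive = np.arange(len(pos))
        cur = pos.copy()
        dvec = np.array(d)
        while len(alive):
            cont = same[tuple(cur.T)]
            alive = alive[cont]
            if not len(alive):
                break
            cur = cur[cont] + dvec
            lengths[alive] += 1
        mat = np.zeros((ng, max_len + 1))
        np.add.at(mat, (run_grey, lengths), 1.0)
        out.append(mat[:, 1:])  # column j-1 holds runs of length j
    return out


def _glszm_matrix(levels: np.ndarray, mask: np.ndarray, grey: np.ndarray) -> np.ndarray:
    """Zone-size count matrix (grey x size), zones 26-connected."""
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int(mask.sum())
    mat = np.zeros((len(grey), max_size + 1))
    for gi, g in enumerate(grey):
        lab, n = ndimage.label(mask & (levels == g), structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            np.add.at(mat, (gi, sizes), 1.0)
    return mat[:, 1:]


def _gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, grey: np.ndarray, alpha: int = 0
) -> np.ndarray:
    """Dependence count matrix (grey x dependence size); size includes the centre."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        ok = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
        dep[src] += ok
    ng = len(grey)
    index = np.full(int(grey.max()) + 1, -1, dtype=np.int64)
    index[grey] = np.arange(ng)
    j = dep[mask] + 1
    i = index[levels[mask]]
    mat = np.zeros((ng, 27 + 1))
    np.add.at(mat, (i, j), 1.0)
    return mat[:, 1:]


def _ngtdm_table(levels: np.ndarray, mask: np.ndarray, grey: np.ndarray):
    """Per-level counts n_i, probabilities p_i and summed differences s_i."""
    nsum = np.zeros(levels.shape, dtype=float)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        ok = mask[src] & mask[dst]
        nsum[src] += np.where(ok, levels[dst], 0)
        ncnt[src] += ok
    valid = mask & (ncnt > 0)
    diffs = np.abs(levels[valid] - nsum[valid] / ncnt[valid])
    lv = levels[valid]
    ng = len(grey)
    index = np.full(int(grey.max()) + 1, -1, dtype=np.int64)
    index[grey] = np.arange(ng)
    idx = index[lv]
    n_i = np.bincount(idx, minlength=ng).astype(float)
    s_i = np.bincount(idx, weights=diffs, minlength=ng)
    return n_i, s_i


def texture_matrices(levels: np.ndarray, mask: np.ndarray) -> dict:
    """All five matrix families for a discretised ROI.

    ``levels`` is an integer grid (values arbitrary outside the mask);
    ``grey`` is the sorted vector of levels present in the ROI.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("texture matrices need a non-empty mask")
    grey = np.unique(levels[mask])
    return {
        "grey": grey,
        "n_voxels": int(mask.sum()),
        "glcm": _glcm_matrices(levels, mask, grey),
        "glrlm": _glrlm_matrices(levels, mask, grey),
        "glszm": _glszm_matrix(levels, mask, grey),
        "gldm": _gldm_matrix(levels, mask, grey),
        "ngtdm": _ngtdm_table(levels, mask, grey),
    }


# ---------------------------------------------------------------- features


def _glcm_features_single(
    P: np.ndarray, grey: np.ndarray, ng_global: int | None = None
) -> dict[str, float]:
    ng = ng_global if ng_global is not None else len(grey)
    # drop grey levels with no co-occurrence along this direction
    present = P.sum(axis=1) + P.sum(axis=0) > 0
    if present.any():
        P = P[np.ix_(present, present)]
        grey = np.asarray(grey)[present]
    total = P.sum()
    P = P / total
    g = grey.astype(float)
    i = g[:, None]
    j = g[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)

    mu_x = float(np.sum(g * px))
    mu_y = float(np.sum(g * py))
    sig_x = float(np.sqrt(np.sum((g - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((g - mu_y) ** 2 * py)))

    diff = np.abs(i - j)
    ks_diff = np.unique(diff)
    p_diff = np.array([P[diff == k].sum() for k in ks_diff])
    summ = i + j
    ks_sum = np.unique(summ)
    p_sum = np.array([P[summ == k].sum() for k in ks_sum])

    da = float(np.sum(ks_diff * p_diff))
    corr = 1.0
    if sig_x > 0 and sig_y > 0:
        corr = float((np.sum(i * j * P) - mu_x * mu_y) / (sig_x * sig_y))

    hxy = float(-np.sum(P * np.log2(P + _EPS)))
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if len(g) > 1:
        A = P / np.where(px[:, None] > 0, px[:, None], 1.0)
        B = P / np.where(py[None, :] > 0, py[None, :], 1.0)
        Q = A @ B.T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    off = diff > 0
    inv_var = float(np.sum(P[off] / (diff[off] ** 2))) if off.any() else 0.0

    return {
        "Autocorrelation": float(np.sum(i * j * P)),
        "ClusterProminence": float(np.sum((i + j - mu_x - mu_y) ** 4 * P)),
        "ClusterShade": float(np.sum((i + j - mu_x - mu_y) ** 3 * P)),
        "ClusterTendency": float(np.sum((i + j - mu_x - mu_y) ** 2 * P)),
        "Contrast": float(np.sum((i - j) ** 2 * P)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum((ks_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(P / (1.0 + diff))),
        "Idm": float(np.sum(P / (1.0 + diff**2))),
        "Idmn": float(np.sum(P / (1.0 + diff**2 / ng**2))),
        "Idn": float(np.sum(P / (1.0 + diff / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(ks_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum((i - mu_x) ** 2 * P)),
    }


def _mean_over_angles(per_angle: list[dict[str, float]]) -> dict[str, float]:
    keys = per_angle[0].keys()
    return {k: float(np.mean([f[k] for f in per_angle])) for k in keys}


def _glrlm_features_single(mat: np.ndarray, grey: np.ndarray, n_vox: int) -> dict[str, float]:
    nr = mat.sum()
    g = grey.astype(float)[:, None]
    lengths = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)  # per grey level
    pl = mat.sum(axis=0)  # per run length
    p = mat / nr
    mu_g = np.sum(g * p)
    mu_l = np.sum(lengths * p)
    return {
        "GreyLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GreyLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "GreyLevelVariance": float(np.sum((g - mu_g) ** 2 * p)),
        "HighGreyLevelRunEmphasis": float(np.sum(mat * g**2) / nr),
        "LongRunEmphasis": float(np.sum(mat * lengths**2) / nr),
        "LongRunHighGreyLevelEmphasis": float(np.sum(mat * g**2 * lengths**2) / nr),
        "LongRunLowGreyLevelEmphasis": float(np.sum(mat * lengths**2 / g**2) / nr),
        "LowGreyLevelRunEmphasis": float(np.sum(mat / g**2) / nr),
        "RunEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0] + _EPS))),
        "RunLengthNonUniformity": float(np.sum(pl**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pl**2) / nr**2),
        "RunPercentage": float(nr / n_vox),
        "RunVariance": float(np.sum((lengths - mu_l) ** 2 * p)),
        "ShortRunEmphasis": float(np.sum(mat / lengths**2) / nr),
        "ShortRunHighGreyLevelEmphasis": float(np.sum(mat * g**2 / lengths**2) / nr),
        "ShortRunLowGreyLevelEmphasis": float(np.sum(mat / (g**2 * lengths**2)) / nr),
    }


def _glszm_features(mat: np.ndarray, grey: np.ndarray, n_vox: int) -> dict[str, float]:
    nz = mat.sum()
    g = grey.astype(float)[:, None]
    sizes = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    p = mat / nz
    mu_g = np.sum(g * p)
    mu_s = np.sum(sizes * p)
    return {
        "GreyLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GreyLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "GreyLevelVariance": float(np.sum((g - mu_g) ** 2 * p)),
        "HighGreyLevelZoneEmphasis": float(np.sum(mat * g**2) / nz),
        "LargeAreaEmphasis": float(np.sum(mat * sizes**2) / nz),
        "LargeAreaHighGreyLevelEmphasis": float(np.sum(mat * g**2 * sizes**2) / nz),
        "LargeAreaLowGreyLevelEmphasis": float(np.sum(mat * sizes**2 / g**2) / nz),
        "LowGreyLevelZoneEmphasis": float(np.sum(mat / g**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(mat / sizes**2) / nz),
        "SmallAreaHighGreyLevelEmphasis": float(np.sum(mat * g**2 / sizes**2) / nz),
        "SmallAreaLowGreyLevelEmphasis": float(np.sum(mat / (g**2 * sizes**2)) / nz),
        "ZoneEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0] + _EPS))),
        "ZonePercentage": float(nz / n_vox),
        "ZoneVariance": float(np.sum((sizes - mu_s) ** 2 * p)),
    }


def _gldm_features(mat: np.ndarray, grey: np.ndarray) -> dict[str, float]:
    nz = mat.sum()
    g = grey.astype(float)[:, None]
    deps = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    p = mat / nz
    mu_g = np.sum(g * p)
    mu_d = np.sum(deps * p)
    return {
        "DependenceEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0] + _EPS))),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "DependenceVariance": float(np.sum((deps - mu_d) ** 2 * p)),
        "GreyLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GreyLevelVariance": float(np.sum((g - mu_g) ** 2 * p)),
        "HighGreyLevelEmphasis": float(np.sum(mat * g**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(mat * deps**2) / nz),
        "LargeDependenceHighGreyLevelEmphasis": float(np.sum(mat * g**2 * deps**2) / nz),
        "LargeDependenceLowGreyLevelEmphasis": float(np.sum(mat * deps**2 / g**2) / nz),
        "LowGreyLevelEmphasis": float(np.sum(mat / g**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(mat / deps**2) / nz),
        "SmallDependenceHighGreyLevelEmphasis": float(np.sum(mat * g**2 / deps**2) / nz),
        "SmallDependenceLowGreyLevelEmphasis": float(np.sum(mat / (g**2 * deps**2)) / nz),
    }


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray, grey: np.ndarray) -> dict[str, float]:
    nvp = n_i.sum()
    p = n_i / nvp
    g = grey.astype(float)
    present = p > 0
    gp, pp, sp = g[present], p[present], s_i[present]
    ngp = int(present.sum())

    coarse_den = float(np.sum(pp * sp))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        dif2 = (gp[:, None] - gp[None, :]) ** 2
        contrast = float(
            np.sum(pp[:, None] * pp[None, :] * dif2) / (ngp * (ngp - 1)) * (sp.sum() / nvp)
        )
        busy_den = float(np.sum(np.abs(gp[:, None] * pp[:, None] - gp[None, :] * pp[None, :])))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(gp[:, None] - gp[None, :])
        complexity = float(
            np.sum(
                absdif
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
            / nvp
        )
        strength_num = float(np.sum((pp[:, None] + pp[None, :]) * dif2))
        strength = strength_num / sp.sum() if sp.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def texture_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 75 texture features, keyed ``family.Name``."""
    mats = texture_matrices(levels, mask)
    grey = mats["grey"]
    n_vox = mats["n_voxels"]

    glcm = _mean_over_angles(
        [_glcm_features_single(m, grey, len(grey)) for m in mats["glcm"] if m.sum() > 0]
        or [_glcm_features_single(np.ones((1, 1)), grey[:1], len(grey))]
    )
    glrlm = _mean_over_angles(
        [_glrlm_features_single(m, grey, n_vox) for m in mats["glrlm"]]
    )
    glszm = _glszm_features(mats["glszm"], grey, n_vox)
    gldm = _gldm_features(mats["gldm"], grey)
    ngtdm = _ngtdm_features(*mats["ngtdm"], grey) if mats["ngtdm"][0].sum() > 0 else {
        k: 0.0 for k in NGTDM_NAMES
    }

    out: dict[str, float] = {}
    for prefix, feats in (
        ("glcm", glcm),
        ("glrlm", glrlm),
        ("glszm", glszm),
        ("gldm", gldm),
        ("ngtdm", ngtdm),
    ):
        for k, v in feats.items():
            out[f"{prefix}.{k}"] = v
    return out
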