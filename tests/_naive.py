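"""Naive reference implementations used as oracles in the tests.

Everything here is written as plain loops translated directly from the
published feature definitions, deliberately ignoring vectorisation and the
engine's internals, so that agreement between the two code paths is
meaningful.  Only standard library + numpy scalars are used for arithmetic;
matrices are dicts keyed by (grey, j).
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

EPS = float(np.spacing(1.0))

DIRS_13 = [
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
NEIGH_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def naive_discretize(values, bin_width):
    vmin = min(values)
    return [math.floor((v - vmin) / bin_width) + 1 for v in values]


def naive_firstorder(values, bin_width, voxel_volume=1.0):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n

    def pct(q):
        return float(np.percentile(v, q))

    levels = naive_discretize(v, bin_width)
    counts = {}
    for w in levels:
        counts[w] = counts.get(w, 0) + 1
    probs = [c / n for c in counts.values()]
    p10, p90 = pct(10), pct(90)
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    energy = sum(x * x for x in v)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": v[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": v[-1],
        "Mean": mean,
        "Median": pct(50),
        "InterquartileRange": pct(75) - pct(25),
        "Range": v[-1] - v[0],
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(x - rmean) for x in robust) / len(robust) if robust else 0.0
        ),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }


def _in(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def _mask_points(mask):
    return [tuple(p) for p in np.argwhere(mask)]


# --------------------------------------------------------------- matrices


def naive_glcm_matrices(levels, mask):
    """Symmetric co-occurrence counts per direction: {(i_value, j_value): count}."""
    shape = mask.shape
    out = []
    for d in DIRS_13:
        m = {}
        for p in _mask_points(mask):
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q]:
                a, b = int(levels[p]), int(levels[q])
                m[(a, b)] = m.get((a, b), 0) + 1
                m[(b, a)] = m.get((b, a), 0) + 1
        out.append(m)
    return out


def naive_glrlm_matrices(levels, mask):
    """Run counts per direction: {(grey_value, run_length): count}."""
    shape = mask.shape
    out = []
    for d in DIRS_13:
        m = {}
        for p in _mask_points(mask):
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            cur = p
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(shape, nxt) and mask[nxt] and levels[nxt] == levels[p]:
                    length += 1
                    cur = nxt
                else:
                    break
            key = (int(levels[p]), length)
            m[key] = m.get(key, 0) + 1
        out.append(m)
    return out


def naive_glszm_matrix(levels, mask):
    """Zone counts {(grey_value, zone_size): count} via BFS, 26-connected."""
    shape = mask.shape
    seen = set()
    m = {}
    for p in _mask_points(mask):
        if p in seen:
            continue
        g = int(levels[p])
        stack = [p]
        seen.add(p)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGH_26:
                q = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if q not in seen and _in(shape, q) and mask[q] and int(levels[q]) == g:
                    seen.add(q)
                    stack.append(q)
        m[(g, size)] = m.get((g, size), 0) + 1
    return m


def naive_gldm_matrix(levels, mask, alpha=0):
    """Dependence counts {(grey_value, dependence_size): count}; size counts the centre."""
    shape = mask.shape
    m = {}
    for p in _mask_points(mask):
        dep = 1
        for d in NEIGH_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q] and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        key = (int(levels[p]), dep)
        m[key] = m.get(key, 0) + 1
    return m


def naive_ngtdm_table(levels, mask):
    """Per-grey-level (n_i, s_i) over voxels with at least one valid neighbour."""
    shape = mask.shape
    n, s = {}, {}
    for p in _mask_points(mask):
        vals = []
        for d in NEIGH_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q]:
                vals.append(int(levels[q]))
        if not vals:
            continue
        g = int(levels[p])
        n[g] = n.get(g, 0) + 1
        s[g] = s.get(g, 0.0) + abs(g - sum(vals) / len(vals))
    return n, s


# --------------------------------------------------------------- features


def naive_glcm_features(levels, mask, n_distinct_greys):
    mats = naive_glcm_matrices(levels, mask)
    per_angle = []
    for m in mats:
        if not m:
            continue
        total = sum(m.values())
        P = {k: c / total for k, c in m.items()}
        px, py = {}, {}
        for (i, j), p in P.items():
            px[i] = px.get(i, 0.0) + p
            py[j] = py.get(j, 0.0) + p
        mu_x = sum(i * p for i, p in px.items())
        mu_y = sum(j * p for j, p in py.items())
        sig_x = math.sqrt(sum((i - mu_x) ** 2 * p for i, p in px.items()))
        sig_y = math.sqrt(sum((j - mu_y) ** 2 * p for j, p in py.items()))
        p_sum, p_diff = {}, {}
        for (i, j), p in P.items():
            p_sum[i + j] = p_sum.get(i + j, 0.0) + p
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
        da = sum(k * p for k, p in p_diff.items())
        ng = n_distinct_greys

        hxy = -sum(p * math.log2(p + EPS) for p in P.values())
        hx = -sum(p * math.log2(p + EPS) for p in px.values())
        hy = -sum(p * math.log2(p + EPS) for p in py.values())
        hxy1 = -sum(p * math.log2(px[i] * py[j] + EPS) for (i, j), p in P.items())
        hxy2 = -sum(
            px[i] * py[j] * math.log2(px[i] * py[j] + EPS) for i in px for j in py
        )
        greys = sorted(px)
        if len(greys) > 1:
            Q = np.zeros((len(greys), len(greys)))
            gi = {g: a for a, g in enumerate(greys)}
            for i in greys:
                for j in greys:
                    Q[gi[i], gi[j]] = sum(
                        P.get((i, k), 0.0) * P.get((j, k), 0.0) / (px[i] * py[k])
                        for k in greys
                    )
            eig = sorted(np.real(np.linalg.eigvals(Q)))
            mcc = math.sqrt(max(0.0, eig[-2]))
        else:
            mcc = 1.0

        f = {
            "Autocorrelation": sum(i * j * p for (i, j), p in P.items()),
            "ClusterProminence": sum((i + j - mu_x - mu_y) ** 4 * p for (i, j), p in P.items()),
            "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * p for (i, j), p in P.items()),
            "ClusterTendency": sum((i + j - mu_x - mu_y) ** 2 * p for (i, j), p in P.items()),
            "Contrast": sum((i - j) ** 2 * p for (i, j), p in P.items()),
            "Correlation": (
                (sum(i * j * p for (i, j), p in P.items()) - mu_x * mu_y) / (sig_x * sig_y)
                if sig_x > 0 and sig_y > 0
                else 1.0
            ),
            "DifferenceAverage": da,
            "DifferenceEntropy": -sum(p * math.log2(p + EPS) for p in p_diff.values()),
            "DifferenceVariance": sum((k - da) ** 2 * p for k, p in p_diff.items()),
            "Id": sum(p / (1 + abs(i - j)) for (i, j), p in P.items()),
            "Idm": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
            "Idmn": sum(p / (1 + (i - j) ** 2 / ng**2) for (i, j), p in P.items()),
            "Idn": sum(p / (1 + abs(i - j) / ng) for (i, j), p in P.items()),
            "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
            "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
            "InverseVariance": sum(
                p / (i - j) ** 2 for (i, j), p in P.items() if i != j
            ),
            "JointAverage": mu_x,
            "JointEnergy": sum(p * p for p in P.values()),
            "JointEntropy": hxy,
            "MCC": mcc,
            "MaximumProbability": max(P.values()),
            "SumAverage": sum(k * p for k, p in p_sum.items()),
            "SumEntropy": -sum(p * math.log2(p + EPS) for p in p_sum.values()),
            "SumSquares": sum((i - mu_x) ** 2 * p for (i, j), p in P.items()),
        }
        per_angle.append(f)
    return {k: sum(f[k] for f in per_angle) / len(per_angle) for k in per_angle[0]}


def _si_features(mat, n_vox, axis_name):
    """Shared grey-by-size feature formulas for GLRLM/GLSZM-style matrices."""
    total = sum(mat.values())
    pg, pl = {}, {}
    for (g, l), c in mat.items():
        pg[g] = pg.get(g, 0) + c
        pl[l] = pl.get(l, 0) + c
    p = {k: c / total for k, c in mat.items()}
    mu_g = sum(g * q for (g, l), q in p.items())
    mu_l = sum(l * q for (g, l), q in p.items())
    return {
        "GLN": sum(c * c for c in pg.values()) / total,
        "GLNN": sum(c * c for c in pg.values()) / total**2,
        "GLV": sum((g - mu_g) ** 2 * q for (g, l), q in p.items()),
        "HGL": sum(c * g * g for (g, l), c in mat.items()) / total,
        "Long": sum(c * l * l for (g, l), c in mat.items()) / total,
        "LongHigh": sum(c * g * g * l * l for (g, l), c in mat.items()) / total,
        "LongLow": sum(c * l * l / g**2 for (g, l), c in mat.items()) / total,
        "LGL": sum(c / g**2 for (g, l), c in mat.items()) / total,
        "Entropy": -sum(q * math.log2(q + EPS) for q in p.values()),
        "LenN": sum(c * c for c in pl.values()) / total,
        "LenNN": sum(c * c for c in pl.values()) / total**2,
        "Percentage": total / n_vox,
        "LenVar": sum((l - mu_l) ** 2 * q for (g, l), q in p.items()),
        "Short": sum(c / l**2 for (g, l), c in mat.items()) / total,
        "ShortHigh": sum(c * g * g / l**2 for (g, l), c in mat.items()) / total,
        "ShortLow": sum(c / (g * g * l * l) for (g, l), c in mat.items()) / total,
    }


def naive_glrlm_features(levels, mask):
    mats = naive_glrlm_matrices(levels, mask)
    n_vox = int(mask.sum())
    per_angle = [_si_features(m, n_vox, "run") for m in mats]
    mean = {k: sum(f[k] for f in per_angle) / len(per_angle) for k in per_angle[0]}
    return {
        "GreyLevelNonUniformity": mean["GLN"],
        "GreyLevelNonUniformityNormalized": mean["GLNN"],
        "GreyLevelVariance": mean["GLV"],
        "HighGreyLevelRunEmphasis": mean["HGL"],
        "LongRunEmphasis": mean["Long"],
        "LongRunHighGreyLevelEmphasis": mean["LongHigh"],
        "LongRunLowGreyLevelEmphasis": mean["LongLow"],
        "LowGreyLevelRunEmphasis": mean["LGL"],
        "RunEntropy": mean["Entropy"],
        "RunLengthNonUniformity": mean["LenN"],
        "RunLengthNonUniformityNormalized": mean["LenNN"],
        "RunPercentage": mean["Percentage"],
        "RunVariance": mean["LenVar"],
        "ShortRunEmphasis": mean["Short"],
        "ShortRunHighGreyLevelEmphasis": mean["ShortHigh"],
        "ShortRunLowGreyLevelEmphasis": mean["ShortLow"],
    }


def naive_glszm_features(levels, mask):
    f = _si_features(naive_glszm_matrix(levels, mask), int(mask.sum()), "zone")
    return {
        "GreyLevelNonUniformity": f["GLN"],
        "GreyLevelNonUniformityNormalized": f["GLNN"],
        "GreyLevelVariance": f["GLV"],
        "HighGreyLevelZoneEmphasis": f["HGL"],
        "LargeAreaEmphasis": f["Long"],
        "LargeAreaHighGreyLevelEmphasis": f["LongHigh"],
        "LargeAreaLowGreyLevelEmphasis": f["LongLow"],
        "LowGreyLevelZoneEmphasis": f["LGL"],
        "SizeZoneNonUniformity": f["LenN"],
        "SizeZoneNonUniformityNormalized": f["LenNN"],
        "SmallAreaEmphasis": f["Short"],
        "SmallAreaHighGreyLevelEmphasis": f["ShortHigh"],
        "SmallAreaLowGreyLevelEmphasis": f["ShortLow"],
        "ZoneEntropy": f["Entropy"],
        "ZonePercentage": f["Percentage"],
        "ZoneVariance": f["LenVar"],
    }


def naive_gldm_features(levels, mask):
    f = _si_features(naive_gldm_matrix(levels, mask), int(mask.sum()), "dep")
    return {
        "DependenceEntropy": f["Entropy"],
        "DependenceNonUniformity": f["LenN"],
        "DependenceNonUniformityNormalized": f["LenNN"],
        "DependenceVariance": f["LenVar"],
        "GreyLevelNonUniformity": f["GLN"],
        "GreyLevelVariance": f["GLV"],
        "HighGreyLevelEmphasis": f["HGL"],
        "LargeDependenceEmphasis": f["Long"],
        "LargeDependenceHighGreyLevelEmphasis": f["LongHigh"],
        "LargeDependenceLowGreyLevelEmphasis": f["LongLow"],
        "LowGreyLevelEmphasis": f["LGL"],
        "SmallDependenceEmphasis": f["Short"],
        "SmallDependenceHighGreyLevelEmphasis": f["ShortHigh"],
        "SmallDependenceLowGreyLevelEmphasis": f["ShortLow"],
    }


def naive_ngtdm_features(levels, mask):
    n, s = naive_ngtdm_table(levels, mask)
    nvp = sum(n.values())
    greys = sorted(n)
    p = {g: n[g] / nvp for g in greys}
    ngp = len(greys)
    coarse_den = sum(p[g] * s[g] for g in greys)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in greys for j in greys)
            / (ngp * (ngp - 1))
            * (sum(s.values()) / nvp)
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in greys for j in greys)
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in greys
                for j in greys
            )
            / nvp
        )
        s_total = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in greys for j in greys) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": 1.0 / coarse_den if coarse_den > 0 else 1e6,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def naive_texture_features(levels, mask):
    greys = sorted({int(levels[p]) for p in _mask_points(mask)})
    out = {}
    for prefix, feats in (
        ("glcm", naive_glcm_features(levels, mask, len(greys))),
        ("glrlm", naive_glrlm_features(levels, mask)),
        ("glszm", naive_glszm_features(levels, mask)),
        ("gldm", naive_gldm_features(levels, mask)),
        ("ngtdm", naive_ngtdm_features(levels, mask)),
    ):
        for k, v in feats.items():
            out[f"{prefix}.{k}"] = v
    return out


def naive_shape(mask, spacing):
    """Shape oracle: trimesh for mesh volume/area, explicit loops elsewhere."""
    import trimesh
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    volume = abs(float(tm.volume))
    area = float(tm.area)

    def max_dist(points):
        best = 0.0
        pts = [tuple(p) for p in points]
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                d = math.dist(pts[a], pts[b])
                best = max(best, d)
        return best

    def planar(axis):
        groups = {}
        for p in verts:
            groups.setdefault(round(float(p[axis]), 6), []).append(p)
        return max((max_dist(g) for g in groups.values() if len(g) > 1), default=0.0)

    coords = np.argwhere(mask) * np.asarray(spacing)
    n = len(coords)
    if n > 1:
        centred = coords - coords.mean(axis=0)
        cov = centred.T @ centred / n
        eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
        eig = [max(e, 0.0) for e in eig]
    else:
        eig = [0.0, 0.0, 0.0]
    return {
        "MeshVolume": volume,
        "VoxelVolume": n * float(np.prod(spacing)),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume if volume > 0 else 0.0,
        "Sphericity": (36 * math.pi * volume**2) ** (1 / 3) / area if area > 0 else 0.0,
        "Maximum3DDiameter": max_dist(verts),
        "Maximum2DDiameterSlice": planar(2),
        "Maximum2DDiameterColumn": planar(0),
        "Maximum2DDiameterRow": planar(1),
        "MajorAxisLength": 4 * math.sqrt(eig[0]),
        "MinorAxisLength": 4 * math.sqrt(eig[1]),
        "LeastAxisLength": 4 * math.sqrt(eig[2]),
        "Elongation": math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 0.0,
        "Flatness": math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 0.0,
    }
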