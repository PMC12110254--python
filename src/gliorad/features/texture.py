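"""3D texture matrices and their scalar features.

Four classical texture descriptors over a quantized ROI:

* GLCM  — gray-level co-occurrence matrix: joint probability of level pairs
  at an offset; counts are accumulated over all 13 unique 3D directions at
  the given radius into a single symmetric matrix normalized to sum 1.
* GLRLM — gray-level run-length matrix: counts of maximal collinear runs of
  equal level, built per direction; features averaged over the 13 directions.
* GLSZM — gray-level size-zone matrix: 26-connected components of equal
  level, counted by (level, zone size).  Direction-free.
* NGTDM — neighborhood gray-tone difference matrix: per-level sums of
  absolute differences between a voxel's level and the mean level of its
  26-neighborhood (Amadasun-King formulation).

Degenerate ROIs (a single voxel, or no valid neighbor pairs) yield ``None``
matrices; feature functions then return NaN for every feature, which the
extractor logs and propagates as a missing-value sentinel in permissive mode.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .manifest import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)
from .quantize import QuantizedROI

logger = logging.getLogger(__name__)

# The 13 unique 3D direction representatives (first nonzero component
# positive); together with their negatives they cover all 26 neighbors.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """Shift a 3D array by ``offset`` voxels, filling vacated cells."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI, radius: int = 1) -> np.ndarray | None:
    """Direction-merged, symmetrized, normalized co-occurrence matrix.

    Returns ``None`` when the ROI contains no in-ROI voxel pair at the given
    radius (e.g. a single-voxel ROI).
    """
    B = q.bins
    counts = np.zeros((B, B), dtype=np.int64)
    lv = q.levels
    mask = q.mask
    for d in DIRECTIONS_3D:
        off = tuple(radius * c for c in d)
        nb_lv = _shift(lv, off)
        nb_ok = _shift(mask.astype(np.int8), off).astype(bool)
        valid = mask & nb_ok
        if not valid.any():
            continue
        a = lv[valid] - 1
        b = nb_lv[valid] - 1
        np.add.at(counts, (a, b), 1)
    total = counts.sum()
    if total == 0:
        logger.warning("GLCM undefined: ROI has no voxel pairs at radius %d", radius)
        return None
    sym = counts + counts.T  # count both orderings of every pair
    return sym / sym.sum()


def glcm_features(p: np.ndarray | None) -> dict[str, float]:
    """Eight scalar features of a normalized symmetric GLCM."""
    if p is None:
        return {name: float("nan") for name in GLCM_FEATURES}
    B = p.shape[0]
    i = np.arange(1, B + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    mu_y = mu_x  # symmetric matrix
    var_x = float(((i - mu_x) ** 2 * px).sum())
    diff = ii - jj
    s = ii + jj - mu_x - mu_y

    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    if var_x > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / var_x)
    else:
        correlation = 1.0  # single gray level: perfectly correlated by convention
    cluster_shade = float((p * s**3).sum())
    cluster_prominence = float((p * s**4).sum())

    return {
        "Contrast": contrast,
        "Dissimilarity": dissimilarity,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity": homogeneity,
        "Correlation": correlation,
        "ClusterShade": cluster_shade,
        "ClusterProminence": cluster_prominence,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _run_lengths_one_direction(
    lv: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]
) -> np.ndarray:
    """Run-length matrix (levels x lengths) for one direction.

    Row i-1 holds counts of maximal runs of level i by length.  Runs are
    maximal sequences of equal in-ROI levels along direction ``d``; out-of-ROI
    voxels break runs.
    """
    # primary axis: first axis with nonzero component (positive by convention)
    axis = next(a for a in range(3) if d[a] != 0)
    n_axis = lv.shape[axis]
    max_len = max(lv.shape)
    B = int(lv.max()) if lv.size else 0
    R = np.zeros((max(B, 1), max_len), dtype=np.int64)

    lateral = tuple(d[a] for a in range(3) if a != axis)

    def shift2d(sl: np.ndarray, fill=0) -> np.ndarray:
        out = np.full_like(sl, fill)
        src, dst = [], []
        for o, n in zip(lateral, sl.shape):
            if o >= 0:
                src.append(slice(0, n - o))
                dst.append(slice(o, n))
            else:
                src.append(slice(-o, n))
                dst.append(slice(0, n + o))
        out[tuple(dst)] = sl[tuple(src)]
        return out

    def take(arr: np.ndarray, idx: int) -> np.ndarray:
        sel = [slice(None)] * 3
        sel[axis] = idx
        return arr[tuple(sel)]

    # C[x] = length of the run ending at x (going along +d)
    C = np.zeros_like(lv)
    for t in range(n_axis):
        cur_lv = take(lv, t)
        cur_m = take(mask, t)
        cur_C = cur_m.astype(np.int64)
        if t > 0:
            prev_lv = shift2d(take(lv, t - 1))
            prev_m = shift2d(take(mask, t - 1).astype(np.int8)).astype(bool)
            prev_C = shift2d(take(C, t - 1))
            cont = cur_m & prev_m & (cur_lv == prev_lv)
            cur_C = np.where(cont, prev_C + 1, cur_C)
        sel = [slice(None)] * 3
        sel[axis] = t
        C[tuple(sel)] = cur_C

    # run ends: in-ROI voxels whose +d neighbor does not continue the run
    neg = tuple(-c for c in d)
    nxt_lv = _shift(lv, neg)
    nxt_m = _shift(mask.astype(np.int8), neg).astype(bool)
    ends = mask & ~(nxt_m & (nxt_lv == lv))
    run_levels = lv[ends]
    run_lens = C[ends]
    np.add.at(R, (run_levels - 1, run_lens - 1), 1)
    return R


def glrlm_matrices(q: QuantizedROI) -> list[np.ndarray]:
    """Per-direction run-length matrices over the 13 unique 3D directions."""
    return [
        _run_lengths_one_direction(q.levels, q.mask, d) for d in DIRECTIONS_3D
    ]


def _glrlm_features_single(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    Nr = R.sum()
    if Nr == 0:
        return {name: float("nan") for name in GLRLM_FEATURES}
    B, L = R.shape
    i = np.arange(1, B + 1)[:, None].astype(float)
    l = np.arange(1, L + 1)[None, :].astype(float)
    r = R.astype(float)
    ri = r.sum(axis=1)
    rl = r.sum(axis=0)
    return {
        "ShortRunEmphasis": float((r / l**2).sum() / Nr),
        "LongRunEmphasis": float((r * l**2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / Nr**2),
        "RunLengthNonUniformityNormalized": float((rl**2).sum() / Nr**2),
        "RunPercentage": float(Nr / n_voxels),
        "LowGrayLevelRunEmphasis": float((r / i**2).sum() / Nr),
        "HighGrayLevelRunEmphasis": float((r * i**2).sum() / Nr),
        "ShortRunLowGrayLevelEmphasis": float((r / (i**2 * l**2)).sum() / Nr),
        "ShortRunHighGrayLevelEmphasis": float((r * i**2 / l**2).sum() / Nr),
        "LongRunLowGrayLevelEmphasis": float((r * l**2 / i**2).sum() / Nr),
    }


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    """Run-length features, computed per direction and averaged."""
    per_dir = [
        _glrlm_features_single(R, q.n_voxels) for R in glrlm_matrices(q)
    ]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURES
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_zones(q: QuantizedROI) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone in the ROI."""
    zones: list[tuple[int, int]] = []
    for level in range(1, q.bins + 1):
        blob = q.levels == level
        if not blob.any():
            continue
        lab, n = ndimage.label(blob, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    return zones


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    zones = glszm_zones(q)
    if not zones:
        return {name: float("nan") for name in GLSZM_FEATURES}
    levels = np.array([z[0] for z in zones], dtype=float)
    sizes = np.array([z[1] for z in zones], dtype=float)
    Nz = float(len(zones))
    Np = float(q.n_voxels)
    p = np.ones_like(sizes) / Nz

    # per-level and per-size marginals
    lvl_counts = {}
    size_counts = {}
    for lv, sz in zones:
        lvl_counts[lv] = lvl_counts.get(lv, 0) + 1
        size_counts[sz] = size_counts.get(sz, 0) + 1
    lvl_marg = np.array(list(lvl_counts.values()), dtype=float)
    size_marg = np.array(list(size_counts.values()), dtype=float)

    mu_lvl = float((levels * p).sum())
    mu_size = float((sizes * p).sum())

    return {
        "SmallAreaEmphasis": float((1.0 / sizes**2).sum() / Nz),
        "LargeAreaEmphasis": float((sizes**2).sum() / Nz),
        "GrayLevelNonUniformity": float((lvl_marg**2).sum() / Nz),
        "GrayLevelNonUniformityNormalized": float((lvl_marg**2).sum() / Nz**2),
        "SizeZoneNonUniformity": float((size_marg**2).sum() / Nz),
        "SizeZoneNonUniformityNormalized": float((size_marg**2).sum() / Nz**2),
        "ZonePercentage": float(Nz / Np),
        "GrayLevelVariance": float((p * (levels - mu_lvl) ** 2).sum()),
        "ZoneVariance": float((p * (sizes - mu_size) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p)).sum()) if Nz > 1 else 0.0,
        "LowGrayLevelZoneEmphasis": float((1.0 / levels**2).sum() / Nz),
        "HighGrayLevelZoneEmphasis": float((levels**2).sum() / Nz),
        "SmallAreaLowGrayLevelEmphasis": float(
            (1.0 / (levels**2 * sizes**2)).sum() / Nz
        ),
        "SmallAreaHighGrayLevelEmphasis": float(
            (levels**2 / sizes**2).sum() / Nz
        ),
        "LargeAreaLowGrayLevelEmphasis": float(
            (sizes**2 / levels**2).sum() / Nz
        ),
        "LargeAreaHighGrayLevelEmphasis": float(
            (levels**2 * sizes**2).sum() / Nz
        ),
        "MeanZoneSize": mu_size,
        "MaximumZoneSize": float(sizes.max()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(
    q: QuantizedROI, radius: int = 1
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-level probabilities p_i and difference sums s_i (Amadasun-King).

    A voxel contributes when it has at least one in-ROI neighbor within the
    cubic 26-neighborhood of the given radius.  Returns ``None`` when no
    voxel qualifies.
    """
    k = 2 * radius + 1
    kernel = np.ones((k, k, k))
    kernel[radius, radius, radius] = 0.0
    m = q.mask.astype(float)
    nb_sum = ndimage.convolve(q.levels * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nb_cnt > 0.5)
    if not valid.any():
        logger.warning("NGTDM undefined: no in-ROI voxel has an in-ROI neighbor")
        return None
    nb_mean = np.zeros_like(nb_sum)
    nb_mean[valid] = nb_sum[valid] / nb_cnt[valid]
    lv = q.levels[valid].astype(float)
    diffs = np.abs(lv - nb_mean[valid])

    B = q.bins
    n_i = np.zeros(B)
    s_i = np.zeros(B)
    np.add.at(n_i, q.levels[valid] - 1, 1.0)
    np.add.at(s_i, q.levels[valid] - 1, diffs)
    p_i = n_i / n_i.sum()
    return p_i, s_i


def ngtdm_features(q: QuantizedROI, radius: int = 1) -> dict[str, float]:
    """The canonical five: Coarseness, Contrast, Busyness, Complexity, Strength."""
    table = ngtdm_table(q, radius)
    if table is None:
        return {name: float("nan") for name in NGTDM_FEATURES}
    p, s = table
    B = len(p)
    levels = np.arange(1, B + 1, dtype=float)
    present = p > 0
    Ngp = int(present.sum())
    N = float(q.n_voxels)

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6  # capped for flat regions

    if Ngp > 1:
        ii = levels[present][:, None]
        jj = levels[present][None, :]
        pi = p[present][:, None]
        pj = p[present][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (Ngp * (Ngp - 1))
            * s.sum()
            / N
        )
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (pi * s[present][:, None] + pj * s[present][None, :])
             / (pi + pj)).sum() / N
        )
        s_tot = float(s.sum())
        strength = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / s_tot if s_tot > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
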