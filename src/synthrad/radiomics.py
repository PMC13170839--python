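"""Radiomic feature battery: 526 features per tumor region and modality.

The battery is 13 shape + 18 intensity + 39 texture + 456 wavelet features.
Texture is 22 grey-level co-occurrence (GLCM, 13 symmetric 3D offsets at
distance 1), 13 grey-level run-length (GLRLM, runs pooled over the same 13
directions) and 4 neighbourhood grey-tone difference (NGTDM) features.
The wavelet family recomputes the 18 intensity and 39 texture features on
each of the 8 sub-bands of a single-level undecimated 3D separable wavelet
transform (8 x 57 = 456).

Intensity and texture features are computed from in-mask voxels only;
grey levels are discretized to a fixed bin count (default 32) over the
in-mask range.  Extraction is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, spatial
from skimage.measure import marching_cubes

from .data_io import MRVolume

N_BINS_DEFAULT = 32

# canonical half of the 26-neighbourhood: 13 unique 3D directions
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

SUBBANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]

# Haar analysis pair; an alternative orthogonal pair may be injected.
HAAR_LO = np.array([1.0, 1.0]) / np.sqrt(2.0)
HAAR_HI = np.array([1.0, -1.0]) / np.sqrt(2.0)


class EmptyMaskError(ValueError):
    """The tumor mask contains no voxels."""


class DegenerateMaskError(ValueError):
    """The masked region cannot support the requested features
    (single voxel or a single grey level after discretization)."""


# ----------------------------------------------------------------------
# feature name registry

SHAPE_NAMES = [
    "shape_volume", "shape_surface_area", "shape_surface_to_volume",
    "shape_compactness1", "shape_compactness2", "shape_sphericity",
    "shape_spherical_disproportion", "shape_max_3d_diameter",
    "shape_major_axis_length", "shape_minor_axis_length",
    "shape_least_axis_length", "shape_elongation", "shape_flatness",
]

INTENSITY_BASE = [
    "mean", "median", "minimum", "maximum", "range", "variance", "std",
    "skewness", "kurtosis", "energy", "entropy", "uniformity", "rms",
    "mad", "robust_mad", "p10", "p90", "iqr",
]

GLCM_BASE = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy",
]

GLRLM_BASE = [
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    "gray_level_variance", "run_length_variance",
]

NGTDM_BASE = ["coarseness", "contrast", "busyness", "complexity"]

INTENSITY_NAMES = [f"intensity_{n}" for n in INTENSITY_BASE]
TEXTURE_NAMES = ([f"glcm_{n}" for n in GLCM_BASE]
                 + [f"glrlm_{n}" for n in GLRLM_BASE]
                 + [f"ngtdm_{n}" for n in NGTDM_BASE])
WAVELET_NAMES = [f"wavelet_{sb}_{n}"
                 for sb in SUBBANDS
                 for n in INTENSITY_NAMES + TEXTURE_NAMES]

FEATURE_NAMES = SHAPE_NAMES + INTENSITY_NAMES + TEXTURE_NAMES + WAVELET_NAMES

FAMILY_COUNTS = {"shape": 13, "intensity": 18, "texture": 39, "wavelet": 456}
assert len(SHAPE_NAMES) == 13
assert len(INTENSITY_NAMES) == 18
assert len(TEXTURE_NAMES) == 39
assert len(WAVELET_NAMES) == 456
assert len(FEATURE_NAMES) == 526


# ----------------------------------------------------------------------
# helpers

def _as_array(vol) -> np.ndarray:
    if isinstance(vol, MRVolume):
        return np.asarray(vol.voxels, dtype=float)
    return np.asarray(vol, dtype=float)


def _check_mask(vol: np.ndarray, mask) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    if not mask.any():
        raise EmptyMaskError("tumor mask is empty")
    return mask


def _bbox_crop(vol: np.ndarray, mask: np.ndarray, pad: int = 1):
    """Crop both arrays to the mask bounding box (+pad) for texture speed."""
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    sl = tuple(slice(max(s.start - pad, 0), min(s.stop + pad, dim))
               for s, dim in zip(sl, vol.shape))
    return vol[sl], mask[sl]


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS_DEFAULT
               ) -> np.ndarray:
    """Fixed-bin-count grey levels 1..n_bins over the in-mask range.

    Returns an integer array of the same shape (0 outside the mask).
    """
    out = np.zeros(values.shape, dtype=np.int64)
    inm = values[mask]
    lo, hi = float(inm.min()), float(inm.max())
    if hi == lo:
        out[mask] = 1
        return out
    lv = np.floor((values[mask] - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    out[mask] = np.clip(lv, 1, n_bins)
    return out


# ----------------------------------------------------------------------
# shape

def shape_features(mask, spacing) -> dict[str, float]:
    """13 mask-only shape descriptors (mm-based; intensity never enters)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("tumor mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    voxvol = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxvol

    # light smoothing before meshing counteracts the staircase-area bias of
    # marching cubes on binary masks (digital spheres otherwise read ~7% high)
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), 0.5)
    if padded.max() <= 0.5:  # tiny masks vanish under smoothing
        padded = np.pad(mask.astype(np.float64), 2)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    area = float(np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum() / 2.0)

    coords = np.argwhere(mask) * spacing
    # physical-coordinate principal moments; axis length = 4 sqrt(lambda)
    if n > 1:
        cov = np.cov(coords.T, bias=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    if n >= 4:
        try:
            hull = spatial.ConvexHull(coords)
            pts = coords[hull.vertices]
        except spatial.QhullError:
            pts = coords
    else:
        pts = coords
    diam = float(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1).max()))

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "shape_volume": volume,
        "shape_surface_area": area,
        "shape_surface_to_volume": area / volume,
        "shape_compactness1": volume / (np.sqrt(np.pi) * area ** 1.5),
        "shape_compactness2": 36.0 * np.pi * volume ** 2 / area ** 3,
        "shape_sphericity": np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area,
        "shape_spherical_disproportion": area / (4.0 * np.pi * r_equiv ** 2),
        "shape_max_3d_diameter": diam,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_least_axis_length": least,
        "shape_elongation": elongation,
        "shape_flatness": flatness,
    }


# ----------------------------------------------------------------------
# intensity

def intensity_features(values, n_bins: int = N_BINS_DEFAULT,
                       prefix: str = "intensity_") -> dict[str, float]:
    """18 first-order statistics of the in-mask intensity sample."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyMaskError("no intensity values supplied")
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    if std > 0:
        z = (x - mean) / std
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean() - 3.0)  # excess kurtosis
    else:
        skew = kurt = 0.0
    # histogram probabilities for entropy/uniformity
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    robust = x[(x >= p10) & (x <= p90)]
    vals = {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": lo,
        "maximum": hi,
        "range": hi - lo,
        "variance": var,
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x ** 2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "uniformity": float((p ** 2).sum()),
        "rms": float(np.sqrt((x ** 2).mean())),
        "mad": float(np.abs(x - mean).mean()),
        "robust_mad": float(np.abs(robust - robust.mean()).mean()),
        "p10": float(p10),
        "p90": float(p90),
        "iqr": float(p75 - p25),
    }
    return {prefix + k: vals[k] for k in INTENSITY_BASE}


# ----------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix pooled over the 13 distance-1 offsets."""
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for d in DIRECTIONS_13:
        sl_a, sl_b = [], []
        ok = True
        for dim, off in zip(levels.shape, d):
            if abs(off) >= dim:
                ok = False
                break
            if off >= 0:
                sl_a.append(slice(0, dim - off))
                sl_b.append(slice(off, dim))
            else:
                sl_a.append(slice(-off, dim))
                sl_b.append(slice(0, dim + off))
        if not ok:
            continue
        a = levels[tuple(sl_a)]
        b = levels[tuple(sl_b)]
        valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if not valid.any():
            continue
        idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
        counts += np.bincount(idx, minlength=n_levels * n_levels
                              ).reshape(n_levels, n_levels)
    counts = counts + counts.T  # symmetric
    return counts


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                  prefix: str = "glcm_") -> dict[str, float]:
    counts = glcm_matrix(levels, mask, n_levels)
    total = counts.sum()
    if total == 0:
        raise DegenerateMaskError("no co-occurring in-mask voxel pairs")
    P = counts / total
    i = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((px * i).sum())
    var = float((px * (i - mu) ** 2).sum())

    k_diff = np.arange(0, n_levels, dtype=float)
    p_diff = np.zeros(n_levels)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)
    k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
    p_sum = np.zeros(2 * n_levels - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, P)

    nz = P > 0
    hxy = float(-(P[nz] * np.log2(P[nz])).sum())
    pxnz = px > 0
    hx = float(-(px[pxnz] * np.log2(px[pxnz])).sum())
    pij = np.outer(px, px)
    both = nz & (pij > 0)
    hxy1 = float(-(P[both] * np.log2(pij[both])).sum())
    hxy2 = float(-(pij[pij > 0] * np.log2(pij[pij > 0])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((k_diff * p_diff).sum())
    diff_sq = (ii - jj) ** 2
    off_diag = diff_sq > 0
    pd_nz = p_diff > 0
    ps_nz = p_sum > 0
    corr = ((float((ii * jj * P).sum()) - mu * mu) / var) if var > 0 else 0.0
    vals = {
        "autocorrelation": float((ii * jj * P).sum()),
        "joint_average": float((ii * P).sum()),
        "cluster_prominence": float((((ii + jj) - 2 * mu) ** 4 * P).sum()),
        "cluster_shade": float((((ii + jj) - 2 * mu) ** 3 * P).sum()),
        "cluster_tendency": float((((ii + jj) - 2 * mu) ** 2 * P).sum()),
        "contrast": float((diff_sq * P).sum()),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": float(-(p_diff[pd_nz] * np.log2(p_diff[pd_nz])).sum()),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "joint_energy": float((P ** 2).sum()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized":
            float((P / (1.0 + np.abs(ii - jj) / n_levels)).sum()),
        "inverse_difference_moment": float((P / (1.0 + diff_sq)).sum()),
        "inverse_difference_moment_normalized":
            float((P / (1.0 + diff_sq / n_levels ** 2)).sum()),
        "inverse_variance": float((P[off_diag] / diff_sq[off_diag]).sum()),
        "maximum_probability": float(P.max()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": float(-(p_sum[ps_nz] * np.log2(p_sum[ps_nz])).sum()),
    }
    return {prefix + k: vals[k] for k in GLCM_BASE}


# ----------------------------------------------------------------------
# GLRLM

def _run_matrix_one_direction(levels: np.ndarray, mask: np.ndarray,
                              d: tuple[int, int, int], n_levels: int,
                              max_len: int) -> np.ndarray:
    """Run-length matrix for one direction via a suffix scan along the
    direction's leading axis (all 13 canonical directions have a +1
    leading component, so slices can be processed far-to-near)."""
    lead = next(ax for ax, off in enumerate(d) if off != 0)
    assert d[lead] > 0
    shape = levels.shape

    def shifted(arr, fill):
        """arr sampled at v + d (out-of-range -> fill)."""
        out = np.full(shape, fill, dtype=arr.dtype)
        src, dst = [], []
        for dim, off in zip(shape, d):
            if abs(off) >= dim:
                return out
            if off >= 0:
                dst.append(slice(0, dim - off))
                src.append(slice(off, dim))
            else:
                dst.append(slice(-off, dim))
                src.append(slice(0, dim + off))
        out[tuple(dst)] = arr[tuple(src)]
        return out

    nxt_lvl = shifted(levels, 0)
    nxt_in = shifted(mask.astype(bool), False)
    same = mask & nxt_in & (levels == nxt_lvl)  # run continues at v+d

    runlen = np.zeros(shape, dtype=np.int64)
    n_lead = shape[lead]
    idx = [slice(None)] * 3
    for pos in range(n_lead - 1, -1, -1):
        idx[lead] = pos
        sl = tuple(idx)
        cont = shifted(runlen, 0)[sl]  # runlen at v+d, already final
        runlen[sl] = np.where(mask[sl], 1 + np.where(same[sl], cont, 0), 0)

    prev_lvl = shifted_neg(levels, d, 0)
    prev_in = shifted_neg(mask.astype(bool), d, False)
    is_start = mask & ~(prev_in & (levels == prev_lvl))

    g = levels[is_start] - 1
    l = runlen[is_start] - 1
    R = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(R, (g, np.clip(l, 0, max_len - 1)), 1.0)
    return R


def shifted_neg(arr: np.ndarray, d, fill):
    """arr sampled at v - d (out-of-range -> fill)."""
    shape = arr.shape
    out = np.full(shape, fill, dtype=arr.dtype)
    src, dst = [], []
    for dim, off in zip(shape, d):
        off = -off
        if abs(off) >= dim:
            return out
        if off >= 0:
            dst.append(slice(0, dim - off))
            src.append(slice(off, dim))
        else:
            dst.append(slice(-off, dim))
            src.append(slice(0, dim + off))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                   prefix: str = "glrlm_") -> dict[str, float]:
    """13 run-length features on the direction-pooled run matrix."""
    max_len = max(levels.shape)
    R = np.zeros((n_levels, max_len), dtype=np.float64)
    for d in DIRECTIONS_13:
        R += _run_matrix_one_direction(levels, mask, d, n_levels, max_len)
    nr = R.sum()
    if nr == 0:
        raise DegenerateMaskError("no runs found in mask")
    n_vox = int(mask.sum())
    g = np.arange(1, n_levels + 1, dtype=float)[:, None]
    l = np.arange(1, max_len + 1, dtype=float)[None, :]
    p = R / nr
    mu_g = float((p * g).sum())
    mu_l = float((p * l).sum())
    vals = {
        "short_run_emphasis": float((R / l ** 2).sum() / nr),
        "long_run_emphasis": float((R * l ** 2).sum() / nr),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": float(nr / (len(DIRECTIONS_13) * n_vox)),
        "low_gray_level_run_emphasis": float((R / g ** 2).sum() / nr),
        "high_gray_level_run_emphasis": float((R * g ** 2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((R / (g ** 2 * l ** 2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((R * g ** 2 / l ** 2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((R * l ** 2 / g ** 2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((R * g ** 2 * l ** 2).sum() / nr),
        "gray_level_variance": float((p * (g - mu_g) ** 2).sum()),
        "run_length_variance": float((p * (l - mu_l) ** 2).sum()),
    }
    return {prefix + k: vals[k] for k in GLRLM_BASE}


# ----------------------------------------------------------------------
# NGTDM

def ngtdm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                   prefix: str = "ngtdm_") -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity from neighbourhood
    grey-tone differences (26-neighbourhood, in-mask neighbours only)."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(float)
    nbr_sum = ndimage.correlate(levels * m, kernel, mode="constant")
    nbr_cnt = ndimage.correlate(m, kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    if not valid.any():
        raise DegenerateMaskError("no voxel has in-mask neighbours")
    abar = nbr_sum[valid] / nbr_cnt[valid]
    lv = levels[valid]
    n_total = int(valid.sum())

    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels)
    np.add.at(s, lv - 1, np.abs(lv - abar))
    np.add.at(n_i, lv - 1, 1.0)
    p_i = n_i / n_total
    present = p_i > 0
    ngp = int(present.sum())
    i_lv = np.arange(1, n_levels + 1, dtype=float)

    eps = np.finfo(float).eps
    coarseness = 1.0 / max((p_i * s).sum(), eps)
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii_, jj_ = np.meshgrid(i_lv[present], i_lv[present], indexing="ij")
        contrast = (float((pi_ * pj_ * (ii_ - jj_) ** 2).sum())
                    / (ngp * (ngp - 1)) * float(s.sum()) / n_total)
        busy_den = float(np.abs(ii_ * pi_ - jj_ * pj_).sum())
        busyness = float((p_i * s).sum()) / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = float((np.abs(ii_ - jj_)
                            * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()) / n_total
    else:
        contrast = busyness = complexity = 0.0
    vals = {"coarseness": float(coarseness), "contrast": float(contrast),
            "busyness": float(busyness), "complexity": float(complexity)}
    return {prefix + k: vals[k] for k in NGTDM_BASE}


# ----------------------------------------------------------------------
# assembly

def texture_features(vol, mask, n_bins: int = N_BINS_DEFAULT,
                     prefix: str = "") -> dict[str, float]:
    """39 texture features (22 GLCM + 13 GLRLM + 4 NGTDM).

    Raises :class:`DegenerateMaskError` when the discretized region has a
    single grey level (no co-occurrence structure exists).
    """
    vol = _as_array(vol)
    mask = _check_mask(vol, mask)
    vol_c, mask_c = _bbox_crop(vol, mask)
    levels = discretize(vol_c, mask_c, n_bins)
    n_distinct = np.unique(levels[mask_c]).size
    if n_distinct < 2:
        raise DegenerateMaskError(
            "texture undefined: single grey level after discretization")
    out: dict[str, float] = {}
    out.update(glcm_features(levels, mask_c, n_bins, prefix=prefix + "glcm_"))
    out.update(glrlm_features(levels, mask_c, n_bins, prefix=prefix + "glrlm_"))
    out.update(ngtdm_features(levels, mask_c, n_bins, prefix=prefix + "ngtdm_"))
    return out


def wavelet_subbands(vol, lo: np.ndarray = HAAR_LO, hi: np.ndarray = HAAR_HI
                     ) -> dict[str, np.ndarray]:
    """Single-level undecimated 3D separable wavelet transform.

    Returns the 8 sub-band volumes keyed LLL..HHH (letters index the x, y, z
    axes); periodic (wrap) boundary handling.
    """
    vol = _as_array(vol)
    if min(vol.shape) < 8:
        raise ValueError(f"volume too small for wavelet transform: {vol.shape}")
    out: dict[str, np.ndarray] = {}
    for sb in SUBBANDS:
        arr = vol
        for axis, letter in enumerate(sb):
            filt = lo if letter == "L" else hi
            arr = ndimage.correlate1d(arr, filt, axis=axis, mode="wrap")
        out[sb] = arr
    return out


def wavelet_features(vol, mask, n_bins: int = N_BINS_DEFAULT,
                     lo: np.ndarray = HAAR_LO, hi: np.ndarray = HAAR_HI
                     ) -> dict[str, float]:
    """456 features: intensity (18) + texture (39) per wavelet sub-band."""
    vol = _as_array(vol)
    mask = _check_mask(vol, mask)
    out: dict[str, float] = {}
    for sb, band in wavelet_subbands(vol, lo, hi).items():
        pre = f"wavelet_{sb}_"
        out.update(intensity_features(band[mask], n_bins, prefix=pre + "intensity_"))
        out.update(texture_features(band, mask, n_bins, prefix=pre))
    return out


def extract_features(vol, mask, spacing=None, n_bins: int = N_BINS_DEFAULT
                     ) -> pd.Series:
    """Full 526-entry feature vector for one modality volume and tumor mask.

    ``spacing`` is taken from ``vol`` when it is an :class:`MRVolume`.
    """
    if isinstance(vol, MRVolume):
        spacing = vol.spacing
    elif spacing is None:
        spacing = (1.0, 1.0, 1.0)
    arr = _as_array(vol)
    mask = _check_mask(arr, mask)
    feats: dict[str, float] = {}
    feats.update(shape_features(mask, spacing))
    feats.update(intensity_features(arr[mask], n_bins))
    feats.update(texture_features(arr, mask, n_bins))
    feats.update(wavelet_features(arr, mask, n_bins))
    vec = pd.Series(feats).reindex(FEATURE_NAMES)
    if vec.isna().any():
        missing = vec.index[vec.isna()].tolist()
        raise RuntimeError(f"feature assembly lost entries: {missing[:5]}")
    return vec


def feature_table(cases, modality, volume_getter=None) -> pd.DataFrame:
    """Extract the battery for every case of one modality.

    ``cases`` are phantom-style objects with ``case_id``, ``mask``,
    ``label`` and a ``volumes`` mapping; ``volume_getter`` may override how
    the scored volume is pulled from a case (e.g. to score synthetic
    volumes).  Returns rows of case_id, modality, label + 526 features.
    """
    rows = []
    for case in cases:
        vol = (volume_getter(case) if volume_getter is not None
               else case.volumes[modality])
        vec = extract_features(vol, case.mask)
        row = {"case_id": case.case_id, "modality": str(modality),
               "label": case.label}
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
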