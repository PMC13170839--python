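"""Similarity scoring of synthetic versus ground-truth images.

All metrics operate on the 0-255 display-normalized scale (the same scale
the translation networks are trained on): MSE in squared intensity units,
PSNR in dB with peak value 255, and SSIM reported multiplied by 100.
Published reading guides for these metrics on this scale: MSE < 80 is an
ideal reconstruction, PSNR > 30 dB is high quality, SSIM > 90 is good
structural consistency; :func:`quality_flags` applies those cut-offs to
cohort means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

#: cohort-mean thresholds for a satisfactory reconstruction
MSE_IDEAL = 80.0
PSNR_GOOD_DB = 30.0
SSIM_GOOD = 90.0

PSNR_INF_SENTINEL = float("inf")


def _check_pair(a: np.ndarray, b: np.ndarray, region: np.ndarray | None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if region is not None:
        region = np.asarray(region).astype(bool)
        if region.shape != a.shape:
            raise ValueError(f"region shape {region.shape} != image shape {a.shape}")
        if not region.any():
            raise ValueError("empty region")
    return a, b, region


def mse(a, b, region=None) -> float:
    """Mean squared voxel difference, optionally restricted to a mask."""
    a, b, region = _check_pair(a, b, region)
    d = (a - b) ** 2
    return float(d[region].mean() if region is not None else d.mean())


def psnr(a, b, region=None, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(max^2 / MSE)`` in dB.

    Identical inputs (MSE = 0) return the ``inf`` sentinel.
    """
    m = mse(a, b, region)
    if m == 0.0:
        return PSNR_INF_SENTINEL
    return float(10.0 * np.log10(max_value ** 2 / m))


def ssim(a, b, max_value: float = 255.0) -> float:
    """Mean structural similarity on the reported x100 scale.

    Gaussian-window SSIM (sigma 1.5, 11-wide window, stabilizers
    ``C1=(0.01*max)^2``, ``C2=(0.03*max)^2``) computed per axial slice for
    3D input and averaged.
    """
    a, b, _ = _check_pair(a, b, None)

    def ssim2d(x, y):
        return structural_similarity(
            x, y, data_range=max_value, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03)

    if a.ndim == 2:
        val = ssim2d(a, b)
    elif a.ndim == 3:
        val = float(np.mean([ssim2d(a[:, :, z], b[:, :, z])
                             for z in range(a.shape[2])]))
    else:
        raise ValueError(f"expected 2D or 3D images, got {a.ndim}D")
    return 100.0 * val


@dataclass
class SimilarityReport:
    """Per-case metrics plus cohort means with 95% t-intervals."""

    target_modality: str
    per_case: pd.DataFrame = field(repr=False)  # case_id, mse, psnr, ssim

    def _mean_ci(self, col: str) -> tuple[float, float, float]:
        x = self.per_case[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        m = float(x.mean())
        if x.size < 2 or x.std(ddof=1) == 0:
            return m, m, m
        # normal-approximation interval; at cohort sizes >= 30 the t
        # correction is immaterial and the z form tracks the bootstrap
        half = stats.norm.ppf(0.975) * x.std(ddof=1) / np.sqrt(x.size)
        return m, m - half, m + half

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for col in ("mse", "psnr", "ssim"):
            m, lo, hi = self._mean_ci(col)
            out[col] = {"mean": m, "ci_low": lo, "ci_high": hi}
        return out


def similarity_report(pairs, target_modality: str,
                      region_masks=None) -> SimilarityReport:
    """Score a list of ``(case_id, synthetic, reference)`` volume pairs.

    ``region_masks`` optionally maps case_id to a boolean mask restricting
    MSE/PSNR (SSIM stays whole-slice: its local window statistics are not
    defined on ragged regions).
    """
    rows = []
    for case_id, syn, ref in pairs:
        reg = None if region_masks is None else region_masks.get(case_id)
        rows.append({
            "case_id": case_id,
            "mse": mse(syn, ref, reg),
            "psnr": psnr(syn, ref, reg),
            "ssim": ssim(syn, ref),
        })
    return SimilarityReport(target_modality=str(target_modality),
                            per_case=pd.DataFrame(rows))


def quality_flags(report: SimilarityReport) -> dict[str, bool]:
    """Pass/fail of the cohort means against the published cut-offs."""
    s = report.summary()
    return {
        "mse_ideal": s["mse"]["mean"] < MSE_IDEAL,
        "psnr_good": s["psnr"]["mean"] > PSNR_GOOD_DB,
        "ssim_good": s["ssim"]["mean"] > SSIM_GOOD,
    }
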