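"""Physics-based multi-modality MR phantoms of sellar tumors.

Each simulated case is a paired set of T2-weighted, diffusion-weighted
(b = 0 and b = 1000 s/mm^2) and ADC volumes plus a binary tumor mask and a
soft/fibrous consistency label.  The diffusion pair obeys the
mono-exponential decay law voxel-wise,

    S(b) = S0 * exp(-b * ADC),

with ADC in mm^2/s and b in s/mm^2, before magnitude (Rician) noise is
added.  Class signal is planted twice: fibrous tumors have lower ADC
(restricted diffusion in collagenous stroma) and a shorter-correlation,
higher-contrast internal texture in T2 and b0, emulating fibrous strands.
The phantoms are statistical stand-ins chosen for class separability, not
anatomically realistic sellar geometry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import (
    CohortManifest,
    Modality,
    MRVolume,
    save_mask,
    save_volume,
)

SOFT = "soft"
FIBROUS = "fibrous"

_LABEL_STREAM = 910_001  # sub-seed for label shuffling
_CASE_STREAM = 910_002  # sub-seed for per-case fields


class GeometryError(ValueError):
    """Tumor does not fit inside the simulation grid."""


@dataclass
class PhantomConfig:
    """Stated world of the phantom cohort.

    ADC ranges follow typical values for soft (0.9-1.3e-3 mm^2/s) versus
    fibrous (0.5-0.8e-3 mm^2/s) adenoma tissue; texture correlation lengths
    and amplitudes (fibrous: short/strong, soft: long/mild) are the planted
    texture contrast the radiomic features must detect.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cases: int = 30
    fibrous_fraction: float = 64 / 152  # cohort prevalence of fibrous tumors
    tumor_radius_range: tuple[float, float] = (8.0, 13.0)  # mm
    adc_soft_range: tuple[float, float] = (0.9e-3, 1.3e-3)  # mm^2/s
    adc_fibrous_range: tuple[float, float] = (0.5e-3, 0.8e-3)  # mm^2/s
    texture_corr_soft: tuple[float, float] = (4.0, 6.0)  # mm
    texture_corr_fibrous: tuple[float, float] = (1.0, 2.0)  # mm
    texture_amp_soft: float = 6.0  # intensity units (S0 ~ 100)
    texture_amp_fibrous: float = 12.0  # 2x soft: higher-contrast stroma
    noise_sigma: float = 2.0  # Rician channel sigma, same units as S0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if not 0.0 <= self.fibrous_fraction <= 1.0:
            raise ValueError("fibrous_fraction must lie in [0, 1]")
        for name in ("tumor_radius_range", "adc_soft_range", "adc_fibrous_range",
                     "texture_corr_soft", "texture_corr_fibrous"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has low > high: ({lo}, {hi})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomCase:
    """One simulated patient: paired volumes, mask, true ADC, label."""

    case_id: str
    t2: MRVolume
    dwi_b0: MRVolume
    dwi_b1000: MRVolume
    adc: MRVolume  # ground-truth ADC map, mm^2/s
    mask: np.ndarray  # boolean tumor mask
    label: str  # "soft" | "fibrous"

    def __post_init__(self) -> None:
        shapes = {self.t2.shape, self.dwi_b0.shape, self.dwi_b1000.shape,
                  self.adc.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"volumes/mask disagree in shape: {shapes}")
        if self.label not in (SOFT, FIBROUS):
            raise ValueError(f"label must be soft|fibrous, got {self.label!r}")
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError("tumor mask is empty")

    @property
    def volumes(self) -> dict[Modality, MRVolume]:
        return {Modality.T2WI: self.t2, Modality.DWI_b0: self.dwi_b0,
                Modality.DWI_b1000: self.dwi_b1000, Modality.ADC: self.adc}

    def mean_tumor_adc(self) -> float:
        return float(self.adc.voxels[self.mask].mean())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def allocate_labels(config: PhantomConfig) -> list[str]:
    """Deterministic label list: round(n * fibrous_fraction) fibrous cases,
    order shuffled by the cohort seed only."""
    n_fib = _round_half_up(config.n_cases * config.fibrous_fraction)
    labels = np.array([FIBROUS] * n_fib + [SOFT] * (config.n_cases - n_fib))
    rng = np.random.default_rng([config.seed, _LABEL_STREAM])
    rng.shuffle(labels)
    return labels.tolist()


def _grf(rng: np.random.Generator, shape, corr_vox) -> np.ndarray:
    """Unit-variance Gaussian random field with given correlation length
    (Gaussian smoothing sigma, voxels)."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of a complex signal with i.i.d. Gaussian channel noise."""
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(scale=sigma, size=signal.shape)
    im = rng.normal(scale=sigma, size=signal.shape)
    return np.hypot(re, im)


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def simulate_case(config: PhantomConfig, case_index: int) -> PhantomCase:
    """Simulate one case; deterministic given ``(config.seed, case_index)``.

    Raises
    ------
    GeometryError
        When the drawn tumor radius cannot fit inside the grid.
    """
    if not 0 <= case_index < config.n_cases:
        raise IndexError(f"case_index {case_index} outside [0, {config.n_cases})")
    label = allocate_labels(config)[case_index]
    rng = np.random.default_rng([config.seed, _CASE_STREAM, case_index])
    shape = tuple(int(g) for g in config.grid_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    mean_vox = float(spacing.mean())

    # --- geometry -------------------------------------------------------
    center = np.array(shape) / 2.0 + rng.uniform(-2.0, 2.0, size=3) / spacing
    radius_mm = rng.uniform(*config.tumor_radius_range)
    half_extent_mm = (np.array(shape) - 2) * spacing / 2.0
    if radius_mm >= half_extent_mm.min():
        raise GeometryError(
            f"tumor radius {radius_mm:.1f} mm exceeds grid half-extent "
            f"{half_extent_mm.min():.1f} mm for shape {shape}"
        )
    # mild eccentricity, still fitting within the checked bound
    ecc = rng.uniform(0.85, 1.0, size=3)
    semi_axes_vox = radius_mm * ecc / spacing
    mask = _ellipsoid(shape, center, semi_axes_vox)

    head = _ellipsoid(shape, np.array(shape) / 2.0,
                      (np.array(shape) / 2.0 - 1.0))  # ellipsoidal "sella" background

    # --- tissue parameter maps -----------------------------------------
    if label == FIBROUS:
        adc_lo, adc_hi = config.adc_fibrous_range
        corr_mm = rng.uniform(*config.texture_corr_fibrous)
        amp = config.texture_amp_fibrous
    else:
        adc_lo, adc_hi = config.adc_soft_range
        corr_mm = rng.uniform(*config.texture_corr_soft)
        amp = config.texture_amp_soft
    tumor_adc = rng.uniform(adc_lo, adc_hi)

    smooth = _grf(rng, shape, 6.0 / mean_vox)  # slow background modulation
    texture = _grf(rng, shape, corr_mm / mean_vox)  # class-dependent stroma

    adc = np.zeros(shape)
    adc[head] = 0.85e-3 + 0.05e-3 * smooth[head]  # normal sellar tissue
    adc[mask] = tumor_adc + 0.03e-3 * smooth[mask]
    adc = np.clip(adc, 0.1e-3, 3.0e-3) * head  # air carries no diffusion signal

    s0 = np.zeros(shape)
    s0[head] = 100.0 + 4.0 * smooth[head]
    s0[mask] = 105.0 + amp * texture[mask]

    t2 = np.zeros(shape)
    t2[head] = 60.0 + 5.0 * smooth[head]
    # fibrous tumors are T2-hypointense; texture shared with b0 so the
    # translator can infer diffusion contrast from T2 appearance
    tumor_t2_base = 90.0 if label == FIBROUS else 140.0
    t2[mask] = tumor_t2_base + 1.5 * amp * texture[mask]

    b1000 = s0 * np.exp(-1000.0 * adc)

    sig = config.noise_sigma
    t2_n = _rician(rng, t2, sig)
    s0_n = _rician(rng, s0, sig)
    b1000_n = _rician(rng, b1000, sig)

    sp = tuple(spacing)
    return PhantomCase(
        case_id=f"case_{case_index:04d}",
        t2=MRVolume(t2_n, sp, Modality.T2WI),
        dwi_b0=MRVolume(s0_n, sp, Modality.DWI_b0),
        dwi_b1000=MRVolume(b1000_n, sp, Modality.DWI_b1000),
        adc=MRVolume(adc, sp, Modality.ADC),
        mask=mask,
        label=label,
    )


def simulate_cohort(config: PhantomConfig) -> list[PhantomCase]:
    """Simulate all cases of the configured cohort."""
    if config.n_cases < 2:
        raise ValueError("a cohort needs n_cases >= 2")
    return [simulate_case(config, i) for i in range(config.n_cases)]


def estimate_adc(b0: np.ndarray, b1000: np.ndarray, b: float = 1000.0,
                 eps: float = 0.0) -> np.ndarray:
    """Per-voxel mono-exponential ADC estimate ``-ln(S_b/S_0)/b``.

    Voxels with non-positive signal in either image yield 0 (no estimate).
    """
    b0 = np.asarray(b0, dtype=float)
    b1000 = np.asarray(b1000, dtype=float)
    ok = (b0 > eps) & (b1000 > eps)
    out = np.zeros_like(b0)
    out[ok] = -np.log(b1000[ok] / b0[ok]) / b
    return out


def volume_checksum(arr: np.ndarray, decimals: int = 6) -> str:
    """SHA-256 of the array quantized to fixed decimals (bit-stable across
    runs and platforms for a fixed seed)."""
    q = np.round(np.asarray(arr, dtype=np.float64), decimals)
    q = q + 0.0  # collapse -0.0 to +0.0 before hashing
    return hashlib.sha256(q.tobytes()).hexdigest()


# ----------------------------------------------------------------------
# serialization

def write_case(case: PhantomCase, out_dir) -> dict[str, str]:
    """Write one case as four NIfTI volumes, a mask, and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {"case_id": case.case_id, "label": case.label}
    name_map = {
        Modality.T2WI: "t2_path", Modality.DWI_b0: "dwi_b0_path",
        Modality.DWI_b1000: "dwi_b1000_path", Modality.ADC: "adc_path",
    }
    for mod, vol in case.volumes.items():
        p = out_dir / f"{case.case_id}_{mod.value}.nii.gz"
        save_volume(vol, p)
        paths[name_map[mod]] = str(p)
    mp = out_dir / f"{case.case_id}_mask.nii.gz"
    save_mask(case.mask.astype(np.uint8), case.t2.spacing, mp)
    paths["mask_path"] = str(mp)
    sidecar = {
        "case_id": case.case_id,
        "label": case.label,
        "true_mean_adc": case.mean_tumor_adc(),
    }
    with open(out_dir / f"{case.case_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths


def write_cohort(cases: list[PhantomCase], out_dir) -> CohortManifest:
    """Write every case and a cohort manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        row = write_case(case, out_dir / case.case_id)
        row["split_assignment"] = "unassigned"
        rows.append(row)
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_case(manifest: CohortManifest, case_id: str) -> PhantomCase:
    """Reload a written case through the manifest."""
    from .data_io import load_mask, load_volume

    vols = {m: load_volume(manifest.path_for(case_id, m), m)
            for m in Modality}
    mask = load_mask(manifest.mask_path(case_id))
    label = manifest.labels()[case_id]
    return PhantomCase(case_id=case_id, t2=vols[Modality.T2WI],
                       dwi_b0=vols[Modality.DWI_b0],
                       dwi_b1000=vols[Modality.DWI_b1000],
                       adc=vols[Modality.ADC], mask=mask, label=label)
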