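"""NIfTI volume I/O, cohort manifests, and display normalization.

Conventions
-----------
Volumes are 3D arrays with axes ``(x, y, z)`` (x fastest in memory when
written by :func:`save_volume`); 2D slices are taken along the last (z)
axis.  Voxel indexing is 0-based.  Masks are strictly binary ``{0, 1}``
and stored as unsigned 8-bit NIfTI.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class Modality(str, enum.Enum):
    """MR modality tags used throughout the pipeline."""

    T2WI = "T2WI"
    DWI_b0 = "DWI_b0"
    DWI_b1000 = "DWI_b1000"
    ADC = "ADC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Diffusion weighting (s/mm^2) associated with each modality, where defined.
B_VALUES = {Modality.DWI_b0: 0.0, Modality.DWI_b1000: 1000.0}

AXIS_ORDER = "xyz"  # documented fixed axis-order tag


class VolumeLoadError(ValueError):
    """Raised when a file cannot be interpreted as a valid volume."""


@dataclass
class MRVolume:
    """A single-modality image volume with geometry and modality tag.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units (mm^2/s for ADC maps).
    spacing : tuple of float
        Voxel spacing in mm per axis; strictly positive.
    modality : Modality
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    origin_convention: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeLoadError(
                f"expected a 3D volume, got {self.voxels.ndim}D payload"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeLoadError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def bvalue(self) -> float | None:
        return B_VALUES.get(self.modality)

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None) -> "MRVolume":
        """New volume sharing this volume's geometry."""
        return replace(
            self,
            voxels=voxels,
            modality=Modality(modality) if modality is not None else self.modality,
        )


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: MRVolume, path) -> Path:
    """Write a volume as 32-bit float NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), _affine(vol.spacing))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def save_mask(mask: np.ndarray, spacing, path) -> Path:
    """Write a strictly binary mask as uint8 NIfTI."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"mask is not binary; values {vals}")
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_volume(path, modality: Modality | str = Modality.T2WI) -> MRVolume:
    """Load a 3D NIfTI volume.

    Raises
    ------
    VolumeLoadError
        Missing file, non-3D payload, or non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected 3D payload, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MRVolume(voxels=np.asarray(data, dtype=np.float64), spacing=spacing,
                    modality=Modality(modality))


def load_mask(path) -> np.ndarray:
    """Load a binary mask; values other than {0, 1} are rejected."""
    vol = load_volume(path, Modality.T2WI)
    data = vol.voxels
    vals = np.unique(data)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise VolumeLoadError(f"{path}: mask is non-binary, values {vals}")
    return data.astype(bool)


def normalize_0_255(vol: MRVolume, window_center: float | None = None,
                    window_width: float | None = None) -> MRVolume:
    """Window/level display normalization onto the 0-255 grayscale range.

    Maps ``[center - width/2, center + width/2]`` linearly onto ``[0, 255]``
    and clips outside.  When no window is given, the window spans the 1st to
    99th intensity percentile of the volume (robust default; display windows
    are an operator setting and are otherwise unknown).
    """
    x = np.asarray(vol.voxels, dtype=np.float64)
    if window_center is None or window_width is None:
        lo, hi = np.percentile(x, [1, 99])
        if hi <= lo:  # constant volume: map everything to mid-gray
            lo, hi = lo - 0.5, lo + 0.5
        window_center = (lo + hi) / 2.0
        window_width = hi - lo
    if window_width <= 0:
        raise ValueError(f"window_width must be positive, got {window_width}")
    lo = window_center - window_width / 2.0
    out = np.clip((x - lo) / window_width, 0.0, 1.0) * 255.0
    return vol.with_voxels(out)


def save_slice_png(vol: MRVolume, z: int, path) -> Path:
    """Export one already-normalized axial slice as an 8-bit PNG panel."""
    import imageio.v3 as iio

    sl = np.clip(np.asarray(vol.voxels)[:, :, z], 0, 255).astype(np.uint8)
    path = Path(path)
    iio.imwrite(path, sl.T)  # y down, x right
    return path


SPLIT_LEVELS = ("train", "test", "external", "unassigned")

MANIFEST_COLUMNS = [
    "case_id", "label", "t2_path", "dwi_b0_path", "dwi_b1000_path",
    "adc_path", "mask_path", "split_assignment",
]

_MODALITY_COLUMN = {
    Modality.T2WI: "t2_path",
    Modality.DWI_b0: "dwi_b0_path",
    Modality.DWI_b1000: "dwi_b1000_path",
    Modality.ADC: "adc_path",
}


@dataclass
class CohortManifest:
    """Table of cases: id, consistency label, per-modality paths, split."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        ids = self.table["case_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate case_ids: {dup}")
        bad = set(self.table["split_assignment"]) - set(SPLIT_LEVELS)
        if bad:
            raise ValueError(f"unknown split levels: {bad}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def case_ids(self) -> list[str]:
        return self.table["case_id"].tolist()

    def labels(self) -> pd.Series:
        return self.table.set_index("case_id")["label"]

    def path_for(self, case_id: str, modality: Modality) -> Path:
        row = self.table.loc[self.table["case_id"] == case_id]
        if row.empty:
            raise KeyError(f"unknown case_id {case_id!r}")
        return Path(row.iloc[0][_MODALITY_COLUMN[Modality(modality)]])

    def mask_path(self, case_id: str) -> Path:
        row = self.table.loc[self.table["case_id"] == case_id]
        if row.empty:
            raise KeyError(f"unknown case_id {case_id!r}")
        return Path(row.iloc[0]["mask_path"])

    def subset(self, case_ids) -> "CohortManifest":
        keep = self.table[self.table["case_id"].isin(list(case_ids))]
        return CohortManifest(keep.copy())

    def with_split(self, train_ids, test_ids) -> "CohortManifest":
        t = self.table.copy()
        t.loc[t.case_id.isin(list(train_ids)), "split_assignment"] = "train"
        t.loc[t.case_id.isin(list(test_ids)), "split_assignment"] = "test"
        return CohortManifest(t)

    def save(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path, check_files: bool = True) -> "CohortManifest":
        path = Path(path)
        table = pd.read_csv(path, dtype={"case_id": str})
        man = cls(table)
        if check_files:
            for col in ("t2_path", "dwi_b0_path", "dwi_b1000_path", "adc_path", "mask_path"):
                for p in table[col]:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
        return man


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
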