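"""Volume containers and NIfTI / Analyze 7.5 I/O.

All volumes are stored as ``(Z, Y, X)`` arrays — slice axis first — with voxel
spacing ``(dz, dy, dx)`` in millimetres.  Region codes for label volumes are

====  =============
code  structure
====  =============
0     background
1     cortex
2     hippocampus
3     striatum
4     thalamus
5     cerebellum
====  =============
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: region code -> name for the five template VOIs (0 is background).
REGION_NAMES = {
    1: "cortex",
    2: "hippocampus",
    3: "striatum",
    4: "thalamus",
    5: "cerebellum",
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}
CEREBELLUM = REGION_CODES["cerebellum"]


def _check_3d(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (Z, Y, X) array, got shape {data.shape}")


@dataclass
class ImageVolume:
    """Scalar 3D image (MR intensities or PET activity concentration)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_3d(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer region-code volume (codes 0..5)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label volume must hold integers")
        self.data = self.data.astype(np.uint8)
        _check_3d(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def codes(self) -> set[int]:
        return set(int(c) for c in np.unique(self.data))


@dataclass
class BinaryMask:
    """Boolean 3D mask (brain parenchyma)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_3d(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    # Array axes are (z, y, x); the affine maps voxel indices to mm.
    dz, dy, dx = spacing_mm
    return np.diag([dz, dy, dx, 1.0])


def save_volume(vol: ImageVolume | LabelVolume | BinaryMask, path: str | Path) -> Path:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or Analyze 7.5 (``.hdr``/``.img``)."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    if path.suffix in {".hdr", ".img"}:
        img = nib.AnalyzeImage(data, _affine(vol.spacing_mm))
    else:
        img = nib.Nifti1Image(data, _affine(vol.spacing_mm))
    nib.save(img, str(path))
    return path


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def load_image(path: str | Path) -> ImageVolume:
    data, spacing = _load(path)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing)


def load_labels(path: str | Path) -> LabelVolume:
    data, spacing = _load(path)
    return LabelVolume(np.rint(np.asarray(data)).astype(np.uint8), spacing)


def load_mask(path: str | Path) -> BinaryMask:
    data, spacing = _load(path)
    return BinaryMask(np.asarray(data) > 0, spacing)
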