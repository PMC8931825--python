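"""Displacement-field warping, numerical inversion, and iVOI projection.

Inverse spatial normalization (iSN) carries template-space objects — here the
five-region VOI template — into an individual brain's native space.  Fields are
dense per-voxel displacements in **voxel units**, axis order ``(dz, dy, dx)``,
0-based indices.  All warps use the pull (backward-sampling) convention::

    out(x) = vol(x + field(x))

so a field attached to direction ``forward`` (template -> individual, i.e. the
point mapping ``F(x) = x + u(x)`` sends template coordinates to individual
coordinates) must be numerically inverted before template content can be pulled
onto the individual grid.  Out-of-grid samples take the background value 0 for
both intensities and labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .core import BinaryMask, ImageVolume, LabelVolume

logger = logging.getLogger(__name__)

FORWARD = "forward"
INVERSE = "inverse"


class FieldInversionError(RuntimeError):
    """Fixed-point inversion failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = float(residual)
        super().__init__(
            f"field inversion did not converge in {max_iter} iterations "
            f"(residual {residual:.4f} voxels)"
        )


@dataclass
class DisplacementField:
    """Dense displacement field, ``vectors[z, y, x] = (dz, dy, dx)`` in voxels."""

    vectors: np.ndarray  # (Z, Y, X, 3)
    spacing_mm: tuple[float, float, float]
    direction: str = FORWARD

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"expected (Z, Y, X, 3) vectors, got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        if self.direction not in (FORWARD, INVERSE):
            raise ValueError(f"direction must be '{FORWARD}' or '{INVERSE}'")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @classmethod
    def zero(cls, grid_shape, spacing_mm, direction: str = FORWARD) -> "DisplacementField":
        return cls(np.zeros((*grid_shape, 3)), spacing_mm, direction)


def _grid_coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Identity coordinate grid, shape (3, Z, Y, X)."""
    return np.stack(
        np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    )


def _sample_field(field_vectors: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Linearly interpolate a vector field at arbitrary coordinates.

    Edge-clamped interpolation: smooth fields are extended by their border
    values, which keeps the fixed-point inversion stable near the grid edge.
    """
    return np.stack(
        [
            map_coordinates(field_vectors[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=-1,
    )


def warp_volume(vol, field: DisplacementField, interp: str = "linear"):
    """Resample a volume through a displacement field (pull convention).

    ``out(x) = vol(x + field(x))``; samples falling outside the grid read the
    background value 0.  Label volumes and masks require nearest-neighbour
    interpolation — averaging region codes is meaningless.
    """
    if isinstance(vol, LabelVolume) and interp != "nearest":
        raise ValueError("label volumes must be warped with interp='nearest'")
    if isinstance(vol, BinaryMask) and interp != "nearest":
        raise ValueError("binary masks must be warped with interp='nearest'")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.shape != field.grid_shape:
        raise ValueError(f"volume shape {vol.shape} != field grid {field.grid_shape}")

    coords = _grid_coords(vol.shape) + np.moveaxis(field.vectors, -1, 0)
    if interp == "nearest":
        # plain rounded lookup: round each sample coordinate to the nearest
        # voxel, read background 0 when the rounded index leaves the grid
        idx = np.rint(coords).astype(np.int64)
        valid = np.ones(vol.shape, dtype=bool)
        for d, n in enumerate(vol.shape):
            valid &= (idx[d] >= 0) & (idx[d] < n)
            idx[d] = np.clip(idx[d], 0, n - 1)
        if isinstance(vol, BinaryMask):
            out = np.where(valid, vol.data[tuple(idx)], False)
            return BinaryMask(out, vol.spacing_mm)
        out = np.where(valid, vol.data[tuple(idx)], 0)
        if isinstance(vol, LabelVolume):
            return LabelVolume(out.astype(np.uint8), vol.spacing_mm)
        return ImageVolume(out.astype(np.float32), vol.spacing_mm)
    out = map_coordinates(
        vol.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return ImageVolume(out.astype(np.float32), vol.spacing_mm)


def composition_residual(u: DisplacementField, g: DisplacementField) -> np.ndarray:
    """Per-voxel magnitude of ``u(x + g(x)) + g(x)`` — zero for exact inverses."""
    coords = _grid_coords(u.grid_shape) + np.moveaxis(g.vectors, -1, 0)
    u_at = _sample_field(u.vectors, coords)
    return np.linalg.norm(u_at + g.vectors, axis=-1)


def invert_field(
    field: DisplacementField, max_iter: int = 50, tol_vox: float = 0.05
) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration.

    Iterates ``v_{k+1}(x) = -u(x + v_k(x))`` from ``v_0 = 0``; converged when
    the composition residual, measured over the interior of the grid (one
    smoothness margin in from each face, where boundary extrapolation does not
    dominate), drops to ``tol_vox``.
    """
    u = field.vectors
    shape = field.grid_shape
    ident = _grid_coords(shape)
    # Interior margin: ceil of the field's max displacement, at least 1 voxel.
    margin = max(1, int(np.ceil(np.abs(u).max())))
    sl = tuple(
        slice(min(margin, s // 2), max(s - margin, s // 2 + 1)) for s in shape
    )

    v = np.zeros_like(u)
    residual = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        coords = ident + np.moveaxis(v, -1, 0)
        v_new = -_sample_field(u, coords)
        v = v_new
        res_map = composition_residual(field, DisplacementField(v, field.spacing_mm, field.direction))
        residual = float(res_map[sl].max()) if res_map[sl].size else float(res_map.max())
        if residual <= tol_vox:
            break
    if residual > tol_vox:
        raise FieldInversionError(residual, max_iter)
    logger.debug("field inversion converged in %d iterations (residual %.4g vox)", n_iter, residual)
    new_dir = INVERSE if field.direction == FORWARD else FORWARD
    return DisplacementField(v, field.spacing_mm, new_dir)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Determinant of the Jacobian of ``F(x) = x + u(x)`` at every voxel.

    Positive everywhere is the numerical certificate that the sampled mapping
    is locally invertible on the grid.
    """
    u = field.vectors
    grads = np.empty((*u.shape[:3], 3, 3))
    for c in range(3):
        gz, gy, gx = np.gradient(u[..., c])
        grads[..., c, 0] = gz
        grads[..., c, 1] = gy
        grads[..., c, 2] = gx
    grads += np.eye(3)
    return np.linalg.det(grads)


def make_ivoi_labels(
    label_template: LabelVolume,
    forward_field: DisplacementField,
    max_iter: int = 50,
    tol_vox: float = 0.05,
) -> LabelVolume:
    """Project the VOI template into an individual brain space (the iSN step).

    The forward field maps template coordinates onto the individual brain; pull
    resampling onto the individual grid therefore needs its numerical inverse.
    Nearest-neighbour interpolation keeps region codes intact: the output code
    set is always a subset of the template's.
    """
    if forward_field.direction != FORWARD:
        raise ValueError("make_ivoi_labels requires a forward (template->individual) field")
    inv = invert_field(forward_field, max_iter=max_iter, tol_vox=tol_vox)
    return warp_volume(label_template, inv, interp="nearest")


def save_field(field: DisplacementField, path: str | Path) -> Path:
    """Serialize as 4D NIfTI (vector dimension last) plus a JSON sidecar."""
    path = Path(path)
    dz, dy, dx = field.spacing_mm
    img = nib.Nifti1Image(field.vectors.astype(np.float32), np.diag([dz, dy, dx, 1.0]))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = sidecar.parent / (sidecar.name + ".json")
    sidecar.write_text(
        json.dumps({"direction": field.direction, "units": "voxels", "axis_order": "zyx"})
    )
    return path


def load_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    vectors = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    direction = FORWARD
    if sidecar.exists():
        direction = json.loads(sidecar.read_text()).get("direction", FORWARD)
    return DisplacementField(vectors, tuple(float(z) for z in zooms), direction)
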