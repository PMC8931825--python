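"""Morphological regularization of raw network probability maps.

The cleanup chain is: threshold -> morphological opening (erosion then
dilation, removing speck false positives) -> kill-islands (keep only the
largest 3D connected component) -> fill-holes (turn enclosed background into
foreground, removing interior false negatives).  After the full chain a mask
always has exactly one connected component and no interior holes.

For multi-class label maps the chain runs per foreground class on the argmax
map; voxels a class loses stay background, so mutual exclusivity is preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, LabelVolume

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),  # face connectivity
    26: ndimage.generate_binary_structure(3, 3),  # face+edge+corner
}


class EmptyMaskError(ValueError):
    """Raised when a cleanup step is handed nothing to keep."""


def _struct(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    return _STRUCTS[connectivity]


def binarize(prob: np.ndarray, threshold: float = 0.5, spacing_mm=(1.0, 1.0, 1.0)):
    """Threshold a probability volume (``>= threshold`` is foreground).

    A 4D input is treated as a per-class probability map and reduced by argmax
    (ties break to the lowest class code), yielding a label volume.
    """
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if prob.ndim == 4:
        return LabelVolume(prob.argmax(axis=-1).astype(np.uint8), spacing_mm)
    if prob.ndim != 3:
        raise ValueError(f"expected a 3D or 4D probability map, got shape {prob.shape}")
    return BinaryMask(prob >= threshold, spacing_mm)


def morph_open(mask: BinaryMask, radius_vox: int = 1) -> BinaryMask:
    """Erosion then dilation with a full 3x3x3 box element (idempotent).

    The box element leaves large solid shapes (including their corners)
    untouched while erasing specks thinner than ``2*radius_vox + 1``.
    """
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    opened = ndimage.binary_opening(
        mask.data, structure=np.ones((3, 3, 3), bool), iterations=radius_vox
    )
    return BinaryMask(opened, mask.spacing_mm)


def kill_islands(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Keep only the largest 3D connected component.

    Equal-sized candidates tie-break to the component containing the
    lexicographically smallest (z, y, x) voxel.
    """
    if not mask.data.any():
        raise EmptyMaskError("kill_islands: mask is empty, nothing to keep")
    labeled, n = ndimage.label(mask.data, structure=_struct(connectivity))
    if n == 1:
        return BinaryMask(mask.data.copy(), mask.spacing_mm)
    sizes = np.bincount(labeled.ravel())[1:]
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labeled.ravel()
        keep = min(candidates, key=lambda lab: int(np.flatnonzero(flat == lab)[0]))
    return BinaryMask(labeled == keep, mask.spacing_mm)


def fill_holes(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Set background components not connected to the volume border to true."""
    filled = ndimage.binary_fill_holes(mask.data, structure=_struct(connectivity))
    return BinaryMask(filled, mask.spacing_mm)


def postprocess_chain(
    prob: np.ndarray,
    task: str = "mask",
    threshold: float = 0.5,
    open_radius: int = 1,
    connectivity: int = 6,
    spacing_mm=(1.0, 1.0, 1.0),
):
    """Full cleanup: binarize -> open -> kill-islands -> fill-holes.

    ``task='mask'`` takes a 3D probability volume and returns a
    :class:`BinaryMask`; ``task='ivoi'`` takes a 4D per-class map, argmaxes it
    and applies the chain to every foreground class, returning a
    :class:`LabelVolume`.  An empty class raises :class:`EmptyMaskError`
    naming the class.
    """
    if task == "mask":
        m = binarize(prob, threshold, spacing_mm)
        m = morph_open(m, open_radius)
        if not m.data.any():
            raise EmptyMaskError("postprocess_chain: mask empty after opening")
        m = kill_islands(m, connectivity)
        return fill_holes(m, connectivity)
    if task == "ivoi":
        labels = binarize(prob, threshold, spacing_mm)
        out = np.zeros_like(labels.data)
        for code in range(1, int(prob.shape[-1])):
            cls = BinaryMask(labels.data == code, spacing_mm)
            if not cls.data.any():
                raise EmptyMaskError(f"postprocess_chain: class {code} predicted empty")
            cls = morph_open(cls, open_radius)
            if not cls.data.any():
                raise EmptyMaskError(f"postprocess_chain: class {code} empty after opening")
            cls = kill_islands(cls, connectivity)
            cls = fill_holes(cls, connectivity)
            # argmax classes are disjoint; opening/kill only shrink, and
            # fill-holes can only reclaim voxels interior to this class
            out[cls.data & (out == 0)] = code
        return LabelVolume(out, spacing_mm)
    raise ValueError(f"unknown task {task!r}")
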