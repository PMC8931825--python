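"""Segmentation-agreement metrics: DSC, ASSD, SEN, SPE, PPV, and Lin's CCC.

Conventions:

* Voxelwise counts come from the whole grid, so SPE depends on the field of
  view (as it does whenever masks are compared on full volumes).
* Boundary voxels are mask voxels with at least one face-adjacent (6-connected)
  background neighbour; the volume border counts as background, so a mask
  touching the edge still has a boundary there and a single voxel is its own
  boundary.
* Surface distances are Euclidean, voxel centre to voxel centre, in mm using
  the grid spacing.
* A both-empty mask pair has DSC 1.0 (perfect agreement on absence), reported
  with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegScores:
    """Per-structure agreement between a predicted and a reference mask."""

    structure: str
    dsc: float
    assd_mm: float
    sen: float
    spe: float
    ppv: float


def _as_bool(m) -> np.ndarray:
    return m.data if isinstance(m, BinaryMask) else np.asarray(m).astype(bool)


def confusion(pred, ref) -> ConfusionCounts:
    """Voxelwise TP/FP/TN/FN counts over the whole grid."""
    p, g = _as_bool(pred), _as_bool(ref)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dsc(pred, ref) -> float:
    """Dice similarity coefficient, 2|P n G| / (|P| + |G|)."""
    p, g = _as_bool(pred), _as_bool(ref)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        warnings.warn("DSC of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.count_nonzero(p & g) / denom)


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when there are no reference positives."""
    d = counts.tp + counts.fn
    return counts.tp / d if d else None


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when there are no reference negatives."""
    d = counts.tn + counts.fp
    return counts.tn / d if d else None


def ppv(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FP); None when nothing was predicted positive."""
    d = counts.tp + counts.fp
    return counts.tp / d if d else None


def boundary(mask) -> np.ndarray:
    """Mask voxels with a face-adjacent background neighbour (border = background)."""
    m = _as_bool(mask)
    interior = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    # binary_erosion with border_value=0 treats the volume border as background
    return m & ~interior


def assd(pred, ref, spacing_mm) -> float:
    """Average symmetric surface distance in mm.

    Mean over both boundaries of each boundary voxel's Euclidean distance to
    the nearest voxel of the other boundary.
    """
    p, g = _as_bool(pred), _as_bool(ref)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        raise ValueError("ASSD undefined for an empty mask")
    bp, bg = boundary(p), boundary(g)
    # distance_transform_edt gives each voxel's distance to the nearest zero
    d_to_g = ndimage.distance_transform_edt(~bg, sampling=spacing_mm)
    d_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing_mm)
    total = d_to_g[bp].sum() + d_to_p[bg].sum()
    return float(total / (np.count_nonzero(bp) + np.count_nonzero(bg)))


def score_masks(pred, ref, spacing_mm, structure: str = "brain_mask") -> SegScores:
    """All five agreement scores for one predicted/reference mask pair."""
    counts = confusion(pred, ref)
    return SegScores(
        structure=structure,
        dsc=dsc(pred, ref),
        assd_mm=assd(pred, ref, spacing_mm),
        sen=sensitivity(counts),
        spe=specificity(counts),
        ppv=ppv(counts),
    )


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2); penalizes both
    scatter and location/scale shift, so |CCC| <= |Pearson r|.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ccc expects two equal-length 1D vectors")
    if x.size < 2:
        raise ValueError("ccc needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("ccc undefined: zero variance and equal means")
    return float(2.0 * np.mean((x - mx) * (y - my)) / denom)
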