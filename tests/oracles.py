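"""Brute-force reference implementations used only by the test suite.

Each oracle states the defining formula as directly (and slowly) as possible:
explicit loops, exhaustive pairwise distances, BFS component labelling.  They
deliberately share no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def confusion_oracle(p: np.ndarray, g: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for idx in np.ndindex(p.shape):
        if p[idx] and g[idx]:
            tp += 1
        elif p[idx] and not g[idx]:
            fp += 1
        elif not p[idx] and g[idx]:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def dsc_oracle(p: np.ndarray, g: np.ndarray) -> float:
    inter = sum(1 for idx in np.ndindex(p.shape) if p[idx] and g[idx])
    return 2.0 * inter / (p.sum() + g.sum())


def boundary_oracle(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Mask voxels with a face-adjacent background neighbour (border = background)."""
    out = []
    shape = mask.shape
    for z, y, x in np.ndindex(shape):
        if not mask[z, y, x]:
            continue
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                out.append((z, y, x))
                break
            if not mask[nz, ny, nx]:
                out.append((z, y, x))
                break
    return out


def assd_oracle(p: np.ndarray, g: np.ndarray, spacing) -> float:
    """Exhaustive all-pairs average symmetric surface distance."""
    bp = boundary_oracle(p)
    bg = boundary_oracle(g)
    sp = np.asarray(spacing, dtype=float)

    def min_dist(v, others):
        v_mm = np.asarray(v) * sp
        return min(np.linalg.norm(v_mm - np.asarray(o) * sp) for o in others)

    total = sum(min_dist(v, bg) for v in bp) + sum(min_dist(v, bp) for v in bg)
    return total / (len(bp) + len(bg))


def ccc_oracle(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    return 2 * cov / (((x - mx) ** 2).mean() + ((y - my) ** 2).mean() + (mx - my) ** 2)


_FACE_NEIGHBOURS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def components_oracle(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """BFS 6-connected component labelling."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in np.ndindex(mask.shape):
        if not mask[start] or seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in _FACE_NEIGHBOURS:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) and mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(comp)
    return comps


_BOX_NEIGHBOURS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def erosion_oracle(mask: np.ndarray) -> np.ndarray:
    """3x3x3 box erosion; border treated as background."""
    out = np.zeros_like(mask)
    for z, y, x in np.ndindex(mask.shape):
        if not mask[z, y, x]:
            continue
        keep = True
        for dz, dy, dx in _BOX_NEIGHBOURS:
            n = (z + dz, y + dy, x + dx)
            if not all(0 <= n[i] < mask.shape[i] for i in range(3)) or not mask[n]:
                keep = False
                break
        out[z, y, x] = keep
    return out


def dilation_oracle(mask: np.ndarray) -> np.ndarray:
    """3x3x3 box dilation."""
    out = mask.copy()
    for z, y, x in np.ndindex(mask.shape):
        if mask[z, y, x]:
            continue
        for dz, dy, dx in _BOX_NEIGHBOURS:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= n[i] < mask.shape[i] for i in range(3)) and mask[n]:
                out[z, y, x] = True
                break
    return out


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Flood-fill background from the border; unreached background becomes true."""
    outside = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for idx in np.ndindex(mask.shape):
        if any(idx[i] in (0, mask.shape[i] - 1) for i in range(3)) and not mask[idx]:
            outside[idx] = True
            queue.append(idx)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in _FACE_NEIGHBOURS:
            n = (z + dz, y + dy, x + dx)
            if (
                all(0 <= n[i] < mask.shape[i] for i in range(3))
                and not mask[n]
                and not outside[n]
            ):
                outside[n] = True
                queue.append(n)
    return mask | ~outside


def nearest_warp_oracle(vol: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Per-voxel pull resample with round-half-to-even nearest lookup."""
    out = np.zeros_like(vol)
    shape = vol.shape
    for z, y, x in np.ndindex(shape):
        src = np.array([z, y, x], dtype=float) + field[z, y, x]
        idx = np.rint(src).astype(int)
        if all(0 <= idx[i] < shape[i] for i in range(3)):
            out[z, y, x] = vol[tuple(idx)]
    return out
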