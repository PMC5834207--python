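"""Confocal-like rendering of snapshots.

Each segment endpoint deposits intensity 1.0 into its voxel and a smaller
weight (default 0.3) into the immediately neighbouring voxels; summing the
stack along z gives a projection resembling a confocal z-projection.  The
axial voxel extent is typically ~10x the lateral extent, mimicking the
anisotropic resolution of a confocal microscope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RenderSpec:
    resolution: tuple = (128, 128, 16)   # (r_x, r_y, r_z) voxel counts
    neighbor_weight: float = 0.3
    neighborhood: int = 6                # 6 face-adjacent or 26 neighbours

    def __post_init__(self):
        if any(r < 1 for r in self.resolution):
            raise ValueError("voxel counts must be >= 1")
        if self.neighbor_weight < 0:
            raise ValueError("neighbor weight must be >= 0")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")


def default_bounds(snapshot, margin: float = 0.1):
    pos = snapshot.positions
    if len(pos) == 0:
        return np.zeros(3), np.ones(3)
    return pos.min(axis=0) - margin, pos.max(axis=0) + margin


def voxelize(snapshot, spec: RenderSpec, bounds) -> np.ndarray:
    """Intensity stack of shape ``spec.resolution`` (x, y, z).

    Segments outside ``bounds`` are clipped into the boundary voxels with a
    warning.  Total intensity equals
    ``n_segments + weight * (neighbour increments inside the stack)``.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    res = np.asarray(spec.resolution, dtype=int)
    stack = np.zeros(tuple(res), dtype=np.float64)
    pos = snapshot.positions
    if len(pos) == 0:
        return stack
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.floor((pos - lo) / span * res).astype(int)
    n_out = int(np.any((idx < 0) | (idx >= res), axis=1).sum())
    if n_out:
        warnings.warn(f"{n_out} segments outside render bounds were clipped")
        idx = np.clip(idx, 0, res - 1)
    base = np.zeros_like(stack)
    np.add.at(base, tuple(idx.T), 1.0)
    stack += base
    if spec.neighborhood == 6:
        shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1)]
    else:
        shifts = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                  for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    w = spec.neighbor_weight
    for sx, sy, sz in shifts:
        src = [slice(max(0, -sx), res[0] - max(0, sx)),
               slice(max(0, -sy), res[1] - max(0, sy)),
               slice(max(0, -sz), res[2] - max(0, sz))]
        dst = [slice(max(0, sx), res[0] - max(0, -sx)),
               slice(max(0, sy), res[1] - max(0, -sy)),
               slice(max(0, sz), res[2] - max(0, -sz))]
        stack[tuple(dst)] += w * base[tuple(src)]
    return stack


def z_project(stack: np.ndarray) -> np.ndarray:
    """Sum the stack along the z axis; total intensity is conserved."""
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack")
    return stack.sum(axis=2)


def save_stack(stack: np.ndarray, path) -> None:
    """Write a multi-page 32-bit float TIFF (pages along z)."""
    import tifffile
    tifffile.imwrite(str(path),
                     np.ascontiguousarray(
                         np.moveaxis(stack.astype(np.float32), 2, 0)),
                     photometric="minisblack")


def save_projection(image: np.ndarray, path) -> None:
    """Write a projection as TIFF (float) or PNG (normalized 8-bit)."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, image.astype(np.float32))
    elif path.endswith(".png"):
        from PIL import Image
        peak = image.max()
        scaled = (255 * image / peak).astype(np.uint8) if peak > 0 \
            else np.zeros_like(image, dtype=np.uint8)
        Image.fromarray(scaled.T[::-1]).save(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
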