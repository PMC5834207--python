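"""Quantification of microtubule networks.

Implements the nematic order parameter over a spatial grid of cubes, the
bundled-tubulin fraction, mean segment-to-membrane distance, per-face
orientation histograms and cue-axis alignment histograms, plus simple
network summaries.  All functions take a :class:`~cmtsim.engine.Snapshot`
(or bare arrays where noted) and return plain dataclasses / floats so the
results drop straight into tidy tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class MetricError(ValueError):
    pass


@dataclass
class AnisotropyResult:
    """Local nematic anisotropy per cube plus the cell average.

    For the directions D (N×3, unit rows) in one cube, M = DᵀD/N has
    eigenvalues λ₁..λ₃ summing to 1, and
    A = sqrt(3/2 · Σ(λᵢ−λ_m)² / Σλᵢ²) ∈ [0, 1].
    """

    grid_shape: tuple
    cube_anisotropy: np.ndarray      # (n_cubes,), NaN where empty
    cube_eigenvalues: np.ndarray     # (n_cubes, 3)
    cube_counts: np.ndarray          # (n_cubes,)
    cell_average: float


@dataclass
class OrientationHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    reference_axis: np.ndarray
    selection: str
    values: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.counts.sum())

    @property
    def modal_bins(self) -> np.ndarray:
        """Centers of the bins attaining the maximal count."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return centers[self.counts == self.counts.max()]


def local_anisotropy(directions: np.ndarray) -> float:
    """Nematic order parameter of a set of unit direction vectors."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.size == 0:
        raise MetricError("anisotropy of an empty direction set is undefined")
    m = d.T @ d / len(d)
    lam = np.linalg.eigvalsh(m)
    lm = lam.mean()
    denom = float(np.sum(lam ** 2))
    if denom <= 0:
        raise MetricError("degenerate direction set")
    return float(np.sqrt(1.5 * np.sum((lam - lm) ** 2) / denom))


def grid_anisotropy(snapshot, bounds, n_cubes: int = 27) -> AnisotropyResult:
    """Cube-grid anisotropy: the bounding box is split into ~``n_cubes``
    axis-aligned cubes (3×3×3 by default); the cell average runs over the
    non-empty cubes.

    ``bounds`` is ``(lo, hi)`` arrays or an object with ``.bounds`` (a
    trimesh/CellSurface mesh), so the grid covers the cell, not just the
    occupied region.
    """
    if hasattr(bounds, "mesh"):
        bounds = bounds.mesh.bounds
    elif hasattr(bounds, "bounds"):
        bounds = bounds.bounds
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    k = max(1, round(n_cubes ** (1 / 3)))
    pos = snapshot.positions
    dirs = snapshot.directions
    if len(pos) == 0:
        raise MetricError("empty snapshot")
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.clip(((pos - lo) / span * k).astype(int), 0, k - 1)
    flat = (idx[:, 0] * k + idx[:, 1]) * k + idx[:, 2]
    ncub = k ** 3
    a = np.full(ncub, np.nan)
    eig = np.full((ncub, 3), np.nan)
    counts = np.bincount(flat, minlength=ncub)
    for c in np.nonzero(counts)[0]:
        d = dirs[flat == c]
        m = d.T @ d / len(d)
        lam = np.linalg.eigvalsh(m)
        eig[c] = lam
        lm = lam.mean()
        a[c] = math.sqrt(1.5 * np.sum((lam - lm) ** 2) / np.sum(lam ** 2))
    occupied = ~np.isnan(a)
    if not occupied.any():
        raise MetricError("all cubes empty")
    return AnisotropyResult(grid_shape=(k, k, k), cube_anisotropy=a,
                            cube_eigenvalues=eig, cube_counts=counts,
                            cell_average=float(np.nanmean(a)))


def bundle_fraction(snapshot, dist_thresh: float = 0.025,
                    angle_thresh_deg: float = 40.0) -> float:
    """Fraction of tubulin segments in bundles.

    A segment is bundled if a segment of a *different* microtubule lies
    within ``dist_thresh`` (endpoint to endpoint) at a line angle at most
    ``angle_thresh_deg`` — the same geometry that drives zippering.
    """
    pos = snapshot.positions
    n = len(pos)
    if n == 0:
        raise MetricError("empty snapshot")
    cos_t = math.cos(math.radians(angle_thresh_deg))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(dist_thresh, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    keep = snapshot.mt_id[i] != snapshot.mt_id[j]
    i, j = i[keep], j[keep]
    cos_ij = np.abs(np.einsum("ij,ij->i", snapshot.directions[i],
                              snapshot.directions[j]))
    keep = cos_ij >= cos_t
    bundled = np.zeros(n, dtype=bool)
    bundled[i[keep]] = True
    bundled[j[keep]] = True
    return float(bundled.mean())


def mean_membrane_distance(snapshot, surface, per_microtubule: bool = False,
                           ) -> float:
    """Mean nearest-surface distance of segment endpoints, in nm.

    With ``per_microtubule=True`` the per-filament means are averaged
    instead of pooling all segments.
    """
    if snapshot.n_segments == 0:
        raise MetricError("empty snapshot")
    dist_um = surface.distances(snapshot.positions)
    if per_microtubule:
        df = pd.DataFrame({"mt": snapshot.mt_id, "d": dist_um})
        return float(df.groupby("mt")["d"].mean().mean() * 1e3)
    return float(dist_um.mean() * 1e3)


def face_orientation_histogram(snapshot, surface_or_mesh, face_normal,
                               ref_axis, band: float = 0.5,
                               bins: int = 36) -> OrientationHistogram:
    """Orientation of segments near one planar face.

    Selects segments whose endpoint lies within ``band`` (μm) of the
    supporting plane of the face with outward ``face_normal``; projects
    their directions onto the face plane and histograms the signed line
    angle to ``ref_axis``, folded into (−90°, 90°].
    """
    n = np.asarray(face_normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.asarray(ref_axis, dtype=float)
    a = a - (a @ n) * n
    if np.linalg.norm(a) < 1e-9:
        raise MetricError("reference axis must not be parallel to the "
                          "face normal")
    a = a / np.linalg.norm(a)
    mesh = getattr(surface_or_mesh, "mesh", surface_or_mesh)
    verts = np.asarray(mesh.vertices if hasattr(mesh, "vertices") else mesh,
                       dtype=float)
    plane_off = float((verts @ n).max())
    b = np.cross(n, a)
    pos = snapshot.positions
    sel = (plane_off - pos @ n) <= band
    d = snapshot.directions[sel]
    edges = np.linspace(-90.0, 90.0, bins + 1)
    if len(d) == 0:
        return OrientationHistogram(bin_edges=edges,
                                    counts=np.zeros(bins, dtype=int),
                                    reference_axis=a, selection="empty",
                                    values=np.empty(0))
    x = d @ a
    y = d @ b
    ang = np.degrees(np.arctan2(y, x))
    ang = (ang + 90.0) % 180.0 - 90.0       # fold lines into (-90, 90]
    ang[ang == -90.0] = 90.0
    counts, _ = np.histogram(ang, bins=edges)
    return OrientationHistogram(bin_edges=edges, counts=counts,
                                reference_axis=a,
                                selection=f"face band {band} um",
                                values=ang)


def axis_alignment_values(snapshot, long_axis) -> np.ndarray:
    """|r·axis| for every segment (nematic alignment with the long axis)."""
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.abs(snapshot.directions @ axis)


def axis_alignment_histogram(snapshot, long_axis,
                             bins: int = 20) -> OrientationHistogram:
    """Histogram of |r·axis| over [0, 1] for all segments."""
    vals = axis_alignment_values(snapshot, long_axis)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    axis = np.asarray(long_axis, dtype=float)
    return OrientationHistogram(bin_edges=edges, counts=counts,
                                reference_axis=axis / np.linalg.norm(axis),
                                selection="whole cell", values=vals)


def network_summary(snapshot) -> tuple:
    """(number of microtubules, mean length in μm, total segments)."""
    n_seg = snapshot.n_segments
    if n_seg == 0:
        return 0, 0.0, 0
    _, counts = np.unique(snapshot.mt_id, return_counts=True)
    ell = 0.008
    return int(len(counts)), float(counts.mean() * ell), int(n_seg)


def snapshot_metrics(snapshot, surface, long_axis=None) -> dict:
    """All scalar metrics of one snapshot as a flat dict (tidy-table row)."""
    n_mt, mean_len, n_seg = network_summary(snapshot)
    row = {"step": snapshot.step, "n_microtubules": n_mt,
           "mean_length_um": mean_len, "total_segments": n_seg}
    if n_seg:
        row["mean_membrane_distance_nm"] = mean_membrane_distance(snapshot,
                                                                  surface)
        row["bundle_fraction"] = bundle_fraction(snapshot)
        row["anisotropy"] = grid_anisotropy(snapshot, surface).cell_average
        if long_axis is not None:
            row["median_axis_alignment"] = float(
                np.median(axis_alignment_values(snapshot, long_axis)))
    return row


def metrics_table(rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows))
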