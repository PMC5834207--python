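"""Cell-surface geometry: shape generation, nearest-point queries, sampling.

The cell envelope is a closed, watertight triangular mesh with outward unit
vertex normals.  The standard cell shapes are rounded boxes (the Minkowski sum
of a shrunken box and a sphere of the corner radius, so the minimal radius of
curvature equals the corner radius by construction) and ellipsoids of
revolution.  :class:`CellSurface` wraps a mesh together with a uniform
triangle grid that backs exact nearest-point/normal/distance queries, both
for analysis and for the simulation kernel.

Units are micrometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from . import _kernels


class GeometryError(ValueError):
    """Degenerate or invalid mesh/query."""


class InvalidShapeError(ValueError):
    """Shape parameters violate their constraints."""


#: full extents (μm) of the standard cell shapes
STANDARD_SHAPES = {
    "cube": (8.8, 8.8, 8.8),
    "square": (9.0, 9.0, 4.7),
    "long": (4.8, 4.8, 15.6),
}
#: minimal radius of curvature (μm) for the sharp / smooth variants
SHARP_RADIUS = 1.3
SMOOTH_RADIUS = 4.7
#: full axis lengths (μm) of the ellipsoid used for cue experiments
ELLIPSOID_AXES = (10.3, 10.3, 16.8)

DEFAULT_MESH_RESOLUTION = 0.4  # μm target edge length (>=10 tris per 1.3 μm radius)


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a cell envelope.

    dimensions are full extents: box side lengths or ellipsoid axis lengths.
    """

    kind: str  # "rounded_box" | "ellipsoid"
    dimensions: tuple[float, float, float]
    corner_radius: float = 0.0
    mesh_resolution: float = DEFAULT_MESH_RESOLUTION

    def __post_init__(self):
        if self.kind not in ("rounded_box", "ellipsoid"):
            raise InvalidShapeError(f"unknown shape kind {self.kind!r}")
        dims = np.asarray(self.dimensions, dtype=float)
        if dims.shape != (3,) or np.any(dims <= 0):
            raise InvalidShapeError("dimensions must be three positive lengths")
        if self.mesh_resolution <= 0:
            raise InvalidShapeError("mesh_resolution must be positive")
        if self.kind == "rounded_box":
            if self.corner_radius < 0:
                raise InvalidShapeError("corner_radius must be >= 0")
            if self.corner_radius > dims.min() / 2 + 1e-12:
                raise InvalidShapeError(
                    "corner_radius exceeds half of the smallest dimension")
        else:
            # ellipsoid of revolution: two of the three axes must be equal
            d = sorted(dims)
            if not (math.isclose(d[0], d[1], rel_tol=1e-9)
                    or math.isclose(d[1], d[2], rel_tol=1e-9)):
                raise InvalidShapeError(
                    "ellipsoid must be a solid of revolution "
                    "(two equal axis lengths)")


@dataclass(frozen=True)
class SurfaceProbe:
    """Result of a nearest-surface query for one point."""

    nearest_point: np.ndarray
    normal: np.ndarray
    distance: float
    inside: bool


def standard_shape_spec(name: str, variant: str = "sharp",
                     mesh_resolution: float = DEFAULT_MESH_RESOLUTION) -> ShapeSpec:
    """Spec for one of the standard cell shapes.

    ``name`` is cube/square/long/ellipsoid; ``variant`` selects the sharp
    (1.3 μm) or smooth (4.7 μm) minimal curvature radius.  Where the nominal
    smooth radius exceeds half the smallest box dimension (square, long, and
    marginally the cube) the radius is capped at that bound, the largest
    rounding for which the shape exists.
    """
    if name == "ellipsoid":
        return ShapeSpec("ellipsoid", ELLIPSOID_AXES,
                         mesh_resolution=mesh_resolution)
    if name not in STANDARD_SHAPES:
        raise InvalidShapeError(f"unknown shape name {name!r}")
    if variant not in ("sharp", "smooth"):
        raise InvalidShapeError(f"unknown variant {variant!r}")
    dims = STANDARD_SHAPES[name]
    radius = SHARP_RADIUS if variant == "sharp" else SMOOTH_RADIUS
    radius = min(radius, min(dims) / 2)
    return ShapeSpec("rounded_box", dims, corner_radius=radius,
                     mesh_resolution=mesh_resolution)


def build_rounded_box(spec: ShapeSpec) -> trimesh.Trimesh:
    """Triangulate a box with rounded edges/corners.

    A subdivided box of the full extents is projected onto the offset surface
    of the inner (shrunken) box: every vertex maps to
    ``clamp(v, inner) + r * unit(v - clamp(v, inner))``, which is exactly the
    Minkowski-sum surface, so the minimal curvature radius equals
    ``corner_radius``.  Vertex normals are the exact offset directions.
    """
    if spec.kind != "rounded_box":
        raise InvalidShapeError("spec.kind must be 'rounded_box'")
    dims = np.asarray(spec.dimensions, dtype=float)
    base = trimesh.creation.box(extents=dims)
    mesh = base.subdivide_to_size(max_edge=spec.mesh_resolution)
    r = spec.corner_radius
    if r <= 0.0:
        out = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                              faces=mesh.faces.copy(), process=False)
        return out
    inner = dims / 2 - r
    v = np.asarray(mesh.vertices, dtype=float)
    q = np.clip(v, -inner, inner)
    d = v - q
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm < 1e-12):  # pragma: no cover - surface vertices only
        raise GeometryError("degenerate vertex in rounded-box projection")
    n = d / norm[:, None]
    out = trimesh.Trimesh(vertices=q + r * n, faces=mesh.faces.copy(),
                          process=False)
    out.vertex_normals = n
    return out


def build_ellipsoid(spec: ShapeSpec) -> trimesh.Trimesh:
    """Triangulate an ellipsoid of revolution (icosphere scaled by semi-axes).

    Vertex normals are the analytic ellipsoid normals.
    """
    if spec.kind != "ellipsoid":
        raise InvalidShapeError("spec.kind must be 'ellipsoid'")
    semi = np.asarray(spec.dimensions, dtype=float) / 2
    # icosahedron edge ~1.05 for unit circumradius, halved per subdivision
    subdiv = max(2, math.ceil(math.log2(1.06 * semi.max()
                                        / spec.mesh_resolution)))
    ico = trimesh.creation.icosphere(subdivisions=subdiv)
    v = np.asarray(ico.vertices, dtype=float) * semi
    n = v / semi ** 2
    n /= np.linalg.norm(n, axis=1)[:, None]
    out = trimesh.Trimesh(vertices=v, faces=ico.faces.copy(), process=False)
    out.vertex_normals = n
    return out


def build_shape(spec: ShapeSpec) -> trimesh.Trimesh:
    if spec.kind == "rounded_box":
        return build_rounded_box(spec)
    return build_ellipsoid(spec)


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area (μm²): the sum of triangle areas."""
    return float(mesh.area)


def load_mesh(path) -> trimesh.Trimesh:
    """Read an OBJ/PLY mesh; vertex normals are recomputed if absent."""
    mesh = trimesh.load(path, force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise GeometryError(f"no triangle mesh in {path}")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write OBJ or PLY (chosen by extension) including vertex normals."""
    path = str(path)
    if path.endswith(".ply"):
        data = trimesh.exchange.ply.export_ply(mesh, encoding="binary")
        with open(path, "wb") as fh:
            fh.write(data)
    elif path.endswith(".obj"):
        text = trimesh.exchange.obj.export_obj(mesh, include_normals=True)
        with open(path, "w") as fh:
            fh.write(text)
    else:
        raise GeometryError(f"unsupported mesh format: {path}")


class CellSurface:
    """A closed cell envelope with accelerated nearest-point queries.

    Wraps a watertight triangle mesh; builds a uniform grid binning each
    triangle into every grid cell overlapped by its bounding box.  Queries
    expand ring by ring from the query point's cell, which yields the exact
    nearest triangle (verified against brute force in the test suite).
    """

    def __init__(self, mesh: trimesh.Trimesh, grid_cell: float | None = None,
                 validate: bool = True):
        if validate:
            if len(mesh.faces) == 0:
                raise GeometryError("empty mesh")
            if not mesh.is_watertight:
                raise GeometryError("mesh is not watertight")
        self.mesh = mesh
        faces = np.asarray(mesh.faces, dtype=np.int64)
        verts = np.asarray(mesh.vertices, dtype=np.float64)
        vn = np.asarray(mesh.vertex_normals, dtype=np.float64)
        # orient vertex normals outward (positive dot with centroid ray)
        centroid = verts.mean(axis=0)
        flip = np.einsum("ij,ij->i", vn, verts - centroid) < 0
        vn = vn.copy()
        vn[flip] *= -1
        self.triangles = verts[faces]  # (F, 3, 3)
        self._TV = np.ascontiguousarray(
            self.triangles.reshape(-1, 9).astype(np.float64))
        self._VN = np.ascontiguousarray(vn[faces].reshape(-1, 9))
        areas = np.asarray(mesh.area_faces, dtype=np.float64)
        total = areas.sum()
        if total <= 0:
            raise GeometryError("mesh has zero surface area")
        self.area = float(total)
        self._cum_area = np.cumsum(areas) / total

        edges = verts[faces[:, [0, 1, 2]]] - verts[faces[:, [1, 2, 0]]]
        mean_edge = float(np.linalg.norm(edges, axis=2).mean())
        self.grid_cell = float(grid_cell) if grid_cell else max(2 * mean_edge,
                                                                1e-3)
        self._build_grid()

    def _build_grid(self):
        tv = self.triangles
        lo = tv.min(axis=(0, 1)) - 1e-9
        hi = tv.max(axis=(0, 1)) + 1e-9
        cell = self.grid_cell
        dims = np.maximum(np.ceil((hi - lo) / cell).astype(np.int64), 1)
        self._glo = lo.astype(np.float64)
        self._gdims = dims
        self._inv_cell = 1.0 / cell
        tlo = np.floor((tv.min(axis=1) - lo) / cell).astype(np.int64)
        thi = np.floor((tv.max(axis=1) - lo) / cell).astype(np.int64)
        tlo = np.clip(tlo, 0, dims - 1)
        thi = np.clip(thi, 0, dims - 1)
        spans = thi - tlo + 1
        counts_per_tri = spans.prod(axis=1)
        n_entries = int(counts_per_tri.sum())
        ncells = int(dims.prod())
        cell_of = np.empty(n_entries, dtype=np.int64)
        tri_of = np.empty(n_entries, dtype=np.int64)
        k = 0
        ny, nz = int(dims[1]), int(dims[2])
        for t in range(len(tv)):
            for ix in range(tlo[t, 0], thi[t, 0] + 1):
                for iy in range(tlo[t, 1], thi[t, 1] + 1):
                    base = (ix * ny + iy) * nz
                    for iz in range(tlo[t, 2], thi[t, 2] + 1):
                        cell_of[k] = base + iz
                        tri_of[k] = t
                        k += 1
        order = np.argsort(cell_of, kind="stable")
        cell_of = cell_of[order]
        self._ctris = tri_of[order].astype(np.int64)
        self._cstart = np.zeros(ncells + 1, dtype=np.int64)
        np.add.at(self._cstart, cell_of + 1, 1)
        np.cumsum(self._cstart, out=self._cstart)

    # -- kernel plumbing ---------------------------------------------------

    @property
    def kernel_args(self):
        d = self._gdims
        return (self._TV, self._VN, self._glo, self._inv_cell, self.grid_cell,
                int(d[0]), int(d[1]), int(d[2]), self._cstart, self._ctris,
                self._cum_area)

    # -- queries -----------------------------------------------------------

    def probe_points(self, points: np.ndarray):
        """Nearest point, outward normal, distance and signed offset.

        Returns ``(nearest (n,3), normal (n,3), distance (n,), signed (n,))``
        where ``signed < 0`` means inside.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        near = np.empty((n, 3))
        norm = np.empty((n, 3))
        dist = np.empty(n)
        sign = np.empty(n)
        d = self._gdims
        _kernels.probe_points(pts, self._TV, self._VN, self._glo,
                              self._inv_cell, self.grid_cell,
                              int(d[0]), int(d[1]), int(d[2]),
                              self._cstart, self._ctris,
                              near, norm, dist, sign)
        return near, norm, dist, sign

    def probe(self, point) -> SurfaceProbe:
        near, norm, dist, sign = self.probe_points(np.asarray(point))
        return SurfaceProbe(nearest_point=near[0], normal=norm[0],
                            distance=float(dist[0]),
                            inside=bool(sign[0] <= 1e-9))

    def contains(self, points) -> np.ndarray:
        _, _, _, sign = self.probe_points(points)
        return sign <= 1e-9

    def distances(self, points) -> np.ndarray:
        _, _, dist, _ = self.probe_points(points)
        return dist

    def sample(self, n: int, rng: np.random.Generator):
        """``n`` points uniform per unit area, with interpolated normals."""
        u = rng.random((n, 3))
        pos = np.empty((n, 3))
        norm = np.empty((n, 3))
        _kernels.sample_surface(u, self._TV, self._VN, self._cum_area,
                                pos, norm)
        return pos, norm


def nearest_surface(surface, point) -> SurfaceProbe:
    """Nearest-point query against a :class:`CellSurface` or raw mesh."""
    if not isinstance(surface, CellSurface):
        surface = CellSurface(surface)
    if not np.all(np.isfinite(point)):
        raise GeometryError("query point must be finite")
    return surface.probe(point)


def tangent_plane(probe: SurfaceProbe):
    """The local membrane approximation: (point on plane, unit normal)."""
    return probe.nearest_point, probe.normal


def sample_surface_point(surface, rng: np.random.Generator):
    """One uniform-per-area surface point and its outward normal."""
    if not isinstance(surface, CellSurface):
        surface = CellSurface(surface)
    pos, norm = surface.sample(1, rng)
    return pos[0], norm[0]


def brute_force_nearest(mesh: trimesh.Trimesh, points) -> np.ndarray:
    """O(F) reference distances used as the oracle in tests."""
    from trimesh.proximity import closest_point_naive
    _, dist, _ = closest_point_naive(mesh, np.atleast_2d(points))
    return dist
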