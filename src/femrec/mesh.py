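"""Triangulated surface meshes and tetrahedral meshes with per-cell intensity.

Surfaces are stored as plain vertex/triangle arrays in millimetres; tetrahedral
meshes additionally carry one Hounsfield value per cell.  ASCII STL and PLY
readers/writers are provided so every artefact round-trips through text files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .transforms import RigidTransform

DEFAULT_FRAME = "xyz:ML,PA,DP"  # x medial->lateral, y posterior->anterior, z distal->proximal


class MeshError(ValueError):
    """Raised for structurally invalid mesh input."""


@dataclass
class SurfaceMesh:
    """Triangulated boundary surface in mm."""

    vertices: np.ndarray
    triangles: np.ndarray
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise MeshError("triangle index out of range")

    # -- basic measures -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.triangles
        v = self.vertices
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_normals(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        ln = np.linalg.norm(n, axis=1)
        ln[ln == 0] = 1.0
        return n / ln[:, None]

    def vertex_normals(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        fn = np.cross(b - a, c - a)  # area weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        ln = np.linalg.norm(vn, axis=1)
        ln[ln == 0] = 1.0
        return vn / ln[:, None]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def signed_volume(self) -> float:
        a, b, c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy(), self.frame)

    def transformed(self, tf: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(tf.apply(self.vertices), self.triangles.copy(), self.frame)

    # -- validity checks ------------------------------------------------
    def has_degenerate_triangles(self, tol: float = 1e-10) -> bool:
        return bool((self.triangle_areas() <= tol).any())

    def is_watertight(self) -> bool:
        """Every undirected edge must be shared by exactly two triangles."""
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und = np.sort(edges, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def orient_outward(self) -> "SurfaceMesh":
        """Flip all windings if the signed volume is negative."""
        if self.signed_volume() < 0:
            self.triangles = self.triangles[:, [0, 2, 1]]
        return self


@dataclass
class TetMesh:
    """Tetrahedral mesh with optional per-cell Hounsfield value.

    ``triangles`` lists the boundary faces using the same node indexing and is
    expected to match the surface mesh the tets were built from (nodes
    ``0..n_surface-1`` are the surface vertices).
    """

    nodes: np.ndarray
    tets: np.ndarray
    triangles: np.ndarray
    cell_hu: Optional[np.ndarray] = None
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.cell_hu is not None:
            self.cell_hu = np.ascontiguousarray(self.cell_hu, dtype=float)
            if len(self.cell_hu) != len(self.tets):
                raise MeshError("cell_hu must have one value per tet")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tet_volumes(self) -> np.ndarray:
        n = self.nodes
        t = self.tets
        a = n[t[:, 1]] - n[t[:, 0]]
        b = n[t[:, 2]] - n[t[:, 0]]
        c = n[t[:, 3]] - n[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def orient_positive(self) -> "TetMesh":
        """Swap two nodes of every inverted tet so all signed volumes are > 0."""
        vol = self.tet_volumes()
        flip = vol < 0
        if flip.any():
            self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]
        return self

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.triangles)

    def surface(self) -> SurfaceMesh:
        return SurfaceMesh(self.nodes.copy(), self.triangles.copy(), self.frame)

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.tets.copy(),
            self.triangles.copy(),
            None if self.cell_hu is None else self.cell_hu.copy(),
            self.frame,
        )


# ---------------------------------------------------------------------------
# point / surface distances
# ---------------------------------------------------------------------------

def _point_triangle_closest(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on triangles ``(a[i], b[i], c[i])`` to points ``p[i]``.

    Vectorised version of the region classification in Ericson,
    *Real-Time Collision Detection*, ch. 5.
    """
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[:] = a + v[:, None] * ab + w[:, None] * ac  # face region default

    # edge AC region
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if m.any():
        t = d2[m] / (d2[m] - d6[m])
        closest[m] = a[m] + t[:, None] * ac[m]
    # edge AB region
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if m.any():
        t = d1[m] / (d1[m] - d3[m])
        closest[m] = a[m] + t[:, None] * ab[m]
    # edge BC region
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    if m.any():
        t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        closest[m] = b[m] + t[:, None] * (c[m] - b[m])
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    m = (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    m = (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]

    return closest


class SurfaceDistance:
    """Closest point-to-triangle distance queries against a fixed surface."""

    def __init__(self, mesh: SurfaceMesh, k: int = 12):
        if mesh.n_triangles == 0:
            raise MeshError("cannot query distances against an empty mesh")
        self.mesh = mesh
        self.k = min(k, mesh.n_triangles)
        self._centroids = mesh.vertices[mesh.triangles].mean(axis=1)
        self._tree = cKDTree(self._centroids)
        a, b, c = mesh.triangle_corners()
        self._a, self._b, self._c = a, b, c

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distances and closest surface points for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        prep = np.repeat(points, k, axis=0)
        flat = idx.ravel()
        cp = _point_triangle_closest(prep, self._a[flat], self._b[flat], self._c[flat])
        d = np.linalg.norm(prep - cp, axis=1).reshape(n, k)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        self.last_triangles = idx[rows, best]  # triangle index of each closest point
        return d[rows, best], cp.reshape(n, k, 3)[rows, best]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.closest(points)[0]


def point_surface_distance(points: np.ndarray, mesh: SurfaceMesh, k: int = 12) -> np.ndarray:
    return SurfaceDistance(mesh, k=k)(points)


# ---------------------------------------------------------------------------
# inside/outside via generalized winding number
# ---------------------------------------------------------------------------

def winding_numbers(mesh: SurfaceMesh, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Generalised winding number of ``points`` w.r.t. the oriented surface.

    ~1 inside a watertight outward-oriented surface, ~0 outside.  Computed with
    the solid-angle formula of van Oosterom & Strackee.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a0, b0, c0 = mesh.triangle_corners()
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        a = a0[None, :, :] - p[:, None, :]
        b = b0[None, :, :] - p[:, None, :]
        c = c0[None, :, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("ptj,ptj->pt", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ptj,ptj->pt", a, b) * lc
            + np.einsum("ptj,ptj->pt", b, c) * la
            + np.einsum("ptj,ptj->pt", a, c) * lb
        )
        out[s : s + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


def points_inside(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    return winding_numbers(mesh, points) > 0.5


def check_no_self_intersection(
    mesh: SurfaceMesh, n_samples: int = 400, offset_factor: float = 0.5, seed: int = 0
) -> bool:
    """Probabilistic self-intersection check via winding-number consistency.

    Points slightly outside (along the vertex normal) must have winding ~0 and
    points slightly inside winding ~1.  Overlapping sheets produce winding
    levels of 2 inside and 1 outside, which this detects.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(mesh.n_vertices, size=min(n_samples, mesh.n_vertices), replace=False)
    normals = mesh.vertex_normals()[idx]
    # offset relative to local edge length
    scale = offset_factor * np.sqrt(mesh.triangle_areas().mean())
    outside = mesh.vertices[idx] + scale * normals
    inside = mesh.vertices[idx] - scale * normals
    w_out = winding_numbers(mesh, outside)
    w_in = winding_numbers(mesh, inside)
    return bool((np.abs(w_out) < 0.5).all() and (np.abs(w_in - 1.0) < 0.5).all())


# ---------------------------------------------------------------------------
# ASCII STL / PLY io
# ---------------------------------------------------------------------------

def write_stl(mesh: SurfaceMesh, path: str | Path, name: str = "femrec") -> None:
    a, b, c = mesh.triangle_corners()
    n = mesh.triangle_normals()
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for i in range(mesh.n_triangles):
            fh.write(f"facet normal {n[i,0]:.9e} {n[i,1]:.9e} {n[i,2]:.9e}\n")
            fh.write(" outer loop\n")
            for p in (a[i], b[i], c[i]):
                fh.write(f"  vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write(f"endsolid {name}\n")


def read_stl(path: str | Path) -> SurfaceMesh:
    """Read an ASCII STL file, merging exactly coincident vertices."""
    verts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("vertex"):
                verts.append([float(x) for x in line.split()[1:4]])
    if not verts or len(verts) % 3:
        raise MeshError(f"not a valid ASCII STL file: {path}")
    pts = np.asarray(verts)
    uniq, inv = np.unique(pts.round(9), axis=0, return_inverse=True)
    tris = inv.reshape(-1, 3)
    return SurfaceMesh(uniq, tris)


def write_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment frame {mesh.frame}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path: str | Path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshError(f"not a PLY file: {path}")
        n_vert = n_face = 0
        frame = DEFAULT_FRAME
        while True:
            line = fh.readline()
            if not line:
                raise MeshError("unexpected end of PLY header")
            line = line.strip()
            if line.startswith("comment frame "):
                frame = line.split(" ", 2)[2]
            elif line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array([[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)])
        tris = np.array([[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)])
    return SurfaceMesh(verts, tris, frame)
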