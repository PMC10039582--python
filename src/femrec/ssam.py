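"""Statistical shape and appearance model construction.

Pipeline: rigid ICP alignment -> free-form-deformation correspondence ->
tetrahedral morph by solving a Laplace (harmonic) boundary-value problem ->
nearest-voxel intensity mapping -> PCA over the stacked shape(+appearance)
vectors.  Mode weights are expressed in standard deviations: an instance is
``mean + sum_i b_i * sqrt(lambda_i) * e_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .image import VolumeImage
from .mesh import MeshError, SurfaceDistance, SurfaceMesh, TetMesh
from .transforms import RigidTransform

__all__ = [
    "SSAM",
    "rigid_align",
    "correspond_ffd",
    "morph_tet_mesh",
    "map_appearance",
    "build_ssam",
    "instantiate",
    "leave_one_out",
    "project_weights",
]


# ---------------------------------------------------------------------------
# rigid ICP
# ---------------------------------------------------------------------------

def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired points moving -> fixed."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, fc - r @ mc)


def rigid_align(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> tuple[RigidTransform, SurfaceMesh]:
    """Iterative-closest-point rigid alignment of ``moving`` onto ``fixed``.

    Closest points are vertex-to-vertex; the matched-pair RMS distance is
    non-increasing over iterations.  Returns the accumulated transform and the
    aligned copy of ``moving``.
    """
    if moving.n_vertices == 0 or fixed.n_vertices == 0:
        raise MeshError("cannot align empty meshes")
    tree = cKDTree(fixed.vertices)
    pts = moving.vertices.copy()
    total = RigidTransform.identity()
    prev_rms = np.inf
    for _ in range(max_iter):
        d, idx = tree.query(pts)
        rms = float(np.sqrt(np.mean(d**2)))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        step = _kabsch(pts, fixed.vertices[idx])
        pts = step.apply(pts)
        total = step.compose(total)
    return total, SurfaceMesh(pts, moving.triangles.copy(), moving.frame)


# ---------------------------------------------------------------------------
# free-form deformation correspondence
# ---------------------------------------------------------------------------

def _bspline_matrix(points: np.ndarray, lo: np.ndarray, hi: np.ndarray, grid: int) -> sp.csr_matrix:
    """Sparse cubic B-spline basis matrix for ``points`` on a ``grid``^3 lattice."""
    extent = hi - lo
    u = (points - lo) / extent * grid  # in [0, grid]
    i0 = np.clip(np.floor(u).astype(int), 0, grid - 1)
    t = u - i0

    # uniform cubic B-spline basis
    b = np.empty((len(points), 3, 4))
    for ax in range(3):
        x = t[:, ax]
        b[:, ax, 0] = (1 - x) ** 3 / 6.0
        b[:, ax, 1] = (3 * x**3 - 6 * x**2 + 4) / 6.0
        b[:, ax, 2] = (-3 * x**3 + 3 * x**2 + 3 * x + 1) / 6.0
        b[:, ax, 3] = x**3 / 6.0

    ncp = grid + 3
    rows, cols, vals = [], [], []
    n = len(points)
    ridx = np.arange(n)
    for a in range(4):
        for bb in range(4):
            for c in range(4):
                w = b[:, 0, a] * b[:, 1, bb] * b[:, 2, c]
                cp = (i0[:, 0] + a) * ncp * ncp + (i0[:, 1] + bb) * ncp + (i0[:, 2] + c)
                rows.append(ridx)
                cols.append(cp)
                vals.append(w)
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, ncp**3),
    )
    return mat.tocsr()


def _symmetric_surface_distance(a: SurfaceMesh, b_dist: "SurfaceDistance", b: SurfaceMesh) -> float:
    da = b_dist(a.vertices)
    db = SurfaceDistance(a)(b.vertices)
    return 0.5 * (float(da.mean()) + float(db.mean()))


def correspond_ffd(
    reference: SurfaceMesh,
    target: SurfaceMesh,
    grid: Sequence[int] = (4, 8, 16),
    iterations: int = 8,
    step: float = 0.75,
    regularisation: float = 1e-2,
) -> tuple[SurfaceMesh, dict]:
    """Morph ``reference`` onto ``target`` with a multi-level B-spline FFD.

    At each lattice level the control displacements are fitted (regularised
    least squares) to symmetric closest-point match vectors and applied with a
    damping ``step``; a level result is only accepted if it improves the
    symmetric surface distance, so the per-level distances are non-increasing.
    Returns the corresponded mesh (reference topology) and a report with the
    per-level and final mean surface distances.
    """
    lo_r, hi_r = reference.bounds()
    lo_t, hi_t = target.bounds()
    if (lo_r > hi_t).any() or (lo_t > hi_r).any():
        raise MeshError("reference and target bounding boxes do not overlap; align first")

    lo = np.minimum(lo_r, lo_t)
    hi = np.maximum(hi_r, hi_t)
    pad = 0.15 * (hi - lo)
    lo, hi = lo - pad, hi + pad

    from .mesh import SurfaceDistance

    verts = reference.vertices.copy()
    tgt_dist = SurfaceDistance(target)
    current = SurfaceMesh(verts, reference.triangles, reference.frame)
    level_dist = [_symmetric_surface_distance(current, tgt_dist, target)]

    for g in grid:
        best = verts.copy()
        best_dist = level_dist[-1]
        for _ in range(iterations):
            # forward matches: every moving vertex pulls toward its closest
            # point on the target surface
            _, cp = tgt_dist.closest(verts)
            desired = cp - verts
            # reverse matches: every target vertex pulls the moving vertices of
            # the triangle its closest moving-surface point lies on
            moving = SurfaceMesh(verts, reference.triangles, reference.frame)
            mdist = SurfaceDistance(moving)
            _, mcp = mdist.closest(target.vertices)
            tri_idx = mdist.last_triangles
            pull = np.zeros_like(verts)
            cnt = np.zeros(len(verts))
            resid = target.vertices - mcp
            for corner in range(3):
                vid = reference.triangles[tri_idx, corner]
                np.add.at(pull, vid, resid)
                np.add.at(cnt, vid, 1.0)
            has = cnt > 0
            desired[has] = 0.5 * (desired[has] + pull[has] / cnt[has, None])

            bmat = _bspline_matrix(verts, lo, hi, g)
            ata = (bmat.T @ bmat + regularisation * sp.identity(bmat.shape[1])).tocsc()
            solve = spla.factorized(ata)
            delta = np.stack([solve(bmat.T @ desired[:, i]) for i in range(3)], axis=1)
            verts = verts + step * np.asarray(bmat @ delta)

            dist = _symmetric_surface_distance(
                SurfaceMesh(verts, reference.triangles, reference.frame), tgt_dist, target
            )
            if dist < best_dist:
                best_dist = dist
                best = verts.copy()
        verts = best
        level_dist.append(best_dist)

    report = {"level_mean_distance": level_dist[1:], "initial_mean_distance": level_dist[0],
              "final_mean_distance": level_dist[-1]}
    return SurfaceMesh(verts, reference.triangles.copy(), reference.frame), report


# ---------------------------------------------------------------------------
# Laplace (harmonic) tet morph
# ---------------------------------------------------------------------------

def _stiffness_matrix(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    """P1 finite-element stiffness matrix of the Laplace operator."""
    v0 = nodes[tets[:, 0]]
    e = np.stack([nodes[tets[:, k]] - v0 for k in (1, 2, 3)], axis=1)  # (m, 3, 3)
    vol6 = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    if np.any(np.abs(vol6) < 1e-14):
        raise MeshError("degenerate tetrahedra in stiffness assembly")
    inv = np.linalg.inv(e)  # rows of inv are gradients of barycentric coords 1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = inv.transpose(0, 2, 1)
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    vols = np.abs(vol6) / 6.0
    local = np.einsum("tik,tjk,t->tij", g, g, vols)  # (m, 4, 4)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    k = sp.coo_matrix((local.reshape(-1), (rows, cols)), shape=(len(nodes), len(nodes)))
    return k.tocsr()


def morph_tet_mesh(
    reference_tets: TetMesh, boundary_displacement: np.ndarray
) -> tuple[TetMesh, dict]:
    """Move boundary nodes by the given displacement, interior nodes harmonically.

    Each coordinate of the interior displacement solves the discrete Laplace
    equation with the boundary displacement as Dirichlet data (P1 finite
    elements, so affine boundary displacements are reproduced exactly).
    Returns the morphed mesh and a report with the inverted-tet fraction.
    """
    tm = reference_tets
    boundary = tm.boundary_nodes()
    disp_b = np.asarray(boundary_displacement, dtype=float)
    if disp_b.shape != (len(boundary), 3):
        raise MeshError(
            f"boundary_displacement must be ({len(boundary)}, 3), got {disp_b.shape}"
        )

    n = tm.n_nodes
    interior = np.setdiff1d(np.arange(n), boundary)
    k = _stiffness_matrix(tm.nodes, tm.tets)

    disp = np.zeros((n, 3))
    disp[boundary] = disp_b
    if len(interior):
        kii = k[interior][:, interior].tocsc()
        kib = k[interior][:, boundary]
        rhs = -kib @ disp_b
        try:
            solve = spla.factorized(kii)
        except RuntimeError as exc:  # singular system
            raise MeshError(f"singular Laplace system (disconnected mesh?): {exc}") from exc
        disp[interior] = np.stack([solve(rhs[:, i]) for i in range(3)], axis=1)

    out = TetMesh(
        tm.nodes + disp,
        tm.tets.copy(),
        tm.triangles.copy(),
        None if tm.cell_hu is None else tm.cell_hu.copy(),
        tm.frame,
    )
    inverted = float((out.tet_volumes() <= 0).mean())
    return out, {"inverted_fraction": inverted}


# ---------------------------------------------------------------------------
# appearance mapping
# ---------------------------------------------------------------------------

def map_appearance(tets: TetMesh, volume: VolumeImage) -> TetMesh:
    """Attach to each tet the HU of the voxel nearest its centroid (no interpolation)."""
    out = tets.copy()
    out.cell_hu = volume.sample_nearest(tets.centroids())
    return out


# ---------------------------------------------------------------------------
# PCA model
# ---------------------------------------------------------------------------

@dataclass
class SSAM:
    """Statistical shape (and appearance) model over corresponded tet meshes."""

    mean_shape: np.ndarray  # (3 * n_nodes,)
    mean_appearance: np.ndarray  # (n_tets,) or empty
    modes: np.ndarray  # (n_modes, dim) orthonormal rows over the combined space
    eigenvalues: np.ndarray  # descending variances
    tets: np.ndarray
    triangles: np.ndarray
    n_specimens: int
    appearance_flag: bool
    appearance_scale: float  # multiplier applied to the appearance block before PCA
    frame: str = "xyz:ML,PA,DP"

    @property
    def n_nodes(self) -> int:
        return len(self.mean_shape) // 3

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def sd(self, i: int) -> float:
        return float(np.sqrt(max(self.eigenvalues[i], 0.0)))

    def instantiate_arrays(self, b: np.ndarray) -> tuple[np.ndarray, Optional[np.ndarray]]:
        """Node coordinates and cell HU for mode weights ``b`` (in SD units)."""
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if len(b) > self.n_modes:
            raise ValueError(f"weight vector has {len(b)} entries but model has {self.n_modes} modes")
        scale = b * np.sqrt(np.maximum(self.eigenvalues[: len(b)], 0.0))
        vec = self.modes[: len(b)].T @ scale
        ns = len(self.mean_shape)
        nodes = (self.mean_shape + vec[:ns]).reshape(-1, 3)
        hu = None
        if self.appearance_flag:
            hu = self.mean_appearance + vec[ns:] / self.appearance_scale
        return nodes, hu

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("mean_shape", data=self.mean_shape)
            f.create_dataset("mean_appearance", data=self.mean_appearance)
            f.create_dataset("modes", data=self.modes)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("tets", data=self.tets)
            f.create_dataset("triangles", data=self.triangles)
            f.attrs["n_specimens"] = self.n_specimens
            f.attrs["appearance_flag"] = self.appearance_flag
            f.attrs["appearance_scale"] = self.appearance_scale
            f.attrs["frame"] = self.frame

    @classmethod
    def load(cls, path: str | Path) -> "SSAM":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                mean_shape=f["mean_shape"][()],
                mean_appearance=f["mean_appearance"][()],
                modes=f["modes"][()],
                eigenvalues=f["eigenvalues"][()],
                tets=f["tets"][()],
                triangles=f["triangles"][()],
                n_specimens=int(f.attrs["n_specimens"]),
                appearance_flag=bool(f.attrs["appearance_flag"]),
                appearance_scale=float(f.attrs["appearance_scale"]),
                frame=str(f.attrs["frame"]),
            )


def build_ssam(specimens: Sequence[TetMesh], use_appearance: bool = True) -> SSAM:
    """PCA over corresponded tet meshes (dual / SVD formulation).

    The appearance block is rescaled so its total standard deviation matches
    the shape block's before the joint decomposition; the scaling constant is
    stored on the model and undone at instantiation.
    """
    if len(specimens) < 2:
        raise ValueError("need at least 2 specimens")
    ref = specimens[0]
    for s in specimens[1:]:
        if not np.array_equal(s.tets, ref.tets) or s.n_nodes != ref.n_nodes:
            raise MeshError("specimens do not share tet topology; run correspondence first")
    if use_appearance and any(s.cell_hu is None for s in specimens):
        raise MeshError("use_appearance=True but some specimens have no cell_hu")

    shapes = np.stack([s.nodes.reshape(-1) for s in specimens])
    mean_shape = shapes.mean(axis=0)
    xs = shapes - mean_shape

    if use_appearance:
        apps = np.stack([s.cell_hu for s in specimens])
        mean_app = apps.mean(axis=0)
        xa = apps - mean_app
        shape_sd = np.sqrt((xs**2).sum() / max(len(specimens) - 1, 1))
        app_sd = np.sqrt((xa**2).sum() / max(len(specimens) - 1, 1))
        scale = shape_sd / app_sd if app_sd > 0 else 1.0
        x = np.concatenate([xs, xa * scale], axis=1)
    else:
        mean_app = np.zeros(0)
        scale = 1.0
        x = xs

    _, sing, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = sing**2 / max(len(specimens) - 1, 1)
    keep = eigenvalues > max(eigenvalues[0], 1e-30) * 1e-12 if eigenvalues.size else []
    return SSAM(
        mean_shape=mean_shape,
        mean_appearance=mean_app,
        modes=vt[keep],
        eigenvalues=eigenvalues[keep],
        tets=ref.tets.copy(),
        triangles=ref.triangles.copy(),
        n_specimens=len(specimens),
        appearance_flag=use_appearance,
        appearance_scale=scale,
        frame=ref.frame,
    )


def instantiate(model: SSAM, b: np.ndarray) -> tuple[SurfaceMesh, TetMesh]:
    """Instantiate the model at mode weights ``b`` (standard-deviation units)."""
    nodes, hu = model.instantiate_arrays(b)
    tm = TetMesh(nodes, model.tets.copy(), model.triangles.copy(), hu, model.frame)
    n_surf = int(model.triangles.max()) + 1
    surf = SurfaceMesh(nodes[:n_surf].copy(), model.triangles.copy(), model.frame)
    return surf, tm


def project_weights(model: SSAM, specimen: TetMesh) -> np.ndarray:
    """Mode weights (SD units) of a corresponded specimen under the model."""
    xs = specimen.nodes.reshape(-1) - model.mean_shape
    if model.appearance_flag:
        if specimen.cell_hu is None:
            raise MeshError("model has appearance but specimen has no cell_hu")
        xa = (specimen.cell_hu - model.mean_appearance) * model.appearance_scale
        x = np.concatenate([xs, xa])
    else:
        x = xs
    raw = model.modes @ x
    sds = np.sqrt(np.maximum(model.eigenvalues, 1e-300))
    return raw / sds


def leave_one_out(
    specimens: Sequence[TetMesh], index: int, use_appearance: bool = True
) -> tuple[SSAM, TetMesh]:
    """Model built from all specimens except ``index``, plus the held-out one."""
    if len(specimens) < 3:
        raise ValueError("need at least 3 specimens for leave-one-out")
    if not 0 <= index < len(specimens):
        raise IndexError(f"index {index} out of range for {len(specimens)} specimens")
    train = [s for i, s in enumerate(specimens) if i != index]
    return build_ssam(train, use_appearance=use_appearance), specimens[index]
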