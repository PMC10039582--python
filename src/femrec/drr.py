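"""Digitally reconstructed radiographs, silhouette contours and defect cropping.

The transfer function maps Hounsfield units to opacity as ``op = 0.25 * HU / 1700``
(clamped to [0, 1], non-positive HU fully transparent).  Rays accumulate an
absorption-only transmittance ``T = prod(1 - op * step / step_ref)`` with a
reference step of 1 mm and the pixel intensity is ``1 - T``.

Two source types are supported: axis-aligned Hounsfield volumes (true ray
marching) and tetrahedral meshes with per-cell HU (point splatting that
reproduces the same compositing law; see :class:`TetSplatter`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .image import VolumeImage
from .mesh import TetMesh

STEP_REF = 1.0  # mm; opacity values are normalised to this sample length

__all__ = [
    "ProjectionGeometry",
    "Radiograph",
    "Contour",
    "TetSplatter",
    "opacity_transfer",
    "project",
    "extract_contour",
    "crop_defect",
    "geometry_for_bounds",
]


class ProjectionError(ValueError):
    pass


def opacity_transfer(hu) -> np.ndarray | float:
    """Linear HU -> opacity transfer function, ``op = 0.25 * HU / 1700``.

    Clamped to [0, 1]; non-positive HU (air, water and below) are transparent.
    """
    op = np.clip(0.25 * np.asarray(hu, dtype=float) / 1700.0, 0.0, 1.0)
    if np.ndim(hu) == 0:
        return float(op)
    return op


_VIEW_AXES = {
    # view: (ray direction, detector u axis, detector v axis)
    "AP": (np.array([0.0, -1.0, 0.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0])),
    "ML": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, -1.0])),
}


@dataclass(frozen=True, eq=False)
class ProjectionGeometry:
    """Planar projection setup in the anatomical frame.

    AP looks along -y, ML along +x; detector rows (``v``) run proximal to
    distal so increasing row index moves distally.  ``source_distance`` is the
    source-to-detector distance; the projected object is assumed centred
    midway between source and detector when the geometry is built with
    :func:`geometry_for_bounds`.
    """

    view: str
    detector_shape: tuple[int, int]  # (rows, cols)
    pixel_spacing: float
    detector_center: np.ndarray
    source_distance: float = 1500.0
    ray_model: str = "perspective"

    def __post_init__(self) -> None:
        if self.view not in _VIEW_AXES:
            raise ProjectionError(f"view must be one of {sorted(_VIEW_AXES)}")
        if self.ray_model not in ("perspective", "parallel"):
            raise ProjectionError("ray_model must be 'perspective' or 'parallel'")
        if self.source_distance <= 0:
            raise ProjectionError("source_distance must be > 0")
        if self.pixel_spacing <= 0:
            raise ProjectionError("pixel_spacing must be > 0")
        object.__setattr__(
            self, "detector_center", np.asarray(self.detector_center, dtype=float).reshape(3)
        )

    @property
    def ray_dir(self) -> np.ndarray:
        return _VIEW_AXES[self.view][0]

    @property
    def u_axis(self) -> np.ndarray:
        return _VIEW_AXES[self.view][1]

    @property
    def v_axis(self) -> np.ndarray:
        return _VIEW_AXES[self.view][2]

    @property
    def source(self) -> np.ndarray:
        return self.detector_center - self.source_distance * self.ray_dir

    def world_to_pixel(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project world points; returns (row, col, magnification) per point."""
        points = np.atleast_2d(points)
        rel = points - self.detector_center
        if self.ray_model == "parallel":
            u = rel @ self.u_axis
            v = rel @ self.v_axis
            mag = np.ones(len(points))
        else:
            sp = points - self.source
            depth = sp @ self.ray_dir
            if np.any(depth <= 0):
                raise ProjectionError("points behind the X-ray source")
            mag = self.source_distance / depth
            hit = self.source + sp * mag[:, None] - self.detector_center
            u = hit @ self.u_axis
            v = hit @ self.v_axis
        rows, cols = self.detector_shape
        return (
            v / self.pixel_spacing + (rows - 1) / 2.0,
            u / self.pixel_spacing + (cols - 1) / 2.0,
            mag,
        )

    def pixel_to_mm(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        rows, cols = self.detector_shape
        u = (np.asarray(col) - (cols - 1) / 2.0) * self.pixel_spacing
        v = (np.asarray(row) - (rows - 1) / 2.0) * self.pixel_spacing
        return np.stack([np.atleast_1d(u), np.atleast_1d(v)], axis=1)

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "detector_shape": list(self.detector_shape),
            "pixel_spacing": self.pixel_spacing,
            "detector_center": self.detector_center.tolist(),
            "source_distance": self.source_distance,
            "ray_model": self.ray_model,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        d = dict(d)
        d["detector_shape"] = tuple(d["detector_shape"])
        d["detector_center"] = np.asarray(d["detector_center"])
        return cls(**d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProjectionGeometry):
            return NotImplemented
        a, b = self.to_dict(), other.to_dict()
        return all(np.all(np.asarray(a[k]) == np.asarray(b[k])) for k in a)


def geometry_for_bounds(
    lo: np.ndarray,
    hi: np.ndarray,
    view: str,
    pixel_spacing: float = 0.5,
    margin: float = 0.10,
    ray_model: str = "perspective",
    source_distance: float = 1500.0,
) -> ProjectionGeometry:
    """Detector sized to the projected bounding box plus a relative margin."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    center = 0.5 * (lo + hi)
    ray, u_ax, v_ax = _VIEW_AXES[view]
    half = 0.5 * (hi - lo)
    extent_u = abs(half @ np.abs(u_ax)) * 2
    extent_v = abs(half @ np.abs(v_ax)) * 2
    mag = 2.0 if ray_model == "perspective" else 1.0  # object midway -> x2
    size_u = extent_u * mag * (1 + 2 * margin)
    size_v = extent_v * mag * (1 + 2 * margin)
    shape = (int(np.ceil(size_v / pixel_spacing)) | 1, int(np.ceil(size_u / pixel_spacing)) | 1)
    det_center = center + 0.5 * source_distance * ray
    return ProjectionGeometry(view, shape, pixel_spacing, det_center, source_distance, ray_model)


@dataclass
class Radiograph:
    """Simulated planar X-ray with validity mask and projected bone extent."""

    pixels: np.ndarray  # (rows, cols) float in [0, 1]
    geometry: ProjectionGeometry
    defect_mask: np.ndarray = None  # type: ignore[assignment]  # True = valid
    bone_extent: Optional[tuple[int, int]] = None  # (proximal row, distal row)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.defect_mask is None:
            self.defect_mask = np.ones_like(self.pixels, dtype=bool)
        self.defect_mask = np.asarray(self.defect_mask, dtype=bool)
        if self.defect_mask.shape != self.pixels.shape:
            raise ProjectionError("defect_mask shape must equal pixel shape")
        if self.pixels.size and (self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9):
            raise ProjectionError("pixel intensities must lie in [0, 1]")
        if self.bone_extent is None:
            self.bone_extent = _bone_extent(self.pixels)

    def masked_pixels(self) -> np.ndarray:
        return np.where(self.defect_mask, self.pixels, 0.0)

    def save(self, stem: str | Path) -> None:
        """Write <stem>.tif (16-bit) plus <stem>.json geometry/mask sidecar."""
        import tifffile

        stem = Path(stem)
        tifffile.imwrite(stem.with_suffix(".tif"), (self.pixels * 65535).astype(np.uint16))
        sidecar = {
            "geometry": self.geometry.to_dict(),
            "bone_extent": list(self.bone_extent) if self.bone_extent else None,
            "masked_rows": np.nonzero(~self.defect_mask.all(axis=1))[0].tolist(),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "Radiograph":
        import tifffile

        stem = Path(stem)
        pixels = tifffile.imread(stem.with_suffix(".tif")).astype(float) / 65535.0
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        mask = np.ones_like(pixels, dtype=bool)
        mask[sidecar["masked_rows"], :] = False
        extent = sidecar.get("bone_extent")
        return cls(
            pixels,
            ProjectionGeometry.from_dict(sidecar["geometry"]),
            mask,
            tuple(extent) if extent else None,
        )


def _bone_extent(pixels: np.ndarray, threshold: float = 0.005) -> Optional[tuple[int, int]]:
    rows = np.nonzero((pixels > threshold).any(axis=1))[0]
    if len(rows) == 0:
        return None
    return int(rows[0]), int(rows[-1])


@dataclass
class Contour:
    """Closed silhouette polygon in detector millimetres (u, v)."""

    points: np.ndarray  # (m, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) >= 2:  # drop duplicated consecutive points
            keep = np.ones(len(self.points), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(self.points, axis=0), axis=1) > 1e-12
            self.points = self.points[keep]
        if self.closed and len(self.points) < 3:
            raise ProjectionError("closed contour needs at least 3 points")

    def most_proximal(self) -> np.ndarray:
        """Point with smallest v; ties broken by smallest lateral coordinate u."""
        v = self.points[:, 1]
        cands = np.nonzero(v <= v.min() + 1e-12)[0]
        return self.points[cands[np.argmin(self.points[cands, 0])]]

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="u_mm,v_mm", comments="")

    @classmethod
    def load_csv(cls, path: str | Path) -> "Contour":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(source, geometry: ProjectionGeometry, step: float = 1.0,
            smooth_sigma: float = 0.0) -> Radiograph:
    """Simulate a radiograph of a volume or tet mesh under the given geometry."""
    if step <= 0:
        raise ProjectionError("step must be > 0")
    if isinstance(source, VolumeImage):
        img = _project_volume(source, geometry, step)
    elif isinstance(source, TetMesh):
        if source.cell_hu is None:
            raise ProjectionError("tet mesh must carry cell_hu to be projected")
        spl = TetSplatter(
            source.tets,
            ref_nodes=source.nodes,
            sample_spacing=0.9 * min(step, geometry.pixel_spacing),
        )
        img = spl.project(source.nodes, source.cell_hu, geometry, step=step)
    else:
        raise TypeError(f"cannot project source of type {type(source)!r}")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
        img = np.clip(img, 0.0, 1.0)
    return Radiograph(img, geometry)


def _project_volume(volume: VolumeImage, geometry: ProjectionGeometry, step: float) -> np.ndarray:
    rows, cols = geometry.detector_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    uv = geometry.pixel_to_mm(rr.ravel(), cc.ravel())
    pix_world = (
        geometry.detector_center
        + uv[:, 0, None] * geometry.u_axis
        + uv[:, 1, None] * geometry.v_axis
    )

    lo, hi = volume.bounds()
    if geometry.ray_model == "parallel":
        origins = pix_world
        dirs = np.broadcast_to(geometry.ray_dir, origins.shape)
    else:
        origins = np.broadcast_to(geometry.source, pix_world.shape)
        dirs = pix_world - geometry.source
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    # conservative common parameter range covering the volume box
    corners = np.array(np.meshgrid(*zip(lo, hi), indexing="ij")).reshape(3, -1).T
    if geometry.ray_model == "parallel":
        t0 = ((corners - pix_world.mean(axis=0)) @ geometry.ray_dir).min() - step
        t1 = ((corners - pix_world.mean(axis=0)) @ geometry.ray_dir).max() + step
    else:
        proj = (corners - geometry.source) @ geometry.ray_dir
        t0, t1 = proj.min() - step, proj.max() + step
    n_steps = max(int(np.ceil((t1 - t0) / step)), 1)
    ts = t0 + (np.arange(n_steps) + 0.5) * step

    log_t = np.zeros(len(origins))
    spacing = volume.spacing
    chunk = max(1, int(4e6 // len(origins)))
    for s in range(0, n_steps, chunk):
        tt = ts[s : s + chunk]
        pts = origins[:, None, :] + dirs[:, None, :] * tt[None, :, None]
        idx = (pts - volume.origin) / spacing
        vals = ndimage.map_coordinates(
            volume.scalars,
            idx.reshape(-1, 3).T,
            order=1,
            mode="constant",
            cval=-1000.0,
            prefilter=False,
        ).reshape(len(origins), -1)
        op = opacity_transfer(vals)
        frac = np.clip(op * step / STEP_REF, 0.0, 1.0 - 1e-9)
        log_t += np.log1p(-frac).sum(axis=1)
    intensity = 1.0 - np.exp(log_t)
    return np.clip(intensity.reshape(rows, cols), 0.0, 1.0)


# barycentric sample sets per tet (weights sum to 1)
_BARY_SETS = {
    1: np.full((1, 4), 0.25),
    4: np.array(
        [
            [0.58541020, 0.13819660, 0.13819660, 0.13819660],
            [0.13819660, 0.58541020, 0.13819660, 0.13819660],
            [0.13819660, 0.13819660, 0.58541020, 0.13819660],
            [0.13819660, 0.13819660, 0.13819660, 0.58541020],
        ]
    ),
}
_BARY_SETS[5] = np.concatenate([_BARY_SETS[1], _BARY_SETS[4]])
_BARY_SETS[8] = np.concatenate(
    [_BARY_SETS[4], 0.25 + 0.60 * (np.eye(4) - 0.25)]
)
_BARY_SETS[11] = np.concatenate([_BARY_SETS[1], _BARY_SETS[4], 0.25 + 0.65 * (np.eye(4) - 0.25)])


class TetSplatter:
    """Fast repeated projection of deforming tet meshes with fixed topology.

    Each tet is represented by a fixed set of barycentric sample points; the
    number of points per tet is chosen so the sample spacing (measured on the
    reference node positions) stays below ``sample_spacing``.  A sample
    standing for solid volume ``w`` deposits an effective path length
    ``w / pixel_area`` into its pixel, composited as
    ``(1 - op * step / step_ref) ** (length / step)`` — identical to the ray
    marching law for material of that thickness.
    """

    def __init__(
        self,
        tets: np.ndarray,
        points_per_tet: int = 5,
        ref_nodes: Optional[np.ndarray] = None,
        sample_spacing: Optional[float] = None,
        seed: int = 12345,
    ):
        self.tets = np.asarray(tets, dtype=np.int64)
        m = len(self.tets)
        if ref_nodes is not None and sample_spacing is not None:
            corners = np.asarray(ref_nodes, float)[self.tets]
            vols = np.abs(
                np.einsum(
                    "ij,ij->i",
                    corners[:, 1] - corners[:, 0],
                    np.cross(corners[:, 2] - corners[:, 0], corners[:, 3] - corners[:, 0]),
                )
            ) / 6.0
            counts = np.maximum(1, np.rint(vols / sample_spacing**3).astype(int))
            rng = np.random.default_rng(seed)
            bary = rng.dirichlet(np.ones(4), size=int(counts.sum()))
            self.bary = bary
            self.tet_of_sample = np.repeat(np.arange(m), counts)
            self.samples_per_tet = counts
        else:
            if points_per_tet not in _BARY_SETS:
                raise ProjectionError(f"points_per_tet must be one of {sorted(_BARY_SETS)}")
            base = _BARY_SETS[points_per_tet]
            self.bary = np.tile(base, (m, 1))
            self.tet_of_sample = np.repeat(np.arange(m), points_per_tet)
            self.samples_per_tet = np.full(m, points_per_tet)

    @property
    def _bary_matrix(self):
        # sparse (n_samples, n_nodes) interpolation matrix, built lazily
        if getattr(self, "_bmat", None) is None:
            import scipy.sparse as sp

            s = len(self.bary)
            rows = np.repeat(np.arange(s), 4)
            cols = self.tets[self.tet_of_sample].ravel()
            n_nodes = int(self.tets.max()) + 1
            self._bmat = sp.csr_matrix(
                (self.bary.ravel(), (rows, cols)), shape=(s, n_nodes)
            )
        return self._bmat

    def sample_points(self, nodes: np.ndarray) -> np.ndarray:
        return self._bary_matrix @ nodes

    def project(
        self,
        nodes: np.ndarray,
        cell_hu: np.ndarray,
        geometry: ProjectionGeometry,
        step: float = 1.0,
        smooth_sigma: float = 0.0,
    ) -> np.ndarray:
        corners = nodes[self.tets]
        a = corners[:, 1] - corners[:, 0]
        b = corners[:, 2] - corners[:, 0]
        c = corners[:, 3] - corners[:, 0]
        vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
        pts = self.sample_points(nodes)
        row, col, mag = geometry.world_to_pixel(pts)

        rows, cols = geometry.detector_shape
        ir = np.rint(row).astype(int)
        ic = np.rint(col).astype(int)
        ok = (ir >= 0) & (ir < rows) & (ic >= 0) & (ic < cols)

        op = opacity_transfer(cell_hu[self.tet_of_sample])
        frac = np.clip(op * step / STEP_REF, 0.0, 1.0 - 1e-9)
        # effective path length: sample volume over the *projected* pixel area
        pix_area = geometry.pixel_spacing**2 / (mag**2)
        length = (vols / self.samples_per_tet)[self.tet_of_sample] / pix_area
        contrib = (length / step) * np.log1p(-frac)

        flat = np.bincount(
            ir[ok] * cols + ic[ok], weights=contrib[ok], minlength=rows * cols
        )
        img = 1.0 - np.exp(flat.reshape(rows, cols))
        if smooth_sigma > 0:
            img = np.clip(ndimage.gaussian_filter(img, smooth_sigma), 0.0, 1.0)
        return img


# ---------------------------------------------------------------------------
# contours and defects
# ---------------------------------------------------------------------------

def extract_contour(image: Radiograph, threshold: float = 0.01) -> Contour:
    """Outer silhouette of the largest above-threshold connected component.

    The boundary is traced at sub-pixel positions along the ``threshold``
    iso-level (marching squares) and returned in detector millimetres.
    """
    from skimage import measure

    pix = image.masked_pixels()
    fg = pix >= threshold
    if not fg.any():
        raise ProjectionError("no pixels above threshold; empty radiograph")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        pix = np.where(labels == keep, pix, 0.0)

    padded = np.pad(pix, 1, mode="constant")
    contours = measure.find_contours(padded, threshold)
    if not contours:
        raise ProjectionError("no iso-contour found at the given threshold")

    def area(c):
        x, y = c[:, 1], c[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    best = max(contours, key=area)
    rowcol = best - 1.0  # undo padding
    pts = image.geometry.pixel_to_mm(rowcol[:, 0], rowcol[:, 1])
    return Contour(pts, closed=True)


def crop_defect(image: Radiograph, defect_level: float) -> Radiograph:
    """Mask out the distal ``defect_level`` fraction of the projected bone.

    Operates on detector rows: with the bone spanning ``n`` rows, the
    ``round(defect_level * n)`` most distal (highest-index) rows are set to
    background and flagged invalid in the defect mask.
    """
    if not 0.0 <= defect_level < 1.0:
        raise ProjectionError(f"defect_level must lie in [0, 1), got {defect_level}")
    if image.bone_extent is None:
        raise ProjectionError("bone_extent unknown; cannot crop an empty radiograph")
    if defect_level == 0.0:
        return Radiograph(image.pixels.copy(), image.geometry,
                          image.defect_mask.copy(), image.bone_extent)
    r0, r1 = image.bone_extent
    n_rows = r1 - r0 + 1
    n_mask = int(round(defect_level * n_rows))
    pixels = image.pixels.copy()
    mask = image.defect_mask.copy()
    if n_mask > 0:
        start = r1 - n_mask + 1
        pixels[start : r1 + 1, :] = 0.0
        mask[start : r1 + 1, :] = False
    return Radiograph(pixels, image.geometry, mask, image.bone_extent)
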