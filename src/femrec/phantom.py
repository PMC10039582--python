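"""Seeded populations of femur-like phantoms with analytic ground truth.

A phantom is a swept tube: two ellipsoid-like condylar lobes distally, a bowed
cylindrical shaft, a filleted frustum neck and a spherical head.  The sweep is
evaluated on a fixed (station x angle) grid, so every phantom generated at the
same resolution shares an identical triangle list and vertex ``k`` corresponds
anatomically across phantoms.  All generating parameters map to analytically
known landmarks and angles, which the measurement code is validated against.

Frame convention: x medial->lateral, y posterior->anterior, z distal->proximal;
the distal-most point of the bone sits at z = 0 and the head apex at
z = ``bone_length``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .image import AIR_HU, VolumeImage
from .mesh import SurfaceMesh, TetMesh
from .transforms import unit

__all__ = [
    "PhantomParams",
    "LandmarkSet",
    "PhantomSpecimen",
    "ParamDistribution",
    "PhantomParameterError",
    "ResolutionError",
    "generate_phantom",
    "phantom_tet_mesh",
    "voxelize_phantom",
    "classify_points",
    "sample_population",
    "analytic_measures",
    "default_distribution",
    "default_correlation",
]


class PhantomParameterError(ValueError):
    """A phantom parameter violates its allowed bounds."""


class ResolutionError(ValueError):
    """Requested voxel spacing cannot resolve the phantom geometry."""


PARAM_FIELDS = (
    "bone_length",
    "shaft_radius",
    "cortical_thickness",
    "head_radius",
    "neck_length",
    "neck_shaft_angle",
    "anteversion_angle",
    "bow_angle",
    "condyle_width",
    "condyle_offset",
    "cortical_hu",
    "medullary_hu",
)


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of one phantom (lengths mm, angles degrees)."""

    bone_length: float = 430.0
    shaft_radius: float = 14.0
    cortical_thickness: float = 5.0
    head_radius: float = 23.0
    neck_length: float = 52.0
    neck_shaft_angle: float = 127.0
    anteversion_angle: float = 12.0
    bow_angle: float = 4.0
    condyle_width: float = 75.0
    condyle_offset: float = 18.0
    cortical_hu: float = 1400.0
    medullary_hu: float = 150.0

    def validate(self) -> None:
        for name in (
            "bone_length",
            "shaft_radius",
            "cortical_thickness",
            "head_radius",
            "neck_length",
            "condyle_width",
            "condyle_offset",
        ):
            if getattr(self, name) <= 0:
                raise PhantomParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 90.0 < self.neck_shaft_angle < 160.0:
            raise PhantomParameterError(
                f"neck_shaft_angle must lie in (90, 160), got {self.neck_shaft_angle}"
            )
        if not abs(self.anteversion_angle) < 45.0:
            raise PhantomParameterError(
                f"|anteversion_angle| must be < 45, got {self.anteversion_angle}"
            )
        if not 0.0 <= self.bow_angle < 15.0:
            raise PhantomParameterError(f"bow_angle must lie in [0, 15), got {self.bow_angle}")
        if self.cortical_hu <= self.medullary_hu:
            raise PhantomParameterError(
                f"cortical_hu ({self.cortical_hu}) must exceed medullary_hu ({self.medullary_hu})"
            )
        if self.cortical_thickness >= self.shaft_radius:
            raise PhantomParameterError("cortical_thickness must be smaller than shaft_radius")
        if self.condyle_width <= 2.0 * self.shaft_radius:
            raise PhantomParameterError("condyle_width must exceed the shaft diameter")
        # geometric feasibility of the neck assembly
        r_ne = 0.60 * self.head_radius
        trim = _fillet_trim(self)
        needed = trim + np.sqrt(self.head_radius**2 - r_ne**2) + 2.0
        if self.neck_length <= needed:
            raise PhantomParameterError(
                f"neck_length must exceed {needed:.1f} mm for this head/shaft geometry"
            )
        if self.bone_length < 4.5 * self.condyle_width:
            raise PhantomParameterError("bone_length too short relative to condyle_width")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "PhantomParams":
        return cls(**{f: float(v) for f, v in zip(PARAM_FIELDS, values)})


@dataclass
class LandmarkSet:
    """Analytic (or digitised) anatomical landmarks of one femur."""

    head_center: np.ndarray
    neck_axis_point: np.ndarray
    neck_axis_dir: np.ndarray
    anatomical_axis: np.ndarray  # (k, 3) polyline of diaphyseal centroids, distal->proximal
    mechanical_axis: np.ndarray  # (2, 3): head centre, knee centre
    epicondyle_medial: np.ndarray
    epicondyle_lateral: np.ndarray
    posterior_condyle_medial: np.ndarray
    posterior_condyle_lateral: np.ndarray
    distal_condyle_medial: np.ndarray
    distal_condyle_lateral: np.ndarray

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))
        self.neck_axis_dir = unit(self.neck_axis_dir)

    def to_json(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name).tolist() for f in dataclasses.fields(self)}
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        data = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v) for k, v in data.items()})


@dataclass
class PhantomSpecimen:
    params: PhantomParams
    mesh: SurfaceMesh
    landmarks: LandmarkSet
    volume: Optional[VolumeImage] = None


# ---------------------------------------------------------------------------
# sweep construction
# ---------------------------------------------------------------------------

_RESOLUTIONS = {
    0: dict(n_theta=24, n_cap=4, n_cond=5, n_blend=3, n_shaft=12, n_fillet=4, n_neck=4, n_head=8),
    1: dict(n_theta=32, n_cap=6, n_cond=7, n_blend=4, n_shaft=18, n_fillet=5, n_neck=5, n_head=10),
    2: dict(n_theta=48, n_cap=8, n_cond=10, n_blend=6, n_shaft=26, n_fillet=7, n_neck=7, n_head=14),
}

# fraction of the bone length spanned by the standard bow measurement
# (10%..90% stations of the axis fitted over the middle 60% of the bone)
_BOW_SPAN_FRACTION = 0.48


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _neck_dir(params: PhantomParams) -> np.ndarray:
    """Unit direction from neck base to head centre."""
    ap = np.radians(180.0 - params.neck_shaft_angle)
    av = np.radians(params.anteversion_angle)
    return np.array(
        [-np.sin(ap) * np.cos(av), np.sin(ap) * np.sin(av), np.cos(ap)]
    )


def _fillet_trim(params: PhantomParams) -> float:
    # trim length of the shaft/neck corner fillet (uses the bow-free tangent;
    # the bow correction to the corner angle is negligible for validation)
    n = _neck_dir(params)
    psi = np.arccos(np.clip(n[2], -1.0, 1.0))
    rho = 2.2 * params.shaft_radius
    return rho * np.tan(psi / 2.0)


class _Sweep:
    """Analytic description of the swept-tube phantom for one parameter set."""

    def __init__(self, params: PhantomParams):
        params.validate()
        self.params = params
        p = params
        L = p.bone_length
        self.kappa = np.radians(p.bow_angle) / (_BOW_SPAN_FRACTION * L) if p.bow_angle > 0 else 0.0

        self.h_cap = 0.30 * 0.55 * p.condyle_width
        self.h_cond = 0.55 * p.condyle_width
        self.l_blend = 0.50 * self.h_cond
        self.z_blend_top = self.h_cond + self.l_blend

        self.n = _neck_dir(p)
        ap = np.radians(180.0 - p.neck_shaft_angle)
        self.z_top = L - p.neck_length * np.cos(ap) - p.head_radius
        if self.z_top <= self.z_blend_top + 0.1 * L:
            raise PhantomParameterError("shaft region collapsed; parameters inconsistent")

        self.B = np.array([0.0, self._arc_y(self.z_top), self.z_top])  # neck base (shaft top)
        self.C = self.B + p.neck_length * self.n  # head centre
        self.r_nb = 0.95 * p.shaft_radius
        self.r_ne = 0.60 * p.head_radius

        # corner fillet between shaft tangent and neck axis
        t_top = self._arc_tangent(self.z_top)
        cosps = np.clip(np.dot(t_top, self.n), -1.0, 1.0)
        self.psi = np.arccos(cosps)
        self.rho_f = 2.2 * p.shaft_radius
        self.trim = self.rho_f * np.tan(self.psi / 2.0)
        u1 = -t_top
        u2 = self.n
        w = unit(u1 + u2)
        self.fillet_center = self.B + (self.rho_f / np.cos(self.psi / 2.0)) * w
        self.T1 = self.B - self.trim * t_top
        self.T2 = self.B + self.trim * self.n
        self._t_top = t_top

        # head junction
        self.u0 = -np.sqrt(p.head_radius**2 - self.r_ne**2)
        self.phi0 = np.arcsin(self.u0 / p.head_radius)
        self.J = self.C + self.u0 * self.n

        self.z_mid_cond = 0.5 * (self.h_cap + self.h_cond)

    # -- centreline -----------------------------------------------------
    def _arc_y(self, z):
        if self.kappa == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float)) if np.ndim(z) else 0.0
        return (np.cos(self.kappa * (np.asarray(z) - self.params.bone_length / 2.0)) - 1.0) / self.kappa

    def _arc_tangent(self, z) -> np.ndarray:
        dy = -np.sin(self.kappa * (z - self.params.bone_length / 2.0)) if self.kappa else 0.0
        return unit(np.array([0.0, dy, 1.0]))

    # -- cross-section profiles -----------------------------------------
    def condyle_profile(self, theta: np.ndarray) -> np.ndarray:
        """Polar radius of the condylar cross-section (two posterior lobes)."""
        p = self.params
        a = p.condyle_width / 2.0
        b = 0.62 * a
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        for centre in (np.radians(237.0), np.radians(303.0)):
            d = np.angle(np.exp(1j * (theta - centre)))
            r = r + p.condyle_offset * np.exp(-0.5 * (d / np.radians(18.0)) ** 2)
        return r

    def _cond_scale(self, z) -> float:
        return 1.0 - 0.15 * ((z - self.z_mid_cond) / (self.h_cond / 2.0)) ** 2

    # -- station table ---------------------------------------------------
    def stations(self, counts: dict, theta: np.ndarray):
        """Ring stations (centre, frame, polar radii) from distal cap to head.

        Returns ``(centers, tangents, e1, e2, radii)`` with radii evaluated on
        the supplied ``theta`` grid.  Poles are not included.
        """
        rows = []

        def add(center, tangent, radii):
            t = unit(tangent)
            e1 = unit(np.array([1.0, 0.0, 0.0]) - t[0] * t)
            e2 = np.cross(t, e1)
            rows.append((np.asarray(center, float), t, e1, e2, np.asarray(radii, float)))

        cond = self.condyle_profile(theta)

        # distal cap (quarter-ellipse shrink to the pole; pole itself excluded)
        for k in range(1, counts["n_cap"]):
            phi = 0.5 * np.pi * k / counts["n_cap"]
            z = self.h_cap * (1.0 - np.cos(phi))
            add(
                [0.0, self._arc_y(z), z],
                self._arc_tangent(z),
                cond * self._cond_scale(self.h_cap) * np.sin(phi),
            )
        # condylar body
        for z in np.linspace(self.h_cap, self.h_cond, counts["n_cond"]):
            add([0.0, self._arc_y(z), z], self._arc_tangent(z), cond * self._cond_scale(z))
        # blend into the shaft
        for z in np.linspace(self.h_cond, self.z_blend_top, counts["n_blend"] + 1)[1:]:
            w = _smoothstep((z - self.h_cond) / self.l_blend)
            radii = (1.0 - w) * cond * self._cond_scale(self.h_cond) + w * self.params.shaft_radius
            add([0.0, self._arc_y(z), z], self._arc_tangent(z), radii)
        # shaft
        z_t1 = self.T1[2]
        for z in np.linspace(self.z_blend_top, z_t1, counts["n_shaft"] + 1)[1:]:
            add([0.0, self._arc_y(z), z], self._arc_tangent(z), np.full_like(theta, self.params.shaft_radius))
        # fillet arc
        v1 = unit(self.T1 - self.fillet_center)
        v2 = unit(self.T2 - self.fillet_center)
        axis = np.cross(v1, v2)
        axis = axis / max(np.linalg.norm(axis), 1e-12)
        for k in range(1, counts["n_fillet"] + 1):
            s = k / counts["n_fillet"]
            ang = s * self.psi
            rot = _axis_angle(axis, ang)
            centre = self.fillet_center + self.rho_f * (rot @ v1)
            tangent = rot @ self._t_top
            r = self.params.shaft_radius + (self.r_nb - self.params.shaft_radius) * s
            add(centre, tangent, np.full_like(theta, r))
        # straight neck (exclusive of both junctions)
        for k in range(1, counts["n_neck"]):
            s = k / counts["n_neck"]
            centre = self.T2 + s * (self.J - self.T2)
            r = self.r_nb + (self.r_ne - self.r_nb) * s
            add(centre, self.n, np.full_like(theta, r))
        # head (sphere; pole excluded)
        for phi in np.linspace(self.phi0, 0.5 * np.pi, counts["n_head"] + 1)[:-1]:
            centre = self.C + self.params.head_radius * np.sin(phi) * self.n
            add(centre, self.n, np.full_like(theta, self.params.head_radius * np.cos(phi)))

        centers = np.array([r[0] for r in rows])
        tangents = np.array([r[1] for r in rows])
        e1 = np.array([r[2] for r in rows])
        e2 = np.array([r[3] for r in rows])
        radii = np.array([r[4] for r in rows])
        return centers, tangents, e1, e2, radii

    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        distal = np.array([0.0, float(self._arc_y(0.0)), 0.0])
        proximal = self.C + self.params.head_radius * self.n
        return distal, proximal


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1.0 - np.cos(angle)) * (kx @ kx)


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def _resolution_counts(level: int) -> dict:
    if level not in _RESOLUTIONS:
        raise ValueError(f"mesh_resolution must be one of {sorted(_RESOLUTIONS)}")
    return _RESOLUTIONS[level]


def generate_phantom(
    params: PhantomParams, mesh_resolution: int = 1
) -> tuple[SurfaceMesh, LandmarkSet]:
    """Generate one phantom surface plus its analytic landmark set.

    Phantoms generated at the same ``mesh_resolution`` share an identical
    triangle index list, so vertex ``k`` corresponds anatomically across the
    whole population.
    """
    sweep = _Sweep(params)
    counts = _resolution_counts(mesh_resolution)
    n_theta = counts["n_theta"]
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta

    centers, tangents, e1, e2, radii = sweep.stations(counts, theta)
    n_rings = len(centers)

    ring_pts = (
        centers[:, None, :]
        + radii[:, :, None] * (np.cos(theta)[None, :, None] * e1[:, None, :]
                               + np.sin(theta)[None, :, None] * e2[:, None, :])
    )
    pole_d, pole_p = sweep.poles()
    vertices = np.concatenate([[pole_d], ring_pts.reshape(-1, 3), [pole_p]])

    tris = []
    def rid(i, j):
        return 1 + i * n_theta + (j % n_theta)
    for j in range(n_theta):
        tris.append([0, rid(0, j), rid(0, j + 1)])
    for i in range(n_rings - 1):
        for j in range(n_theta):
            tris.append([rid(i, j), rid(i + 1, j), rid(i + 1, j + 1)])
            tris.append([rid(i, j), rid(i + 1, j + 1), rid(i, j + 1)])
    last = len(vertices) - 1
    for j in range(n_theta):
        tris.append([last, rid(n_rings - 1, j + 1), rid(n_rings - 1, j)])

    mesh = SurfaceMesh(vertices, np.asarray(tris)).orient_outward()
    return mesh, _landmarks(sweep)


def _landmarks(sweep: _Sweep) -> LandmarkSet:
    p = sweep.params
    L = p.bone_length
    z_axis = np.linspace(0.2 * L, 0.8 * L, 41)
    axis_pts = np.stack([np.zeros_like(z_axis), sweep._arc_y(z_axis), z_axis], axis=1)

    # dense evaluation of the widest condylar section
    th = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    prof = sweep.condyle_profile(th) * sweep._cond_scale(sweep.z_mid_cond)
    z0 = sweep.z_mid_cond
    c0 = np.array([0.0, float(sweep._arc_y(z0)), z0])
    t0 = sweep._arc_tangent(z0)
    f1 = unit(np.array([1.0, 0.0, 0.0]) - t0[0] * t0)
    f2 = np.cross(t0, f1)
    pts = c0 + prof[:, None] * (np.cos(th)[:, None] * f1 + np.sin(th)[:, None] * f2)

    epi_lat = pts[np.argmax(pts[:, 0])]
    epi_med = pts[np.argmin(pts[:, 0])]
    lat_half = pts[:, 0] > 0
    post_lat = pts[lat_half][np.argmin(pts[lat_half][:, 1])]
    post_med = pts[~lat_half][np.argmin(pts[~lat_half][:, 1])]

    # distal condyle points from the analytic cap surface, per side, away from
    # the pole so the picks sit on the lobes
    phis = np.linspace(0.05, 0.5 * np.pi, 96)
    cond = sweep.condyle_profile(th) * sweep._cond_scale(sweep.h_cap)
    best = {1: None, -1: None}
    xmin = 0.25 * p.condyle_width / 2.0
    for phi in phis:
        z = sweep.h_cap * (1.0 - np.cos(phi))
        c = np.array([0.0, float(sweep._arc_y(z)), z])
        t = sweep._arc_tangent(z)
        g1 = unit(np.array([1.0, 0.0, 0.0]) - t[0] * t)
        g2 = np.cross(t, g1)
        ring = c + (cond * np.sin(phi))[:, None] * (np.cos(th)[:, None] * g1 + np.sin(th)[:, None] * g2)
        for side in (1, -1):
            sel = ring[:, 0] * side > xmin
            if sel.any():
                cand = ring[sel][np.argmin(ring[sel][:, 2])]
                if best[side] is None or cand[2] < best[side][2]:
                    best[side] = cand
    dist_lat, dist_med = best[1], best[-1]

    knee = 0.5 * (epi_med + epi_lat)
    return LandmarkSet(
        head_center=sweep.C,
        neck_axis_point=sweep.B,
        neck_axis_dir=sweep.n,
        anatomical_axis=axis_pts,
        mechanical_axis=np.stack([sweep.C, knee]),
        epicondyle_medial=epi_med,
        epicondyle_lateral=epi_lat,
        posterior_condyle_medial=post_med,
        posterior_condyle_lateral=post_lat,
        distal_condyle_medial=dist_med,
        distal_condyle_lateral=dist_lat,
    )


def analytic_measures(params: PhantomParams) -> dict[str, float]:
    """Ground-truth values of the anatomical measures implied by the parameters."""
    sweep = _Sweep(params)
    lm = _landmarks(sweep)
    mech = lm.mechanical_axis[0] - lm.mechanical_axis[1]
    z = np.array([0.0, 0.0, 1.0])
    cosang = abs(np.dot(unit(mech), z))
    faa_fma = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return {
        "neck_angle": params.neck_shaft_angle,
        "version_pca": params.anteversion_angle,
        "version_tea": params.anteversion_angle,
        "bow_angle": params.bow_angle,
        "faa_fma_angle": faa_fma,
        "diaphyseal_condylar_angle": 90.0,
        "head_radius": params.head_radius,
    }


# ---------------------------------------------------------------------------
# tetrahedral mesh with exact surface boundary
# ---------------------------------------------------------------------------

_RADIAL_FRACTIONS = (0.4, 0.72)


def phantom_tet_mesh(
    params: PhantomParams,
    mesh_resolution: int = 1,
    radial_fractions: Sequence[float] = _RADIAL_FRACTIONS,
) -> TetMesh:
    """Structured tetrahedral mesh whose boundary equals the phantom surface.

    Interior node layers are scaled copies of the surface rings (plus the ring
    centreline), giving identical tet topology for every phantom at one
    resolution; prisms between layers are split into tets with a globally
    consistent diagonal rule so the mesh is conforming.
    """
    sweep = _Sweep(params)
    counts = _resolution_counts(mesh_resolution)
    n_theta = counts["n_theta"]
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    centers, *_ = sweep.stations(counts, theta)
    mesh, _lm = generate_phantom(params, mesh_resolution)

    n_rings = len(centers)
    ns = mesh.n_vertices
    # shrink target per surface vertex: its ring centre (poles use the
    # neighbouring ring centre so the layers stay distinct)
    ring_of = np.empty(ns, dtype=int)
    ring_of[0] = 0
    ring_of[-1] = n_rings - 1
    ring_of[1:-1] = np.repeat(np.arange(n_rings), n_theta)
    targets = centers[ring_of]

    fracs = sorted(radial_fractions, reverse=True)
    layers = [mesh.vertices]
    for f in fracs:
        layers.append(targets + f * (mesh.vertices - targets))
    nodes = np.concatenate(layers + [centers])
    n_layers = len(layers)

    def node_id(layer: int, k: int) -> int:
        if layer < n_layers:
            return layer * ns + k
        return n_layers * ns + ring_of[k]  # collapsed centreline layer

    tris = mesh.triangles
    tets: list[tuple[int, int, int, int]] = []

    def split_quad(q0, q1, q2, q3):
        """Triangulate quad (q0..q3 cyclic) with the min-id diagonal rule."""
        if min(q0, q2) < min(q1, q3):
            return [(q0, q1, q2), (q0, q2, q3)]
        return [(q1, q2, q3), (q1, q3, q0)]

    for layer in range(n_layers):
        top = layer
        bot = layer + 1
        for tri in tris:
            a1, b1, c1 = (node_id(top, v) for v in tri)
            a0, b0, c0 = (node_id(bot, v) for v in tri)
            cell = {a1, b1, c1, a0, b0, c0}
            faces = [(a1, b1, c1), (c0, b0, a0)]
            faces += split_quad(a0, b0, b1, a1)
            faces += split_quad(b0, c0, c1, b1)
            faces += split_quad(c0, a0, a1, c1)
            m = min(cell)
            for f in faces:
                if m in f or len(set(f)) < 3:
                    continue
                tets.append((m, *f))

    tet_arr = np.asarray(tets, dtype=np.int64)
    tm = TetMesh(nodes, tet_arr, tris.copy(), frame=mesh.frame)
    vol = tm.tet_volumes()
    keep = np.abs(vol) > 1e-9
    tm.tets = tm.tets[keep]
    tm.orient_positive()
    return tm


# ---------------------------------------------------------------------------
# voxelization / classification
# ---------------------------------------------------------------------------

class _Classifier:
    """Analytic inside/cortical/medullary test against the sweep geometry."""

    def __init__(self, sweep: _Sweep, ds: float = 1.5, n_theta: int = 256):
        self.sweep = sweep
        counts = {k: max(2, int(np.ceil(v * 2))) for k, v in _RESOLUTIONS[2].items()}
        theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
        centers, tangents, e1, e2, radii = sweep.stations(counts, theta)
        pole_d, pole_p = sweep.poles()
        # resample along arc length to an even spacing
        seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n_dense = max(8, int(np.ceil(s[-1] / ds)))
        sq = np.linspace(0.0, s[-1], n_dense)
        self.centers = np.stack([np.interp(sq, s, centers[:, i]) for i in range(3)], axis=1)
        tq = np.stack([np.interp(sq, s, tangents[:, i]) for i in range(3)], axis=1)
        self.tangents = tq / np.linalg.norm(tq, axis=1, keepdims=True)
        e1q = np.stack([np.interp(sq, s, e1[:, i]) for i in range(3)], axis=1)
        self.e1 = e1q / np.linalg.norm(e1q, axis=1, keepdims=True)
        self.e2 = np.cross(self.tangents, self.e1)
        self.radii = np.stack([np.interp(sq, s, radii[:, j]) for j in range(n_theta)], axis=1)
        self.ds = s[-1] / (n_dense - 1)
        self.n_theta = n_theta
        self.tree = cKDTree(self.centers)

    def depth(self, points: np.ndarray, k: int = 6) -> np.ndarray:
        """Approximate inward distance from the surface; negative outside."""
        points = np.atleast_2d(points)
        k = min(k, len(self.centers))
        _, idx = self.tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        depth = np.full(len(points), -np.inf)
        for col in range(idx.shape[1]):
            st = idx[:, col]
            delta = points - self.centers[st]
            ax = np.einsum("ij,ij->i", delta, self.tangents[st])
            rad = delta - ax[:, None] * self.tangents[st]
            rho = np.linalg.norm(rad, axis=1)
            th = np.arctan2(
                np.einsum("ij,ij->i", rad, self.e2[st]),
                np.einsum("ij,ij->i", rad, self.e1[st]),
            ) % (2.0 * np.pi)
            tb = th / (2.0 * np.pi) * self.n_theta
            i0 = np.floor(tb).astype(int) % self.n_theta
            i1 = (i0 + 1) % self.n_theta
            w = tb - np.floor(tb)
            r_out = (1.0 - w) * self.radii[st, i0] + w * self.radii[st, i1]
            covered = np.abs(ax) <= 0.8 * self.ds
            d = np.where(covered, r_out - rho, -np.inf)
            depth = np.maximum(depth, d)
        # spherical head overrides the tube approximation
        dh = self.sweep.params.head_radius - np.linalg.norm(points - self.sweep.C, axis=1)
        depth = np.maximum(depth, dh)
        return depth


def classify_points(points: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Label points 0 = outside, 1 = cortical shell, 2 = medullary interior."""
    cls = _Classifier(_Sweep(params))
    depth = cls.depth(points)
    labels = np.zeros(len(np.atleast_2d(points)), dtype=np.int8)
    inside = depth >= 0.0
    labels[inside & (depth <= params.cortical_thickness)] = 1
    labels[inside & (depth > params.cortical_thickness)] = 2
    return labels


def voxelize_phantom(
    mesh: SurfaceMesh, params: PhantomParams, spacing: float, margin_voxels: int = 3
) -> VolumeImage:
    """Rasterise the phantom into a Hounsfield volume (cortex / canal / air)."""
    if spacing > params.shaft_radius / 2.0:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse; must be <= shaft_radius/2 = "
            f"{params.shaft_radius / 2.0:.2f} mm"
        )
    lo, hi = mesh.bounds()
    origin = lo - margin_voxels * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + margin_voxels + 1
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = origin + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing
    labels = classify_points(pts, params)
    values = np.full(len(pts), AIR_HU, dtype=np.float32)
    values[labels == 1] = params.cortical_hu
    values[labels == 2] = params.medullary_hu
    return VolumeImage(values.reshape(shape), np.full(3, float(spacing)), origin, mesh.frame)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDistribution:
    """Mean and standard deviation per phantom parameter."""

    mean: PhantomParams = PhantomParams()
    sd: dict = None  # type: ignore[assignment]

    def sds(self) -> np.ndarray:
        sd = dict(_DEFAULT_SDS)
        if self.sd:
            sd.update(self.sd)
        return np.array([sd[f] for f in PARAM_FIELDS])


_DEFAULT_SDS = {
    "bone_length": 25.0,
    "shaft_radius": 1.2,
    "cortical_thickness": 0.4,
    "head_radius": 2.0,
    "neck_length": 3.0,
    "neck_shaft_angle": 5.0,
    "anteversion_angle": 8.0,
    "bow_angle": 1.5,
    "condyle_width": 7.0,
    "condyle_offset": 3.5,
    "cortical_hu": 80.0,
    "medullary_hu": 30.0,
}


def default_distribution() -> ParamDistribution:
    return ParamDistribution(PhantomParams(), dict(_DEFAULT_SDS))


def default_correlation() -> np.ndarray:
    """Mild, plausible correlation structure between the size parameters."""
    c = np.eye(len(PARAM_FIELDS))
    pairs = {
        ("bone_length", "head_radius"): 0.5,
        ("bone_length", "condyle_width"): 0.15,
        ("bone_length", "neck_length"): 0.4,
        ("shaft_radius", "cortical_thickness"): 0.3,
        ("head_radius", "condyle_width"): 0.15,
    }
    idx = {f: i for i, f in enumerate(PARAM_FIELDS)}
    for (a, b), v in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = v
    return c


def sample_population(
    n: int,
    seed: int,
    distribution: Optional[ParamDistribution] = None,
    correlation: Optional[np.ndarray] = None,
    mesh_resolution: int = 1,
    voxel_spacing: Optional[float] = None,
    max_tries: int = 1000,
    generate_geometry: bool = True,
) -> list[PhantomSpecimen]:
    """Draw a seeded population of phantoms from a truncated multivariate normal.

    Parameter vectors violating the :class:`PhantomParams` bounds are redrawn
    (truncation by rejection), so the distribution has no boundary atoms.
    ``voxel_spacing=None`` skips the (comparatively expensive) voxelization;
    ``generate_geometry=False`` returns parameters only (mesh/landmarks None).
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    distribution = distribution or default_distribution()
    correlation = default_correlation() if correlation is None else np.asarray(correlation, float)
    eig = np.linalg.eigvalsh(correlation)
    if eig.min() < -1e-9:
        raise ValueError(f"correlation matrix not positive semi-definite (min eig {eig.min():.3g})")

    sds = distribution.sds()
    mean = distribution.mean.as_array()
    cov = correlation * np.outer(sds, sds)
    rng = np.random.default_rng(seed)

    specimens: list[PhantomSpecimen] = []
    for _ in range(n):
        params = None
        for _try in range(max_tries):
            vec = rng.multivariate_normal(mean, cov, method="svd")
            candidate = PhantomParams.from_array(vec)
            try:
                candidate.validate()
            except PhantomParameterError:
                continue
            params = candidate
            break
        if params is None:
            raise RuntimeError("could not draw valid phantom parameters; check distribution")
        if generate_geometry:
            mesh, lm = generate_phantom(params, mesh_resolution)
            vol = voxelize_phantom(mesh, params, voxel_spacing) if voxel_spacing else None
            specimens.append(PhantomSpecimen(params, mesh, lm, vol))
        else:
            specimens.append(PhantomSpecimen(params, None, None, None))  # type: ignore[arg-type]
    return specimens
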