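"""Surface error and anatomical-measure scoring of reconstructed femurs.

Measures: bow angle (tangent spread of the diaphyseal axis), FAA-FMA angle
(anatomical vs mechanical axis), femoral neck angle, diaphyseal-condylar
angle, version angles against the posterior-condylar and trans-epicondylar
axes (projected onto the transverse plane, i.e. the plane normal to the
anatomical axis) and femoral head radius from a least-squares sphere fit.

Landmark-free measurement digitises landmarks with extremal-point heuristics
in a canonical pose derived from the mesh itself, which makes every measure
exactly equivariant under rigid motion; an explicit :class:`LandmarkSet`
can override the heuristics.  All region thresholds scale with bone length,
so angle measures are invariant under uniform scaling as well.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .mesh import MeshError, SurfaceDistance, SurfaceMesh
from .phantom import LandmarkSet
from .ssam import rigid_align
from .transforms import RigidTransform, angle_between, line_angle, unit

__all__ = [
    "AnatomicalMeasures",
    "EvaluationReport",
    "FemoralAxes",
    "surface_rmse",
    "hausdorff",
    "fit_sphere",
    "derive_axes",
    "compute_measures",
    "evaluate_case",
]


class RegionUnavailableError(ValueError):
    """A mesh region required for an axis is missing (e.g. cropped away)."""


MEASURE_NAMES = (
    "bow_angle",
    "faa_fma_angle",
    "neck_angle",
    "diaphyseal_condylar_angle",
    "version_pca",
    "version_tea",
    "head_radius",
)


@dataclass
class AnatomicalMeasures:
    bow_angle: float
    faa_fma_angle: float
    neck_angle: float
    diaphyseal_condylar_angle: float
    version_pca: float
    version_tea: float
    head_radius: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in MEASURE_NAMES}


@dataclass
class EvaluationReport:
    rmse: float
    rmse_symmetric: float
    hausdorff: float
    measure_errors: dict[str, float]
    alignment: RigidTransform
    metadata: dict

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "rmse_symmetric": self.rmse_symmetric,
            "hausdorff": self.hausdorff,
            "measure_errors": self.measure_errors,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


# ---------------------------------------------------------------------------
# surface errors
# ---------------------------------------------------------------------------

def _aligned(recon: SurfaceMesh, truth: SurfaceMesh, align: bool):
    if recon.n_vertices == 0 or truth.n_vertices == 0:
        raise MeshError("cannot score empty meshes")
    if align:
        tf, moved = rigid_align(recon, truth)
    else:
        tf, moved = RigidTransform.identity(), recon
    return tf, moved


def surface_rmse(
    recon: SurfaceMesh, truth: SurfaceMesh, align: bool = True
) -> float:
    """RMS point-to-surface distance of recon vertices after rigid ICP alignment."""
    _, moved = _aligned(recon, truth, align)
    d = SurfaceDistance(truth)(moved.vertices)
    return float(np.sqrt(np.mean(d**2)))


def hausdorff(recon: SurfaceMesh, truth: SurfaceMesh, align: bool = True) -> float:
    """Symmetric Hausdorff point-to-surface distance after the same alignment."""
    _, moved = _aligned(recon, truth, align)
    d1 = SurfaceDistance(truth)(moved.vertices)
    d2 = SurfaceDistance(moved)(truth.vertices)
    return float(max(d1.max(), d2.max()))


# ---------------------------------------------------------------------------
# sphere fit
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves the linearised system ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` and
    returns ``(center, radius, rms_residual)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    a = np.concatenate([2.0 * points, np.ones((len(points), 1))], axis=1)
    rhs = (points**2).sum(axis=1)
    sol, _res, rank, _sv = np.linalg.lstsq(a, rhs, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) points; sphere fit is singular")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    residual = float(np.sqrt(np.mean((np.linalg.norm(points - center, axis=1) - radius) ** 2)))
    return center, radius, residual


# ---------------------------------------------------------------------------
# canonical pose
# ---------------------------------------------------------------------------

def _canonical_transform(mesh: SurfaceMesh) -> RigidTransform:
    """Pose normalisation derived from the mesh alone (rigidly equivariant).

    z: long axis oriented so the end with the larger lateral centroid offset
    (the head) is proximal; x: opposite of the proximal offset direction
    (head is medial); y completes the right-handed frame.
    """
    v = mesh.vertices
    c = v.mean(axis=0)
    _w, vec = np.linalg.eigh(np.cov((v - c).T))
    long_axis = vec[:, -1]

    t = (v - c) @ long_axis
    n_slab = 10
    edges = np.linspace(t.min(), t.max() + 1e-9, n_slab + 1)
    offsets = []
    for i in range(n_slab):
        sel = (t >= edges[i]) & (t < edges[i + 1])
        if sel.sum() < 3:
            offsets.append(np.zeros(3))
            continue
        sc = v[sel].mean(axis=0) - c
        offsets.append(sc - (sc @ long_axis) * long_axis)
    off0 = np.linalg.norm(offsets[0])
    off9 = np.linalg.norm(offsets[-1])
    if off0 > off9:  # head at the low end -> flip
        long_axis = -long_axis
        head_off = offsets[0]
    else:
        head_off = offsets[-1]
    z = long_axis
    x = -unit(head_off - (head_off @ z) * z)
    y = np.cross(z, x)
    r = np.stack([x, y, z])  # world -> canonical
    return RigidTransform(r, -r @ c)


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------

@dataclass
class FemoralAxes:
    anatomical_point: np.ndarray
    anatomical_dir: np.ndarray  # unit, pointing proximally
    anatomical_polyline: np.ndarray  # (k, 3) distal -> proximal
    bow_tangent_distal: np.ndarray
    bow_tangent_proximal: np.ndarray
    mechanical_dir: np.ndarray  # knee centre -> head centre
    neck_point: np.ndarray
    neck_dir: np.ndarray  # pointing toward the head
    tea_dir: np.ndarray  # lateral -> medial
    pca_dir: np.ndarray  # lateral -> medial
    distal_condylar_dir: np.ndarray
    head_center: np.ndarray
    head_radius: float
    head_fit_residual: float
    knee_center: np.ndarray
    medial_dir: np.ndarray

    def transformed(self, tf: RigidTransform) -> "FemoralAxes":
        r = tf.rotation
        return FemoralAxes(
            anatomical_point=tf.apply(self.anatomical_point),
            anatomical_dir=r @ self.anatomical_dir,
            anatomical_polyline=tf.apply(self.anatomical_polyline),
            bow_tangent_distal=r @ self.bow_tangent_distal,
            bow_tangent_proximal=r @ self.bow_tangent_proximal,
            mechanical_dir=r @ self.mechanical_dir,
            neck_point=tf.apply(self.neck_point),
            neck_dir=r @ self.neck_dir,
            tea_dir=r @ self.tea_dir,
            pca_dir=r @ self.pca_dir,
            distal_condylar_dir=r @ self.distal_condylar_dir,
            head_center=tf.apply(self.head_center),
            head_radius=self.head_radius,
            head_fit_residual=self.head_fit_residual,
            knee_center=tf.apply(self.knee_center),
            medial_dir=r @ self.medial_dir,
        )


def _fit_axis_polyline(v: np.ndarray, z_dir: np.ndarray, n_stations: int = 25,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Diaphyseal axis: soft-binned centroids of cross-sections, cubic-smoothed.

    The diaphysis is the middle 60% of the bone length along ``z_dir``.
    Gaussian soft bins along the axis suppress aliasing between the bin edges
    and the discrete vertex rings of typical surface meshes.  Returns
    (polyline, direction, tangent at 10% station, tangent at 90% station).
    """
    z = v @ z_dir
    z_lo, z_hi = z.min(), z.max()
    length = z_hi - z_lo
    sel = (z >= z_lo + 0.2 * length) & (z <= z_lo + 0.8 * length)
    if sel.sum() < 30:
        raise RegionUnavailableError("diaphysis region too sparse for the anatomical axis")
    d = v[sel]
    # surface PCA gives the tube direction directly
    dc = d - d.mean(axis=0)
    _w, vec = np.linalg.eigh(dc.T @ dc)
    axis = vec[:, -1]
    if axis @ z_dir < 0:
        axis = -axis

    t = dc @ axis
    sigma = (t.max() - t.min()) / n_stations
    stations = np.linspace(t.min() + 1.5 * sigma, t.max() - 1.5 * sigma, n_stations)
    w = np.exp(-0.5 * ((t[None, :] - stations[:, None]) / sigma) ** 2)
    wsum = w.sum(axis=1)
    if (wsum < 1e-9).any():
        raise RegionUnavailableError("diaphysis region too sparse for the anatomical axis")
    centroids = (w @ d) / wsum[:, None]

    # cubic fit of each coordinate against the normalised arc parameter
    s = (centroids - centroids[0]) @ axis
    s = s / s[-1]
    coef = np.stack([np.polyfit(s, centroids[:, i], 3) for i in range(3)], axis=1)
    sq = np.linspace(0.0, 1.0, 41)
    poly = np.stack([np.polyval(coef[:, i], sq) for i in range(3)], axis=1)
    dcoef = np.stack([np.polyder(coef[:, i]) for i in range(3)], axis=1)

    def tangent(station: float) -> np.ndarray:
        return unit(np.array([np.polyval(dcoef[:, i], station) for i in range(3)]))

    # bow tangent stations: 10%/90% of the middle-60% diaphysis, measured on
    # the bone-length scale (soft binning shrinks the fitted span slightly,
    # so the stations are located by their axial position, not by the
    # normalised fit parameter)
    z_poly = poly @ z_dir
    z_mid = 0.5 * (z_poly[0] + z_poly[-1])
    half_span = 0.5 * 0.8 * 0.6 * length
    s_lo = float(np.interp(z_mid - half_span, z_poly, sq))
    s_hi = float(np.interp(z_mid + half_span, z_poly, sq))

    cc = centroids - centroids.mean(axis=0)
    _w2, vec2 = np.linalg.eigh(cc.T @ cc)
    direction = vec2[:, -1]
    if direction @ axis < 0:
        direction = -direction
    return poly, unit(direction), tangent(s_lo), tangent(s_hi)


def _head_fit(v: np.ndarray, scale: float, z_dir: np.ndarray, x_dir: np.ndarray
              ) -> tuple[np.ndarray, float, float]:
    """Iterative inlier-band sphere fit of the femoral head."""
    score = 0.77 * (v @ z_dir) - 0.64 * (v @ x_dir)
    seed = v[np.argmax(score)]
    sel = np.linalg.norm(v - seed, axis=1) < 0.065 * scale
    if sel.sum() < 10:
        raise RegionUnavailableError("head region too sparse for a sphere fit")
    center, radius, resid = fit_sphere(v[sel])
    for _ in range(6):
        d = np.linalg.norm(v - center, axis=1)
        sel = np.abs(d - radius) < 0.10 * radius
        if sel.sum() < 10:
            break
        center, radius, resid = fit_sphere(v[sel])
    return center, radius, resid


def _neck_axis(v: np.ndarray, head_center: np.ndarray, head_radius: float,
               anat_point: np.ndarray, anat_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Neck axis anchored at the head centre.

    The direction is iterated as head_centre -> Gaussian-weighted centroid of
    a mid-neck window; the window's proximal end is refined from the closest
    approach of the current neck line to the shaft axis so the trochanteric
    junction never contaminates the centroid.  A windowed centroid of full
    cross-section rings lies on the neck axis, so the fixed point is the true
    axis up to surface discretisation.
    """
    rel = head_center - anat_point
    foot = anat_point + (rel @ anat_dir) * anat_dir
    n = unit(head_center - foot)
    t_base = np.linalg.norm(head_center - foot)
    for phase in range(4):
        if phase == 0:
            t_hi = 1.8 * head_radius
        else:
            # distance to the shaft axis along the current neck line
            m = np.stack([anat_dir, n], axis=1)
            su, *_ = np.linalg.lstsq(m, head_center - anat_point, rcond=None)
            t_base = abs(su[1])
            t_hi = min(2.2 * head_radius, max(0.62 * t_base, 1.35 * head_radius))
        t_lo = 1.15 * head_radius
        for _ in range(8):
            t = (v - head_center) @ (-n)
            tmid = 0.5 * (t_lo + t_hi)
            width = (t_hi - t_lo) / 3.0
            wgt = np.exp(-0.5 * ((t - tmid) / width) ** 2)
            if (wgt > 0.1).sum() < 8:
                raise RegionUnavailableError("neck region too sparse for the neck axis")
            c_w = (wgt @ v) / wgt.sum()
            n = unit(head_center - c_w)
    return head_center - t_base * n, n


def derive_axes(mesh: SurfaceMesh, landmarks: Optional[LandmarkSet] = None) -> FemoralAxes:
    """All measurement axes of a femur mesh.

    Without landmarks the mesh is first brought to a canonical pose (making
    the heuristics rigidly equivariant); explicit landmarks take precedence
    for head/neck/condyles while the diaphyseal axis is always re-fitted from
    the mesh surface.
    """
    if landmarks is not None:
        return _axes_from_landmarks(mesh, landmarks)
    tf = _canonical_transform(mesh)
    canon = mesh.transformed(tf)
    axes = _axes_canonical(canon.vertices)
    return axes.transformed(tf.inverse())


def _axes_canonical(v: np.ndarray) -> FemoralAxes:
    """Axes from extremal-point heuristics, with a two-pass frame refinement.

    Pass 1 works in the rough PCA pose; its anatomical axis and
    trans-epicondylar direction then define a refined frame (z along the
    diaphysis, x along medial->lateral) in which all picks are repeated.
    This removes the pose bias of the PCA long axis and of the anteverted
    head-offset direction.
    """
    x_dir = np.array([1.0, 0.0, 0.0])
    z_dir = np.array([0.0, 0.0, 1.0])

    for _pass in range(3):
        y_dir = np.cross(z_dir, x_dir)
        zs = v @ z_dir
        z_lo_all = zs.min()
        length = zs.max() - z_lo_all

        poly, anat_dir, tan_d, tan_p = _fit_axis_polyline(v, z_dir)
        head_center, head_radius, head_resid = _head_fit(v, length, z_dir, x_dir)

        distal = v[zs < z_lo_all + 0.16 * length]
        if len(distal) < 30:
            raise RegionUnavailableError("distal condylar region missing")
        # widest transverse direction of the condylar mass defines the
        # epicondylar search direction (robust to the anteverted head pulling
        # the frame's x off axis)
        q = distal - distal.mean(axis=0)
        q = q - np.outer(q @ z_dir, z_dir)
        _wq, vecq = np.linalg.eigh(q.T @ q)
        w_dir = vecq[:, -1]
        if w_dir @ x_dir < 0:
            w_dir = -w_dir
        dx = distal @ w_dir
        epi_lat = distal[np.argmax(dx)]
        epi_med = distal[np.argmin(dx)]
        knee = 0.5 * (epi_lat + epi_med)
        tea = unit(epi_med - epi_lat)

        y_w = np.cross(z_dir, w_dir)
        med_mask = dx < knee @ w_dir
        med_side, lat_side = distal[med_mask], distal[~med_mask]
        if len(med_side) < 5 or len(lat_side) < 5:
            raise RegionUnavailableError("condylar lobes missing for the posterior axis")
        post_med = med_side[np.argmin(med_side @ y_w)]
        post_lat = lat_side[np.argmin(lat_side @ y_w)]
        pca = unit(post_med - post_lat)

        half_w = 0.5 * np.linalg.norm(epi_lat - epi_med)
        dm = med_side[np.abs((med_side - knee) @ w_dir) > 0.25 * half_w]
        dl = lat_side[np.abs((lat_side - knee) @ w_dir) > 0.25 * half_w]
        if len(dm) < 3 or len(dl) < 3:
            raise RegionUnavailableError("condylar lobes missing for the distal axis")
        dist_med = dm[np.argmin(dm @ z_dir)]
        dist_lat = dl[np.argmin(dl @ z_dir)]
        dc = unit(dist_med - dist_lat)

        # refined frame for the second pass
        z_dir = anat_dir
        x_new = unit(epi_lat - epi_med)
        x_dir = unit(x_new - (x_new @ z_dir) * z_dir)

    neck_point, neck_dir = _neck_axis(v, head_center, head_radius, poly[0], anat_dir)
    mech = unit(head_center - knee)
    medial = unit(epi_med - epi_lat)

    return FemoralAxes(
        anatomical_point=poly[0],
        anatomical_dir=anat_dir,
        anatomical_polyline=poly,
        bow_tangent_distal=tan_d,
        bow_tangent_proximal=tan_p,
        mechanical_dir=mech,
        neck_point=neck_point,
        neck_dir=neck_dir,
        tea_dir=tea,
        pca_dir=pca,
        distal_condylar_dir=dc,
        head_center=head_center,
        head_radius=head_radius,
        head_fit_residual=head_resid,
        knee_center=knee,
        medial_dir=medial,
    )


def _axes_from_landmarks(mesh: SurfaceMesh, lm: LandmarkSet) -> FemoralAxes:
    poly = lm.anatomical_axis
    cc = poly - poly.mean(axis=0)
    _w, vec = np.linalg.eigh(cc.T @ cc)
    anat_dir = vec[:, -1]
    if anat_dir @ (poly[-1] - poly[0]) < 0:
        anat_dir = -anat_dir
    s = np.linspace(0.0, 1.0, len(poly))
    coef = np.stack([np.polyfit(s, poly[:, i], 3) for i in range(3)], axis=1)
    dcoef = np.stack([np.polyder(coef[:, i]) for i in range(3)], axis=1)

    def tangent(st):
        return unit(np.array([np.polyval(dcoef[:, i], st) for i in range(3)]))

    knee = lm.mechanical_axis[1]
    # head radius from surface vertices near the landmark head centre
    d = np.linalg.norm(mesh.vertices - lm.head_center, axis=1)
    r0 = np.median(d[d < np.percentile(d, 5)])
    sel = np.abs(d - r0) < 0.25 * r0
    center, radius, resid = fit_sphere(mesh.vertices[sel]) if sel.sum() >= 10 else (
        lm.head_center, float(r0), 0.0)
    return FemoralAxes(
        anatomical_point=poly[0],
        anatomical_dir=unit(anat_dir),
        anatomical_polyline=poly,
        bow_tangent_distal=tangent(0.1),
        bow_tangent_proximal=tangent(0.9),
        mechanical_dir=unit(lm.mechanical_axis[0] - lm.mechanical_axis[1]),
        neck_point=lm.neck_axis_point,
        neck_dir=unit(lm.neck_axis_dir),
        tea_dir=unit(lm.epicondyle_medial - lm.epicondyle_lateral),
        pca_dir=unit(lm.posterior_condyle_medial - lm.posterior_condyle_lateral),
        distal_condylar_dir=unit(lm.distal_condyle_medial - lm.distal_condyle_lateral),
        head_center=np.asarray(center, float),
        head_radius=float(radius),
        head_fit_residual=float(resid),
        knee_center=knee,
        medial_dir=unit(lm.epicondyle_medial - lm.epicondyle_lateral),
    )


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def _signed_version(neck: np.ndarray, condylar: np.ndarray, anat: np.ndarray) -> float:
    """Signed angle (deg) between neck and condylar axis in the transverse plane.

    Positive for an anteverted neck.  The condylar axis is oriented to the
    medial hemisphere of the neck projection before the angle is taken.
    """
    n_p = neck - (neck @ anat) * anat
    c = condylar.copy()
    c_p = c - (c @ anat) * anat
    if np.linalg.norm(n_p) < 1e-12 or np.linalg.norm(c_p) < 1e-12:
        raise RegionUnavailableError("axis parallel to the transverse normal; version undefined")
    n_p = unit(n_p)
    c_p = unit(c_p)
    if n_p @ c_p < 0:
        c_p = -c_p
    ang = np.degrees(np.arctan2(np.cross(n_p, c_p) @ anat, n_p @ c_p))
    return float(ang)


def compute_measures(
    mesh: SurfaceMesh,
    axes: Optional[FemoralAxes] = None,
    landmarks: Optional[LandmarkSet] = None,
) -> AnatomicalMeasures:
    """Anatomical measures from a femur mesh (axes derived if not supplied)."""
    if axes is None:
        axes = derive_axes(mesh, landmarks)
    a = axes.anatomical_dir
    bow = angle_between(axes.bow_tangent_distal, axes.bow_tangent_proximal)
    faa_fma = line_angle(a, axes.mechanical_dir)
    neck_angle = angle_between(axes.neck_dir, -a)
    diaph_cond = line_angle(a, axes.distal_condylar_dir)
    v_pca = _signed_version(axes.neck_dir, axes.pca_dir, a)
    v_tea = _signed_version(axes.neck_dir, axes.tea_dir, a)
    return AnatomicalMeasures(
        bow_angle=bow,
        faa_fma_angle=faa_fma,
        neck_angle=neck_angle,
        diaphyseal_condylar_angle=diaph_cond,
        version_pca=v_pca,
        version_tea=v_tea,
        head_radius=axes.head_radius,
    )


def evaluate_case(
    recon: SurfaceMesh,
    truth: SurfaceMesh,
    metadata: Optional[dict] = None,
    truth_landmarks: Optional[LandmarkSet] = None,
) -> EvaluationReport:
    """Bundle surface errors and per-measure absolute differences.

    The truth mesh must be intact; both meshes are measured with the same
    (landmark-free) algorithm so measure errors reflect shape differences,
    not digitisation differences.
    """
    tf, moved = _aligned(recon, truth, align=True)
    d1 = SurfaceDistance(truth)(moved.vertices)
    d2 = SurfaceDistance(moved)(truth.vertices)
    rmse = float(np.sqrt(np.mean(d1**2)))
    rmse_sym = float(np.sqrt(0.5 * (np.mean(d1**2) + np.mean(d2**2))))
    haus = float(max(d1.max(), d2.max()))

    m_rec = compute_measures(recon).as_dict()
    m_tru = compute_measures(truth, landmarks=truth_landmarks).as_dict()
    errors = {k: abs(m_rec[k] - m_tru[k]) for k in MEASURE_NAMES}
    return EvaluationReport(
        rmse=rmse,
        rmse_symmetric=rmse_sym,
        hausdorff=haus,
        measure_errors=errors,
        alignment=tf,
        metadata=metadata or {},
    )
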