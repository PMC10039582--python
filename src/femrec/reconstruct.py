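"""Recover model mode weights from one or two (possibly cropped) radiographs.

The objective instantiates the model at weights ``b``, projects it with the
target's geometry, applies the target's defect mask, aligns the projections in
2D (proximal-point pre-alignment followed by rigid ICP on the silhouettes) and
evaluates either the mean contour distance (mm) or ``1 - Pearson r`` of the
grey values.  Optimization is bound-constrained L-BFGS-B, run incrementally:
stage ``k`` optimizes ``k`` weights starting from the stage ``k-1`` solution
padded with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .drr import Contour, ProjectionError, Radiograph, TetSplatter, extract_contour
from .mesh import SurfaceMesh
from .ssam import SSAM

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "align_images",
    "contour_metric",
    "intensity_metric",
    "objective",
    "reconstruct",
    "prepare_targets",
    "make_splatter",
]


class MetricError(ValueError):
    pass


@dataclass
class ReconstructionConfig:
    metric: str = "contour"  # "contour" | "intensity"
    views: str = "AP_ML"  # "AP" | "AP_ML"
    n_modes: int = 14
    weight_bounds: float = 3.0  # +- SD per mode
    defect_level: float = 0.0
    step: float = 1.5  # ray sampling step, mm
    smooth_sigma: float = 0.8  # projection smoothing, px
    sample_spacing: Optional[float] = None  # splat sample spacing; None = 0.9 * pixel spacing
    contour_threshold: float = 0.01
    symmetric_contour: bool = False
    align_max_iter: int = 30
    align_tol: float = 1e-3
    maxiter: int = 60
    gtol: float = 1e-6
    ftol: float = 1e-9
    fd_eps: float = 0.15  # central-difference step in SD units
    bracket_new_mode: bool = True  # coarse 1D scan of each newly added mode

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.weight_bounds <= 0:
            raise ValueError("weight_bounds must be > 0")
        if self.metric not in ("contour", "intensity"):
            raise ValueError("metric must be 'contour' or 'intensity'")
        if self.views not in ("AP", "AP_ML"):
            raise ValueError("views must be 'AP' or 'AP_ML'")

    @property
    def view_list(self) -> list[str]:
        return ["AP"] if self.views == "AP" else ["AP", "ML"]


@dataclass
class ReconstructionResult:
    weights: np.ndarray
    mesh: SurfaceMesh
    objective_trace: list[float]  # final objective per incremental stage
    converged: list[bool]
    per_view_residuals: dict[str, float]
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# 2D rigid contour alignment
# ---------------------------------------------------------------------------

def _rigid_2d(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    return r, fc - r @ mc


def align_images(
    model_contour: Contour,
    target_contour: Contour,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """2D rigid transform aligning the model contour onto the target contour.

    Translation is initialised so the most proximal points coincide (ties
    broken by the smaller lateral coordinate), then refined with rigid ICP on
    closest contour points.  An identity-start ICP is run as well and the
    solution with the lower matched RMS is returned (guards against local
    optima of the proximal-point start on ragged silhouettes).
    Returns ``(R, t)`` with ``p' = R p + t``.
    """
    if len(model_contour.points) == 0 or len(target_contour.points) == 0:
        raise MetricError("cannot align empty contours")
    tree = cKDTree(target_contour.points)
    # decimate dense marching-squares contours for the alignment only
    src = model_contour.points
    if len(src) > 400:
        src = src[:: len(src) // 400 + 1]

    def run_icp(t_init: np.ndarray):
        pts = src + t_init
        r_total = np.eye(2)
        t_total = t_init.copy()
        rms = prev = np.inf
        for _ in range(max_iter):
            d, idx = tree.query(pts)
            rms = float(np.sqrt(np.mean(d**2)))
            if prev - rms < tol:
                break
            prev = rms
            r, t = _rigid_2d(pts, target_contour.points[idx])
            pts = pts @ r.T + t
            r_total = r @ r_total
            t_total = r @ t_total + t
        return r_total, t_total, rms

    pre = target_contour.most_proximal() - model_contour.most_proximal()
    best = run_icp(pre)
    # only pay for the identity-start fallback when the proximal start did badly
    med_seg = np.median(
        np.linalg.norm(np.diff(target_contour.points[:64], axis=0), axis=1)
    )
    if best[2] > 4.0 * med_seg:
        alt = run_icp(np.zeros(2))
        if alt[2] < best[2]:
            best = alt
    return best[0], best[1]


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def _segments(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    p = contour.points
    q = np.roll(p, -1, axis=0) if contour.closed else p[1:]
    if not contour.closed:
        p = p[:-1]
    return p, q


def _points_to_polyline(points: np.ndarray, contour: Contour, k: int = 12) -> np.ndarray:
    """Distance from each point to the nearest segment of the contour.

    Candidate segments come from a KD-tree over segment midpoints; since
    marching-squares segments are at most a pixel long this is exact in
    practice while staying linear in the contour size.
    """
    a, b = _segments(contour)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    mid = 0.5 * (a + b)
    k = min(k, len(mid))
    _, idx = cKDTree(mid).query(points, k=k)
    idx = idx.reshape(len(points), k)
    flat = idx.ravel()
    p = np.repeat(points, k, axis=0)
    ap = p - a[flat]
    t = np.clip(np.einsum("ij,ij->i", ap, ab[flat]) / denom[flat], 0.0, 1.0)
    proj = a[flat] + t[:, None] * ab[flat]
    d = np.linalg.norm(p - proj, axis=1).reshape(len(points), k)
    return d.min(axis=1)


def contour_metric(
    model_contour: Contour,
    target_contour: Contour,
    valid_v_max: Optional[float] = None,
    symmetric: bool = False,
) -> float:
    """Mean distance (mm) from model-contour points to the target contour.

    Points with ``v >= valid_v_max`` (the defect-cropped region) are excluded.
    The symmetric variant averages both one-way means.
    """
    pts = model_contour.points
    if valid_v_max is not None:
        pts = pts[pts[:, 1] < valid_v_max]
        if len(pts) == 0:
            raise MetricError("all model contour points fall in the masked region")
    fwd = float(_points_to_polyline(pts, target_contour).mean())
    if not symmetric:
        return fwd
    tpts = target_contour.points
    if valid_v_max is not None:
        tpts = tpts[tpts[:, 1] < valid_v_max]
        if len(tpts) == 0:
            raise MetricError("all target contour points fall in the masked region")
    rev = float(_points_to_polyline(tpts, model_contour).mean())
    return 0.5 * (fwd + rev)


def intensity_metric(
    model_image: np.ndarray, target_image: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation of grey values over the unmasked pixels."""
    a = np.asarray(model_image, dtype=float).ravel()
    b = np.asarray(target_image, dtype=float).ravel()
    if a.shape != b.shape:
        raise MetricError("images must have identical shape")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    if len(a) < 2:
        raise MetricError("need at least 2 unmasked pixels")
    sa = a - a.mean()
    sb = b - b.mean()
    va = float(sa @ sa)
    vb = float(sb @ sb)
    if va == 0.0 or vb == 0.0:
        raise MetricError("zero variance in the unmasked region; correlation undefined")
    return float((sa @ sb) / np.sqrt(va * vb))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

@dataclass
class _TargetView:
    radiograph: Radiograph
    contour: Contour
    valid_v_max: Optional[float]  # detector-mm boundary of the cropped region


def prepare_targets(
    targets: dict[str, Radiograph], config: ReconstructionConfig
) -> dict[str, _TargetView]:
    """Extract target contours and defect boundaries once per reconstruction."""
    prepped = {}
    for view in config.view_list:
        if view not in targets:
            raise MetricError(f"missing target radiograph for view {view}")
        rad = targets[view]
        contour = extract_contour(rad, config.contour_threshold)
        valid_v = None
        invalid_rows = np.nonzero(~rad.defect_mask.all(axis=1))[0]
        if len(invalid_rows):
            # exclude everything from one pixel above the cut so the straight
            # crop edge itself never contributes to the metric
            cut_row = invalid_rows.min() - 1.0
            valid_v = float(rad.geometry.pixel_to_mm(np.array([cut_row]), np.array([0]))[0, 1])
        prepped[view] = _TargetView(rad, contour, valid_v)
    return prepped


def make_splatter(model: SSAM, config: ReconstructionConfig, targets: dict) -> TetSplatter:
    """Adaptive splat sampler for the model, matched to the target pixel size."""
    spacing = config.sample_spacing
    if spacing is None:
        px = min(
            (
                (v.radiograph if isinstance(v, _TargetView) else v).geometry.pixel_spacing
                for v in targets.values()
            ),
            default=config.step,
        )
        spacing = 0.9 * min(px, config.step)
    return TetSplatter(
        model.tets, ref_nodes=model.mean_shape.reshape(-1, 3), sample_spacing=spacing
    )


def objective(
    b: np.ndarray,
    model: SSAM,
    targets: dict[str, "_TargetView | Radiograph"],
    config: ReconstructionConfig,
    splatter: Optional[TetSplatter] = None,
    views: Optional[Sequence[str]] = None,
) -> float:
    """Sum of per-view metric values for mode weights ``b``."""
    if any(not isinstance(v, _TargetView) for v in targets.values()):
        targets = prepare_targets({k: v for k, v in targets.items()}, config)  # type: ignore[arg-type]
    if splatter is None:
        splatter = make_splatter(model, config, targets)

    nodes, hu = model.instantiate_arrays(np.asarray(b, dtype=float))
    if hu is None:
        hu = np.full(len(model.tets), 800.0)  # plain SSM: constant-opacity silhouette

    total = 0.0
    for view in (views if views is not None else config.view_list):
        tgt: _TargetView = targets[view]  # type: ignore[assignment]
        geom = tgt.radiograph.geometry
        img = splatter.project(nodes, hu, geom, step=config.step,
                               smooth_sigma=config.smooth_sigma)
        img = np.where(tgt.radiograph.defect_mask, img, 0.0)
        try:
            mcontour = extract_contour(Radiograph(img, geom), config.contour_threshold)
        except ProjectionError:
            total += 1e3  # instance projects outside the detector
            continue
        r2, t2 = align_images(mcontour, tgt.contour, config.align_max_iter, config.align_tol)
        aligned = Contour(mcontour.points @ r2.T + t2, closed=True)
        if config.metric == "contour":
            total += contour_metric(aligned, tgt.contour, tgt.valid_v_max,
                                    config.symmetric_contour)
        else:
            moved = _warp_image(img, geom, r2, t2)
            mask = tgt.radiograph.defect_mask
            r = intensity_metric(moved, tgt.radiograph.pixels, mask)
            total += 1.0 - r
    return total


def _warp_image(img: np.ndarray, geom, r2: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Apply the 2D rigid contour transform to the model image (detector mm)."""
    ps = geom.pixel_spacing
    rows, cols = img.shape
    c = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    # contour transform acts on (u, v) = ((col - cu) ps, (row - cv) ps)
    m = np.array([[r2[0, 0], r2[0, 1]], [r2[1, 0], r2[1, 1]]])
    # output pixel -> input pixel (inverse map, in (col,row) order)
    minv = np.linalg.inv(m)
    offset_uv = -minv @ t2
    a = np.zeros((2, 2))
    a[0, 0], a[0, 1] = minv[1, 1], minv[1, 0]
    a[1, 0], a[1, 1] = minv[0, 1], minv[0, 0]
    # row/col affine: in_rc = A @ (out_rc - c_rc) + c_rc + offset_rc
    c_rc = c[::-1]
    off = c_rc + offset_uv[::-1] / ps - a @ c_rc
    return ndimage.affine_transform(img, a, offset=off, order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# incremental bound-constrained optimization
# ---------------------------------------------------------------------------

def reconstruct(
    model: SSAM,
    targets: dict[str, Radiograph],
    config: ReconstructionConfig,
) -> ReconstructionResult:
    """Incremental-mode reconstruction of mode weights from target radiographs."""
    if model.n_modes < config.n_modes:
        raise ValueError(
            f"model has {model.n_modes} modes but config requests {config.n_modes}"
        )
    prepped = prepare_targets(targets, config)
    splatter = make_splatter(model, config, prepped)
    n_eval = 0

    def fun(b):
        nonlocal n_eval
        n_eval += 1
        return objective(b, model, prepped, config, splatter)

    def jac(b):
        # central differences at a step large enough to see through the
        # sub-pixel jitter of the rendered silhouettes
        g = np.empty(len(b))
        h = config.fd_eps
        for i in range(len(b)):
            e = np.zeros(len(b))
            e[i] = h
            g[i] = (fun(b + e) - fun(b - e)) / (2.0 * h)
        return g

    trace: list[float] = []
    converged: list[bool] = []
    current = np.zeros(1)
    scan = np.linspace(-0.8 * config.weight_bounds, 0.8 * config.weight_bounds, 7)
    for k in range(1, config.n_modes + 1):
        x0 = np.zeros(k)
        x0[: len(current)] = current[:k]
        if config.bracket_new_mode:
            # coarse bracket of the newly added weight (the 0.0 initial guess
            # stays in the candidate set); guards against local optima of the
            # ragged silhouette objective
            cands = np.unique(np.append(scan, x0[k - 1]))
            vals = []
            for g in cands:
                trial = x0.copy()
                trial[k - 1] = g
                vals.append(fun(trial))
            x0[k - 1] = cands[int(np.argmin(vals))]
        res = minimize(
            fun,
            x0,
            jac=jac,
            method="L-BFGS-B",
            bounds=[(-config.weight_bounds, config.weight_bounds)] * k,
            options={
                "maxiter": config.maxiter,
                "maxfun": config.maxiter * 2,  # line-search points re-evaluate jac too
                "ftol": config.ftol,
                "gtol": config.gtol,
            },
        )
        start_val = fun(x0)
        if res.fun <= start_val:
            current = res.x
            trace.append(float(res.fun))
        else:  # optimizer failed to improve; keep the padded previous solution
            current = x0
            trace.append(float(start_val))
        converged.append(bool(res.success))

    weights = np.zeros(config.n_modes)
    weights[: len(current)] = current
    from .ssam import instantiate

    surf, _tm = instantiate(model, weights)
    residuals = {
        view: objective(weights, model, prepped, config, splatter, views=[view])
        for view in config.view_list
    }
    return ReconstructionResult(
        weights=weights,
        mesh=surf,
        objective_trace=trace,
        converged=converged,
        per_view_residuals=residuals,
        n_evaluations=n_eval,
    )
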