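"""Centerline extraction by the ridgeline method, with deformable-model repair.

A worm ROI is reduced to a 50-point equal-arc-length centerline in three
steps: (1) the two body endpoints are the most convex points of the ROI
outline (two interior-curvature minima at least a quarter contour apart);
(2) ridge points are pixels of the Euclidean distance transform that are
local maxima in both the horizontal and the vertical direction — an
approximation of the medial axis that, unlike morphological skeletons,
rarely grows spurs; (3) a smoothing spline through endpoint, chained ridge
points, endpoint is resampled to 50 points equally spaced by arc length.

Centerlines longer than 750 um, containing a bend sharper than a 45-degree
interior angle, or that self-intersect are flagged (self-overlapping
postures such as omega turns defeat the ridgeline).  Flagged centerlines are
repaired with a 9-point deformable model: a constant-width tube whose area
matches the target ROI, initialized on the nearest-in-time clean centerline
and pulled onto the target by inverse-square attraction from uncovered
pixels, plus a rigid net-force translation and net-torque rotation per
iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from skimage import measure

N_POINTS = 50
MAX_LENGTH_UM = 750.0
MAX_ANGLE_DEG = 45.0


class DegenerateShapeError(ValueError):
    """ROI outline has no usable convexity minima (e.g. a disc)."""


class NoAnchorError(LookupError):
    """Track has no clean centerline to initialize a repair from."""


class CorrectionFailedError(RuntimeError):
    """Deformable model could not be fit to the target ROI."""


@dataclass
class Centerline:
    """50 ordered (x, y) points in um, leading point first by convention of
    the producing stage (orientation is fixed later by the tracker)."""

    points_um: np.ndarray
    flags: frozenset = frozenset()
    corrected: bool = False
    fit_iou: float | None = None

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1)))

    def reversed(self) -> "Centerline":
        return Centerline(self.points_um[::-1].copy(), self.flags, self.corrected,
                          self.fit_iou)

    @property
    def is_clean(self) -> bool:
        return not self.flags or self.corrected


# ---------------------------------------------------------------------------
# endpoints

def _longest_contour(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateShapeError("ROI has no contour")
    contour = max(contours, key=len) - 1.0  # undo padding
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour  # (n, 2) as (row, col)


def find_endpoints(mask: np.ndarray, max_tip_interior_rad: float = 2.2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two most-convex outline points, >= 1/4 contour apart, as (row, col).

    Interior angle at each contour vertex is measured between the vectors to
    the neighbors k steps away (after light contour smoothing to suppress
    pixelation jaggies); convex tips have small interior angles, concave
    (elbow) vertices have reflex ones, so the two are never confused.  An
    outline without a distinctly convex tip — minimum interior angle above
    the floor, e.g. a disc — raises :class:`DegenerateShapeError`.
    """
    contour = _longest_contour(mask)
    n = len(contour)
    if n < 12:
        raise DegenerateShapeError("contour too short")
    k = max(3, n // 30)
    contour = np.column_stack([
        ndimage.uniform_filter1d(contour[:, i], size=max(3, k // 2), mode="wrap")
        for i in (0, 1)])
    prev = np.roll(contour, k, axis=0)
    nxt = np.roll(contour, -k, axis=0)
    a = contour - prev
    b = nxt - contour
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    turn = np.arctan2(cross, dot)
    # polygon orientation from the total signed turning
    orient = 1.0 if turn.sum() >= 0 else -1.0
    interior = np.pi - orient * turn  # small at convex tips, > pi at concavities
    if interior.min() > max_tip_interior_rad:
        raise DegenerateShapeError("outline has no distinctly convex tip")
    order = np.argsort(interior)
    first = order[0]
    min_sep = n // 4
    second = None
    for idx in order[1:]:
        sep = abs(idx - first)
        if min(sep, n - sep) >= min_sep:
            second = idx
            break
    if second is None:
        raise DegenerateShapeError("no second convexity minimum far enough away")
    return contour[first], contour[second]


# ---------------------------------------------------------------------------
# ridge points

def find_ridge_points(mask: np.ndarray, start_near: np.ndarray | None = None,
                      jump_cap_px: float | None = None) -> np.ndarray:
    """Distance-transform ridge points, chained by greedy nearest neighbor.

    A pixel is a ridge point if its distance value is >= both horizontal
    neighbors and >= both vertical neighbors (plateau-tolerant, so flat
    ridges of even-width bodies survive).  Chaining starts from the ridge
    point nearest ``start_near`` and greedily appends the nearest unvisited
    point within the jump cap; farther points start discarded branches.
    The default cap scales with the body half-width (never below 3 px),
    because diagonal ridge sections have intrinsic gaps of that order.
    Returns (m, 2) ordered (row, col); may be empty for 1-px-wide ROIs.
    """
    dt = ndimage.distance_transform_edt(mask)
    if jump_cap_px is None:
        jump_cap_px = max(3.0, float(dt.max()) + 1.0)
    padded = np.pad(dt, 1)
    c = padded[1:-1, 1:-1]
    horiz = (c >= padded[1:-1, :-2]) & (c >= padded[1:-1, 2:])
    vert = (c >= padded[:-2, 1:-1]) & (c >= padded[2:, 1:-1])
    ridge = np.argwhere(mask & horiz & vert).astype(float)
    if len(ridge) == 0:
        return ridge
    if start_near is None:
        start = 0
    else:
        start = int(np.argmin(np.linalg.norm(ridge - np.asarray(start_near), axis=1)))
    remaining = np.ones(len(ridge), dtype=bool)
    order = [start]
    remaining[start] = False
    cur = ridge[start]
    while remaining.any():
        idx = np.nonzero(remaining)[0]
        d = np.linalg.norm(ridge[idx] - cur, axis=1)
        j = int(np.argmin(d))
        if d[j] > jump_cap_px:
            break
        order.append(idx[j])
        remaining[idx[j]] = False
        cur = ridge[idx[j]]
    return ridge[order]


# ---------------------------------------------------------------------------
# spline fit

def _resample_equal_arclength(points: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    want = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(want, s, points[:, 0]),
                            np.interp(want, s, points[:, 1])])


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    if len(points) < 2:
        return points
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


def fit_centerline(endpoints: tuple[np.ndarray, np.ndarray], ridge_points: np.ndarray,
                   um_per_px: float, smoothing_per_point: float = 0.25) -> Centerline:
    """Smoothing spline through endpoint-A, chained ridge points, endpoint-B,
    resampled to 50 equal-arc-length points and converted to um.

    Degenerate support (< 4 distinct points or a spline failure) falls back
    to piecewise-linear interpolation.
    """
    ep0, ep1 = (np.asarray(e, dtype=float) for e in endpoints)
    if len(ridge_points):
        pts = np.vstack([ep0, ridge_points, ep1])
    else:
        pts = np.vstack([ep0, ep1])
    pts = _dedupe(pts)
    resampled = None
    if len(pts) >= 4:
        try:
            tck, _ = interpolate.splprep(
                [pts[:, 0], pts[:, 1]], s=len(pts) * smoothing_per_point, k=3)
            u = np.linspace(0.0, 1.0, 400)
            rr, cc = interpolate.splev(u, tck)
            resampled = _resample_equal_arclength(np.column_stack([rr, cc]))
        except Exception:
            resampled = None
    if resampled is None:
        resampled = _resample_equal_arclength(pts)
    # (row, col) px -> (x, y) um
    xy = np.column_stack([resampled[:, 1], resampled[:, 0]]) * um_per_px
    return Centerline(points_um=xy)


def extract_centerline(mask: np.ndarray, um_per_px: float, flag: bool = True,
                       origin_px: tuple[int, int] = (0, 0)) -> Centerline:
    """Full ridgeline pipeline on a boolean mask: endpoints -> ridge points
    -> spline -> 50 points -> (optionally) flags.

    ``origin_px`` (row, col) lets callers pass a bounding-box submask and
    get coordinates in the full-frame system.
    """
    ep0, ep1 = find_endpoints(mask)
    ridge = find_ridge_points(mask, start_near=ep0)
    cl = fit_centerline((ep0, ep1), ridge, um_per_px)
    if origin_px != (0, 0):
        off = np.array([origin_px[1], origin_px[0]], dtype=float) * um_per_px
        cl = Centerline(cl.points_um + off)
    if flag:
        cl = Centerline(cl.points_um, flags=flag_centerline(cl))
    return cl


# ---------------------------------------------------------------------------
# flags

def _orient_sign(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Broadcast sign of the cross product (b-a) x (c-a)."""
    v = ((b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
         - (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0]))
    return np.sign(np.where(np.abs(v) < 1e-12, 0.0, v))


def _any_self_intersection(pts: np.ndarray) -> bool:
    """Exact segment-intersection test over all non-adjacent segment pairs,
    vectorized over the (n_seg x n_seg) pair grid."""
    p = pts[:-1]
    q = pts[1:]
    n = len(p)
    ii, jj = np.triu_indices(n, k=2)
    if len(ii) == 0:
        return False
    # drop the wrap-around pair for a closed curve
    closed = np.allclose(pts[0], pts[-1])
    if closed:
        keep = ~((ii == 0) & (jj == n - 1))
        ii, jj = ii[keep], jj[keep]
    a, b = p[ii], q[ii]
    c, d = p[jj], q[jj]
    o1 = _orient_sign(a, b, c)
    o2 = _orient_sign(a, b, d)
    o3 = _orient_sign(c, d, a)
    o4 = _orient_sign(c, d, b)
    crossing = (o1 != o2) & (o3 != o4)
    degenerate = (o1 == 0) & (o2 == 0) & (o3 == 0) & (o4 == 0)
    return bool(np.any(crossing | (degenerate & _collinear_overlap(a, b, c, d))))


def _collinear_overlap(a, b, c, d) -> np.ndarray:
    lo1 = np.minimum(a, b)
    hi1 = np.maximum(a, b)
    lo2 = np.minimum(c, d)
    hi2 = np.maximum(c, d)
    return np.all((lo1 <= hi2) & (lo2 <= hi1), axis=-1)


def flag_centerline(cl: Centerline, max_length_um: float = MAX_LENGTH_UM,
                    max_angle_deg: float = MAX_ANGLE_DEG) -> frozenset:
    """Flags: too_long (> 750 um), sharp_angle (interior angle sharper than
    45 degrees, i.e. the path bends by more than 135 degrees at a vertex),
    self_intersecting (any two non-adjacent segments cross)."""
    flags = set()
    pts = cl.points_um
    if cl.length_um > max_length_um:
        flags.add("too_long")
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    ok = (norms[:-1] > 1e-12) & (norms[1:] > 1e-12)
    if ok.any():
        cosv = (seg[:-1] * seg[1:]).sum(axis=1)[ok] / (norms[:-1] * norms[1:])[ok]
        dev = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
        if np.any(dev > 180.0 - max_angle_deg):
            flags.add("sharp_angle")
    if _any_self_intersection(pts):
        flags.add("self_intersecting")
    return frozenset(flags)


# ---------------------------------------------------------------------------
# deformable model

@dataclass
class DeformableModel:
    model_points_px: np.ndarray  # (9, 2) as (row, col)
    half_width_px: float
    iteration: int = 0
    fit_iou: float = 0.0


N_MODEL_POINTS = 9


def _stadium_half_width(length_px: float, area_px: float) -> float:
    """Half-width w of a constant-width tube with round caps whose area
    equals ``area_px``: pi w^2 + 2 L w - A = 0 (exact closed form)."""
    return (-length_px + math.sqrt(length_px ** 2 + math.pi * area_px)) / math.pi


def _chaikin(points: np.ndarray, rounds: int = 2) -> np.ndarray:
    """Corner-cutting subdivision (endpoint-preserving); two rounds turn the
    9-point polyline into a smooth quadratic-B-spline-like curve."""
    pts = points
    for _ in range(rounds):
        q = 0.75 * pts[:-1] + 0.25 * pts[1:]
        r = 0.25 * pts[:-1] + 0.75 * pts[1:]
        mid = np.empty((2 * (len(pts) - 1), 2))
        mid[0::2] = q
        mid[1::2] = r
        pts = np.vstack([pts[:1], mid, pts[-1:]])
    return pts


def _rasterize_tube(points: np.ndarray, half_width: float, shape: tuple[int, int]
                    ) -> np.ndarray:
    """Tip-to-tip tube: round caps restore the half-width trimmed from each
    end, so the rendered support spans exactly the polyline extent."""
    from .synth import _stamp_tube, _trim_polyline_ends

    canvas = np.zeros(shape, dtype=bool)
    smooth = _chaikin(points)
    spine = _trim_polyline_ends(smooth, half_width)
    # _stamp_tube expects (x, y) = (col, row)
    _stamp_tube(canvas, spine[:, ::-1], half_width)
    return canvas


def fit_deformable_model(target_mask: np.ndarray, init: Centerline, um_per_px: float,
                         max_iter: int = 300, min_iter: int = 50,
                         iou_stop: float = 0.6, plateau_window: int = 50,
                         plateau_tol: float = 1e-4,
                         ) -> tuple[Centerline, float]:
    """Repair a flagged centerline by fitting a 9-point tube to the target.

    The moving ROI is a stadium tube around the 9 model points, width set so
    its area matches the target's.  Each iteration: per-point attraction
    from uncovered target pixels (unit vector / (r^2 + 1), largest point
    displacement normalized to 1 px), then a rigid translation along the net
    force and a rigid rotation by the net moment about the model centroid.
    Fitting completes after >= 50 iterations once IoU > 0.6 and IoU has not
    improved over the trailing 50 iterations, or at 300 iterations.  Returns
    the best-IoU model resampled to a 50-point centerline with
    ``corrected=True``, and the final IoU.
    """
    area = int(target_mask.sum())
    if area < 4:
        raise CorrectionFailedError("target ROI too small to rasterize a tube")
    # 9 model points along the initializer, in px (row, col)
    pts_um = init.points_um
    idx = np.linspace(0, len(pts_um) - 1, N_MODEL_POINTS).round().astype(int)
    model = np.column_stack([pts_um[idx, 1], pts_um[idx, 0]]) / um_per_px

    # work in a local window around target + initializer (the fit is local;
    # a full-frame canvas only slows the per-iteration rasterization)
    rr, cc = np.nonzero(target_mask)
    pad = 12
    r_lo = int(min(rr.min(), np.floor(model[:, 0].min()))) - pad
    r_hi = int(max(rr.max(), np.ceil(model[:, 0].max()))) + pad + 1
    c_lo = int(min(cc.min(), np.floor(model[:, 1].min()))) - pad
    c_hi = int(max(cc.max(), np.ceil(model[:, 1].max()))) + pad + 1
    r_lo, c_lo = max(0, r_lo), max(0, c_lo)
    r_hi = min(target_mask.shape[0], r_hi)
    c_hi = min(target_mask.shape[1], c_hi)
    target_mask = target_mask[r_lo:r_hi, c_lo:c_hi]
    model = model - np.array([r_lo, c_lo])
    shape = target_mask.shape

    target_idx = np.argwhere(target_mask).astype(float)
    ious: list[float] = []
    best_iou, best_model = -1.0, model.copy()
    length = float(np.sum(np.linalg.norm(np.diff(_chaikin(model), axis=0), axis=1)))
    w = _stadium_half_width(length, area)
    it = 0
    for it in range(1, max_iter + 1):
        moving = _rasterize_tube(model, w, shape)
        mov_area = int(moving.sum())
        if mov_area > 0:
            # keep the rasterized tube area matched to the target area
            w *= float(np.clip(math.sqrt(area / mov_area), 0.9, 1.1))
        inter = np.count_nonzero(moving & target_mask)
        union = np.count_nonzero(moving | target_mask)
        iou = inter / union if union else 0.0
        ious.append(iou)
        if iou > best_iou:
            best_iou, best_model = iou, model.copy()
        if it >= min_iter and iou_stop is not None and len(ious) > plateau_window:
            recent = max(ious[-plateau_window:])
            before = max(ious[:-plateau_window])
            if ious[-1] > iou_stop and recent <= before + plateau_tol:
                break
        uncovered = target_idx[~moving[target_idx[:, 0].astype(int),
                                       target_idx[:, 1].astype(int)]]
        if len(uncovered) == 0:
            # fully covering the target: nothing pulls the model; stop early
            # once the minimum iteration count is satisfied
            if it >= min_iter:
                break
            continue
        forces = np.zeros_like(model)
        for i, p in enumerate(model):
            dv = uncovered - p
            r2 = (dv ** 2).sum(axis=1)
            r = np.sqrt(r2)
            good = r > 1e-9
            forces[i] = (dv[good] / (r[good][:, None] * (r2[good][:, None] + 1.0))).sum(axis=0)
        fmax = np.linalg.norm(forces, axis=1).max()
        if fmax <= 0:
            continue
        model = model + forces / fmax  # largest per-point step = 1 px
        net = forces.sum(axis=0)
        model = model + net / (N_MODEL_POINTS * fmax)  # rigid translation, <= 1 px
        centroid = model.mean(axis=0)
        rel = model - centroid
        torque = float(np.sum(rel[:, 0] * forces[:, 1] - rel[:, 1] * forces[:, 0]))
        inertia = float(np.sum((rel ** 2).sum(axis=1)))
        if inertia > 0:
            dtheta = np.clip(torque / (fmax * inertia), -0.05, 0.05)
            ca, sa = math.cos(dtheta), math.sin(dtheta)
            rot = np.array([[ca, -sa], [sa, ca]])
            model = centroid + rel @ rot.T

    final = best_model + np.array([r_lo, c_lo])
    # 9-point polyline -> spline -> 50 equally spaced points, in um
    try:
        tck, _ = interpolate.splprep([final[:, 0], final[:, 1]], s=0, k=3)
        u = np.linspace(0.0, 1.0, 400)
        rr, cc = interpolate.splev(u, tck)
        dense = np.column_stack([rr, cc])
    except Exception:
        dense = final
    pts50 = _resample_equal_arclength(dense)
    xy_um = np.column_stack([pts50[:, 1], pts50[:, 0]]) * um_per_px
    out = Centerline(points_um=xy_um, corrected=True, fit_iou=best_iou)
    out = Centerline(xy_um, flags=flag_centerline(out), corrected=True, fit_iou=best_iou)
    return out, best_iou


# ---------------------------------------------------------------------------
# RMSD

def centerline_rmsd_points(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two polylines in um, minimum over both orientations of
    b; inputs are resampled to 50 equal-arc-length points first."""
    aa = _resample_equal_arclength(np.asarray(a, dtype=float))
    bb = _resample_equal_arclength(np.asarray(b, dtype=float))
    d1 = np.sqrt(np.mean(np.sum((aa - bb) ** 2, axis=1)))
    d2 = np.sqrt(np.mean(np.sum((aa - bb[::-1]) ** 2, axis=1)))
    return float(min(d1, d2))


def centerline_rmsd(a: Centerline, b: Centerline) -> float:
    return centerline_rmsd_points(a.points_um, b.points_um)
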