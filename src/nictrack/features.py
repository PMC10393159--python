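"""Per-worm-frame behavioral features and their temporal expansions.

Seventeen primary features are computed per worm-frame from the oriented
centerline, the ROI, and the raw image: body geometry (length, area, width,
straightness, curvature summaries), motion (centroid/end/body point speeds,
path direction change, alignment of movement with the body axis), and two
image-based cues that the centerline cannot carry — focus ("blur", which
drops when the elevated end of a nictating worm leaves the focal plane) and
difference-image activity.  Each primary feature is then expanded with its
backward and forward first derivatives and five statistics (mean, median,
min, max, population variance) over a centered 1.0 s (5-frame at 5 fps)
window, giving 17 x 8 = 136 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import ROI
from .tracking import WormTrack

PRIMARY_FEATURES: tuple[str, ...] = (
    "length",            # um, centerline arc length
    "area",              # um^2, ROI area
    "width",             # um, area / length proxy
    "straightness",      # end-to-end distance / length
    "total_curvature",   # rad, sum |turning angle|
    "max_curvature",     # rad, max |turning angle|
    "mean_curvature",    # rad, mean signed turning angle
    "centroid_speed",    # um/s
    "head_speed",        # um/s, leading end
    "tail_speed",        # um/s, trailing end
    "body_speed",        # um/s, mean point-wise centerline speed
    "path_angle_change", # rad, change of centroid travel direction
    "axis_alignment",    # |cos| of angle between displacement and body axis
    "blur",              # focus measure (lower = more defocused)
    "activity",          # gray/frame, difference-image activity over ROI
    "intensity_contrast",# gray, local background minus ROI mean (worms dark)
    "intensity_std",     # gray, intensity spread within ROI
)

STAT_NAMES = ("mean", "median", "min", "max", "var")
N_PRIMARY = len(PRIMARY_FEATURES)
N_COLUMNS = N_PRIMARY * (1 + 2 + len(STAT_NAMES))  # 136


@dataclass
class FeatureRegistry:
    """Ordered primary-feature registry; the default pins exactly 17 names
    so the 136-column contract downstream holds."""

    names: tuple[str, ...] = PRIMARY_FEATURES

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.names) * 8

    def all_columns(self) -> list[str]:
        cols = list(self.names)
        for n in self.names:
            cols += [f"{n}_dback", f"{n}_dfwd"]
        for n in self.names:
            cols += [f"{n}_{s}" for s in STAT_NAMES]
        return cols


# ---------------------------------------------------------------------------
# image-based features

def _roi_patch(frame: np.ndarray, roi: ROI, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """(image patch, mask patch) around the ROI's bounding box."""
    r0, c0, r1, c1 = roi.bbox
    rows, cols = frame.shape
    pr0, pc0 = max(0, r0 - pad), max(0, c0 - pad)
    pr1, pc1 = min(rows, r1 + pad), min(cols, c1 + pad)
    patch = frame[pr0:pr1, pc0:pc1].astype(float)
    mask = np.zeros(patch.shape, dtype=bool)
    mask[r0 - pr0:r0 - pr0 + (r1 - r0), c0 - pc0:c0 - pc0 + (c1 - c0)] = roi.mask
    return patch, mask


def blur(frame: np.ndarray, roi: ROI) -> float:
    """Focus measure: variance of the 3x3 discrete Laplacian over ROI
    pixels, divided by the mean ROI intensity.  Lower = more defocused.
    Returns NaN for ROIs smaller than the kernel support."""
    if roi.area_px < 9:
        return np.nan
    patch, mask = _roi_patch(frame, roi, pad=2)
    vals = ndimage.laplace(patch)[mask]
    mean_int = float(patch[mask].mean())
    if mean_int == 0:
        return np.nan
    return float(vals.var() / mean_int)


def difference_image_activity(frame_t: np.ndarray, frame_prev: np.ndarray | None,
                              roi: ROI, half_width_px: float = 3.0) -> float:
    """Mean absolute intensity change over the ROI dilated by one worm
    half-width; NaN on the first frame of a track."""
    if frame_prev is None:
        return np.nan
    it = max(1, int(round(half_width_px)))
    patch, mask = _roi_patch(frame_t, roi, pad=it + 1)
    dil = ndimage.binary_dilation(mask, iterations=it)
    r0, c0, r1, c1 = roi.bbox
    pad = it + 1
    rows, cols = frame_t.shape
    pr0, pc0 = max(0, r0 - pad), max(0, c0 - pad)
    prev_patch = frame_prev[pr0:pr0 + patch.shape[0],
                            pc0:pc0 + patch.shape[1]].astype(float)
    return float(np.abs(patch - prev_patch)[dil].mean())


def _intensity_contrast(frame: np.ndarray, roi: ROI, half_width_px: float = 3.0) -> float:
    it = max(2, int(round(2 * half_width_px)))
    patch, mask = _roi_patch(frame, roi, pad=it + 1)
    ring = ndimage.binary_dilation(mask, iterations=it) & ~mask
    if not ring.any():
        return np.nan
    return float(patch[ring].mean() - patch[mask].mean())


# ---------------------------------------------------------------------------
# geometry helpers

def _turning_angles(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    d = np.diff(ang)
    return (d + np.pi) % (2 * np.pi) - np.pi


def compute_primary_features(track: WormTrack, video: np.ndarray,
                             registry: FeatureRegistry | None = None) -> pd.DataFrame:
    """17-column primary feature block for one track.

    Motion features need a neighboring frame; at track boundaries (and next
    to censored frames) the nearest computable value is copied so the matrix
    stays dense.  Rows with a censored (None) centerline are all-NaN.
    Index: (track_id, frame).
    """
    registry = registry or FeatureRegistry()
    n = track.n_frames
    fps = track.fps
    cols = {name: np.full(n, np.nan) for name in registry.names}
    half_width_px = None

    cls = track.centerlines
    for i in range(n):
        cl = cls[i]
        roi = track.rois[i]
        frame = video[track.frames[i]]
        if cl is None:
            continue
        pts = cl.points_um
        length = cl.length_um
        cols["length"][i] = length
        cols["area"][i] = roi.area_um2
        cols["width"][i] = roi.area_um2 / length if length > 0 else np.nan
        cols["straightness"][i] = (np.linalg.norm(pts[-1] - pts[0]) / length
                                   if length > 0 else np.nan)
        ta = _turning_angles(pts)
        cols["total_curvature"][i] = np.abs(ta).sum()
        cols["max_curvature"][i] = np.abs(ta).max()
        cols["mean_curvature"][i] = ta.mean()
        if half_width_px is None:
            half_width_px = 0.5 * (roi.area_um2 / max(length, 1e-9)) / roi.um_per_px
        cols["blur"][i] = blur(frame, roi)
        cols["intensity_contrast"][i] = _intensity_contrast(frame, roi, half_width_px)
        r0, c0, r1, c1 = roi.bbox
        cols["intensity_std"][i] = float(
            frame[r0:r1, c0:c1].astype(float)[roi.mask].std())

        prev_ok = i > 0 and cls[i - 1] is not None
        if prev_ok:
            prev_pts = cls[i - 1].points_um
            c0 = np.array(track.rois[i - 1].centroid_um)
            c1 = np.array(roi.centroid_um)
            disp = c1 - c0
            cols["centroid_speed"][i] = np.linalg.norm(disp) * fps
            cols["head_speed"][i] = np.linalg.norm(pts[0] - prev_pts[0]) * fps
            cols["tail_speed"][i] = np.linalg.norm(pts[-1] - prev_pts[-1]) * fps
            m = min(len(pts), len(prev_pts))
            cols["body_speed"][i] = float(
                np.linalg.norm(pts[:m] - prev_pts[:m], axis=1).mean()) * fps
            axis = pts[0] - pts[-1]
            na, nd = np.linalg.norm(axis), np.linalg.norm(disp)
            cols["axis_alignment"][i] = (abs(float(np.dot(axis, disp))) / (na * nd)
                                         if na > 1e-9 and nd > 1e-9 else 0.0)
            frame_prev = video[track.frames[i - 1]]
            cols["activity"][i] = difference_image_activity(
                frame, frame_prev, roi, half_width_px)
            if i > 1 and cls[i - 2] is not None:
                cm1 = np.array(track.rois[i - 2].centroid_um)
                d_prev = c0 - cm1
                if np.linalg.norm(d_prev) > 1e-9 and nd > 1e-9:
                    a0 = np.arctan2(d_prev[1], d_prev[0])
                    a1 = np.arctan2(disp[1], disp[0])
                    cols["path_angle_change"][i] = abs(
                        (a1 - a0 + np.pi) % (2 * np.pi) - np.pi)

    df = pd.DataFrame(cols, columns=list(registry.names))
    # boundary policy: copy the nearest computable value so the matrix is
    # dense where the centerline exists
    valid = np.array([c is not None for c in cls])
    for name in registry.names:
        s = df[name].copy()
        s[~valid] = np.nan
        filled = s.ffill().bfill()
        filled[~valid] = np.nan
        df[name] = filled
    df.index = pd.MultiIndex.from_arrays(
        [[track.track_id] * n, track.frames], names=["track_id", "frame"])
    return df


def compute_derived_features(primary: pd.DataFrame, fps: float,
                             window: int = 5) -> pd.DataFrame:
    """Expand a per-track primary block to the full 136-column matrix.

    Backward/forward first derivatives are per-frame differences times fps;
    window statistics are over the centered ``window`` frames, truncated at
    the track boundaries; variance is the population variance.  Tracks
    shorter than 3 frames are marked invalid (all-NaN derived columns).
    """
    if not isinstance(primary.index, pd.MultiIndex):
        raise ValueError("expect a (track_id, frame) MultiIndex")
    half = window // 2
    pieces = []
    for tid, block in primary.groupby(level="track_id", sort=False):
        vals = block.to_numpy(dtype=float)
        n = len(block)
        out = {c: vals[:, j] for j, c in enumerate(primary.columns)}
        if n < 3:
            for c in primary.columns:
                out[f"{c}_dback"] = np.full(n, np.nan)
                out[f"{c}_dfwd"] = np.full(n, np.nan)
                for s in STAT_NAMES:
                    out[f"{c}_{s}"] = np.full(n, np.nan)
        else:
            dback = np.diff(vals, axis=0, prepend=vals[:1]) * fps
            dback[0] = dback[1]  # boundary copy
            dfwd = np.diff(vals, axis=0, append=vals[-1:]) * fps
            dfwd[-1] = dfwd[-2]
            for j, c in enumerate(primary.columns):
                out[f"{c}_dback"] = dback[:, j]
                out[f"{c}_dfwd"] = dfwd[:, j]
            stats = {s: np.empty_like(vals) for s in STAT_NAMES}
            with warnings.catch_warnings():
                # all-NaN windows (censored neighborhoods) yield NaN rows
                warnings.simplefilter("ignore", RuntimeWarning)
                for t in range(n):
                    w = vals[max(0, t - half):min(n, t + half + 1)]
                    stats["mean"][t] = np.nanmean(w, axis=0)
                    stats["median"][t] = np.nanmedian(w, axis=0)
                    stats["min"][t] = np.nanmin(w, axis=0)
                    stats["max"][t] = np.nanmax(w, axis=0)
                    stats["var"][t] = np.nanvar(w, axis=0)
            for s in STAT_NAMES:
                for j, c in enumerate(primary.columns):
                    out[f"{c}_{s}"] = stats[s][:, j]
        cols = list(primary.columns)
        for c in primary.columns:
            cols += [f"{c}_dback", f"{c}_dfwd"]
        for c in primary.columns:
            cols += [f"{c}_{s}" for s in STAT_NAMES]
        pieces.append(pd.DataFrame(out, index=block.index)[cols])
    return pd.concat(pieces)


def compute_features(tracks: list[WormTrack], video: np.ndarray,
                     fps: float | None = None) -> pd.DataFrame:
    """Primary + derived features for a list of tracks (136 columns)."""
    blocks = [compute_primary_features(t, video) for t in tracks]
    primary = pd.concat(blocks)
    return compute_derived_features(primary, fps or tracks[0].fps)


# ---------------------------------------------------------------------------
# scaling

SCALING_METHODS = ("none", "min-max", "z-score", "robust")


def fit_apply_scaling(matrix: pd.DataFrame, train_mask: np.ndarray,
                      method: str = "min-max") -> tuple[pd.DataFrame, dict]:
    """Fit column scaling on training rows only; transform all rows.

    min-max maps the training min/max to 0/1 (inference values may fall
    outside); z-score standardizes; robust centers on the median and scales
    by the IQR.  Zero-range columns map to 0 with a warning.
    """
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    train = matrix.loc[np.asarray(train_mask)]
    if method == "none":
        return matrix.copy(), {"method": "none"}
    if method == "min-max":
        lo, hi = train.min(), train.max()
        scale = hi - lo
    elif method == "z-score":
        lo, scale = train.mean(), train.std(ddof=0)
    else:
        lo = train.median()
        scale = train.quantile(0.75) - train.quantile(0.25)
    zero = scale == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-range columns mapped to 0")
        scale = scale.mask(zero, 1.0)
    out = (matrix - lo) / scale
    out[out.columns[zero]] = 0.0
    return out, {"method": method, "center": lo.to_dict(), "scale": scale.to_dict()}
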