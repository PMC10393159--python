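"""Per-frame worm segmentation and its benchmarking.

Two routes produce worm ROIs from the same thresholding code path:

* intensity route — stabilize, max-merge background, background-subtract,
  Gaussian-smooth, binarize;
* adapter route — per-frame "worm probability" images from an external
  instance-segmentation model (soft masks max-merged above a confidence
  cutoff and scaled to 0-255) fed straight into the same smoothing +
  thresholding.

Benchmarking against manual (or generator) annotations uses four criteria:
detection, IoU against the union of overlapping ROIs, gap count (overlapping
ROIs minus one), and centerline RMSD in both orientations taking the
minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation


@dataclass
class ROI:
    """One 8-connected segmented region in one frame."""

    frame_index: int
    bbox: tuple[int, int, int, int]       # (min_row, min_col, max_row, max_col), half-open
    mask: np.ndarray                      # bool, within bbox
    frame_shape: tuple[int, int]
    um_per_px: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.um_per_px ** 2

    @property
    def centroid_um(self) -> tuple[float, float]:
        """(x, y) centroid in um, pixel-center based."""
        rr, cc = np.nonzero(self.mask)
        r = (rr.mean() + self.bbox[0]) * self.um_per_px
        c = (cc.mean() + self.bbox[1]) * self.um_per_px
        return (c, r)

    @property
    def touches_edge(self) -> bool:
        r0, c0, r1, c1 = self.bbox
        return r0 == 0 or c0 == 0 or r1 == self.frame_shape[0] or c1 == self.frame_shape[1]

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.frame_shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class SegmentationParams:
    """Smoothing sigma (um), gray threshold, and ROI filters."""

    sigma_um: float = 0.0
    threshold: int = 100
    area_min_um2: float = 3674.0
    area_max_um2: float = 16533.0
    exclude_edge: bool = True

    def validate(self) -> None:
        if self.sigma_um < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be in [0, 255]")
        if self.area_min_um2 >= self.area_max_um2:
            raise ValueError("area_min must be < area_max")


@dataclass
class SegmentationEval:
    detection_rate: float
    mean_iou: float
    mean_gaps: float
    mean_centerline_rmsd_um: float


def max_merge_background(frames: np.ndarray) -> np.ndarray:
    """Pixel-wise maximum over frames; dark worms vanish from the bright
    background as long as each pixel is worm-free in at least one frame."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a (n_frames, rows, cols) stack")
    return frames.max(axis=0)


def stabilize_frames(frames: np.ndarray, reference: np.ndarray | None = None,
                     upsample_factor: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Rigid subpixel translation of each frame onto the reference.

    Returns (stabilized uint8 stack, (n, 2) applied shifts).  Featureless
    (zero-variance) frames are passed through with a warning.
    """
    frames = np.asarray(frames)
    if frames.shape[0] < 2 and reference is None:
        raise ValueError("need >= 2 frames to stabilize")
    ref = frames[0] if reference is None else reference
    out = np.empty_like(frames)
    shifts = np.zeros((frames.shape[0], 2))
    if ref.std() == 0:
        warnings.warn("reference frame has zero variance; stabilization skipped")
        return frames.copy(), shifts
    for i, frame in enumerate(frames):
        if frame.std() == 0:
            warnings.warn(f"frame {i} has zero variance; left unshifted")
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample_factor)
        shifts[i] = shift
        if np.any(shift != 0):
            out[i] = np.clip(np.round(
                ndimage.shift(frame.astype(float), shift, order=1, mode="nearest")
            ), 0, 255).astype(frames.dtype)
        else:
            out[i] = frame
    return out, shifts


def background_subtract(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Clamped (background - frame): dark worms become bright on ~0."""
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    return np.clip(background.astype(np.int16) - frame.astype(np.int16), 0, 255).astype(np.uint8)


def segment_grayscale(image: np.ndarray, params: SegmentationParams, um_per_px: float,
                      frame_index: int = 0) -> list[ROI]:
    """Gaussian-smooth, binarize at > t, connected components, area + edge
    filters.  Applies identically to background-subtracted frames and to
    adapter probability images."""
    params.validate()
    if image.ndim != 2:
        raise ValueError("expect a single-channel image")
    img = image.astype(float)
    sigma_px = round(params.sigma_um / um_per_px, 2)
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma_px)
    binary = img > params.threshold
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    rois: list[ROI] = []
    if n == 0:
        return rois
    slices = ndimage.find_objects(labeled)
    for lab, sl in enumerate(slices, start=1):
        sub = labeled[sl] == lab
        area_um2 = sub.sum() * um_per_px ** 2
        if not (params.area_min_um2 <= area_um2 <= params.area_max_um2):
            continue
        roi = ROI(
            frame_index=frame_index,
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            mask=sub,
            frame_shape=image.shape,
            um_per_px=um_per_px,
        )
        if params.exclude_edge and roi.touches_edge:
            continue
        rois.append(roi)
    return rois


def merge_instance_masks(instances: list[tuple[np.ndarray, float]],
                         conf_min: float = 0.7) -> np.ndarray:
    """Max-merge soft instance masks with confidence >= conf_min, scaled to
    0-255.  This adapter output feeds :func:`segment_grayscale`."""
    kept = [np.asarray(m, dtype=float) for m, c in instances if c >= conf_min]
    if not instances:
        raise ValueError("need at least the frame shape; pass instances=[(zeros, 0)]")
    shape = np.asarray(instances[0][0]).shape
    if any(np.asarray(m).shape != shape for m, _ in instances):
        raise ValueError("instance masks must share the frame shape")
    if not kept:
        return np.zeros(shape, dtype=np.uint8)
    merged = np.max(np.stack(kept), axis=0)
    return np.clip(np.round(merged * 255.0), 0, 255).astype(np.uint8)


@dataclass
class ManualAnnotation:
    """One manually annotated worm: a full-frame mask plus (optionally) a
    drawn centerline in um (n, 2)."""

    mask: np.ndarray
    centerline_um: np.ndarray | None = None


def evaluate_segmentation(rois_per_image: list[list[ROI]],
                          annotations_per_image: list[list[ManualAnnotation]],
                          um_per_px: float) -> SegmentationEval:
    """Benchmark ROIs against manual annotations.

    Per manual worm: detected iff any ROI overlaps any annotated pixel; IoU
    between the manual mask and the union of overlapping ROIs (0 if none);
    gaps = overlapping-ROI count - 1 (detected worms only); centerline RMSD
    = minimum over both orientations and over overlapping ROIs.
    """
    from . import centerline as _cl

    if len(rois_per_image) != len(annotations_per_image):
        raise ValueError("image counts differ")
    detected, ious, gaps, rmsds = [], [], [], []
    for rois, annots in zip(rois_per_image, annotations_per_image):
        full = [r.full_mask() for r in rois]
        for ann in annots:
            overlapping = [i for i, m in enumerate(full) if np.any(m & ann.mask)]
            det = len(overlapping) > 0
            detected.append(det)
            if not det:
                ious.append(0.0)
                continue
            union_roi = np.zeros_like(ann.mask)
            for i in overlapping:
                union_roi |= full[i]
            inter = np.count_nonzero(union_roi & ann.mask)
            uni = np.count_nonzero(union_roi | ann.mask)
            ious.append(inter / uni)
            gaps.append(len(overlapping) - 1)
            if ann.centerline_um is None:
                warnings.warn("annotation without centerline; RMSD omitted")
                continue
            best = np.inf
            for i in overlapping:
                try:
                    cl = _cl.extract_centerline(full[i], um_per_px)
                except _cl.DegenerateShapeError:
                    continue
                best = min(best, _cl.centerline_rmsd_points(cl.points_um, ann.centerline_um))
            if np.isfinite(best):
                rmsds.append(best)
    if not detected:
        raise ValueError("no annotations to evaluate")
    return SegmentationEval(
        detection_rate=float(np.mean(detected)),
        mean_iou=float(np.mean(ious)),
        mean_gaps=float(np.mean(gaps)) if gaps else 0.0,
        mean_centerline_rmsd_um=float(np.mean(rmsds)) if rmsds else np.nan,
    )


@dataclass
class Benchmarks:
    """Qualification thresholds for a (sigma, t) combination."""

    detection_rate: float = 1.0
    max_gaps: float = 0.0
    min_iou: float = 0.5
    max_rmsd_um: float = 10.0


def grid_search_params(images: list[np.ndarray],
                       annotations_per_image: list[list[ManualAnnotation]],
                       sigma_grid_um: np.ndarray, t_grid: np.ndarray,
                       um_per_px: float,
                       params_template: SegmentationParams | None = None,
                       benchmarks: Benchmarks | None = None) -> pd.DataFrame:
    """Evaluate every (sigma, t) combination and mark the qualifying set.

    Qualification requires full detection, zero gaps, mean IoU >= 0.5 and
    mean centerline RMSD < 10 um (by default).  Returns a table with one row
    per combination and a ``qualifies`` column.
    """
    sigma_grid_um = np.atleast_1d(sigma_grid_um)
    t_grid = np.atleast_1d(t_grid)
    if sigma_grid_um.size == 0 or t_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if not any(annotations_per_image):
        raise ValueError("empty annotation set")
    bm = benchmarks or Benchmarks()
    template = params_template or SegmentationParams()
    rows = []
    for sigma in sigma_grid_um:
        for t in t_grid:
            params = SegmentationParams(
                sigma_um=float(sigma), threshold=int(t),
                area_min_um2=template.area_min_um2,
                area_max_um2=template.area_max_um2,
                exclude_edge=template.exclude_edge,
            )
            rois = [segment_grayscale(img, params, um_per_px, frame_index=i)
                    for i, img in enumerate(images)]
            ev = evaluate_segmentation(rois, annotations_per_image, um_per_px)
            qualifies = (
                ev.detection_rate >= bm.detection_rate
                and ev.mean_gaps <= bm.max_gaps
                and ev.mean_iou >= bm.min_iou
                and (np.isnan(ev.mean_centerline_rmsd_um)
                     or ev.mean_centerline_rmsd_um < bm.max_rmsd_um)
            )
            rows.append({
                "sigma_um": float(sigma), "t": int(t),
                "detection_rate": ev.detection_rate, "mean_iou": ev.mean_iou,
                "mean_gaps": ev.mean_gaps,
                "mean_rmsd_um": ev.mean_centerline_rmsd_um,
                "qualifies": bool(qualifies),
            })
    return pd.DataFrame(rows)
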