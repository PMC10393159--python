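"""End-to-end orchestration: video (or probability images) -> metrics.

Stages: segment every frame -> extract + flag centerlines -> stitch tracks
-> repair flagged centerlines with the deformable model -> orient
centerlines -> drop short tracks -> compute features -> (train and/or
apply) behavior scorer -> denoise -> nictation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import centerline as cl
from . import features as ft
from . import metrics as mx
from . import scoring as sc
from . import segmentation as seg
from . import tracking as tk

SPECIES_PRESETS = {
    # area bounds (um^2), max stitch displacement (um), sigma (um), threshold
    "elegans": {"area_min_um2": 3674.0, "area_max_um2": 16533.0,
                "max_disp_um": 429.0, "sigma_um": 6.4, "threshold": 100},
    "steinernema": {"area_min_um2": 4000.0, "area_max_um2": 22000.0,
                    "max_disp_um": 300.0, "sigma_um": 0.0, "threshold": 100},
}


@dataclass
class PipelineConfig:
    um_per_px: float = 3.75
    fps: float = 5.0
    species: str = "elegans"
    sigma_um: float | None = None          # None -> species preset
    threshold: int | None = None
    min_track_duration_s: float = 10.0
    smoothing_method: str = "gaussian"
    smoothing_param: float = 0.184
    seed: int = 0

    def segmentation_params(self) -> seg.SegmentationParams:
        p = SPECIES_PRESETS[self.species]
        return seg.SegmentationParams(
            sigma_um=self.sigma_um if self.sigma_um is not None else p["sigma_um"],
            threshold=self.threshold if self.threshold is not None else p["threshold"],
            area_min_um2=p["area_min_um2"], area_max_um2=p["area_max_um2"],
        )

    @property
    def max_disp_um(self) -> float:
        return SPECIES_PRESETS[self.species]["max_disp_um"]


def segment_video(images: np.ndarray, config: PipelineConfig) -> list[list[seg.ROI]]:
    params = config.segmentation_params()
    return [seg.segment_grayscale(img, params, config.um_per_px, frame_index=i)
            for i, img in enumerate(images)]


def extract_centerlines(rois_per_frame: list[list[seg.ROI]], um_per_px: float
                        ) -> list[list[cl.Centerline | None]]:
    out: list[list[cl.Centerline | None]] = []
    for rois in rois_per_frame:
        row: list[cl.Centerline | None] = []
        for roi in rois:
            # 1-px zero border reproduces the background adjacent to the
            # tight bounding box (the distance transform needs it)
            sub = np.pad(roi.mask, 1)
            try:
                row.append(cl.extract_centerline(
                    sub, um_per_px, origin_px=(roi.bbox[0] - 1, roi.bbox[1] - 1)))
            except cl.DegenerateShapeError:
                row.append(None)
        out.append(row)
    return out


def build_tracks(images: np.ndarray, config: PipelineConfig,
                 repair: bool = True) -> list[tk.WormTrack]:
    """Segmentation through track filtering on a grayscale stack (raw
    difference images or adapter probability images)."""
    rois = segment_video(images, config)
    cls = extract_centerlines(rois, config.um_per_px)
    tracks = tk.stitch_tracks(rois, cls, max_disp_um=config.max_disp_um,
                              fps=config.fps)
    tracks = tk.filter_tracks(tracks, config.min_track_duration_s)
    for t in tracks:
        if repair:
            tk.repair_track_centerlines(t, config.um_per_px)
        tk.align_orientation(t)
    return tracks


@dataclass
class PipelineResult:
    tracks: list
    features: pd.DataFrame
    probabilities: pd.DataFrame
    raw_labels: pd.Series
    labels: pd.Series
    metrics: mx.NictationMetrics


def run_pipeline(images: np.ndarray, config: PipelineConfig,
                 scorer: sc.TrainedScorer) -> PipelineResult:
    """Full inference pipeline with a pre-trained scorer."""
    tracks = build_tracks(images, config)
    if not tracks:
        raise ValueError("no tracks recovered from the input stack")
    feats = ft.compute_features(tracks, images, config.fps)
    probs, raw = sc.score_tracks(scorer, feats)
    labels = sc.apply_denoiser(config.smoothing_method, probs, raw,
                               config.smoothing_param, config.fps)
    metrics = mx.nictation_metrics(labels, config.fps)
    return PipelineResult(tracks=tracks, features=feats, probabilities=probs,
                          raw_labels=raw, labels=labels, metrics=metrics)


def match_tracks_to_truth(tracks: list[tk.WormTrack], truth) -> dict[int, int]:
    """Map track_id -> ground-truth worm index by centroid proximity, and
    report identity purity (fraction of worm-frames whose nearest true worm
    matches the track's majority worm)."""
    mapping = {}
    for t in tracks:
        votes = []
        for i, f in enumerate(t.frames):
            c = np.array(t.centroid(i))
            d = np.linalg.norm(truth.centroids_um[:, f, :] - c, axis=1)
            votes.append(int(np.argmin(d)))
        mapping[t.track_id] = int(np.bincount(votes).argmax())
    return mapping


def track_identity_purity(tracks: list[tk.WormTrack], truth) -> float:
    total = correct = 0
    for t in tracks:
        votes = []
        for i, f in enumerate(t.frames):
            c = np.array(t.centroid(i))
            d = np.linalg.norm(truth.centroids_um[:, f, :] - c, axis=1)
            votes.append(int(np.argmin(d)))
        majority = int(np.bincount(votes).argmax())
        correct += int(np.sum(np.asarray(votes) == majority))
        total += len(votes)
    return correct / total if total else float("nan")


def truth_ethogram_for_tracks(tracks: list[tk.WormTrack], truth) -> pd.Series:
    """Ground-truth labels aligned with the (track_id, frame) index of the
    recovered tracks."""
    mapping = match_tracks_to_truth(tracks, truth)
    idx, vals = [], []
    for t in tracks:
        w = mapping[t.track_id]
        for f in t.frames:
            idx.append((t.track_id, f))
            vals.append(int(truth.ethogram[w, f]))
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(
        idx, names=["track_id", "frame"]), dtype=int)
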