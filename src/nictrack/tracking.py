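"""Frame stitching: link per-frame detections into worm tracks.

Adjacent-frame detections are matched greedily by centroid proximity
(closest pairs first), with matches farther than a species-dependent cap
(429 um for C. elegans dauers, 300 um for S. carpocapsae IJs) rejected to
limit identity switching.  Centerline orientation is made temporally
consistent by endpoint proximity, and tracks shorter than 10 s are dropped.
Tracks never bridge missed detections: a worm unmatched in one frame ends
its track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline, NoAnchorError
from .segmentation import ROI

MAX_DISP_ELEGANS_UM = 429.0
MAX_DISP_CARPOCAPSAE_UM = 300.0


@dataclass
class WormTrack:
    """Time-ordered worm-frames for one worm identity.

    Frame indices increase strictly by 1 (no gaps within a track).
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    rois: list[ROI] = field(default_factory=list)
    centerlines: list[Centerline | None] = field(default_factory=list)
    fps: float = 5.0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def centroid(self, i: int) -> tuple[float, float]:
        return self.rois[i].centroid_um


def stitch_tracks(rois_per_frame: list[list[ROI]],
                  centerlines_per_frame: list[list[Centerline | None]] | None = None,
                  max_disp_um: float = MAX_DISP_ELEGANS_UM,
                  fps: float = 5.0) -> list[WormTrack]:
    """Greedy closest-centroid-first matching between adjacent frames.

    All cross-frame centroid pairs are sorted by distance (ties broken by
    earlier track id, then lower detection index, for determinism); a pair
    is accepted iff neither member is already matched and the distance is
    within ``max_disp_um``.  Unmatched detections start new tracks;
    unmatched tracks end.
    """
    tracks: list[WormTrack] = []
    active: list[WormTrack] = []
    next_id = 0
    for f, rois in enumerate(rois_per_frame):
        cls = (centerlines_per_frame[f] if centerlines_per_frame is not None
               else [None] * len(rois))
        if len(cls) != len(rois):
            raise ValueError(f"frame {f}: centerline/ROI count mismatch")
        pairs = []
        for ti, tr in enumerate(active):
            cx, cy = tr.centroid(-1)
            for di, roi in enumerate(rois):
                dx, dy = roi.centroid_um
                d = np.hypot(dx - cx, dy - cy)
                if d <= max_disp_um:
                    pairs.append((d, tr.track_id, di, ti))
        pairs.sort()
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for d, tid, di, ti in pairs:
            if ti in matched_tracks or di in matched_dets:
                continue
            matched_tracks.add(ti)
            matched_dets.add(di)
            assignment[ti] = di
        new_active: list[WormTrack] = []
        for ti, tr in enumerate(active):
            if ti in assignment:
                di = assignment[ti]
                tr.frames.append(f)
                tr.rois.append(rois[di])
                tr.centerlines.append(cls[di])
                new_active.append(tr)
        for di, roi in enumerate(rois):
            if di in matched_dets:
                continue
            tr = WormTrack(track_id=next_id, frames=[f], rois=[roi],
                           centerlines=[cls[di]], fps=fps)
            next_id += 1
            tracks.append(tr)
            new_active.append(tr)
        active = new_active
    return tracks


def align_orientation(track: WormTrack) -> WormTrack:
    """Orient centerlines consistently in time by endpoint proximity.

    Each centerline after the first is reversed iff the summed
    endpoint-to-endpoint distance to the previous aligned centerline is
    smaller when reversed.  Idempotent; operates in place and returns the
    track.
    """
    prev: Centerline | None = None
    for i, cl in enumerate(track.centerlines):
        if cl is None:
            continue
        if prev is not None:
            p = prev.points_um
            c = cl.points_um
            d_same = np.linalg.norm(c[0] - p[0]) + np.linalg.norm(c[-1] - p[-1])
            d_rev = np.linalg.norm(c[-1] - p[0]) + np.linalg.norm(c[0] - p[-1])
            if d_rev < d_same:
                cl = cl.reversed()
                track.centerlines[i] = cl
        prev = cl
    return track


def filter_tracks(tracks: list[WormTrack], min_duration_s: float = 10.0
                  ) -> list[WormTrack]:
    """Keep tracks of duration >= ``min_duration_s``."""
    return [t for t in tracks if t.duration_s >= min_duration_s]


def nearest_valid_centerline(track: WormTrack, frame_index: int) -> Centerline:
    """Temporally closest clean (unflagged or corrected) centerline; ties
    broken toward earlier frames.  Raises :class:`NoAnchorError` if none."""
    best: tuple[int, int] | None = None  # (|dt|, frame)
    best_cl: Centerline | None = None
    for f, cl in zip(track.frames, track.centerlines):
        if cl is None or not cl.is_clean:
            continue
        key = (abs(f - frame_index), f)
        if best is None or key < best:
            best = key
            best_cl = cl
    if best_cl is None:
        raise NoAnchorError(f"track {track.track_id}: no clean centerline")
    return best_cl


def repair_track_centerlines(track: WormTrack, um_per_px: float) -> WormTrack:
    """Repair flagged centerlines in a track with the deformable model,
    initializing each repair from the nearest-in-time clean centerline.
    Centerlines still flagged after repair are censored (set to None)."""
    from .centerline import fit_deformable_model

    for i, cl in enumerate(track.centerlines):
        if cl is None or cl.is_clean:
            continue
        try:
            anchor = nearest_valid_centerline(track, track.frames[i])
        except NoAnchorError:
            track.centerlines[i] = None
            continue
        try:
            fixed, _ = fit_deformable_model(track.rois[i].full_mask(), anchor, um_per_px)
        except Exception:
            track.centerlines[i] = None
            continue
        # exclude worm-frames whose centerline still meets flagging criteria
        track.centerlines[i] = fixed if not fixed.flags else None
    return track
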