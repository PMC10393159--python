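"""Synthetic micropost-arena videos with exact ground truth.

Emulates top-down recordings of dauer/IJ nematodes behaving on a molded agar
arena bearing a rectilinear grid of cylindrical posts (75 um center-to-center
by default).  Worms are dark, roughly 450-550 um long tubes that crawl with an
undulatory gait while recumbent; nictation (standing on the tail) is rendered
with the three pixel-level cues the downstream features are designed to
detect: the visible body is foreshortened, the elevated (leading) end is
defocused, and translation stops.  Behavior follows a two-state
recumbent/nictating continuous-time Markov chain sampled at the video frame
rate.

Ground truth (per-frame integer label masks, 50-point centerlines in um, and
a per-worm-frame ethogram) is returned alongside the rendered video so that
segmentation, centerline extraction, tracking and scoring can all be
benchmarked without recorded data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class ArenaSpec:
    """Geometry and appearance of the micropost arena.

    Distances are in micrometers; gray levels on the 8-bit scale.
    ``background_jitter_px`` is the amplitude (in pixels) of the slow random
    drift of the whole background between frames, emulating the residual
    motion of a hand-mounted arena.
    """

    post_spacing_um: float = 75.0
    post_diameter_um: float = 50.0
    um_per_px: float = 3.75
    frame_shape: tuple[int, int] = (512, 512)
    background_level: int = 180
    post_edge_darkening: int = 40
    background_jitter_px: float = 0.0

    def validate(self) -> None:
        if not (self.post_spacing_um > self.post_diameter_um > 0):
            raise ValueError("require post_spacing > post_diameter > 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.frame_shape[0] <= 0 or self.frame_shape[1] <= 0:
            raise ValueError("frame shape must be positive")
        if self.background_jitter_px < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class SyntheticWormSpec:
    """Physical and behavioral parameters of one synthetic worm.

    Defaults give a ~500 x 25 um dauer-like animal whose rendered area
    (~12,500 um^2) sits inside the 3674-16533 um^2 ROI band used for
    C. elegans dauers.  ``behavior_rates`` are the (initiation, stopping)
    rates in Hz of the recumbent->nictating and nictating->recumbent
    transitions; the defaults reproduce trainer-scored dauer rates and give
    a stationary nictation fraction of ~0.44.
    """

    length_um: float = 500.0
    width_um: float = 25.0
    intensity_offset: int = 60
    wave_amplitude_rad: float = 0.55
    wavelength_um: float = 250.0
    period_s: float = 2.0
    crawl_speed_um_s: float = 50.0
    nictation_foreshortening: float = 0.35
    nictation_blur_sigma_px: float = 1.6
    behavior_rates_hz: tuple[float, float] = (0.073, 0.094)

    def validate(self) -> None:
        if not (0.0 < self.nictation_foreshortening < 1.0):
            raise ValueError("foreshortening must be in (0, 1)")
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("length and width must be positive")
        if any(r < 0 for r in self.behavior_rates_hz):
            raise ValueError("behavior rates must be >= 0")


@dataclass
class GroundTruth:
    """Exact generator output for one simulation.

    centerlines_um: (n_worms, n_frames, 50, 2) array of (x, y) um, ordered
        leading end first; the stored centerline is the *rendered* (possibly
        foreshortened) one.
    ethogram: (n_worms, n_frames) int array, 0 recumbent / 1 nictating.
    """

    centerlines_um: np.ndarray
    ethogram: np.ndarray
    centroids_um: np.ndarray  # (n_worms, n_frames, 2), from the 50 points
    seed: int
    fps: float

    @property
    def n_worms(self) -> int:
        return self.centerlines_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.centerlines_um.shape[1]


N_CENTERLINE_POINTS = 50


# ---------------------------------------------------------------------------
# background

def render_arena_background(spec: ArenaSpec, n_frames: int, seed: int = 0) -> np.ndarray:
    """Render ``n_frames`` 8-bit frames of the empty post grid.

    Posts are drawn as darkened discs with a stronger dark rim (the molded
    post edge scatters light).  With positive jitter the whole field drifts
    by a smooth, bounded random walk between frames.
    """
    spec.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rows, cols = spec.frame_shape
    spacing_px = spec.post_spacing_um / spec.um_per_px
    radius_px = 0.5 * spec.post_diameter_um / spec.um_per_px

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    # distance to nearest post center on the rectilinear grid; half-spacing
    # offset keeps a full post away from the exact frame corner
    off = spacing_px / 2.0
    dx = (xx - off) % spacing_px
    dy = (yy - off) % spacing_px
    dx = np.minimum(dx, spacing_px - dx)
    dy = np.minimum(dy, spacing_px - dy)
    r = np.hypot(dx, dy)

    disc = (r <= radius_px).astype(float)  # pixel-center rasterization
    # the molded post edge scatters light: extra darkening just inside the rim
    rim = disc * np.clip(1.0 - (radius_px - r) / 1.5, 0.0, 1.0)
    base = (
        float(spec.background_level)
        - disc * (0.35 * spec.post_edge_darkening)
        - rim * (0.65 * spec.post_edge_darkening)
    )

    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    offsets = background_jitter_offsets(spec, n_frames, seed)
    for i in range(n_frames):
        if np.any(offsets[i] != 0.0):
            shifted = ndimage.shift(base, offsets[i], order=1, mode="nearest")
        else:
            shifted = base
        frames[i] = np.clip(np.round(shifted), 0, 255).astype(np.uint8)
    return frames


def background_jitter_offsets(spec: ArenaSpec, n_frames: int, seed: int) -> np.ndarray:
    """Smooth random-walk (dy, dx) offsets bounded by the jitter amplitude."""
    amp = spec.background_jitter_px
    if amp == 0.0 or n_frames == 1:
        return np.zeros((n_frames, 2))
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, amp / 4.0, size=(n_frames, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    return np.clip(walk, -amp, amp)


# ---------------------------------------------------------------------------
# behavior + locomotion

def _sample_ethogram(rates_hz: tuple[float, float], n_frames: int, fps: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov ethogram at frame resolution.

    Per-frame switch probability is 1 - exp(-rate/fps), the exact discrete
    sampling of a continuous-time rate.  The initial state is drawn from the
    stationary distribution (all-recumbent if the initiation rate is zero).
    """
    ir, sr = rates_hz
    p_init = ir / (ir + sr) if (ir + sr) > 0 else 0.0
    p_start = 1.0 - math.exp(-ir / fps)
    p_stop = 1.0 - math.exp(-sr / fps)
    eth = np.zeros(n_frames, dtype=np.int8)
    state = 1 if rng.random() < p_init else 0
    u = rng.random(n_frames)
    for t in range(n_frames):
        eth[t] = state
        if state == 0:
            if u[t] < p_start:
                state = 1
        else:
            if u[t] < p_stop:
                state = 0
    return eth


class _TrailWorm:
    """Head-trail locomotion model.

    The head advances at the crawl speed with a sinusoidally oscillating
    heading (the undulatory gait); the body occupies the trailing
    ``length_um`` of the head's path, which reproduces the track-following
    crawling of real nematodes.  Steering gently turns the base heading
    toward the center of the worm's roaming box so the animal never leaves
    its assigned region.
    """

    TRAIL_DS = 2.0  # um between stored trail points

    def __init__(self, spec: SyntheticWormSpec, box_um: tuple[float, float, float, float],
                 rng: np.random.Generator):
        self.spec = spec
        self.box = box_um  # (xmin, ymin, xmax, ymax) roaming box for the head
        cx = 0.5 * (box_um[0] + box_um[2])
        cy = 0.5 * (box_um[1] + box_um[3])
        jitter_x = rng.uniform(-0.1, 0.1) * (box_um[2] - box_um[0])
        jitter_y = rng.uniform(-0.1, 0.1) * (box_um[3] - box_um[1])
        self.base_heading = rng.uniform(0.0, 2.0 * math.pi)
        self.phase = rng.uniform(0.0, 2.0 * math.pi)
        self.distance = 0.0
        # seed the trail with a sinuous body behind the start point,
        # steering back toward the roaming box so the body stays in frame
        head = np.array([cx + jitter_x, cy + jitter_y])
        pts = [head]
        h = self.base_heading + math.pi  # walk backwards
        n_back = int(math.ceil(spec.length_um * 1.5 / self.TRAIL_DS))
        p = head.copy()
        for i in range(n_back):
            if not (box_um[0] <= p[0] <= box_um[2]
                    and box_um[1] <= p[1] <= box_um[3]):
                to_center = math.atan2(cy - p[1], cx - p[0])
                diff = (to_center - h + math.pi) % (2.0 * math.pi) - math.pi
                h += float(np.clip(diff, -0.04, 0.04))
            s = i * self.TRAIL_DS
            ang = h + spec.wave_amplitude_rad * math.sin(2.0 * math.pi * s / spec.wavelength_um)
            p = p + self.TRAIL_DS * np.array([math.cos(ang), math.sin(ang)])
            pts.append(p.copy())
        self.trail = pts[::-1]  # oldest first; head is trail[-1]
        self._carry = 0.0

    def step(self, dt: float, moving: bool) -> None:
        if not moving:
            return
        spec = self.spec
        advance = spec.crawl_speed_um_s * dt
        self.phase += 2.0 * math.pi * dt / spec.period_s
        # steer toward box center when the head nears the box edge
        head = self.trail[-1]
        xmin, ymin, xmax, ymax = self.box
        margin = 0.15 * min(xmax - xmin, ymax - ymin)
        near_edge = (
            head[0] < xmin + margin or head[0] > xmax - margin
            or head[1] < ymin + margin or head[1] > ymax - margin
        )
        if near_edge:
            to_center = math.atan2(0.5 * (ymin + ymax) - head[1],
                                   0.5 * (xmin + xmax) - head[0])
            diff = (to_center - self.base_heading + math.pi) % (2.0 * math.pi) - math.pi
            self.base_heading += np.clip(diff, -0.35, 0.35)
        # advance the head in small substeps so the trail stays dense
        remaining = advance + self._carry
        p = np.asarray(self.trail[-1], dtype=float)
        while remaining >= self.TRAIL_DS:
            ang = self.base_heading + self.spec.wave_amplitude_rad * math.sin(self.phase)
            p = p + self.TRAIL_DS * np.array([math.cos(ang), math.sin(ang)])
            self.trail.append(p.copy())
            remaining -= self.TRAIL_DS
            self.distance += self.TRAIL_DS
        self._carry = remaining
        # keep the trail bounded
        max_pts = int(self.spec.length_um * 2.0 / self.TRAIL_DS) + 4
        if len(self.trail) > max_pts:
            del self.trail[: len(self.trail) - max_pts]

    def centerline(self, foreshortened: bool) -> np.ndarray:
        """50-point tip-to-tip centerline, leading end first, in um.

        The body is a constant-width tube with round caps; its visible
        extent (and hence the stored centerline) runs nose tip to tail tip,
        so the tube is rendered around the spine obtained by trimming half
        a body width from each end (see :func:`render_video`).
        """
        frac = 1.0 - self.spec.nictation_foreshortening if foreshortened else 1.0
        target = self.spec.length_um * frac
        pts = np.asarray(self.trail[::-1])  # head first
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        target = min(target, s[-1])
        want = np.linspace(0.0, target, N_CENTERLINE_POINTS)
        x = np.interp(want, s, pts[:, 0])
        y = np.interp(want, s, pts[:, 1])
        return np.column_stack([x, y])


def _roaming_boxes(arena: ArenaSpec, worms: list[SyntheticWormSpec]) -> list[tuple[float, float, float, float]]:
    """Partition the frame into per-worm roaming cells (head never leaves
    its cell, so bodies of distinct worms cannot touch)."""
    rows_px, cols_px = arena.frame_shape
    w_um = cols_px * arena.um_per_px
    h_um = rows_px * arena.um_per_px
    n = len(worms)
    ncols = int(math.ceil(math.sqrt(n * w_um / h_um)))
    nrows = int(math.ceil(n / ncols))
    cell_w = w_um / ncols
    cell_h = h_um / nrows
    # the head roams the cell inset by a bit more than half a body length on
    # each side; the trailing body then stays inside the cell proper
    boxes = []
    for i in range(n):
        r, c = divmod(i, ncols)
        inset = 0.55 * worms[i].length_um
        x0, y0 = c * cell_w, r * cell_h
        box = (x0 + inset, y0 + inset, x0 + cell_w - inset, y0 + cell_h - inset)
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(
                f"cannot place worm {i}: cell {cell_w:.0f}x{cell_h:.0f} um too "
                f"small for a {worms[i].length_um:.0f} um worm"
            )
        boxes.append(box)
    return boxes


def simulate_worms(arena: ArenaSpec, worms: list[SyntheticWormSpec], duration_s: float,
                   fps: float = 5.0, seed: int = 0) -> GroundTruth:
    """Simulate worm behavior and posture; returns exact ground truth.

    Recumbent frames advance the worm along its undulatory path; nictating
    frames freeze translation and shorten the rendered centerline by the
    foreshortening fraction.  Deterministic given ``seed``.
    """
    arena.validate()
    for w in worms:
        w.validate()
    if fps <= 0:
        raise ValueError("fps must be positive")
    if duration_s < 1.0 / fps:
        raise ValueError("duration shorter than one frame")
    n_frames = int(round(duration_s * fps))
    rng = np.random.default_rng(seed)
    boxes = _roaming_boxes(arena, worms)

    eth = np.zeros((len(worms), n_frames), dtype=np.int8)
    cls = np.zeros((len(worms), n_frames, N_CENTERLINE_POINTS, 2))
    for i, spec in enumerate(worms):
        eth[i] = _sample_ethogram(spec.behavior_rates_hz, n_frames, fps, rng)
        worm = _TrailWorm(spec, boxes[i], rng)
        for t in range(n_frames):
            worm.step(1.0 / fps, moving=(eth[i, t] == 0))
            cls[i, t] = worm.centerline(foreshortened=(eth[i, t] == 1))
    centroids = cls.mean(axis=2)
    return GroundTruth(centerlines_um=cls, ethogram=eth, centroids_um=centroids,
                       seed=seed, fps=fps)


# ---------------------------------------------------------------------------
# rendering

def _trim_polyline_ends(points: np.ndarray, trim: float) -> np.ndarray:
    """Drop ``trim`` of arc length from each end of a polyline (the tube
    spine around which round caps restore the full tip-to-tip extent)."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 2.0 * trim:
        mid = 0.5 * total
        return np.column_stack([np.interp([mid, mid], s, pts[:, 0]),
                                np.interp([mid, mid], s, pts[:, 1])])
    want = np.linspace(trim, total - trim, max(2, len(pts) - 2))
    return np.column_stack([np.interp(want, s, pts[:, 0]),
                            np.interp(want, s, pts[:, 1])])


def _stamp_tube(canvas: np.ndarray, centerline_px: np.ndarray, radius_px: float) -> None:
    """Constant-width tube with round caps: pixel centers within
    ``radius_px`` of the polyline.  Marks True in ``canvas``.

    Exact point-to-segment distances (computed on the polyline's bounding
    box only) keep the rasterized area unbiased relative to the analytic
    stadium area.
    """
    pts = np.asarray(centerline_px, dtype=float)  # (x, y)
    rows, cols = canvas.shape
    pad = radius_px + 1.0
    c0 = max(0, int(math.floor(pts[:, 0].min() - pad)))
    c1 = min(cols, int(math.ceil(pts[:, 0].max() + pad)) + 1)
    r0 = max(0, int(math.floor(pts[:, 1].min() - pad)))
    r1 = min(rows, int(math.ceil(pts[:, 1].max() + pad)) + 1)
    if c0 >= c1 or r0 >= r1:
        return
    # distance transform to a densely resampled polyline; with 0.5 px
    # sample spacing the quantization of the support boundary is sub-pixel
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(2, int(math.ceil(s[-1] / 0.5)) + 1)
    want = np.linspace(0.0, s[-1], n_dense)
    dx = np.interp(want, s, pts[:, 0]) - c0
    dy = np.interp(want, s, pts[:, 1]) - r0
    local = np.ones((r1 - r0, c1 - c0), dtype=bool)
    ix = np.clip(np.round(dx).astype(int), 0, c1 - c0 - 1)
    iy = np.clip(np.round(dy).astype(int), 0, r1 - r0 - 1)
    local[iy, ix] = False
    dist = ndimage.distance_transform_edt(local)
    canvas[r0:r1, c0:c1] |= dist <= radius_px


def render_video(arena_frames: np.ndarray, truth: GroundTruth,
                 worms: list[SyntheticWormSpec], arena: ArenaSpec
                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw worms over the background frames.

    Returns (video uint8, label_masks uint16, report).  Each worm is a
    constant-width dark tube along its ground-truth centerline; nictating
    frames are additionally defocused near the leading end.  The label mask
    of a worm is exactly the rendered tube support.  Worms (partially)
    outside the frame are clipped and listed in the report.
    """
    n_frames, rows, cols = arena_frames.shape
    if truth.n_frames != n_frames:
        raise ValueError("ground truth and arena frame counts differ")
    upp = arena.um_per_px
    video = np.empty_like(arena_frames)
    labels = np.zeros((n_frames, rows, cols), dtype=np.uint16)
    clipped: list[tuple[int, int]] = []

    for t in range(n_frames):
        frame = arena_frames[t].astype(np.float32)
        label = labels[t]
        for i, spec in enumerate(worms):
            cl_px = truth.centerlines_um[i, t] / upp  # (x, y) px
            radius_px = 0.5 * spec.width_um / upp
            if (cl_px[:, 0].min() < -radius_px or cl_px[:, 1].min() < -radius_px
                    or cl_px[:, 0].max() > cols + radius_px
                    or cl_px[:, 1].max() > rows + radius_px):
                clipped.append((i, t))
            mask = np.zeros((rows, cols), dtype=bool)
            # trim half a pixel less than the cap radius so the stored tip
            # points always land on mask pixels despite rounding
            spine_px = _trim_polyline_ends(cl_px, max(0.0, radius_px - 0.5))
            _stamp_tube(mask, spine_px, radius_px)
            # local patch around the worm keeps the per-frame cost bounded
            pad = int(math.ceil(radius_px + 4 * max(spec.nictation_blur_sigma_px, 1)))
            r0 = max(0, int(cl_px[:, 1].min()) - pad)
            r1 = min(rows, int(cl_px[:, 1].max()) + pad + 1)
            c0 = max(0, int(cl_px[:, 0].min()) - pad)
            c1 = min(cols, int(cl_px[:, 0].max()) + pad + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            contrib = np.where(mask[r0:r1, c0:c1], float(spec.intensity_offset), 0.0)
            if truth.ethogram[i, t] == 1 and spec.nictation_blur_sigma_px > 0:
                # defocus falls off with distance from the elevated leading tip
                blurred = ndimage.gaussian_filter(contrib, spec.nictation_blur_sigma_px)
                tip = cl_px[0]
                yy, xx = np.mgrid[r0:r1, c0:c1]
                d = np.hypot(xx - tip[0], yy - tip[1]) * upp
                w = np.clip(1.0 - d / (0.6 * spec.length_um), 0.0, 1.0)
                contrib = w * blurred + (1.0 - w) * contrib
            frame[r0:r1, c0:c1] -= contrib
            label[mask & (label == 0)] = i + 1
        video[t] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    report = {"clipped_worm_frames": clipped}
    return video, labels, report


def simulate_video(arena: ArenaSpec, worms: list[SyntheticWormSpec], duration_s: float,
                   fps: float = 5.0, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, GroundTruth, dict]:
    """Convenience wrapper: background + behavior + rendering in one call."""
    n_frames = int(round(duration_s * fps))
    bg = render_arena_background(arena, n_frames, seed=seed)
    truth = simulate_worms(arena, worms, duration_s, fps=fps, seed=seed + 1)
    video, labels, report = render_video(bg, truth, worms, arena)
    return video, labels, truth, report


def sinuous_posture(wave_amplitude_rad: float, seed: int = 0, length_um: float = 500.0,
                    width_um: float = 25.0, wavelength_um: float = 250.0,
                    um_per_px: float = 3.75, margin_um: float = 150.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One rendered worm posture with its exact 50-point centerline.

    The body follows a sinusoidal-heading curve of the given angular
    amplitude (0 = straight); random phase and base heading come from the
    seed.  Returns (boolean mask, tip-to-tip centerline in um).  Useful for
    benchmarking centerline extraction across curvatures without running
    the full behavior simulation.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, length_um, 200)
    ang = (rng.uniform(0.0, 2.0 * math.pi)
           + wave_amplitude_rad * np.sin(2.0 * math.pi * s / wavelength_um
                                         + rng.uniform(0.0, 2.0 * math.pi)))
    ds = np.diff(s)
    x = np.concatenate([[0.0], np.cumsum(np.cos(ang[:-1]) * ds)])
    y = np.concatenate([[0.0], np.cumsum(np.sin(ang[:-1]) * ds)])
    pts = np.column_stack([x, y])
    pts -= pts.min(axis=0) - margin_um
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    want = np.linspace(0.0, cum[-1], N_CENTERLINE_POINTS)
    cl50 = np.column_stack([np.interp(want, cum, pts[:, 0]),
                            np.interp(want, cum, pts[:, 1])])
    shape = (int((pts[:, 1].max() + margin_um) / um_per_px),
             int((pts[:, 0].max() + margin_um) / um_per_px))
    mask = np.zeros(shape, dtype=bool)
    radius_px = 0.5 * width_um / um_per_px
    _stamp_tube(mask, _trim_polyline_ends(cl50 / um_per_px,
                                          max(0.0, radius_px - 0.5)), radius_px)
    return mask, cl50


def sample_ethograms(rates_hz: tuple[float, float], n_tracks: int, n_frames: int,
                     fps: float, seed: int = 0) -> np.ndarray:
    """(n_tracks, n_frames) two-state Markov ethograms at frame resolution
    (0 recumbent, 1 nictating), without rendering."""
    rng = np.random.default_rng(seed)
    return np.stack([_sample_ethogram(rates_hz, n_frames, fps, rng)
                     for _ in range(n_tracks)])


def default_worms(n: int, **overrides) -> list[SyntheticWormSpec]:
    """``n`` copies of the default worm spec with optional field overrides."""
    return [dataclasses.replace(SyntheticWormSpec(), **overrides) for _ in range(n)]
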