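"""Nictation metrics and scorer-comparison statistics.

Nictation is summarized by four quantities: the nictation ratio NR
(fraction of scored time spent nictating), the initiation rate IR
(nictation starts per recumbent second), the stopping rate SR (stops per
nictating second), and the overall transition rate TR (both kinds of
transition per scored second).  Censored frames are excluded from every
time denominator and break tracks into independent segments, so a
transition is never counted across a censored gap.  A denominator of zero
leaves the corresponding rate undefined (None), never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

RECUMBENT, NICTATING, CENSORED = 0, 1, -1


@dataclass
class NictationMetrics:
    nr: float | None
    ir: float | None
    sr: float | None
    tr: float | None
    n_initiations: int
    n_terminations: int
    recumbent_time_s: float
    nictating_time_s: float


def _as_track_dict(ethograms) -> dict:
    """Accept a (track_id, frame)-indexed Series, a dict of label arrays, or
    a single 1-D array."""
    if isinstance(ethograms, pd.Series):
        if isinstance(ethograms.index, pd.MultiIndex):
            return {tid: block.to_numpy()
                    for tid, block in ethograms.groupby(level="track_id", sort=False)}
        return {"track": ethograms.to_numpy()}
    if isinstance(ethograms, dict):
        return {k: np.asarray(v) for k, v in ethograms.items()}
    return {"track": np.asarray(ethograms)}


def _segments(labels: np.ndarray):
    """Maximal uncensored runs."""
    good = labels != CENSORED
    i = 0
    n = len(labels)
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j < n and good[j]:
            j += 1
        yield labels[i:j]
        i = j


def _track_counts(labels: np.ndarray) -> tuple[int, int, int, int]:
    """(n_recumbent, n_nictating, n_initiations, n_terminations)."""
    n_rec = int(np.sum(labels == RECUMBENT))
    n_nic = int(np.sum(labels == NICTATING))
    n_init = n_term = 0
    for seg in _segments(labels):
        d = np.diff(seg)
        n_init += int(np.sum(d == 1))
        n_term += int(np.sum(d == -1))
    return n_rec, n_nic, n_init, n_term


def _metrics_from_counts(n_rec: int, n_nic: int, n_init: int, n_term: int,
                         fps: float) -> NictationMetrics:
    rec_t = n_rec / fps
    nic_t = n_nic / fps
    total = rec_t + nic_t
    return NictationMetrics(
        nr=nic_t / total if total > 0 else None,
        ir=n_init / rec_t if rec_t > 0 else None,
        sr=n_term / nic_t if nic_t > 0 else None,
        tr=(n_init + n_term) / total if total > 0 else None,
        n_initiations=n_init, n_terminations=n_term,
        recumbent_time_s=rec_t, nictating_time_s=nic_t,
    )


def nictation_metrics(ethograms, fps: float, level: str = "pooled"):
    """NR/IR/SR/TR from one or more ethograms.

    level="pooled" sums counts over all tracks before forming ratios (a
    track-duration-weighted summary); level="per_track" returns a dict of
    per-track metrics.
    """
    tracks = _as_track_dict(ethograms)
    if level == "per_track":
        return {tid: _metrics_from_counts(*_track_counts(lab), fps)
                for tid, lab in tracks.items()}
    if level != "pooled":
        raise ValueError(f"unknown level {level!r}")
    tot = np.zeros(4, dtype=int)
    for lab in tracks.values():
        tot += np.array(_track_counts(lab))
    return _metrics_from_counts(*tot, fps)


def relative_error(measured: float, truth: float) -> float:
    """measured / truth - 1 (zero when there is no error); NaN if truth is 0."""
    if truth == 0:
        warnings.warn("relative error undefined for zero truth value")
        return float("nan")
    return measured / truth - 1.0


def agreement(e1, e2) -> tuple[float, np.ndarray]:
    """Frame-wise accuracy between two ethograms over shared worm-frames;
    frames censored in either are excluded.  Returns (accuracy, 2x2
    confusion matrix with rows = e1, cols = e2)."""
    a = np.asarray(e1.to_numpy() if isinstance(e1, pd.Series) else e1)
    b = np.asarray(e2.to_numpy() if isinstance(e2, pd.Series) else e2)
    if a.shape != b.shape:
        raise ValueError("ethograms cover different worm-frames")
    ok = (a != CENSORED) & (b != CENSORED)
    if not ok.any():
        raise ValueError("no jointly uncensored frames to compare")
    a, b = a[ok], b[ok]
    conf = np.zeros((2, 2), dtype=int)
    for i in (0, 1):
        for j in (0, 1):
            conf[i, j] = int(np.sum((a == i) & (b == j)))
    return float(np.mean(a == b)), conf


def confidence_margin(probs: pd.DataFrame, scored: pd.Series) -> pd.Series:
    """Probability of the scored behavior minus the highest other-class
    probability; NaN on censored frames."""
    p = probs.to_numpy(dtype=float)
    lab = np.asarray(scored)
    out = np.full(len(p), np.nan)
    ok = (lab != CENSORED) & np.isfinite(p).all(axis=1)
    idx = lab[ok]
    chosen = p[ok, idx]
    other = p[ok, 1 - idx]
    out[ok] = chosen - other
    return pd.Series(out, index=probs.index)


def transition_events(labels: np.ndarray) -> list[tuple[int, str]]:
    """(frame, kind) for every label change across adjacent uncensored
    frames; kind in {initiation, termination}.  The frame is the first
    frame of the new behavior."""
    events = []
    for t in range(1, len(labels)):
        a, b = labels[t - 1], labels[t]
        if a == CENSORED or b == CENSORED or a == b:
            continue
        events.append((t, "initiation" if b == NICTATING else "termination"))
    return events


def transition_offsets(reference: pd.Series, comparison: pd.Series,
                       window_s: float = 2.0, fps: float = 5.0):
    """Timing comparison around reference transitions.

    For each reference transition preceded and followed by >= window_s of
    uninterrupted behavior: the per-offset accuracy of the comparison in a
    +/- window around the transition, and — when the comparison contains
    exactly one same-kind transition in that window — the signed offset in
    seconds.  Windows containing several candidate transitions are
    excluded.  Returns (offsets DataFrame, accuracy-curve DataFrame,
    two-sided binomial sign test on the nonzero offsets or None).
    """
    w = int(round(window_s * fps))
    ref_tracks = _as_track_dict(reference)
    cmp_tracks = _as_track_dict(comparison)
    if set(ref_tracks) != set(cmp_tracks):
        raise ValueError("ethograms cover different tracks")
    offsets = []
    acc_num = np.zeros(2 * w + 1)
    acc_den = np.zeros(2 * w + 1)
    for tid, ref in ref_tracks.items():
        cmp_ = cmp_tracks[tid]
        if len(ref) != len(cmp_):
            raise ValueError(f"track {tid}: length mismatch")
        for t, kind in transition_events(ref):
            if t - w < 0 or t + w > len(ref):
                continue
            before = ref[t - w:t]
            after = ref[t:t + w]
            if not (np.all(before == ref[t - 1]) and np.all(after == ref[t])):
                continue
            for o in range(-w, w + 1):
                j = t + o
                if 0 <= j < len(ref) and cmp_[j] != CENSORED:
                    acc_num[o + w] += float(cmp_[j] == ref[j])
                    acc_den[o + w] += 1.0
            nearby = [(tc, kc) for tc, kc in transition_events(cmp_)
                      if kc == kind and abs(tc - t) <= w]
            if len(nearby) == 1:
                offsets.append({"track_id": tid, "reference_frame": t,
                                "kind": kind,
                                "offset_s": (nearby[0][0] - t) / fps})
    curve = pd.DataFrame({
        "offset_s": np.arange(-w, w + 1) / fps,
        "accuracy": np.divide(acc_num, acc_den, out=np.full_like(acc_num, np.nan),
                              where=acc_den > 0),
    })
    offsets_df = pd.DataFrame(offsets, columns=["track_id", "reference_frame",
                                                "kind", "offset_s"])
    test = None
    nonzero = offsets_df.loc[offsets_df["offset_s"] != 0, "offset_s"]
    if len(nonzero) > 0:
        test = _stats.binomtest(int(np.sum(nonzero > 0)), len(nonzero), 0.5)
    return offsets_df, curve, test


def recording_duration_analysis(groups: dict[str, dict[str, object]],
                                cutoffs_s, fps: float):
    """How much recording suffices: NR from the first ``cutoff`` seconds.

    ``groups`` maps group name -> {video name -> ethograms of that video}.
    For each cutoff the per-video NR is computed from frames before the
    cutoff only; the relative variance (variance / mean of the per-video
    NRs) is averaged over groups.  Returns (per-video NR table, relative-
    variance curve, argmin cutoff in seconds).
    """
    cutoffs_s = np.atleast_1d(np.asarray(cutoffs_s, dtype=float))
    nr_rows, rv_rows = [], []
    for cutoff in cutoffs_s:
        nmax = int(round(cutoff * fps))
        if nmax < 1:
            continue
        rvs = []
        for gname, videos in groups.items():
            if len(videos) < 2:
                raise ValueError(f"group {gname!r} needs >= 2 videos")
            nrs = []
            for vname, eth in videos.items():
                tracks = _as_track_dict(eth)
                clipped = {tid: lab[:nmax] for tid, lab in tracks.items()}
                m = nictation_metrics(clipped, fps)
                nrs.append(m.nr)
                nr_rows.append({"cutoff_s": cutoff, "group": gname,
                                "video": vname, "nr": m.nr})
            nrs = np.asarray(nrs, dtype=float)
            mean = np.nanmean(nrs)
            rvs.append(np.nanvar(nrs) / mean if mean > 0 else np.nan)
        rv_rows.append({"cutoff_s": cutoff,
                        "relative_variance": float(np.nanmean(rvs))})
    rv = pd.DataFrame(rv_rows)
    best = float(rv.loc[rv["relative_variance"].idxmin(), "cutoff_s"])
    return pd.DataFrame(nr_rows), rv, best


def snapshot_track_selection(videos: dict[str, list], fps: float,
                             min_duration_s: float = 60.0):
    """Pick the snapshot frame for cross-video single-worm comparisons.

    ``videos`` maps video name -> list of (track span, ethogram) pairs,
    where the span is (first_frame, last_frame) inclusive.  Candidate
    frames are those at which every video has >= 2 spanning tracks of
    duration >= min_duration_s; the selected frame maximizes the total
    spanning-track count (ties -> earliest).  Each qualifying track is
    truncated to its first min_duration_s before computing its NR.
    Returns (frame, per-worm NR table).
    """
    min_frames = int(round(min_duration_s * fps))
    spans = {}
    max_frame = 0
    for vname, tracks in videos.items():
        qual = []
        for i, (span, eth) in enumerate(tracks):
            f0, f1 = span
            if f1 - f0 + 1 >= min_frames:
                qual.append((i, f0, f1, np.asarray(eth)))
                max_frame = max(max_frame, f1)
        spans[vname] = qual
    counts = np.zeros(max_frame + 1, dtype=int)
    mins = np.full(max_frame + 1, np.inf)
    for vname, qual in spans.items():
        per_video = np.zeros(max_frame + 1, dtype=int)
        for _, f0, f1, _ in qual:
            per_video[f0:f1 + 1] += 1
        counts += per_video
        mins = np.minimum(mins, per_video)
    candidates = np.nonzero(mins >= 2)[0]
    if len(candidates) == 0:
        raise ValueError(f"no frame with >= 2 qualifying tracks in every video; "
                         f"qualifying tracks per video: "
                         f"{ {v: len(q) for v, q in spans.items()} }")
    best_frame = int(candidates[np.argmax(counts[candidates])])
    rows = []
    for vname, qual in spans.items():
        for i, f0, f1, eth in qual:
            if not (f0 <= best_frame <= f1):
                continue
            m = nictation_metrics(eth[:min_frames], fps)
            rows.append({"video": vname, "track": i, "nr": m.nr})
    return best_frame, pd.DataFrame(rows)
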