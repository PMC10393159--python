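"""Nictation metrics, agreement, transition timing, duration sufficiency."""

import numpy as np
import pandas as pd
import pytest

from nictrack import metrics as mx
from nictrack import synth

FPS = 5.0


def series(vals, tid=0):
    idx = pd.MultiIndex.from_arrays([[tid] * len(vals), range(len(vals))],
                                    names=["track_id", "frame"])
    return pd.Series(list(vals), index=idx, dtype=int)


class TestNictationMetrics:
    def test_simple_ratio(self):
        m = mx.nictation_metrics(series([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]), FPS)
        assert m.nr == pytest.approx(0.4)

    def test_hand_counted_rates(self):
        # [R R N N N R]: 1 initiation / 0.6 s recumbent, 1 termination /
        # 0.6 s nictating
        m = mx.nictation_metrics(series([0, 0, 1, 1, 1, 0]), FPS)
        assert m.n_initiations == 1
        assert m.n_terminations == 1
        assert m.recumbent_time_s == pytest.approx(0.6)
        assert m.nictating_time_s == pytest.approx(0.6)
        assert m.ir == pytest.approx(1.0 / 0.6)
        assert m.sr == pytest.approx(1.0 / 0.6)
        assert m.tr == pytest.approx(2.0 / 1.2)

    def test_all_recumbent_degenerate_denominators(self):
        m = mx.nictation_metrics(series([0, 0, 0, 0]), FPS)
        assert m.ir == 0.0
        assert m.sr is None
        assert m.nr == 0.0

    def test_censored_frames_excluded_and_split(self):
        # censored gap hides the 0->1 transition and its frames
        m = mx.nictation_metrics(series([0, 0, -1, 1, 1]), FPS)
        assert m.n_initiations == 0
        assert m.recumbent_time_s == pytest.approx(0.4)
        assert m.nictating_time_s == pytest.approx(0.4)

    def test_pooled_equals_time_weighted_mean_of_tracks(self):
        rng = np.random.default_rng(0)
        tracks = {t: rng.integers(0, 2, rng.integers(10, 40))
                  for t in range(6)}
        pooled = mx.nictation_metrics(tracks, FPS)
        per = mx.nictation_metrics(tracks, FPS, level="per_track")
        total = sum(len(v) for v in tracks.values())
        weighted = sum(per[t].nr * len(tracks[t]) for t in tracks) / total
        assert pooled.nr == pytest.approx(weighted)

    def test_transition_count_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            lab = rng.integers(0, 2, 30)
            m = mx.nictation_metrics({"t": lab}, FPS)
            assert m.n_initiations - m.n_terminations in (-1, 0, 1)


class TestRelativeError:
    def test_exact_is_zero(self):
        assert mx.relative_error(0.42, 0.42) == 0.0

    def test_ten_percent_high(self):
        assert mx.relative_error(1.1 * 0.4, 0.4) == pytest.approx(0.1)

    def test_half_is_minus_half(self):
        assert mx.relative_error(0.2, 0.4) == pytest.approx(-0.5)

    def test_zero_truth_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(mx.relative_error(0.1, 0.0))


class TestAgreement:
    def test_identical(self):
        e = series([0, 1, 1, 0])
        acc, conf = mx.agreement(e, e)
        assert acc == 1.0
        assert conf[0, 1] == conf[1, 0] == 0

    def test_complement(self):
        acc, _ = mx.agreement(series([0, 1, 0]), series([1, 0, 1]))
        assert acc == 0.0

    def test_censored_frames_excluded_from_denominator(self):
        e1 = series([0, -1, 1, 1, 0, 0, 1, 0, 1, 1])
        e2 = series([0, 1, 1, 1, 0, 0, 1, 0, 1, 0])
        acc, conf = mx.agreement(e1, e2)
        assert conf.sum() == 9
        assert acc == pytest.approx(8 / 9)

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError):
            mx.agreement(series([-1, -1]), series([0, 1]))


class TestConfidenceMargin:
    def test_extreme_and_tied_probabilities(self):
        idx = pd.MultiIndex.from_arrays([[0, 0], [0, 1]],
                                        names=["track_id", "frame"])
        probs = pd.DataFrame({"p_recumbent": [0.999, 0.5],
                              "p_nictating": [0.001, 0.5]}, index=idx)
        scored = pd.Series([0, 0], index=idx)
        margin = mx.confidence_margin(probs, scored)
        assert margin.iloc[0] == pytest.approx(0.998)
        assert margin.iloc[1] == pytest.approx(0.0)

    def test_margin_lower_near_disagreements(self):
        # frames near transitions get probabilities close to 0.5; frames
        # deep inside bouts are confident
        p_nict = np.concatenate([np.full(10, 0.05), [0.45, 0.55],
                                 np.full(10, 0.95)])
        idx = pd.MultiIndex.from_arrays(
            [[0] * len(p_nict), range(len(p_nict))], names=["track_id", "frame"])
        probs = pd.DataFrame({"p_recumbent": 1 - p_nict,
                              "p_nictating": p_nict}, index=idx)
        scored = pd.Series((p_nict > 0.5).astype(int), index=idx)
        margin = mx.confidence_margin(probs, scored)
        disagree_zone = margin.iloc[10:12]
        agree_zone = pd.concat([margin.iloc[:10], margin.iloc[12:]])
        assert disagree_zone.median() < agree_zone.median()


class TestTransitionOffsets:
    def test_identical_ethograms(self):
        ref = series([0] * 12 + [1] * 12)
        offsets, curve, test = mx.transition_offsets(ref, ref, 2.0, FPS)
        assert (offsets["offset_s"] == 0.0).all()
        assert len(offsets) == 1
        valid = curve["accuracy"].dropna()
        assert (valid == 1.0).all()

    def test_delayed_comparison_offset(self):
        ref = series([0] * 12 + [1] * 12)
        cmp_ = series([0] * 14 + [1] * 10)
        offsets, _, _ = mx.transition_offsets(ref, cmp_, 2.0, FPS)
        assert offsets["offset_s"].tolist() == [pytest.approx(0.4)]

    def test_two_candidate_transitions_excluded(self):
        ref = series([0] * 12 + [1] * 12)
        cmp_ = series([0] * 10 + [1, 0] + [1] * 12)  # two initiations near t=12
        offsets, _, _ = mx.transition_offsets(ref, cmp_, 2.0, FPS)
        assert len(offsets) == 0

    def test_no_qualifying_transitions_empty(self):
        ref = series([0] * 30)
        offsets, curve, test = mx.transition_offsets(ref, ref, 2.0, FPS)
        assert len(offsets) == 0
        assert test is None


class TestRecordingDuration:
    def test_identical_videos_zero_relative_variance(self):
        eth = {0: np.array([0, 1] * 50)}
        groups = {"g": {"v1": dict(eth), "v2": dict(eth), "v3": dict(eth)}}
        nr, rv, best = mx.recording_duration_analysis(groups, [2.0, 10.0], FPS)
        assert np.allclose(rv["relative_variance"], 0.0)

    def test_full_cutoff_equals_whole_video_nr(self):
        rng = np.random.default_rng(2)
        videos = {f"v{i}": {0: rng.integers(0, 2, 100)} for i in range(4)}
        groups = {"g": videos}
        nr, rv, best = mx.recording_duration_analysis(groups, [20.0], FPS)
        for vname, eth in videos.items():
            whole = mx.nictation_metrics(eth, FPS).nr
            got = nr.loc[nr["video"] == vname, "nr"].iloc[0]
            assert got == pytest.approx(whole)

    def test_relative_variance_declines_with_duration(self):
        rng = np.random.default_rng(3)
        groups = {}
        for g in range(3):
            videos = {}
            for v in range(4):
                eth = synth.sample_ethograms((0.073, 0.094), 5, 900, FPS,
                                             seed=100 * g + v)
                videos[f"v{v}"] = {i: eth[i] for i in range(len(eth))}
            groups[f"g{g}"] = videos
        cutoffs = [10.0, 60.0, 180.0]
        _, rv, best = mx.recording_duration_analysis(groups, cutoffs, FPS)
        assert rv["relative_variance"].iloc[-1] < rv["relative_variance"].iloc[0]
        assert best in cutoffs

    def test_single_video_group_rejected(self):
        with pytest.raises(ValueError):
            mx.recording_duration_analysis(
                {"g": {"v": {0: np.zeros(10, int)}}}, [1.0], FPS)


class TestSnapshotSelection:
    def _track(self, f0, f1, nr=0.5, seed=0):
        rng = np.random.default_rng(seed)
        eth = (rng.uniform(0, 1, f1 - f0 + 1) < nr).astype(int)
        return ((f0, f1), eth)

    def test_total_count_maximized(self):
        n = 60 * 5  # 1 min of frames
        videos = {
            "a": [self._track(0, 400), self._track(0, 400)],
            "b": [self._track(50, 460), self._track(50, 460)],
            "c": [self._track(90, 500), self._track(90, 500),
                  self._track(100, 420)],
        }
        frame, table = mx.snapshot_track_selection(videos, FPS, 60.0)
        # every video has >= 2 qualifying tracks on [100, 400]; the third
        # track of video c spans [100, 420], so counts peak at 7 there
        assert 100 <= frame <= 400
        assert len(table) == 7

    def test_tie_goes_to_earliest_frame(self):
        videos = {
            "a": [self._track(0, 400), self._track(0, 400)],
            "b": [self._track(0, 400), self._track(0, 400)],
        }
        frame, _ = mx.snapshot_track_selection(videos, FPS, 60.0)
        assert frame == 0

    def test_truncation_to_first_minute(self):
        (span, eth) = self._track(0, 999, seed=5)
        videos = {"a": [((0, 999), eth), ((0, 999), 1 - eth)],
                  "b": [((0, 999), eth), ((0, 999), eth)]}
        frame, table = mx.snapshot_track_selection(videos, FPS, 60.0)
        first_min_nr = eth[:300].mean()
        assert table["nr"].iloc[0] == pytest.approx(first_min_nr)

    def test_insufficient_coverage_errors(self):
        videos = {"a": [self._track(0, 400)],  # only one long track
                  "b": [self._track(0, 400), self._track(0, 400)]}
        with pytest.raises(ValueError):
            mx.snapshot_track_selection(videos, FPS, 60.0)


class TestParameterRecovery:
    def test_markov_rates_recovered_from_simulated_tracks(self):
        ir, sr = 0.073, 0.094
        eth = synth.sample_ethograms((ir, sr), 200, 300, FPS, seed=9)
        m = mx.nictation_metrics({i: eth[i] for i in range(len(eth))}, FPS)
        assert abs(m.ir - ir) / ir < 0.10
        assert abs(m.sr - sr) / sr < 0.10
        assert abs(m.nr - ir / (ir + sr)) / (ir / (ir + sr)) < 0.05
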