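"""Classifier harness, denoisers, and the Viterbi decoders.

The two HMM decoders are checked against exhaustive enumeration of all 2^T
state paths on short tracks — an oracle that shares no code with the
dynamic-programming implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nictrack import scoring as sc

FPS = 5.0


def series(vals, tid=0, start=0):
    idx = pd.MultiIndex.from_arrays(
        [[tid] * len(vals), range(start, start + len(vals))],
        names=["track_id", "frame"])
    return pd.Series(list(vals), index=idx, dtype=int)


def prob_frame(p_nict, tid=0):
    idx = pd.MultiIndex.from_arrays(
        [[tid] * len(p_nict), range(len(p_nict))], names=["track_id", "frame"])
    p = np.asarray(p_nict, dtype=float)
    return pd.DataFrame({"p_recumbent": 1 - p, "p_nictating": p}, index=idx)


class TestPrepareTrainingSet:
    def _features(self, n=20, tid=0):
        idx = pd.MultiIndex.from_arrays([[tid] * n, range(n)],
                                        names=["track_id", "frame"])
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                            index=idx)

    def test_censored_frame_halo_excluded(self):
        X = self._features()
        y = series([0] * 20)
        y.iloc[10] = -1
        Xo, yo, _ = sc.prepare_training_set(X, y)
        kept = Xo.index.get_level_values("frame")
        assert set(range(8, 13)).isdisjoint(kept)
        assert 7 in kept and 13 in kept

    def test_clean_input_identity(self):
        X = self._features()
        y = series([0] * 10 + [1] * 10)
        Xo, yo, tids = sc.prepare_training_set(X, y)
        assert len(Xo) == 20
        assert np.array_equal(yo.to_numpy(), y.to_numpy())

    def test_two_censored_frames_union_of_halos(self):
        X = self._features()
        y = series([0] * 20)
        y.iloc[10] = -1
        y.iloc[13] = -1
        Xo, _, _ = sc.prepare_training_set(X, y)
        kept = set(Xo.index.get_level_values("frame"))
        assert kept == set(range(20)) - set(range(8, 16))

    def test_everything_censored_errors(self):
        X = self._features(n=4)
        y = series([-1, -1, -1, -1])
        with pytest.raises(ValueError):
            sc.prepare_training_set(X, y)


def separable_features(n_tracks=12, frames_per_track=30, seed=0):
    """Linearly separable two-class blobs, one behavior label per track
    half, grouped by track for fold splitting."""
    rng = np.random.default_rng(seed)
    rows, labels, tids = [], [], []
    for t in range(n_tracks):
        lab = t % 2
        mu = np.array([3.0, -2.0]) if lab else np.array([-3.0, 2.0])
        rows.append(mu + rng.normal(0, 0.5, size=(frames_per_track, 2)))
        labels += [lab] * frames_per_track
        tids += [t] * frames_per_track
    X = pd.DataFrame(np.vstack(rows), columns=["u", "v"],
                     index=pd.MultiIndex.from_arrays(
                         [tids, np.tile(range(frames_per_track), n_tracks)],
                         names=["track_id", "frame"]))
    return X, pd.Series(labels, index=X.index), np.asarray(tids)


class TestCrossValidate:
    def test_separable_blobs_all_models_accurate(self):
        X, y, tids = separable_features()
        table = sc.cross_validate(X, y, tids, scaling_grid=("min-max",), seed=0)
        assert (table["val_accuracy"] >= 0.95).all()

    def test_shuffled_labels_at_chance(self):
        X, y, tids = separable_features(n_tracks=20, frames_per_track=50)
        rng = np.random.default_rng(1)
        y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        grid = {"logistic regression": sc.default_model_grid(0)["logistic regression"]}
        table = sc.cross_validate(X, y_shuf, tids, model_grid=grid,
                                  scaling_grid=("min-max",), seed=1)
        assert abs(table["val_accuracy"].iloc[0] - 0.5) <= 0.05

    def test_folds_split_tracks_not_frames(self):
        X, y, tids = separable_features()
        folds = sc._track_folds(tids, y.to_numpy(), k=5, seed=0)
        for mask in folds:
            in_fold = set(tids[mask])
            out_fold = set(tids[~mask])
            assert in_fold.isdisjoint(out_fold)
        total = np.zeros(len(tids), dtype=int)
        for mask in folds:
            total += mask
        assert (total == 1).all()


class TestTrainScore:
    def test_separable_training_accuracy(self):
        X, y, _ = separable_features()
        scorer = sc.train_scorer(X, y, seed=0)
        probs, labels = sc.score_tracks(scorer, X)
        assert (labels.to_numpy() == y.to_numpy()).mean() >= 0.99
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_retrain_deterministic(self):
        X, y, _ = separable_features()
        p1, _ = sc.score_tracks(sc.train_scorer(X, y, seed=3), X)
        p2, _ = sc.score_tracks(sc.train_scorer(X, y, seed=3), X)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_single_class_rejected(self):
        X, y, _ = separable_features()
        with pytest.raises(ValueError):
            sc.train_scorer(X, pd.Series(0, index=X.index), seed=0)

    def test_schema_mismatch_names_columns(self):
        X, y, _ = separable_features()
        scorer = sc.train_scorer(X, y, seed=0)
        with pytest.raises(ValueError, match="v"):
            scorer.predict_proba(X[["u"]])


class TestGaussianSmoothing:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        p = prob_frame(rng.uniform(0, 1, 40))
        raw = (p["p_nictating"] > 0.5).astype(int)
        out = sc.smooth_gaussian(p, 0.0, FPS)
        assert np.array_equal(out.to_numpy(), raw.to_numpy())

    def test_isolated_flip_removed(self):
        p_nict = np.full(20, 0.9)
        p_nict[10] = 0.1  # single-frame dip inside a long nictation bout
        out = sc.smooth_gaussian(prob_frame(p_nict), 0.4, FPS)
        assert out.to_numpy().tolist() == [1] * 20

    def test_transition_count_nonincreasing_with_sigma(self):
        rng = np.random.default_rng(2)
        p = prob_frame(np.clip(rng.normal(0.5, 0.3, 300), 0, 1))
        def transitions(lab):
            v = lab.to_numpy()
            return int(np.sum(v[1:] != v[:-1]))
        assert transitions(sc.smooth_gaussian(p, 1.0, FPS)) <= \
            transitions(sc.smooth_gaussian(p, 0.0, FPS))


class TestRemoveShortBouts:
    def test_documented_forward_pass(self):
        # [R R N R R], min 2 -> all R
        out = sc.remove_short_bouts(series([0, 0, 1, 0, 0]), 2)
        assert out.to_numpy().tolist() == [0, 0, 0, 0, 0]

    def test_min_one_identity(self):
        raw = series([0, 1, 0, 1, 1])
        out = sc.remove_short_bouts(raw, 1)
        assert np.array_equal(out.to_numpy(), raw.to_numpy())

    def test_single_short_bout_track_unchanged(self):
        raw = series([1, 1, 1])
        out = sc.remove_short_bouts(raw, 10)
        assert out.to_numpy().tolist() == [1, 1, 1]

    def test_track_initial_short_bout_merges_forward(self):
        out = sc.remove_short_bouts(series([1, 0, 0, 0, 0]), 3)
        assert out.to_numpy().tolist() == [0] * 5

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40),
           st.integers(1, 6))
    def test_postcondition_and_idempotence(self, labels, min_len):
        raw = series(labels)
        once = sc.remove_short_bouts(raw, min_len)
        twice = sc.remove_short_bouts(once, min_len)
        assert np.array_equal(once.to_numpy(), twice.to_numpy())
        runs = []
        for v in once.to_numpy():
            if runs and runs[-1][0] == v:
                runs[-1][1] += 1
            else:
                runs.append([v, 1])
        if len(runs) > 1:
            assert all(ln >= min_len for _, ln in runs)


def brute_force_best_path(log_emit, spec):
    best_ll, best_path = -np.inf, None
    n = log_emit.shape[0]
    for path in itertools.product((0, 1), repeat=n):
        ll = sc.viterbi_path_loglik(np.array(path), log_emit, spec)
        if ll > best_ll:
            best_ll, best_path = ll, np.array(path)
    return best_ll, best_path


class TestViterbi:
    @pytest.mark.parametrize("variant", ["state", "prob"])
    def test_matches_exhaustive_enumeration(self, variant):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            pp = float(rng.uniform(0.45, 0.99))
            pi = float(rng.uniform(0.1, 0.9))
            spec = sc.HMMSpec(pp, float(rng.uniform(0.6, 0.99)), (pi, 1 - pi))
            if variant == "state":
                obs = rng.integers(0, 2, n)
                log_emit = sc.state_emission_logprobs(obs, spec)
                decoded = sc.viterbi_state_based(series(obs), spec).to_numpy()
            else:
                p = rng.uniform(0.01, 0.99, n)
                log_emit = np.log(np.column_stack([1 - p, p]))
                decoded = sc.viterbi_probability_based(prob_frame(p), spec).to_numpy()
            best_ll, _ = brute_force_best_path(log_emit, spec)
            ll = sc.viterbi_path_loglik(decoded, log_emit, spec)
            assert ll == pytest.approx(best_ll, abs=1e-9)

    def test_uniform_transitions_reduce_to_argmax(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, 50)
        spec = sc.HMMSpec(0.5, 0.9, (0.5, 0.5))
        out = sc.viterbi_probability_based(prob_frame(p), spec)
        assert np.array_equal(out.to_numpy(), (p > 0.5).astype(int))
        obs = rng.integers(0, 2, 50)
        out2 = sc.viterbi_state_based(series(obs), spec)
        assert np.array_equal(out2.to_numpy(), obs)

    def test_full_persistence_gives_constant_path(self):
        obs = np.array([0, 1, 0, 0, 1, 0, 0, 0])
        spec = sc.HMMSpec(1.0, 0.9, (0.5, 0.5))
        out = sc.viterbi_state_based(series(obs), spec).to_numpy()
        assert len(set(out)) == 1
        assert out[0] == 0  # majority state has the higher emission product

    def test_weak_frame_conforms_to_neighbors(self):
        p = np.array([0.95, 0.45, 0.95])
        spec = sc.HMMSpec(0.9, 0.9, (0.5, 0.5))
        out = sc.viterbi_probability_based(prob_frame(p), spec)
        assert out.to_numpy().tolist() == [1, 1, 1]


class TestOptimizeSmoothing:
    def _fold(self, p_nict, manual):
        p = prob_frame(p_nict)
        raw = (p["p_nictating"] > 0.5).astype(int)
        return (p, raw, series(manual))

    def test_perfect_scores_pick_sigma_zero(self):
        manual = [0] * 10 + [1] * 10 + [0] * 10
        p = np.where(np.array(manual) == 1, 0.95, 0.05)
        best, curve = sc.optimize_smoothing(
            [self._fold(p, manual)], np.array([0.0, 0.2, 0.6]), FPS)
        assert best == 0.0
        assert curve["objective"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert len(curve) == 3

    def test_noisy_scores_prefer_positive_sigma(self):
        manual = [0] * 25 + [1] * 25
        p = np.where(np.array(manual) == 1, 0.9, 0.1)
        for i in (5, 12, 19, 30, 37, 44):  # isolated single-frame flips
            p[i] = 1.0 - p[i]
        best, curve = sc.optimize_smoothing(
            [self._fold(p, manual)], np.array([0.0, 0.3, 0.5]), FPS)
        assert best > 0.0
        obj0 = curve.loc[curve["param"] == 0.0, "objective"].iloc[0]
        assert curve["objective"].min() < obj0
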