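"""Behavior classification and temporal denoising of the score sequence.

A supervised classifier (neural network by default) maps the 136-column
feature matrix to per-worm-frame probabilities of recumbence vs nictation.
Cross-validation folds split worm *tracks*, never frames, so temporally
correlated frames of one animal cannot straddle the train/validation
boundary.  The raw score sequence switches state far more often than real
behavior; four denoisers are provided — Gaussian smoothing of the class
probabilities in time, short-bout removal, and two Viterbi decoders of a
bisymmetric two-state hidden Markov model (one treating the raw labels as
noisy observations with a fixed emission accuracy, one using the model
probabilities directly as emissions).  The smoothing parameter is optimized
on cross-validation output against the combined objective
|relerr NR| + |relerr IR| + |relerr SR| + (1 - accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import SCALING_METHODS, fit_apply_scaling

RECUMBENT, NICTATING, CENSORED = 0, 1, -1
PROB_FLOOR = 1e-12


@dataclass
class HMMSpec:
    """Bisymmetric two-state HMM: transition matrix [[P_P, 1-P_P],
    [1-P_P, P_P]]; emission accuracy a = P(obs == state); initial
    distribution from the training-set behavior ratio."""

    persistence_probability: float = 0.95
    emission_accuracy: float = 0.95
    initial_probs: tuple[float, float] = (0.5, 0.5)

    def validate(self) -> None:
        if not (0.0 <= self.persistence_probability <= 1.0):
            raise ValueError("persistence probability must be in [0, 1]")
        if not (0.5 < self.emission_accuracy < 1.0):
            raise ValueError("emission accuracy must be in (0.5, 1)")
        if abs(sum(self.initial_probs) - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")


# ---------------------------------------------------------------------------
# training-set preparation

def prepare_training_set(features: pd.DataFrame, labels: pd.Series,
                         exclusion_halo: int = 2
                         ) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Drop censored/unscoreable frames plus their 2-frame halo.

    ``labels`` is aligned with ``features`` (index (track_id, frame)),
    values in {0, 1, -1}; frames with any non-finite feature are treated as
    unscoreable too.  Returns (X, y, track_ids).
    """
    labels = labels.reindex(features.index)
    bad = (labels == CENSORED) | labels.isna()
    bad |= ~np.isfinite(features).all(axis=1)
    drop = bad.copy()
    for tid, block in bad.groupby(level="track_id", sort=False):
        b = block.to_numpy()
        if not b.any():
            continue
        expanded = b.copy()
        for off in range(1, exclusion_halo + 1):
            expanded[off:] |= b[:-off]
            expanded[:-off] |= b[off:]
        drop.loc[block.index] = expanded
    keep = ~drop
    X = features.loc[keep]
    y = labels.loc[keep].astype(int)
    if len(X) == 0:
        raise ValueError("no training rows left after exclusions")
    return X, y, X.index.get_level_values("track_id").to_numpy()


# ---------------------------------------------------------------------------
# models

def default_model_grid(seed: int = 0) -> dict[str, object]:
    return {
        "logistic regression": LogisticRegression(max_iter=2000, random_state=seed),
        "k nearest neighbors": KNeighborsClassifier(n_neighbors=5),
        "decision tree": DecisionTreeClassifier(random_state=seed),
        "random forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "support vector": SVC(probability=True, random_state=seed),
        "neural network": MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                                        early_stopping=True, random_state=seed),
    }


def _track_folds(track_ids: np.ndarray, y: np.ndarray, k: int, seed: int
                 ) -> list[np.ndarray]:
    """Partition tracks (not frames) into k folds; redraw if a fold misses
    a class."""
    rng = np.random.default_rng(seed)
    unique = np.unique(track_ids)
    if len(unique) < k:
        raise ValueError(f"need >= {k} tracks for {k}-fold CV")
    for attempt in range(25):
        perm = rng.permutation(unique)
        chunks = np.array_split(perm, k)
        masks = [np.isin(track_ids, ch) for ch in chunks]
        if all(len(np.unique(y[m])) == 2 for m in masks):
            return masks
        warnings.warn("a fold missed a class; re-drawing fold assignment")
    return masks


def cross_validate(X: pd.DataFrame, y: pd.Series, track_ids: np.ndarray,
                   model_grid: dict | None = None,
                   scaling_grid: tuple[str, ...] = SCALING_METHODS,
                   k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Track-wise k-fold CV over (model, scaling) combinations.

    Scaling is fitted per fold on the training rows only.  Returns a table
    with mean train/validation accuracy per combination.
    """
    model_grid = model_grid if model_grid is not None else default_model_grid(seed)
    y_arr = np.asarray(y)
    folds = _track_folds(np.asarray(track_ids), y_arr, k, seed)
    rows = []
    for model_name, model in model_grid.items():
        for scaling in scaling_grid:
            tr_accs, va_accs = [], []
            for val_mask in folds:
                train_mask = ~val_mask
                scaled, _ = fit_apply_scaling(X, train_mask, scaling)
                import sklearn.base
                est = sklearn.base.clone(model)
                est.fit(scaled.loc[train_mask], y_arr[train_mask])
                tr_accs.append(est.score(scaled.loc[train_mask], y_arr[train_mask]))
                va_accs.append(est.score(scaled.loc[val_mask], y_arr[val_mask]))
            rows.append({"model": model_name, "scaling": scaling,
                         "train_accuracy": float(np.mean(tr_accs)),
                         "val_accuracy": float(np.mean(va_accs))})
    return pd.DataFrame(rows)


@dataclass
class TrainedScorer:
    estimator: object
    scaling_params: dict
    feature_names: list[str]
    scaling_method: str

    def _scale(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing columns: {missing}")
        X = X[self.feature_names]
        if self.scaling_method == "none":
            return X
        center = pd.Series(self.scaling_params["center"])
        scale = pd.Series(self.scaling_params["scale"])
        return (X - center) / scale

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(self._scale(X))


def train_scorer(X: pd.DataFrame, y: pd.Series, model: str = "neural network",
                 scaling: str = "min-max", seed: int = 0) -> TrainedScorer:
    """Fit scaler then classifier with a fixed seed; refit with the same
    seed is bit-deterministic."""
    y_arr = np.asarray(y)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("training labels contain a single class")
    bad_cols = X.columns[~np.isfinite(X).all(axis=0)].tolist()
    if bad_cols:
        raise ValueError(f"non-finite features in columns: {bad_cols}")
    scaled, params = fit_apply_scaling(X, np.ones(len(X), dtype=bool), scaling)
    est = default_model_grid(seed)[model]
    est.fit(scaled, y_arr)
    return TrainedScorer(estimator=est, scaling_params=params,
                         feature_names=list(X.columns), scaling_method=scaling)


def score_tracks(scorer: TrainedScorer, features: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-frame class probabilities and argmax labels; frames with invalid
    features are censored."""
    valid = np.isfinite(features[scorer.feature_names]).all(axis=1).to_numpy()
    probs = np.full((len(features), 2), np.nan)
    if valid.any():
        probs[valid] = scorer.predict_proba(features.loc[valid])
    prob_df = pd.DataFrame(probs, index=features.index,
                           columns=["p_recumbent", "p_nictating"])
    labels = pd.Series(CENSORED, index=features.index, dtype=int)
    labels[valid] = np.argmax(probs[valid], axis=1)
    return prob_df, labels


# ---------------------------------------------------------------------------
# denoising

def _per_track_segments(index: pd.MultiIndex, censored: np.ndarray):
    """Yield (row positions) of maximal uncensored runs within each track."""
    tids = index.get_level_values("track_id").to_numpy()
    start = 0
    n = len(tids)
    for i in range(1, n + 1):
        if i == n or tids[i] != tids[start]:
            pos = np.arange(start, i)
            good = ~censored[pos]
            j = 0
            while j < len(pos):
                if not good[j]:
                    j += 1
                    continue
                j0 = j
                while j < len(pos) and good[j]:
                    j += 1
                yield pos[j0:j]
            start = i


def smooth_gaussian(probs: pd.DataFrame, sigma_s: float, fps: float) -> pd.Series:
    """Gaussian-smooth each class probability in time within each track
    (reflective boundaries); label = argmax after smoothing.  sigma 0 is
    the identity.  Censored (NaN) frames split tracks into segments."""
    if sigma_s < 0:
        raise ValueError("sigma must be >= 0")
    sigma_frames = sigma_s * fps
    vals = probs.to_numpy(dtype=float)
    censored = ~np.isfinite(vals).all(axis=1)
    out = vals.copy()
    if sigma_frames > 0:
        for seg in _per_track_segments(probs.index, censored):
            for c in range(vals.shape[1]):
                out[seg, c] = gaussian_filter1d(vals[seg, c], sigma_frames,
                                                mode="reflect")
    labels = pd.Series(CENSORED, index=probs.index, dtype=int)
    ok = ~censored
    labels[ok] = np.argmax(out[ok], axis=1)
    return labels


def _rle(labels: np.ndarray) -> list[list]:
    runs = []
    for v in labels:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def _remove_short_bouts_1d(labels: np.ndarray, min_len: int) -> np.ndarray:
    runs = _rle(labels)
    i = 0
    while i < len(runs):
        lab, ln = runs[i]
        if ln < min_len and len(runs) > 1:
            if i == 0:
                # track-initial short bout merges into the following bout
                runs[1][1] += ln
                del runs[0]
            else:
                runs[i - 1][1] += ln
                del runs[i]
                if i < len(runs) and runs[i][0] == runs[i - 1][0]:
                    runs[i - 1][1] += runs[i][1]
                    del runs[i]
            continue
        i += 1
    return np.concatenate([np.full(ln, lab) for lab, ln in runs]).astype(labels.dtype)


def remove_short_bouts(labels: pd.Series, min_len_frames: int) -> pd.Series:
    """Forward pass merging bouts shorter than ``min_len_frames`` into the
    surrounding bout (track-initial short bouts merge into the following
    one).  A single-bout track is left unchanged.  Censored frames split
    tracks into independent segments."""
    vals = labels.to_numpy().copy()
    censored = vals == CENSORED
    for seg in _per_track_segments(labels.index, censored):
        vals[seg] = _remove_short_bouts_1d(vals[seg], min_len_frames)
    return pd.Series(vals, index=labels.index, dtype=int)


# ---------------------------------------------------------------------------
# Viterbi decoders

def _viterbi_log(log_emit: np.ndarray, spec: HMMSpec) -> np.ndarray:
    """Two-state log-space Viterbi given per-frame log emission scores."""
    pp = max(spec.persistence_probability, PROB_FLOOR)
    pc = max(1.0 - spec.persistence_probability, PROB_FLOOR)
    log_a = np.log([[pp, pc], [pc, pp]])
    pi = np.maximum(np.asarray(spec.initial_probs, dtype=float), PROB_FLOOR)
    n = log_emit.shape[0]
    delta = np.empty((n, 2))
    back = np.zeros((n, 2), dtype=int)
    delta[0] = np.log(pi) + log_emit[0]
    for t in range(1, n):
        trans = delta[t - 1][:, None] + log_a
        back[t] = np.argmax(trans, axis=0)
        delta[t] = trans[back[t], [0, 1]] + log_emit[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi_path_loglik(path: np.ndarray, log_emit: np.ndarray, spec: HMMSpec) -> float:
    """Log-likelihood of a given state path (for oracle comparisons)."""
    pp = max(spec.persistence_probability, PROB_FLOOR)
    pc = max(1.0 - spec.persistence_probability, PROB_FLOOR)
    log_a = np.log([[pp, pc], [pc, pp]])
    pi = np.maximum(np.asarray(spec.initial_probs, dtype=float), PROB_FLOOR)
    ll = np.log(pi[path[0]]) + log_emit[0, path[0]]
    for t in range(1, len(path)):
        ll += log_a[path[t - 1], path[t]] + log_emit[t, path[t]]
    return float(ll)


def state_emission_logprobs(obs: np.ndarray, spec: HMMSpec) -> np.ndarray:
    """(n, 2) log emission matrix for the state-based variant: P(obs == s
    | state s) = a, else 1 - a."""
    a = spec.emission_accuracy
    le = np.empty((len(obs), 2))
    for s in (0, 1):
        le[:, s] = np.where(obs == s, np.log(a), np.log(1.0 - a))
    return le


def viterbi_state_based(labels: pd.Series, spec: HMMSpec) -> pd.Series:
    """Decode raw binary scores as noisy observations of the two-state HMM."""
    spec.validate()
    vals = labels.to_numpy().copy()
    censored = vals == CENSORED
    out = vals.copy()
    for seg in _per_track_segments(labels.index, censored):
        le = state_emission_logprobs(vals[seg], spec)
        out[seg] = _viterbi_log(le, spec)
    return pd.Series(out, index=labels.index, dtype=int)


def viterbi_probability_based(probs: pd.DataFrame, spec: HMMSpec) -> pd.Series:
    """Modified Viterbi using the classifier probabilities directly as
    emissions: delta_t(s) = p_t(s) * max_s' delta_{t-1}(s') A(s', s)."""
    spec.validate()
    vals = probs.to_numpy(dtype=float)
    censored = ~np.isfinite(vals).all(axis=1)
    out = np.full(len(vals), CENSORED, dtype=int)
    for seg in _per_track_segments(probs.index, censored):
        le = np.log(np.maximum(vals[seg], PROB_FLOOR))
        out[seg] = _viterbi_log(le, spec)
    return pd.Series(out, index=probs.index, dtype=int)


# ---------------------------------------------------------------------------
# smoothing-parameter optimization

def apply_denoiser(method: str, probs: pd.DataFrame, raw_labels: pd.Series,
                   param: float, fps: float,
                   initial_probs: tuple[float, float] = (0.5, 0.5),
                   emission_accuracy: float = 0.95) -> pd.Series:
    if method == "gaussian":
        return smooth_gaussian(probs, param, fps)
    if method == "bout":
        return remove_short_bouts(raw_labels, int(param))
    if method == "viterbi_state":
        return viterbi_state_based(raw_labels, HMMSpec(param, emission_accuracy,
                                                       initial_probs))
    if method == "viterbi_prob":
        return viterbi_probability_based(probs, HMMSpec(param, emission_accuracy,
                                                        initial_probs))
    raise ValueError(f"unknown denoiser {method!r}")


def optimize_smoothing(fold_outputs: list[tuple[pd.DataFrame, pd.Series, pd.Series]],
                       param_grid: np.ndarray, fps: float,
                       method: str = "gaussian", **denoiser_kwargs
                       ) -> tuple[float, pd.DataFrame]:
    """Pick the denoiser parameter minimizing the combined objective.

    ``fold_outputs``: per CV fold, (validation probabilities, raw validation
    labels, manual labels).  Objective per parameter = |relerr NR| +
    |relerr IR| + |relerr SR| + (1 - accuracy), averaged over folds; terms
    undefined in the truth (no transitions) are skipped with a warning.
    Returns (best parameter, curve table aligned with the grid).
    """
    from .metrics import agreement, nictation_metrics, relative_error

    rows = []
    for param in np.atleast_1d(param_grid):
        objs = []
        for probs, raw, manual in fold_outputs:
            denoised = apply_denoiser(method, probs, raw, float(param), fps,
                                      **denoiser_kwargs)
            truth = nictation_metrics(manual, fps)
            est = nictation_metrics(denoised, fps)
            obj = 0.0
            for attr in ("nr", "ir", "sr"):
                tv, mv = getattr(truth, attr), getattr(est, attr)
                if tv is None or tv == 0 or mv is None:
                    warnings.warn(f"{attr.upper()} undefined in truth; term skipped")
                    continue
                obj += abs(relative_error(mv, tv))
            acc, _ = agreement(denoised, manual)
            obj += 1.0 - acc
            objs.append(obj)
        rows.append({"param": float(param), "objective": float(np.mean(objs))})
    curve = pd.DataFrame(rows)
    best = float(curve.loc[curve["objective"].idxmin(), "param"])
    return best, curve
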