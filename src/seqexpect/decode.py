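"""Linear population decoding with repeated random splits.

Three designs share one engine (a linear support-vector classifier,
one-vs-rest, C = 1, behind per-cell standardization fit on the training
fold only):

* **stimulus** — 15-way identity: 12 element-in-sequence conditions plus
  the three per-sequence gray periods, half/half split per class, chance
  1/15 = 6.7 %;
* **block** — 5-way block identity within one element condition, training
  on 50 random trials per block and testing on the remaining 250, pooled
  over the 12 element conditions, chance 1/5;
* **time** — 24-way gray-period frame identity at 30 Hz, splitting by gray
  period (never by frame, which would leak trial structure), chance
  1/24 = 4.2 %.

Reports carry the row-normalized mean confusion matrix, per-iteration
accuracies and the analytic chance level.  Label shuffling (per iteration)
gives the empirical null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .align import extract_trials, time_average
from .schedule import event_frame_bounds, select_events
from .simulate import ActivityMatrix


@dataclass
class DecoderReport:
    """Outcome of one decoding design."""

    confusion: np.ndarray          # K x K, rows true, row-normalized mean
    accuracies: np.ndarray         # per iteration
    classes: np.ndarray
    chance: float
    n_iterations: int
    n_test_trials: int = 0         # test-set size (per condition for block)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def _make_classifier():
    return make_pipeline(StandardScaler(),
                         LinearSVC(C=1.0, max_iter=2000))


def _fit_score(X_train, y_train, X_test, y_test, classes) -> tuple[float, np.ndarray]:
    clf = _make_classifier()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_train, y_train)
    pred = clf.predict(X_test)
    acc = float(np.mean(pred == y_test))
    cm = confusion_matrix(y_test, pred, labels=classes).astype(float)
    rows = cm.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return acc, cm / rows


def decode_stimulus(X: np.ndarray, y: np.ndarray, n_iterations: int = 100,
                    rng: np.random.Generator | None = None,
                    shuffle_labels: bool = False) -> DecoderReport:
    """K-way decoding with per-class half/half train/test splits.

    Each iteration splits every class's trials in half at random, trains the
    linear classifier and accumulates accuracy and the row-normalized
    confusion matrix.  With ``shuffle_labels`` the labels are randomly
    permuted each iteration before splitting (empirical chance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 trials")
    if rng is None:
        rng = np.random.default_rng()

    accs = np.empty(n_iterations)
    cm_sum = np.zeros((len(classes), len(classes)))
    for it in range(n_iterations):
        y_it = y[rng.permutation(len(y))] if shuffle_labels else y
        train_idx, test_idx = [], []
        for c in classes:
            idx = np.flatnonzero(y_it == c)
            idx = idx[rng.permutation(len(idx))]
            half = len(idx) // 2
            train_idx.append(idx[:half])
            test_idx.append(idx[half:])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        accs[it], cm = _fit_score(X[tr], y_it[tr], X[te], y_it[te], classes)
        cm_sum += cm
        n_test = len(te)
    return DecoderReport(confusion=cm_sum / n_iterations, accuracies=accs,
                         classes=classes, chance=1.0 / len(classes),
                         n_iterations=n_iterations, n_test_trials=n_test)


def decode_block(responses_by_condition, n_iterations: int = 100,
                 train_per_block: int = 50,
                 rng: np.random.Generator | None = None,
                 normalize: bool = False,
                 shuffle_labels: bool = False) -> DecoderReport:
    """Block-identity decoding pooled over element conditions.

    Parameters
    ----------
    responses_by_condition
        Iterable of ``(X, blocks)`` pairs, one per element condition:
        trials x cells responses and the per-trial block index.
    train_per_block
        Trials per block used for training; the rest form the test set.
    normalize
        Scale each trial vector to unit length first (the drift control:
        a pure global-gain drift is removed by normalization).
    """
    conditions = [(np.asarray(X, dtype=float), np.asarray(b))
                  for X, b in responses_by_condition]
    if not conditions:
        raise ValueError("no conditions given")
    classes = np.unique(np.concatenate([b for _, b in conditions]))
    if len(classes) < 2:
        raise ValueError("need at least 2 blocks")
    if rng is None:
        rng = np.random.default_rng()

    accs = np.empty(n_iterations)
    cm_sum = np.zeros((len(classes), len(classes)))
    for it in range(n_iterations):
        correct = total = 0
        cm_it = np.zeros_like(cm_sum)
        for X, blocks in conditions:
            if normalize:
                norms = np.linalg.norm(X, axis=1, keepdims=True)
                X = X / np.where(norms > 0, norms, 1.0)
            b_it = blocks[rng.permutation(len(blocks))] if shuffle_labels else blocks
            train_idx, test_idx = [], []
            for c in classes:
                idx = np.flatnonzero(b_it == c)
                if len(idx) <= train_per_block:
                    raise ValueError(
                        f"block {c} has {len(idx)} trials; need more than "
                        f"train_per_block={train_per_block}")
                idx = idx[rng.permutation(len(idx))]
                train_idx.append(idx[:train_per_block])
                test_idx.append(idx[train_per_block:])
            tr = np.concatenate(train_idx)
            te = np.concatenate(test_idx)
            acc, cm = _fit_score(X[tr], b_it[tr], X[te], b_it[te], classes)
            correct += acc * len(te)
            total += len(te)
            cm_it += cm
            n_test = len(te)
        accs[it] = correct / total
        cm_sum += cm_it / len(conditions)
    return DecoderReport(confusion=cm_sum / n_iterations, accuracies=accs,
                         classes=classes, chance=1.0 / len(classes),
                         n_iterations=n_iterations, n_test_trials=n_test)


def decode_time(frame_vectors: np.ndarray, n_iterations: int = 100,
                rng: np.random.Generator | None = None,
                shuffle_labels: bool = False) -> tuple[DecoderReport, np.ndarray]:
    """Time-bin decoding from per-frame population vectors.

    Parameters
    ----------
    frame_vectors
        Periods x frames x cells array (one population vector per frame of
        each gray period or sequence window).

    Returns
    -------
    (report, per_bin_accuracy)
        ``per_bin_accuracy`` is the diagonal of the mean confusion matrix
        (accuracy at each time bin).
    """
    G = np.asarray(frame_vectors, dtype=float)
    if G.ndim != 3:
        raise ValueError("frame_vectors must be periods x frames x cells")
    n_periods, n_bins, n_cells = G.shape
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    if n_periods < 2:
        raise ValueError("need at least 2 periods to split")
    if rng is None:
        rng = np.random.default_rng()
    classes = np.arange(n_bins)

    accs = np.empty(n_iterations)
    cm_sum = np.zeros((n_bins, n_bins))
    for it in range(n_iterations):
        perm = rng.permutation(n_periods)
        half = n_periods // 2
        tr_p, te_p = perm[:half], perm[half:]
        y_tr = np.tile(classes, len(tr_p))
        y_te = np.tile(classes, len(te_p))
        if shuffle_labels:
            y_tr = y_tr[rng.permutation(len(y_tr))]
            y_te = y_te[rng.permutation(len(y_te))]
        X_tr = G[tr_p].reshape(-1, n_cells)
        X_te = G[te_p].reshape(-1, n_cells)
        accs[it], cm = _fit_score(X_tr, y_tr, X_te, y_te, classes)
        cm_sum += cm
    confusion = cm_sum / n_iterations
    report = DecoderReport(confusion=confusion, accuracies=accs,
                           classes=classes, chance=1.0 / n_bins,
                           n_iterations=n_iterations)
    return report, np.diag(confusion)


# ---------------------------------------------------------------------------
# feature builders

def stimulus_condition_responses(activity: ActivityMatrix, events: pd.DataFrame,
                                 offset_frames: int = 2
                                 ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Time-averaged responses and 15-way labels for stimulus decoding.

    Classes are the 12 element-in-sequence conditions (``"ABCD:2"`` ...) and
    the per-sequence gray periods (``"ABCD:gray"`` ...), with the first
    ``offset_frames`` frames excluded from each average.

    Returns ``(X, y, labels)`` with trials stacked across conditions.
    """
    Xs, ys, lab = [], [], []
    elems = events[events["kind"] == "element"]
    for (seq, pos), grp in elems.groupby(["sequence", "position"]):
        tensor = extract_trials(activity, grp, offset_frames=offset_frames,
                                mode="truncate")
        resp = time_average(tensor)
        Xs.append(resp.values)
        ys.append(np.full(resp.n_trials, f"{seq}:{pos}"))
        lab.append(resp.labels)
    grays = events[events["kind"] == "gray"]
    for seq, grp in grays.groupby("sequence"):
        tensor = extract_trials(activity, grp, offset_frames=offset_frames,
                                mode="truncate")
        resp = time_average(tensor)
        Xs.append(resp.values)
        ys.append(np.full(resp.n_trials, f"{seq}:gray"))
        lab.append(resp.labels)
    return (np.concatenate(Xs), np.concatenate(ys),
            pd.concat(lab, ignore_index=True))


def block_condition_responses(activity: ActivityMatrix, events: pd.DataFrame,
                              offset_frames: int = 2):
    """Per element condition ``(X, blocks)`` pairs for block decoding."""
    out = []
    elems = events[events["kind"] == "element"]
    for (seq, pos), grp in elems.groupby(["sequence", "position"]):
        tensor = extract_trials(activity, grp, offset_frames=offset_frames,
                                mode="truncate")
        resp = time_average(tensor)
        out.append((resp.values, resp.labels["block"].to_numpy()))
    return out


def gray_frame_vectors(activity: ActivityMatrix, events: pd.DataFrame,
                       sequence: str | None = None) -> np.ndarray:
    """Periods x frames x cells population vectors of gray periods."""
    grays = select_events(events, kind="gray", sequence=sequence)
    tensor = extract_trials(activity, grays, offset_frames=0, mode="shift")
    return np.transpose(tensor.values, (1, 2, 0))


def sequence_frame_vectors(activity: ActivityMatrix, events: pd.DataFrame,
                           sequence: str) -> np.ndarray:
    """Per-frame vectors over whole sequence presentations (for time decoding
    within the stimulation period)."""
    elems = select_events(events, kind="element", sequence=sequence)
    spans = elems.groupby("trial").agg(onset_ms=("onset_ms", "min"),
                                       offset_ms=("offset_ms", "max")).reset_index()
    tensor = extract_trials(activity, spans, offset_frames=0, mode="shift")
    return np.transpose(tensor.values, (1, 2, 0))
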