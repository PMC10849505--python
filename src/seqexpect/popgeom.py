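"""Population geometry: PCA untangling, decorrelation, representational drift.

* :func:`pca_untangle` concatenates the three sequence-averaged population
  traces along time into a time-by-cell matrix, centers per cell, and
  decomposes; component scores are re-split per sequence so one shared set
  of components can be inspected sequence by sequence.
* :func:`element_correlations` computes, for every presentation, Pearson
  correlations between the time-averaged population vectors of all six
  unordered element pairs (first two frames after each onset excluded) —
  500 presentations x 6 pairs = 3000 coefficients per sequence per day.
* :func:`drift_curve` correlates all pairs of single-trial population
  vectors for one condition and groups coefficients by trial distance;
  multiplicative drift shows as a monotone decline with distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .align import extract_trials, time_average
from .schedule import select_events
from .simulate import ActivityMatrix


@dataclass
class PCADecomposition:
    """Shared principal components with per-sequence time courses."""

    scores: dict[str, np.ndarray]         # sequence -> time x components
    explained_variance_ratio: np.ndarray
    n_components_90: int
    var_threshold: float


@dataclass
class DriftCurve:
    """Mean pairwise correlation per trial-distance bin."""

    table: pd.DataFrame                    # bin_left, bin_right, mean_r, n_pairs
    bin_width: int


def pca_untangle(traces: dict[str, np.ndarray],
                 var_threshold: float = 0.9) -> PCADecomposition:
    """Decompose trial-averaged traces concatenated across sequences.

    Parameters
    ----------
    traces
        Mapping sequence -> (cells x time) trial-averaged traces over a
        common cell set.
    var_threshold
        Report the number of components needed to reach this cumulative
        explained-variance fraction.
    """
    seqs = list(traces)
    if not seqs:
        raise ValueError("no traces given")
    n_cells = traces[seqs[0]].shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    lengths = []
    blocks = []
    for s in seqs:
        tr = np.asarray(traces[s], dtype=float)
        if tr.shape[0] != n_cells:
            raise ValueError("all sequences must share the cell set")
        blocks.append(tr.T)               # time x cells
        lengths.append(tr.shape[1])
    X = np.concatenate(blocks, axis=0)    # (sum time) x cells

    pca = PCA()                            # centers per cell (column)
    scores_all = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n90 = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)

    scores = {}
    start = 0
    for s, L in zip(seqs, lengths):
        scores[s] = scores_all[start:start + L]
        start += L
    return PCADecomposition(scores=scores, explained_variance_ratio=evr,
                            n_components_90=n90, var_threshold=var_threshold)


def sequence_traces(activity: ActivityMatrix, events: pd.DataFrame,
                    sequences=("ABCD", "ABBD", "ACBD")) -> dict[str, np.ndarray]:
    """Trial-averaged full-presentation traces (elements + gray) per sequence."""
    traces = {}
    for seq in sequences:
        elems = select_events(events, kind="element", sequence=seq)
        spans = elems.groupby("trial").agg(onset_ms=("onset_ms", "min"),
                                           offset_ms=("offset_ms", "max"))
        spans = spans.reset_index()
        spans["kind"] = "span"
        tensor = extract_trials(activity, spans.assign(position=0), offset_frames=0)
        traces[seq] = tensor.values.mean(axis=1)
    return traces


def element_correlations(activity: ActivityMatrix, events: pd.DataFrame,
                         sequence: str, offset_frames: int = 2,
                         day: str = "") -> pd.DataFrame:
    """Pearson r between element-pair population vectors per presentation.

    Returns a tidy frame with columns ``trial``, ``pair`` (e.g. ``"1-3"``),
    ``r`` and attrs ``n_dropped`` (zero-variance vectors) and ``day``.
    """
    positions = sorted(select_events(events, kind="element",
                                     sequence=sequence)["position"].unique())
    vectors = {}
    trials = None
    for pos in positions:
        sel = select_events(events, kind="element", sequence=sequence,
                            position=pos)
        tensor = extract_trials(activity, sel, offset_frames=offset_frames,
                                mode="truncate")
        resp = time_average(tensor)        # trials x cells
        vectors[pos] = resp.values
        t = resp.labels["trial"].to_numpy()
        if trials is None:
            trials = t
        elif not np.array_equal(trials, t):
            raise ValueError("positions disagree on trial ordering")

    rows = []
    n_dropped = 0
    centered = {p: v - v.mean(axis=1, keepdims=True) for p, v in vectors.items()}
    norms = {p: np.linalg.norm(c, axis=1) for p, c in centered.items()}
    for p1, p2 in combinations(positions, 2):
        c1, c2 = centered[p1], centered[p2]
        denom = norms[p1] * norms[p2]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", c1, c2) / denom
        ok = denom > 0
        n_dropped += int((~ok).sum())
        for t, rv in zip(trials[ok], r[ok]):
            rows.append((int(t), f"{p1}-{p2}", float(rv)))
    out = pd.DataFrame(rows, columns=["trial", "pair", "r"])
    out.attrs["n_dropped"] = n_dropped
    out.attrs["day"] = day
    out.attrs["sequence"] = sequence
    return out


def drift_curve(vectors: np.ndarray, bin_width: int = 50,
                trial_positions: np.ndarray | None = None) -> DriftCurve:
    """Pairwise-correlation decline with trial distance for one condition.

    Parameters
    ----------
    vectors
        Trials x cells response matrix (session-time order).
    bin_width
        Trial-distance bin width.
    trial_positions
        Optional per-trial session positions (defaults to 0..n-1); distance
        is computed on these, so interleaved-block designs can pass true
        trial indices.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 trials")
    pos = (np.arange(n) if trial_positions is None
           else np.asarray(trial_positions))

    sd = X.std(axis=1)
    valid = sd > 0
    C = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        C[np.ix_(valid, valid)] = np.corrcoef(X[valid])
    iu, ju = np.triu_indices(n, k=1)
    dist = np.abs(pos[iu] - pos[ju])
    r = C[iu, ju]
    ok = np.isfinite(r)
    dist, r = dist[ok], r[ok]

    max_d = int(dist.max()) if len(dist) else 1
    edges = np.arange(1, max_d + bin_width + 1, bin_width)
    rows = []
    for left in edges[:-1] if len(edges) > 1 else [1]:
        right = left + bin_width
        sel = (dist >= left) & (dist < right)
        if sel.any():
            rows.append((int(left), int(right), float(r[sel].mean()),
                         int(sel.sum())))
    return DriftCurve(table=pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "mean_r", "n_pairs"]),
        bin_width=bin_width)
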