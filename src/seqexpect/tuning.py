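"""Stimulus/context selectivity classification and sparseness measures.

Three per-cell screens are implemented:

* **selectivity** — a cell is labeled with stimulus *s* when its trial- and
  time-averaged response to *s* exceeds the mean of the other stimulus
  responses by ``k_sd`` standard deviations of those other responses;
  applied once context-free (stimuli A, B, C, D, gray) and once per
  element-in-sequence condition;
* **stimulus-driven** — response to some stimulus exceeds the cell's
  session-wide mean rate by ``k_sd`` session-wide SDs (first sparseness
  measure);
* **visually modulated** — a two-sample KS test distinguishes time-averaged
  266 ms chunks of grating periods from gray periods (second, more
  permissive measure).  Consecutive chunks are separated by a 133 ms gap to
  reduce serial correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .align import extract_trials, time_average
from .schedule import event_frame_bounds, select_events
from .simulate import ActivityMatrix

CONTEXT_FREE_STIMULI = ("A", "B", "C", "D", "gray")


def _mean_response(activity: ActivityMatrix, events: pd.DataFrame,
                   offset_frames: int, mode: str) -> np.ndarray:
    tensor = extract_trials(activity, events, offset_frames=offset_frames, mode=mode)
    return time_average(tensor).values.mean(axis=0)


def stimulus_means(activity: ActivityMatrix, events: pd.DataFrame,
                   offset_frames: int = 2, mode: str = "shift") -> pd.DataFrame:
    """Trial- and time-averaged response per context-free stimulus.

    Columns A-D pool every element event of that letter across sequences and
    positions; ``gray`` pools the full intersequence gray periods.
    """
    cols = {}
    for letter in "ABCD":
        sel = events[(events["kind"] == "element") & (events["element"] == letter)]
        if len(sel):
            cols[letter] = _mean_response(activity, sel, offset_frames, mode)
    grays = events[events["kind"] == "gray"]
    if len(grays):
        cols["gray"] = _mean_response(activity, grays, offset_frames, mode)
    return pd.DataFrame(cols)


def stimulus_trial_sds(activity: ActivityMatrix, events: pd.DataFrame,
                       offset_frames: int = 2, mode: str = "shift") -> pd.DataFrame:
    """Trial-to-trial SD of time-averaged responses per context-free stimulus."""
    cols = {}
    for letter in "ABCD":
        sel = events[(events["kind"] == "element") & (events["element"] == letter)]
        if len(sel):
            tensor = extract_trials(activity, sel, offset_frames=offset_frames,
                                    mode=mode)
            cols[letter] = time_average(tensor).values.std(axis=0, ddof=1)
    grays = events[events["kind"] == "gray"]
    if len(grays):
        tensor = extract_trials(activity, grays, offset_frames=offset_frames,
                                mode=mode)
        cols["gray"] = time_average(tensor).values.std(axis=0, ddof=1)
    return pd.DataFrame(cols)


def context_means(activity: ActivityMatrix, events: pd.DataFrame,
                  offset_frames: int = 2, mode: str = "shift") -> pd.DataFrame:
    """Per element-in-sequence condition means (e.g. column ``"ABCD:2"``)."""
    cols = {}
    elems = events[events["kind"] == "element"]
    for (seq, pos), grp in elems.groupby(["sequence", "position"]):
        cols[f"{seq}:{pos}"] = _mean_response(activity, grp, offset_frames, mode)
    return pd.DataFrame(cols)


def classify_selectivity(means: pd.DataFrame, k_sd: float = 2.0,
                         trial_sd: pd.DataFrame | None = None) -> pd.Series:
    """Assign at most one selectivity label per cell.

    Default rule: a cell is labeled with column *s* iff
    ``mean_s > mean(others) + k_sd * SD(others)`` where *others* are the
    remaining column means.  The "two SDs higher than any other stimulus"
    phrasing admits a second reading; passing ``trial_sd`` (per-stimulus
    trial-to-trial SDs, same shape as ``means``) switches to the stricter
    variant ``mean_s > max_o(mean_o + k_sd * sd_o)``.  Cells where no (or
    more than one) stimulus passes are labeled ``"none"`` — ties are
    resolved conservatively rather than curated.

    Raises
    ------
    ValueError
        With fewer than three stimuli the SD over "others" is undefined.
    """
    if means.shape[1] < 3:
        raise ValueError("need >= 3 stimulus columns to define the other-SD")
    X = means.to_numpy(dtype=float)
    n = X.shape[1]
    labels = np.full(X.shape[0], "none", dtype=object)
    passing = np.zeros(X.shape, dtype=bool)
    if trial_sd is not None:
        S = trial_sd[means.columns].to_numpy(dtype=float)
        for j in range(n):
            bar = np.delete(X + k_sd * S, j, axis=1).max(axis=1)
            passing[:, j] = X[:, j] > bar
    else:
        for j in range(n):
            others = np.delete(X, j, axis=1)
            mu = others.mean(axis=1)
            sd = others.std(axis=1, ddof=1)
            passing[:, j] = X[:, j] > mu + k_sd * sd
    n_pass = passing.sum(axis=1)
    winners = passing.argmax(axis=1)
    single = n_pass == 1
    labels[single] = means.columns.to_numpy()[winners[single]]
    return pd.Series(labels, index=means.index, name="label")


def overall_rate_stats(activity: ActivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean and SD of activity across all time bins."""
    return activity.values.mean(axis=1), activity.values.std(axis=1, ddof=0)


def stimulus_driven_flags(means: pd.DataFrame, overall_mean: np.ndarray,
                          overall_sd: np.ndarray, k_sd: float = 2.0) -> pd.DataFrame:
    """Flag responses exceeding ``overall_mean + k_sd * overall_sd``.

    Zero-variance cells fall back to ``response > overall_mean``; fully
    silent cells get no flags.  The first sparseness measure is the fraction
    of cells with at least one flag (``flags.any(axis=1).mean()``).
    """
    mu = np.asarray(overall_mean, dtype=float)[:, None]
    sd = np.asarray(overall_sd, dtype=float)[:, None]
    thresh = np.where(sd > 0, mu + k_sd * sd, mu)
    X = means.to_numpy(dtype=float)
    # sd == 0 falls back to response > mean; silent cells (mean 0) need
    # response > 0, which the same comparison gives
    flags = X > thresh
    return pd.DataFrame(flags, index=means.index, columns=means.columns)


def _tile_chunks(first: np.ndarray, last: np.ndarray, chunk: int, gap: int) -> np.ndarray:
    """Start frames of non-overlapping chunks tiled within [first, last) spans."""
    starts = []
    for f, l in zip(first, last):
        s = f
        while s + chunk <= l:
            starts.append(s)
            s += chunk + gap
    return np.asarray(starts, dtype=int)


def visual_modulation(activity: ActivityMatrix, events: pd.DataFrame,
                      chunk_ms: float = 266.0, gap_ms: float = 133.0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """KS-test gray vs grating chunk-mean distributions per cell.

    Returns a frame with ``pvalue`` and ``modulated`` (p < alpha) per cell,
    plus the chunk counts used.
    """
    fr = activity.frame_rate
    chunk = int(round(chunk_ms * fr / 1000.0))
    gap = int(round(gap_ms * fr / 1000.0))
    if chunk < 1:
        raise ValueError("chunk shorter than one frame")

    elems = events[events["kind"] == "element"]
    # one grating span per presentation: first element onset to last offset
    spans = elems.groupby("presentation").agg(
        onset_ms=("onset_ms", "min"), offset_ms=("offset_ms", "max"))
    gfirst, glast = event_frame_bounds(spans.reset_index(), fr)
    grays = select_events(events, kind="gray")
    yfirst, ylast = event_frame_bounds(grays, fr)

    grating_starts = _tile_chunks(gfirst, glast, chunk, gap)
    gray_starts = _tile_chunks(yfirst, ylast, chunk, gap)
    if len(grating_starts) < 2 or len(gray_starts) < 2:
        raise ValueError("insufficient chunks for the KS test")

    def chunk_means(starts: np.ndarray) -> np.ndarray:
        idx = starts[:, None] + np.arange(chunk)
        return activity.values[:, idx].mean(axis=2)   # cells x chunks

    grating = chunk_means(grating_starts)
    gray = chunk_means(gray_starts)
    pvals = np.empty(activity.n_cells)
    for i in range(activity.n_cells):
        pvals[i] = stats.ks_2samp(grating[i], gray[i]).pvalue
    return pd.DataFrame({
        "pvalue": pvals,
        "modulated": pvals < alpha,
        "n_grating_chunks": len(grating_starts),
        "n_gray_chunks": len(gray_starts),
    })


def build_selectivity(activity: ActivityMatrix, events: pd.DataFrame,
                      k_sd: float = 2.0, offset_frames: int = 2,
                      sd_mode: str = "across_means") -> pd.DataFrame:
    """Full per-cell selectivity table (context-free + context labels).

    ``sd_mode="across_means"`` uses the SD over the other stimulus means
    (default); ``"across_trials"`` uses per-stimulus trial SDs, the stricter
    reading of the two-SD rule.
    """
    free = stimulus_means(activity, events, offset_frames=offset_frames)
    ctx = context_means(activity, events, offset_frames=offset_frames)
    trial_sd = None
    if sd_mode == "across_trials":
        trial_sd = stimulus_trial_sds(activity, events, offset_frames=offset_frames)
    elif sd_mode != "across_means":
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    table = pd.DataFrame({
        "label": classify_selectivity(free, k_sd=k_sd, trial_sd=trial_sd),
        "context_label": classify_selectivity(ctx, k_sd=k_sd),
    })
    mu, sd = overall_rate_stats(activity)
    flags = stimulus_driven_flags(free, mu, sd, k_sd=k_sd)
    for col in flags.columns:
        table[f"driven_{col}"] = flags[col]
    table["stimulus_driven"] = flags.any(axis=1)
    return table


def selectivity_summary(labels: pd.Series) -> pd.DataFrame:
    """Counts and percentages per label (the selectivity-table summary)."""
    counts = labels.value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100.0 * out["count"] / len(labels)
    return out
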