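"""Trial alignment: cut activity into event-locked windows and average.

Two window conventions coexist in the analyses and both are provided here:

* ``mode="shift"`` — the response-latency offset *shifts* the window by
  ``offset_frames`` without shrinking it (selectivity windows stay 250 ms
  for gratings / 800 ms for gray);
* ``mode="truncate"`` — the first ``offset_frames`` frames are *dropped*
  (the prediction-error and correlation stages exclude the first ~67 ms).

Because 250 ms elements do not divide the 33.3 ms frame period, element
windows alternate between 7 and 8 frames; a trial tensor uses the minimum
window length across its events so all trials align without padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import event_frame_bounds
from .simulate import ActivityMatrix


@dataclass
class TrialTensor:
    """Aligned activity windows, cells x trials x window-frames."""

    values: np.ndarray
    events: pd.DataFrame       # one row per trial, session-time order
    offset_frames: int
    mode: str
    frame_rate: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_window_frames(self) -> int:
        return self.values.shape[2]


@dataclass
class ResponseMatrix:
    """Time-averaged responses, trials x cells, with per-trial labels."""

    values: np.ndarray
    labels: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def extract_trials(activity: ActivityMatrix, events: pd.DataFrame,
                   offset_frames: int = 0, mode: str = "shift") -> TrialTensor:
    """Cut an activity matrix into one aligned window per event.

    Parameters
    ----------
    activity
        Session activity (cells x frames).
    events
        Pre-filtered event rows (one kind/condition; see
        :func:`~seqexpect.schedule.select_events`).
    offset_frames
        Response-latency offset in acquisition frames (nominally 2).
    mode
        ``"shift"`` moves the window start without shrinking it;
        ``"truncate"`` drops the leading frames instead.

    Returns
    -------
    TrialTensor
        Windows of the common (minimum) length, trials ordered by onset.
    """
    if len(events) == 0:
        raise ValueError("no events selected")
    if mode not in ("shift", "truncate"):
        raise ValueError(f"unknown mode {mode!r}")
    if offset_frames < 0:
        raise ValueError("offset_frames must be >= 0")

    ev = events.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    first, last = event_frame_bounds(ev, activity.frame_rate)
    base_len = int((last - first).min())
    length = base_len if mode == "shift" else base_len - offset_frames
    if length <= 0:
        raise ValueError(
            f"windows empty after truncating {offset_frames} of {base_len} frames")
    start = first + offset_frames
    if start.min() < 0 or (start + length).max() > activity.n_frames:
        raise ValueError("event windows fall outside the session frame range")

    idx = start[:, None] + np.arange(length)       # trials x frames
    values = activity.values[:, idx]               # cells x trials x frames
    return TrialTensor(values=np.ascontiguousarray(values, dtype=float),
                       events=ev, offset_frames=offset_frames, mode=mode,
                       frame_rate=activity.frame_rate)


def time_average(tensor: TrialTensor) -> ResponseMatrix:
    """Mean over window frames per (cell, trial) -> trials x cells."""
    if tensor.values.size == 0:
        raise ValueError("empty tensor")
    vals = tensor.values.mean(axis=2).T
    return ResponseMatrix(values=vals, labels=tensor.events.copy())


def _trial_subset_indices(n_trials: int, trials) -> np.ndarray:
    if trials is None:
        return np.arange(n_trials)
    if isinstance(trials, str):
        if trials == "even":       # 2nd, 4th, ... (0-based odd indices)
            return np.arange(1, n_trials, 2)
        if trials == "odd":        # 1st, 3rd, ... (0-based even indices)
            return np.arange(0, n_trials, 2)
        if trials == "first100":
            return np.arange(min(100, n_trials))
        raise ValueError(f"unknown trial subset {trials!r}")
    idx = np.asarray(trials, dtype=int)
    return idx


def trial_average(tensor: TrialTensor, trials=None) -> np.ndarray:
    """Mean trace over a trial subset -> cells x window-frames.

    ``trials`` may be ``None`` (all), ``"odd"``/``"even"`` (1st/2nd of each
    within-condition pair, i.e. 1-based odd/even trial order), ``"first100"``
    or an index array.
    """
    idx = _trial_subset_indices(tensor.n_trials, trials)
    if idx.size == 0:
        raise ValueError("empty trial subset")
    return tensor.values[:, idx, :].mean(axis=1)
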