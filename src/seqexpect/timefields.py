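"""Time-field estimation via even/odd split consistency screening.

Trials are split into odd and even groups (1st, 3rd, ... vs 2nd, 4th, ...
by within-condition order) and averaged.  A cell whose two half-average
traces peak within ``tolerance_frames`` (nominally 4 frames = 133 ms) of
each other has a temporally consistent firing pattern; consistent cells are
assigned a time field from the all-trial average and enter the peak-latency
histogram.  Ties in the peak search break to the earliest frame, and
all-zero traces are inconsistent by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import TrialTensor, trial_average


@dataclass
class TimeFieldMap:
    """Per-cell peak frames and consistency flags for one window."""

    table: pd.DataFrame        # peak_even, peak_odd, consistent, peak
    tolerance_frames: int
    n_window_frames: int

    @property
    def n_consistent(self) -> int:
        return int(self.table["consistent"].sum())


def _peaks(traces: np.ndarray) -> np.ndarray:
    # argmax returns the first (earliest) maximum on ties
    return traces.argmax(axis=1)


def estimate_time_fields(tensor: TrialTensor,
                         tolerance_frames: int = 4) -> TimeFieldMap:
    """Screen cells for consistent peak timing and assign time fields."""
    if tensor.n_trials < 2:
        raise ValueError("need >= 2 trials for the even/odd split")
    even = trial_average(tensor, "even")
    odd = trial_average(tensor, "odd")
    full = trial_average(tensor, None)

    peak_even = _peaks(even)
    peak_odd = _peaks(odd)
    peak = _peaks(full)
    flat = (full.max(axis=1) == 0) | (even.max(axis=1) == 0) | (odd.max(axis=1) == 0)
    consistent = (np.abs(peak_even - peak_odd) <= tolerance_frames) & ~flat

    table = pd.DataFrame({
        "peak_even": peak_even,
        "peak_odd": peak_odd,
        "consistent": consistent,
        "peak": peak,
    })
    return TimeFieldMap(table=table, tolerance_frames=tolerance_frames,
                        n_window_frames=tensor.n_window_frames)


def null_consistency_probability(n_frames: int, tolerance_frames: int) -> float:
    """Exact P(consistent) when both half-peaks are independent uniform.

    Enumerates frame pairs within tolerance out of ``n_frames**2``; for a
    24-frame window at tolerance 4 this is 196/576 ~ 0.34, the chance floor
    against which observed consistency fractions are judged.
    """
    count = sum(1 for i in range(n_frames) for j in range(n_frames)
                if abs(i - j) <= tolerance_frames)
    return count / n_frames**2


def element_onset_frames(n_window_frames: int, frame_rate: float = 30.0,
                         element_duration_ms: int = 250) -> list[int]:
    """Window-relative frames at which element onsets fall (peak-histogram
    bookkeeping for sequence windows)."""
    from .schedule import ms_to_first_frame
    onsets = []
    k = 0
    while True:
        f = ms_to_first_frame(k * element_duration_ms, frame_rate)
        if f >= n_window_frames:
            return onsets
        onsets.append(f)
        k += 1


def latency_histogram(tfmap: TimeFieldMap, sort_by: str = "peak",
                      omit_after_onsets: list[int] | None = None,
                      omit_frames: int = 2
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of assigned peak frames and the sorted heatmap row order.

    Parameters
    ----------
    sort_by
        ``"peak"`` (all-trial assignment) or ``"peak_even"`` for the
        cross-validated display (sort on even trials, show odd).
    omit_after_onsets
        Window-relative element-onset frames; the first ``omit_frames``
        bins after each onset are zeroed in the histogram (the ~67 ms
        transmission delay makes them uninterpretable).

    Returns
    -------
    (counts, order)
        ``counts`` over window frames (consistent cells only) and the
        stable row ordering of consistent cells by the sort key.
    """
    if tfmap.n_consistent < 1:
        raise ValueError("no consistent cells")
    tbl = tfmap.table[tfmap.table["consistent"]]
    counts = np.bincount(tbl["peak"].to_numpy(),
                         minlength=tfmap.n_window_frames).astype(float)
    if omit_after_onsets:
        for onset in omit_after_onsets:
            counts[onset:onset + omit_frames] = 0.0
    order = tbl.index.to_numpy()[np.argsort(tbl[sort_by].to_numpy(),
                                            kind="stable")]
    return counts, order
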