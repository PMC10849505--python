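"""Stimulus timetables for the sequence-learning protocol.

The experimental protocol presents three four-element grating sequences
(a standard ``ABCD`` and two deviants ``ABBD``/``ACBD``) in blocks, with an
800 ms gray screen after every presentation, a 10 s rest between blocks and a
one-minute gray lead-in/lead-out.  Baseline and test sessions interleave
blocks of all sequences; training sessions show only the standard sequence.

The timetable (:class:`EventTable` rows in a :class:`pandas.DataFrame`) is the
single source of timing truth for every downstream stage: events carry exact
millisecond onsets/offsets and are mapped to acquisition frames with exact
rational arithmetic, so the 250 ms / 30 Hz mismatch (elements alternate
between 7 and 8 frames) is reproduced faithfully rather than hidden by
rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALPHABET = frozenset("ABCD")

#: canonical event-table columns (CSV schema)
EVENT_COLUMNS = [
    "kind",
    "sequence",
    "element",
    "position",
    "block",
    "trial",
    "onset_ms",
    "offset_ms",
]

DAY_LABELS = {"baseline": "baseline", "training": "training", "test": "test",
              0: "baseline", 1: "training", 2: "training", 3: "training",
              4: "training", 5: "test"}


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing parameters of one session of the sequence protocol.

    Defaults reproduce the study design: 250 ms elements, 800 ms
    intersequence gray (1800 ms per presentation), 5 blocks of 100
    presentations per sequence, 10 s interblock rests and 1 min gray
    periods bracketing the session, imaged at a nominal 30 Hz.
    """

    sequences: tuple[str, ...] = ("ABCD", "ABBD", "ACBD")
    element_duration_ms: int = 250
    gray_duration_ms: int = 800
    block_size: int = 100
    blocks_per_sequence: int = 5
    interblock_gap_ms: int = 10_000
    lead_in_ms: int = 60_000
    lead_out_ms: int = 60_000
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.element_duration_ms <= 0:
            raise ValueError("element_duration_ms must be positive")
        if self.gray_duration_ms < 0:
            raise ValueError("gray_duration_ms must be nonnegative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.block_size < 0 or self.blocks_per_sequence < 0:
            raise ValueError("block counts must be nonnegative")
        if not self.sequences:
            raise ValueError("at least one sequence is required")
        for seq in self.sequences:
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {seq!r} uses letters outside {{A,B,C,D}}: {sorted(bad)}"
                )

    @property
    def presentation_duration_ms(self) -> int:
        """Span of one presentation including its trailing gray period."""
        n = len(self.sequences[0])
        return n * self.element_duration_ms + self.gray_duration_ms

    @property
    def training_sequence(self) -> str:
        """Sequence shown exclusively on training days (the first listed)."""
        return self.sequences[0]


@dataclass(frozen=True)
class FrameWindow:
    """Half-open acquisition-frame window ``[first_frame, last_frame)``."""

    first_frame: int
    last_frame: int
    offset_frames: int = 0

    def __post_init__(self) -> None:
        if self.first_frame >= self.last_frame:
            raise ValueError("empty frame window")

    def __len__(self) -> int:
        return self.last_frame - self.first_frame

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame)


def _frame_rate_fraction(frame_rate: float) -> Fraction:
    # exact for integral rates (the nominal 30 Hz); limit_denominator guards
    # against binary-float dust for rates given as e.g. 29.97
    return Fraction(frame_rate).limit_denominator(10**6)


def ms_to_first_frame(t_ms, frame_rate: float) -> int:
    """Index of the first frame whose start time is at or after ``t_ms``.

    Frame ``f`` covers ``[f*dt, (f+1)*dt)`` with ``dt = 1000/frame_rate`` ms.
    """
    fr = _frame_rate_fraction(frame_rate)
    return math.ceil(Fraction(t_ms) * fr / 1000)


def frames_for_event(event, frame_rate: float, offset_frames: int = 0) -> FrameWindow:
    """Map one event to its acquisition-frame window.

    A frame belongs to the event iff its start time lies in
    ``[onset_ms, offset_ms)``; the first ``offset_frames`` frames are then
    dropped (the response-latency offset, nominally 2 frames = 67 ms).

    Parameters
    ----------
    event
        Mapping (e.g. an event-table row) with ``onset_ms``/``offset_ms``.
    frame_rate
        Acquisition rate in Hz.
    offset_frames
        Number of leading frames to drop.

    Raises
    ------
    ValueError
        If the window is empty after the offset (event too short).
    """
    if offset_frames < 0:
        raise ValueError("offset_frames must be >= 0")
    first = ms_to_first_frame(event["onset_ms"], frame_rate)
    last = ms_to_first_frame(event["offset_ms"], frame_rate)
    first += offset_frames
    if first >= last:
        raise ValueError(
            f"event [{event['onset_ms']}, {event['offset_ms']}) ms has no frames "
            f"left after dropping {offset_frames}"
        )
    return FrameWindow(first, last, offset_frames)


def event_frame_bounds(events: pd.DataFrame, frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``(first_frame, last_frame)`` arrays for an event table."""
    fr = _frame_rate_fraction(frame_rate)
    num, den = fr.numerator, 1000 * fr.denominator
    onset = events["onset_ms"].to_numpy(dtype=np.int64)
    offset = events["offset_ms"].to_numpy(dtype=np.int64)
    first = -((-onset * num) // den)
    last = -((-offset * num) // den)
    return first, last


def session_n_frames(events: pd.DataFrame, frame_rate: float) -> int:
    """Number of acquisition frames spanning the whole event table."""
    if len(events) == 0:
        return 0
    return ms_to_first_frame(int(events["offset_ms"].max()), frame_rate)


def build_protocol(config: ProtocolConfig, day) -> pd.DataFrame:
    """Build the deterministic event table for one session.

    Parameters
    ----------
    config
        Protocol timing parameters.
    day
        ``"baseline"``/``"test"`` (all sequences, blocks interleaved) or
        ``"training"`` (standard sequence only).  Integer day numbers 0-5
        are accepted as aliases (0 -> baseline, 1-4 -> training, 5 -> test).

    Returns
    -------
    pandas.DataFrame
        Rows of kind ``element`` (one per grating), ``gray`` (the 800 ms
        period closing each presentation) and ``interblock`` (lead-in/out and
        10 s rests), with exact ms onsets/offsets, per-sequence block and
        trial indices, and a global ``presentation`` counter on element/gray
        rows.  The frame clock is continuous: events tile the session with
        no gaps.
    """
    try:
        label = DAY_LABELS[day]
    except (KeyError, TypeError):
        raise ValueError(f"unknown day label {day!r}; expected one of "
                         f"{{baseline, training, test}} or 0-5") from None

    if label == "training":
        block_plan = [config.training_sequence] * config.blocks_per_sequence
    else:
        block_plan = [seq for _ in range(config.blocks_per_sequence)
                      for seq in config.sequences]

    rows: list[tuple] = []
    t = 0
    trial_counter: dict[str, int] = {}
    block_counter: dict[str, int] = {}
    presentation = 0

    def gray_row(duration: int, kind: str = "interblock") -> None:
        nonlocal t
        if duration > 0:
            rows.append((kind, "", "", 0, 0, 0, t, t + duration, -1))
            t += duration

    gray_row(config.lead_in_ms)
    for i, seq in enumerate(block_plan):
        block = block_counter.get(seq, 0) + 1
        block_counter[seq] = block
        for _ in range(config.block_size):
            trial = trial_counter.get(seq, 0) + 1
            trial_counter[seq] = trial
            for pos, letter in enumerate(seq, start=1):
                rows.append(("element", seq, letter, pos, block, trial,
                             t, t + config.element_duration_ms, presentation))
                t += config.element_duration_ms
            if config.gray_duration_ms > 0:
                rows.append(("gray", seq, "", 0, block, trial,
                             t, t + config.gray_duration_ms, presentation))
                t += config.gray_duration_ms
            presentation += 1
        if i < len(block_plan) - 1:
            gray_row(config.interblock_gap_ms)
    gray_row(config.lead_out_ms)

    return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["presentation"])


def select_events(events: pd.DataFrame, kind: str | None = None,
                  sequence: str | None = None, element: str | None = None,
                  position: int | None = None) -> pd.DataFrame:
    """Filter an event table by kind / sequence / element letter / position."""
    mask = pd.Series(True, index=events.index)
    if kind is not None:
        mask &= events["kind"] == kind
    if sequence is not None:
        mask &= events["sequence"] == sequence
    if element is not None:
        mask &= events["element"] == element
    if position is not None:
        mask &= events["position"] == position
    out = events[mask]
    if len(out) == 0:
        raise ValueError(
            f"no events match kind={kind!r} sequence={sequence!r} "
            f"element={element!r} position={position!r}"
        )
    return out


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_protocol`."""

    n_events: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_protocol(events: pd.DataFrame, fatal: bool = False) -> ValidationReport:
    """Check structural invariants of an event table.

    Verifies that events tile the session contiguously, that element
    positions within each presentation are complete and ordered, that every
    presentation is closed by exactly one gray event, and that per-sequence
    trial indices run 1..N without gaps.

    Parameters
    ----------
    events
        Event table (as from :func:`build_protocol`).
    fatal
        If true, raise ``ValueError`` on any violation instead of reporting.
    """
    report = ValidationReport(n_events=len(events))
    if len(events) == 0:
        return report
    v = report.violations

    ev = events.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    gaps = ev["onset_ms"].to_numpy()[1:] - ev["offset_ms"].to_numpy()[:-1]
    if (gaps != 0).any():
        v.append(f"{int((gaps != 0).sum())} non-contiguous event boundaries")
    if (ev["offset_ms"] <= ev["onset_ms"]).any():
        v.append("events with nonpositive duration")

    elems = ev[ev["kind"] == "element"]
    grays = ev[ev["kind"] == "gray"]
    for (seq, trial), grp in elems.groupby(["sequence", "trial"]):
        positions = grp.sort_values("onset_ms")["position"].tolist()
        if positions != list(range(1, len(seq) + 1)):
            v.append(f"presentation {seq} trial {trial}: positions {positions}")
        n_gray = ((grays["sequence"] == seq) & (grays["trial"] == trial)).sum()
        if n_gray != 1:
            v.append(f"unpaired presentation {seq} trial {trial}: "
                     f"{n_gray} gray events")
    for seq, grp in elems.groupby("sequence"):
        trials = sorted(grp["trial"].unique())
        if trials != list(range(1, len(trials) + 1)):
            v.append(f"sequence {seq}: trial indices not contiguous from 1")

    if fatal and v:
        raise ValueError("protocol validation failed: " + "; ".join(v))
    return report
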