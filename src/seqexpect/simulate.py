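"""Synthetic deconvolved two-photon activity with planted ground truth.

The generator emulates the statistical structure of deconvolved L2/3
population activity under the sequence protocol so that every analysis stage
can be verified against known parameters:

* **element-selective cells** emit a Gaussian response bump (amplitude,
  latency, width per cell) at every *visual transition* to their preferred
  grating; latencies are drawn late-skewed at baseline and from a bimodal
  onset/offset mixture after training;
* **omission responses**: when a cell's preferred element is held on screen
  (the repeated B of ABBD — no visual transition), the cell emits sustained
  activity whose offset-window time average equals ``omission_gain`` times
  its standard-window average, with a small bump at the time the next
  element was expected;
* **context gain**: responses to a preferred element appearing outside its
  trained sequence position (e.g. C in ACBD) are scaled by a per-day
  substitution gain;
* **gray-period cells** respond ~300 ms after gray onset (``gray_onset``) or
  ramp linearly up to the end of the gray period (``gray_ramp``);
* **representational drift** is a per-cell multiplicative gain
  ``exp(eta * W_t)`` with ``W`` a standard random walk over presentations,
  optionally augmented by a fraction of cells that switch preferred latency
  mid-session;
* additive Gaussian frame noise, truncated at zero (deconvolved amplitudes
  are nonnegative and sparse).

Responses are confined to the frames of their driving event, which keeps the
planted omission/substitution ratios exactly recoverable by the
prediction-error stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schedule import (DAY_LABELS, ProtocolConfig, event_frame_bounds,
                       session_n_frames)

ELEMENT_CLASSES = ("element_A", "element_B", "element_C", "element_D")
GRAY_CLASSES = ("gray_onset", "gray_ramp")
CELL_CLASSES = ELEMENT_CLASSES + GRAY_CLASSES + ("background",)

# Planted selective-class fractions: element fractions follow the reported
# per-day selectivity table (A 6.1/2.7, B 10.0/7.1, C 6.1/2.7, D 9.2/4.3 %);
# the gray fraction (9.4/10.3 %) is split 60/40 between onset-responsive and
# ramping cells.  Remainder = background.
DAY0_FRACTIONS: dict[str, float] = {
    "element_A": 0.061, "element_B": 0.100, "element_C": 0.061,
    "element_D": 0.092, "gray_onset": 0.056, "gray_ramp": 0.038,
}
DAY5_FRACTIONS: dict[str, float] = {
    "element_A": 0.027, "element_B": 0.071, "element_C": 0.027,
    "element_D": 0.043, "gray_onset": 0.062, "gray_ramp": 0.041,
}


@dataclass
class CellSpec:
    """Ground-truth parameters of one simulated cell."""

    mouse_id: str
    cell_id: int
    cell_class: str
    amplitude: float
    latency_ms: float
    width_ms: float
    baseline: float
    omission_gain: float = 1.0
    context_gain: float = 1.0
    drift_eta: float = 0.0
    latency_ms_late: float = np.nan  # second latency for swap cells
    swap_presentation: int = -1      # presentation index of the swap, -1 = never

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.omission_gain < 0:
            raise ValueError("omission_gain must be >= 0")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic population, defaulting to study conditions.

    Attributes
    ----------
    n_mice, cells_per_mouse
        Population size; defaults approximate 8 mice x ~170 cells.
    class_fractions
        Per-day selective-class fractions; the remainder is background.
    omission_gain
        Planted ratio of held-element to standard-element activity per day
        (the omission prediction-error effect, 1.10 baseline / 1.44 test).
    substitution_gain
        Gain on responses to a preferred element outside its trained
        position (0.88 baseline / 0.84 test).
    latency ranges
        Baseline latencies are drawn with density increasing over
        (response_offset, element] ms; test-day latencies from a bimodal
        mixture near onset and near element offset.
    drift_eta
        Per-presentation volatility of the multiplicative gain random walk.
    noise_scale
        SD of the additive Gaussian frame noise (before truncation at zero).
    """

    n_mice: int = 8
    cells_per_mouse: int = 171
    class_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"baseline": dict(DAY0_FRACTIONS),
                                 "test": dict(DAY5_FRACTIONS)})
    mean_amplitude: float = 5.0
    amplitude_spread: float = 0.3       # lognormal sigma
    width_ms: float = 40.0
    gray_width_ms: float = 60.0
    baseline_rate: float = 0.1
    omission_gain: dict[str, float] = field(
        default_factory=lambda: {"baseline": 1.10, "test": 1.44})
    substitution_gain: dict[str, float] = field(
        default_factory=lambda: {"baseline": 0.88, "test": 0.84})
    omission_bump_frac: float = 0.5
    drift_eta: float = 0.01
    latency_swap_fraction: float = 0.0
    noise_scale: float = 0.5
    response_offset_ms: float = 67.0
    element_duration_ms: int = 250
    gray_duration_ms: int = 800
    gray_latency_mean_ms: float = 300.0
    gray_latency_sd_ms: float = 40.0
    pe_offset_frames: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        for day, fracs in self.class_fractions.items():
            total = sum(fracs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"class fractions for {day!r} sum to {total} > 1")
            bad = set(fracs) - set(CELL_CLASSES)
            if bad:
                raise ValueError(f"unknown cell classes {sorted(bad)}")
        for name in ("mean_amplitude", "noise_scale", "baseline_rate",
                     "drift_eta", "latency_swap_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ActivityMatrix:
    """Deconvolved activity, cells x acquisition frames, nonnegative a.u."""

    values: np.ndarray
    frame_rate: float
    cell_meta: pd.DataFrame
    day: str = ""
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be cells x frames")
        if len(self.cell_meta) != self.values.shape[0]:
            raise ValueError("cell_meta length must match number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _day_key(day, mapping: Mapping[str, object]) -> str:
    label = DAY_LABELS.get(day, day)
    if label in mapping:
        return label
    if label == "training" and "baseline" in mapping:
        return "baseline"  # training sessions use pre-training statistics
    raise ValueError(f"no parameters configured for day {day!r}")


def _draw_latency(config: GeneratorConfig, day_label: str, rng: np.random.Generator) -> float:
    lo = config.response_offset_ms
    hi = config.element_duration_ms
    if day_label != "test":
        # density increasing linearly over (lo, hi]: inverse-CDF sqrt draw
        return float(lo + (hi - lo) * np.sqrt(rng.uniform()) * 0.999)
    # bimodal: near onset (post-delay) and near element offset
    if rng.uniform() < 0.5:
        return float(np.clip(rng.normal(lo + 20.0, 15.0), lo + 1.0, hi * 0.6))
    return float(np.clip(rng.normal(hi - 15.0, 10.0), hi * 0.7, hi - 1.0))


def generate_population(config: GeneratorConfig, day,
                        rng: np.random.Generator | None = None) -> list[CellSpec]:
    """Draw the ground-truth cell population for one session day.

    Class counts are multinomial around the configured fractions per mouse;
    latencies follow the day-specific distributions described in the module
    docstring.  Reproducible given a seeded ``rng`` (or ``config.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    day_label = _day_key(day, config.class_fractions)
    fracs = config.class_fractions[day_label]
    classes = list(fracs) + ["background"]
    probs = np.array([fracs[c] for c in fracs] + [1.0 - sum(fracs.values())])
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()

    omission = _day_key(day, config.omission_gain)
    substitution = _day_key(day, config.substitution_gain)
    cells: list[CellSpec] = []
    cell_id = 0
    for m in range(config.n_mice):
        counts = rng.multinomial(config.cells_per_mouse, probs)
        for cls, count in zip(classes, counts):
            for _ in range(count):
                amplitude = float(config.mean_amplitude
                                  * rng.lognormal(0.0, config.amplitude_spread))
                if cls in ELEMENT_CLASSES:
                    latency = _draw_latency(config, day_label, rng)
                    width = config.width_ms
                elif cls == "gray_onset":
                    latency = float(np.clip(
                        rng.normal(config.gray_latency_mean_ms,
                                   config.gray_latency_sd_ms),
                        50.0, config.gray_duration_ms - 50.0))
                    width = config.gray_width_ms
                else:  # gray_ramp / background
                    latency = float(config.gray_duration_ms)
                    width = config.gray_width_ms
                swap = -1
                late = np.nan
                if (cls in ELEMENT_CLASSES
                        and rng.uniform() < config.latency_swap_fraction):
                    swap = 0  # resolved to a presentation index at simulation
                    late = _draw_latency(config, day_label, rng)
                cells.append(CellSpec(
                    mouse_id=f"m{m}", cell_id=cell_id, cell_class=cls,
                    amplitude=amplitude, latency_ms=latency, width_ms=width,
                    baseline=config.baseline_rate,
                    omission_gain=config.omission_gain[omission],
                    context_gain=config.substitution_gain[substitution],
                    drift_eta=config.drift_eta,
                    latency_ms_late=late, swap_presentation=swap))
                cell_id += 1
    return cells


def ground_truth_frame(cells: Sequence[CellSpec]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in cells])


def _element_annotations(events: pd.DataFrame, training_sequence: str) -> pd.DataFrame:
    """Annotate element events with transition / trained-position flags."""
    elems = events[events["kind"] == "element"].copy()
    seqs = elems["sequence"].to_numpy()
    pos = elems["position"].to_numpy()
    letters = elems["element"].to_numpy()
    transition = np.array([p == 1 or s[p - 2] != e
                           for s, p, e in zip(seqs, pos, letters)])
    trained_pos = {c: training_sequence.index(c) + 1
                   for c in set(training_sequence)}
    deviant = np.array([transition[i] and pos[i] != trained_pos.get(letters[i], pos[i])
                        for i in range(len(elems))])
    elems["is_transition"] = transition
    elems["is_deviant_position"] = deviant
    return elems


def _scatter_groups(row: np.ndarray, first: np.ndarray, last: np.ndarray,
                    onset_ms: np.ndarray, gains: np.ndarray, dt_ms: float,
                    value_fn) -> None:
    """Add ``gains[i] * value_fn(t_rel)`` into ``row`` for each event window.

    Events are grouped by window length so the frame-time grid broadcasts;
    ``value_fn`` receives times (ms, relative to event onset) of shape
    (events, frames).
    """
    lengths = last - first
    for L in np.unique(lengths):
        sel = lengths == L
        f0 = first[sel]
        t_rel = (f0[:, None] + np.arange(L)) * dt_ms - onset_ms[sel][:, None]
        vals = value_fn(t_rel) * gains[sel][:, None]
        np.add.at(row, (f0[:, None] + np.arange(L)).ravel(), vals.ravel())


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_session(cells: Sequence[CellSpec], events: pd.DataFrame,
                     config: GeneratorConfig,
                     rng: np.random.Generator | None = None,
                     frame_rate: float = 30.0,
                     training_sequence: str = "ABCD",
                     day: str = "") -> ActivityMatrix:
    """Render one session of synthetic activity for a cell population.

    Parameters
    ----------
    cells
        Ground-truth population (:func:`generate_population`).
    events
        Event table from :func:`~seqexpect.schedule.build_protocol`; must
        carry the ``presentation`` column (drift is indexed by it).
    config
        Generator parameters (noise, drift, planted gains).
    rng
        Seeded generator; defaults to ``config.seed``.
    """
    if len(cells) == 0:
        raise ValueError("cells must be non-empty")
    if len(events) == 0:
        raise ValueError("events must be non-empty")
    if "presentation" not in events.columns:
        raise ValueError("events need a 'presentation' column "
                         "(use schedule.build_protocol or io.read_events)")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_frames = session_n_frames(events, frame_rate)
    dt_ms = 1000.0 / frame_rate
    n_pres = int(events["presentation"].max()) + 1

    elems = _element_annotations(events, training_sequence)
    grays = events[events["kind"] == "gray"]
    e_first, e_last = event_frame_bounds(elems, frame_rate)
    g_first, g_last = event_frame_bounds(grays, frame_rate)
    e_onset = elems["onset_ms"].to_numpy(dtype=float)
    g_onset = grays["onset_ms"].to_numpy(dtype=float)
    g_dur = (grays["offset_ms"] - grays["onset_ms"]).to_numpy(dtype=float)
    e_pres = elems["presentation"].to_numpy(dtype=int)
    g_pres = grays["presentation"].to_numpy(dtype=int)
    letters = elems["element"].to_numpy()
    is_transition = elems["is_transition"].to_numpy()
    is_deviant = elems["is_deviant_position"].to_numpy()
    off = config.pe_offset_frames

    values = np.zeros((len(cells), n_frames), dtype=np.float32)
    child_rngs = rng.spawn(len(cells))

    for ci, (cell, crng) in enumerate(zip(cells, child_rngs)):
        row = np.zeros(n_frames, dtype=float)
        if cell.drift_eta > 0:
            walk = np.cumsum(crng.standard_normal(n_pres))
            gain = np.exp(cell.drift_eta * walk)
        else:
            gain = np.ones(n_pres)

        if cell.cell_class in ELEMENT_CLASSES:
            letter = cell.cell_class[-1]
            mine = letters == letter
            drive = mine & is_transition
            tau = np.full(drive.sum(), cell.latency_ms)
            if cell.swap_presentation >= 0 and np.isfinite(cell.latency_ms_late):
                switch = int(crng.integers(1, n_pres)) if n_pres > 1 else 0
                tau[e_pres[drive] >= switch] = cell.latency_ms_late
            ev_gain = gain[e_pres[drive]] * np.where(
                is_deviant[drive], cell.context_gain, 1.0)
            # per-event latency requires per-event evaluation; group by
            # (length, tau) — tau takes at most two values
            for tval in np.unique(tau):
                pick = np.flatnonzero(drive)[tau == tval]
                _scatter_groups(
                    row, e_first[pick], e_last[pick], e_onset[pick],
                    ev_gain[tau == tval], dt_ms,
                    lambda t, tv=tval: cell.amplitude * _gauss(t, tv, cell.width_ms))

            held = np.flatnonzero(mine & ~is_transition)
            if held.size and cell.omission_gain > 0:
                _add_omission(row, cell, config, elems, e_first, e_last,
                              e_onset, held, gain, dt_ms, off)
        elif cell.cell_class == "gray_onset":
            _scatter_groups(row, g_first, g_last, g_onset, gain[g_pres], dt_ms,
                            lambda t: cell.amplitude
                            * _gauss(t, cell.latency_ms, cell.width_ms))
        elif cell.cell_class == "gray_ramp":
            dur = float(np.median(g_dur))
            _scatter_groups(row, g_first, g_last, g_onset, gain[g_pres], dt_ms,
                            lambda t: cell.amplitude * np.clip(t / dur, 0.0, 1.0))

        row += cell.baseline
        if config.noise_scale > 0:
            # noise is itself truncated at zero: deconvolution emits spurious
            # nonnegative events, never negative ones
            row += np.maximum(crng.normal(0.0, config.noise_scale, n_frames), 0.0)
        np.maximum(row, 0.0, out=row)
        values[ci] = row

    meta = pd.DataFrame({
        "mouse_id": [c.mouse_id for c in cells],
        "cell_id": [c.cell_id for c in cells],
        "cell_class": [c.cell_class for c in cells],
        "day": day,
    })
    return ActivityMatrix(values=values, frame_rate=frame_rate,
                          cell_meta=meta, day=str(day),
                          ground_truth=ground_truth_frame(cells))


def _add_omission(row: np.ndarray, cell: CellSpec, config: GeneratorConfig,
                  elems: pd.DataFrame, e_first: np.ndarray, e_last: np.ndarray,
                  e_onset: np.ndarray, held_idx: np.ndarray,
                  gain: np.ndarray, dt_ms: float, off: int) -> None:
    """Sustained held-element response planting the omission-gain ratio.

    The held window carries a flat response plus a bump at the cell's usual
    latency (the time the next transition was expected).  The planted gain
    is defined on the scale the prediction-error statistic measures: the
    response is scaled so the *expected measured* activity (signal +
    baseline + mean truncated noise) averaged over the offset analysis
    window equals ``omission_gain`` times the expected measured activity in
    the preceding (standard) element's offset window.
    """
    floor = cell.baseline + config.noise_scale / np.sqrt(2.0 * np.pi)
    pos = elems["position"].to_numpy()
    seqs = elems["sequence"].to_numpy()
    trials = elems["trial"].to_numpy()
    pres = elems["presentation"].to_numpy(dtype=int)
    # locate the standard event (same presentation, previous position)
    index_by_key = {(s, t, p): i for i, (s, t, p)
                    in enumerate(zip(seqs, trials, pos))}
    for hi in held_idx:
        si = index_by_key.get((seqs[hi], trials[hi], pos[hi] - 1))
        if si is None:
            continue
        # standard-window mean of the noiseless bump (offset applied)
        t_std = (np.arange(e_first[si] + off, e_last[si]) * dt_ms
                 - e_onset[si])
        m_std = float(np.mean(cell.amplitude
                              * _gauss(t_std, cell.latency_ms, cell.width_ms)))
        frames = np.arange(e_first[hi], e_last[hi])
        t_rel = frames * dt_ms - e_onset[hi]
        shape = 1.0 + config.omission_bump_frac * _gauss(
            t_rel, cell.latency_ms, cell.width_ms)
        shape_mean = float(np.mean(shape[off:]))
        target = cell.omission_gain * (m_std + floor) - floor
        scale = max(target, 0.0) / shape_mean if shape_mean > 0 else 0.0
        row[frames] += gain[pres[hi]] * scale * shape
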