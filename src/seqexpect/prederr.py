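"""Prediction-error ratios, day comparisons and the hierarchical bootstrap.

The prediction-error (PE) ratio of a cell divides its trial- and
time-averaged activity during a deviant event by that during a matched
standard event, both windows starting two acquisition frames (~67 ms) after
the nominal transition:

* **omission** design — B-responsive cells; deviant = the held B of ABBD
  (position 3, no visual transition), standard = the driven B (position 2;
  variant: B of ABCD);
* **substitution** design — C-responsive cells; deviant = C in ACBD
  (position 2, unexpected), standard = C in ABCD (position 3, expected).
  Window identity follows the element letter, not the position.

Day distributions are compared with a two-sample KS test, reporting the
combined sample size.  The hierarchical bootstrap resamples mice with
replacement, pools their cells, then resamples cells to pool size —
respecting the nesting of cells within animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import extract_trials, time_average
from .schedule import select_events
from .simulate import ActivityMatrix

#: (deviant, standard) event selectors per design: (sequence, element, position)
DESIGNS = {
    "omission": (("ABBD", "B", 3), ("ABBD", "B", 2)),
    "omission_abcd_standard": (("ABBD", "B", 3), ("ABCD", "B", 2)),
    "substitution": (("ACBD", "C", 2), ("ABCD", "C", 3)),
}

#: responsive cell set (context-free selectivity label) per design
RESPONSIVE_LABEL = {
    "omission": "B",
    "omission_abcd_standard": "B",
    "substitution": "C",
}


@dataclass
class PEResult:
    """Per-cell PE ratios for one design on one day."""

    design: str
    day: str
    ratios: pd.Series            # indexed by cell position, retained cells only
    n_excluded: int              # standard-window mean below epsilon
    epsilon: float

    @property
    def n(self) -> int:
        return len(self.ratios)

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())


@dataclass
class KSComparison:
    statistic: float
    pvalue: float
    n: int                        # combined sample size convention


@dataclass
class BootstrapResult:
    """Hierarchical-bootstrap distribution of a group mean."""

    means: np.ndarray             # n_iter (scalars) or n_iter x frames (traces)
    median: np.ndarray | float
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    n_iterations: int


def window_means(activity: ActivityMatrix, events: pd.DataFrame,
                 offset_frames: int = 2) -> np.ndarray:
    """Per-cell trial-averaged mean over truncated event windows."""
    tensor = extract_trials(activity, events, offset_frames=offset_frames,
                            mode="truncate")
    return time_average(tensor).values.mean(axis=0)


def pe_ratio(activity: ActivityMatrix, events: pd.DataFrame,
             responsive_mask: np.ndarray, design: str = "omission",
             offset_frames: int = 2, eps_frac: float = 1e-6,
             day: str = "") -> PEResult:
    """Per-cell PE ratios for one deviant/standard design.

    Parameters
    ----------
    responsive_mask
        Boolean per-cell mask of the relevant responsive set (recomputed on
        the same day's data; cells are not tracked across days).
    eps_frac
        Cells with standard-window mean below ``eps_frac`` times the
        population mean amplitude are excluded (ratio instability) and
        counted in ``n_excluded``.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; options: {sorted(DESIGNS)}")
    (dseq, delt, dpos), (sseq, selt, spos) = DESIGNS[design]
    deviant = select_events(events, kind="element", sequence=dseq,
                            element=delt, position=dpos)
    standard = select_events(events, kind="element", sequence=sseq,
                             element=selt, position=spos)
    dev_mean = window_means(activity, deviant, offset_frames)
    std_mean = window_means(activity, standard, offset_frames)

    epsilon = eps_frac * float(activity.values.mean())
    mask = np.asarray(responsive_mask, dtype=bool)
    keep = mask & (std_mean > epsilon)
    ratios = pd.Series(dev_mean[keep] / std_mean[keep],
                       index=np.flatnonzero(keep), name="pe_ratio")
    return PEResult(design=design, day=day, ratios=ratios,
                    n_excluded=int(mask.sum() - keep.sum()), epsilon=epsilon)


def compare_days(day0: PEResult | Sequence[float],
                 day5: PEResult | Sequence[float]) -> KSComparison:
    """Two-sample KS test between two days' PE-ratio distributions."""
    a = day0.ratios.to_numpy() if isinstance(day0, PEResult) else np.asarray(day0)
    b = day5.ratios.to_numpy() if isinstance(day5, PEResult) else np.asarray(day5)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return KSComparison(statistic=float(res.statistic),
                        pvalue=float(res.pvalue), n=len(a) + len(b))


def prediction_error_cell_screen(activity: ActivityMatrix, events: pd.DataFrame,
                                 design: str = "omission",
                                 offset_frames: int = 2,
                                 active_sd: float = 2.0,
                                 exclusivity: float = 3.0) -> np.ndarray:
    """Flag cells firing (nearly) exclusively during the deviant window.

    A dedicated "prediction-error cell" is active in the deviant window
    (mean above ``overall mean + active_sd * SD``) while at least
    ``exclusivity`` times weaker in every other stimulus window (per-letter
    element means excluding the deviant events, and the gray periods).
    Ordinary responsive cells — whose deviant-to-standard ratio is the PE
    ratio itself, near 1 — never reach the exclusivity bar.
    """
    (dseq, delt, dpos), _ = DESIGNS[design]
    is_dev = ((events["kind"] == "element") & (events["sequence"] == dseq)
              & (events["element"] == delt) & (events["position"] == dpos))
    deviant = events[is_dev]
    if len(deviant) == 0:
        raise ValueError(f"no deviant events for design {design!r}")
    dev_mean = window_means(activity, deviant, offset_frames)
    mu = activity.values.mean(axis=1)
    sd = activity.values.std(axis=1)
    active_deviant = dev_mean > mu + active_sd * sd

    others = []
    elems = events[(events["kind"] == "element") & ~is_dev]
    for _, grp in elems.groupby("element"):
        others.append(window_means(activity, grp, offset_frames))
    others.append(window_means(activity, events[events["kind"] == "gray"],
                               offset_frames))
    max_other = np.max(np.stack(others), axis=0)
    return active_deviant & (dev_mean > exclusivity * max_other)


def hierarchical_bootstrap(values_by_mouse: Mapping[str, np.ndarray],
                           n_iter: int = 1000,
                           rng: np.random.Generator | None = None,
                           ci: float = 95.0) -> BootstrapResult:
    """Two-level bootstrap of a group mean over cells nested in mice.

    Each iteration resamples mice with replacement (same count), pools the
    chosen mice's cells, resamples cells with replacement to pool size, and
    stores the mean.  Works for scalar per-cell values (e.g. PE ratios,
    shape ``(cells,)``) and per-cell traces (``(cells, frames)``).
    """
    if not values_by_mouse:
        raise ValueError("need at least one mouse")
    groups = {m: np.atleast_1d(np.asarray(v, dtype=float))
              for m, v in values_by_mouse.items()}
    for m, v in groups.items():
        if v.shape[0] == 0:
            raise ValueError(f"mouse {m!r} has no cells")
    if rng is None:
        rng = np.random.default_rng()
    mice = list(groups)
    n_mice = len(mice)
    means = []
    for _ in range(n_iter):
        chosen = rng.integers(0, n_mice, size=n_mice)
        pool = np.concatenate([groups[mice[i]] for i in chosen], axis=0)
        draw = rng.integers(0, pool.shape[0], size=pool.shape[0])
        means.append(pool[draw].mean(axis=0))
    means = np.asarray(means)
    lo, hi = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    return BootstrapResult(
        means=means,
        median=np.median(means, axis=0),
        ci_low=np.percentile(means, lo, axis=0),
        ci_high=np.percentile(means, hi, axis=0),
        n_iterations=n_iter,
    )
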