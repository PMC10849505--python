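"""Minimal figure helpers (PNG output; headless backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_confusion(report, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion, cmap="viridis", vmin=0)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_cdf(coeff_sets: dict[str, np.ndarray], path,
                         title: str = "") -> None:
    """Empirical CDFs of element-pair correlation coefficients per day."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, r in coeff_sets.items():
        x = np.sort(np.asarray(r))
        ax.plot(x, np.arange(1, len(x) + 1) / len(x), label=label)
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("CDF")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_latency_histogram(counts: np.ndarray, path, frame_rate: float = 30.0,
                           title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    t = np.arange(len(counts)) * 1000.0 / frame_rate
    ax.bar(t, counts, width=1000.0 / frame_rate * 0.9)
    ax.set_xlabel("peak time (ms)")
    ax.set_ylabel("cells")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
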