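"""Figure helpers.

All figures regenerate from saved CSV/JSON artifacts, never from
in-memory pipeline state.  Matplotlib's Agg backend is forced so plotting
works headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_offset_histogram", "plot_pulse_bubble", "plot_triggered_average"]


def plot_offset_histogram(matched, control, path, bins=30):
    """Stacked comparison of matched vs randomized-cell first-pulse offsets."""
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    axes[0].hist(matched, bins=bins, color="tab:green", alpha=0.8)
    axes[0].set_ylabel("matched cells")
    axes[1].hist(control, bins=bins, color="tab:gray", alpha=0.8)
    axes[1].set_ylabel("randomized cells")
    axes[1].set_xlabel("time from calcium burst to Crz1 pulse (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pulse_bubble(groups, path):
    """Pulse-count probability per burst-height group (bubble area = probability)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in groups:
        if not g["count_probs"]:
            continue
        x = g["mean_height"]
        for count, prob in g["count_probs"].items():
            ax.scatter([x], [count], s=1000 * prob, color="tab:blue", alpha=0.6)
        ax.errorbar([x], [g["mean_count"]], yerr=[g["ci_half_width"]],
                    fmt="o", color="tab:red", capsize=4)
    ax.set_xlabel("mean calcium burst height (group)")
    ax.set_ylabel("Crz1 pulses after burst")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_triggered_average(rel_times, mean, ci, path, ylabel="signal"):
    """Event-aligned mean trace with its 95% confidence band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(rel_times, mean, color="tab:blue")
    ax.fill_between(rel_times, mean - ci, mean + ci, color="tab:blue", alpha=0.3)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time relative to event (s)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
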