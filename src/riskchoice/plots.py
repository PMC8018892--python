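"""Static figure export for continuity tests and indifference maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.special import expit

__all__ = ["plot_continuity", "plot_indifference_map", "plot_triangle"]


def plot_continuity(result, ax=None):
    """Per-level AC-choice proportions with the fitted softmax overlay."""
    ax = ax or plt.subplots()[1]
    ax.axhline(0.5, ls="--", c="gray", lw=0.8)
    ax.plot(result.levels, result.proportions, "o", c="tab:blue")
    if result.ip is not None:
        x = np.linspace(result.levels.min(), result.levels.max(), 200)
        ax.plot(x, expit((x - result.ip.alpha) / result.ip.tau), "r-")
        ax.axvline(result.ip.alpha, c="r", ls=":", lw=0.8)
    ax.set(xlabel="mixture probability pA", ylabel="P(choose AC)",
           ylim=(-0.02, 1.02))
    return ax


def plot_indifference_map(imap, measured_ips=None, ax=None):
    """Model-predicted indifference curves, optionally with measured IPs."""
    ax = ax or plt.subplots()[1]
    for b, (mags, probs) in imap.curves.items():
        ax.plot(mags, probs, "-", lw=1.2)
    if measured_ips:
        ax.plot([ip.a_magnitude for ip in measured_ips],
                [ip.alpha for ip in measured_ips], "ko", ms=4)
    ax.set(xlabel="reward magnitude (ml)", ylabel="reward probability",
           ylim=(0, 1.02))
    return ax


def plot_triangle(points, ax=None):
    """Gambles as (p1, p3) points in the Marschak-Machina triangle."""
    ax = ax or plt.subplots()[1]
    ax.plot([0, 1, 0, 0], [1, 0, 0, 1], "k-", lw=1)
    ax.plot([p.p1 for p in points], [p.p3 for p in points], "ro", ms=4)
    ax.set(xlabel="p1 (lowest outcome)", ylabel="p3 (highest outcome)",
           xlim=(-0.02, 1.02), ylim=(-0.02, 1.02), aspect="equal")
    return ax
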