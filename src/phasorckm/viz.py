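"""Plot exports: polar phasor plot and predicted survival curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_phasor_polar(results, path=None, ax=None):
    """Polar phasor plot: one vector per participant.

    Vector length is the phasor magnitude (coupling strength), the angle the
    acrophase (clockwise positive = activity lags light).  ``results`` is an
    iterable of objects with ``magnitude`` and ``acrophase_hours``.
    """
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for res in results:
        theta = res.acrophase_hours * 2 * np.pi / 24.0
        ax.annotate("", xy=(theta, res.magnitude), xytext=(0, 0),
                    arrowprops={"arrowstyle": "->"})
    ax.set_rmax(1.0)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 6))
    ax.set_xticklabels([f"{h}h" for h in range(0, 24, 2)])
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_survival_curves(curves, path=None, ax=None):
    """Step plot of predicted survival by exposure level (tidy frame input)."""
    if ax is None:
        _, ax = plt.subplots()
    for level, sub in curves.groupby("level"):
        ax.step(sub["months"], sub["survival"], where="post", label=str(level))
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("predicted survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="magnitude quartile")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
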