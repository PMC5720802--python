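"""Minimal plotting helpers (time courses with cluster bars, TG matrices)."""

from __future__ import annotations

import numpy as np


def plot_timecourse(times, values, clusters=None, ax=None, labels=None, ylabel=""):
    """Plot one or more time courses with horizontal significance bars.

    ``values`` is (n_lines, n_times) or (n_times,); ``clusters`` an optional
    iterable of objects with ``start``/``stop``/``significant`` attributes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.atleast_2d(values)
    for i, v in enumerate(values):
        ax.plot(times, v, label=None if labels is None else labels[i])
    if clusters is not None:
        y = np.nanmin(values) - 0.05 * (np.nanmax(values) - np.nanmin(values) + 1e-12)
        for c in clusters:
            if getattr(c, "significant", True):
                ax.hlines(y, c.start, c.stop, lw=3)
    ax.axvline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    if labels is not None:
        ax.legend()
    return ax


def plot_tg_matrix(times, tg, ax=None):
    """Temporal-generalization matrix (train time x test time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        tg, origin="lower", aspect="auto",
        extent=[times[0], times[-1], times[0], times[-1]],
        vmin=0.3, vmax=1.0, cmap="RdBu_r",
    )
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("train time (s)")
    plt.colorbar(im, ax=ax, label="accuracy")
    return ax
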