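"""Publication-style figures for PSF populations and coherence summaries."""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_psf_means",
    "plot_coherence_moving_average",
    "plot_predicted_vs_observed",
    "moving_average_histogram",
]


def moving_average_histogram(
    values: np.ndarray,
    bin_width: float = 0.1,
    lo: float = 0.0,
    hi: float = 0.9,
    window: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving average (over ``window`` bins) of a coherence histogram.

    Returns (bin_centers, smoothed_fractions); fractions are of the total
    cell count, smoothed with a centered boxcar.
    """
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.asarray(values, float), bins=edges)
    frac = counts / max(len(values), 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(frac, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, smooth


def plot_psf_means(curves_by_group: dict[str, np.ndarray], grid=None, ax=None):
    """Mean normalized PSF per group with standard-error envelopes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, curves in curves_by_group.items():
        curves = np.atleast_2d(curves)
        g = grid if grid is not None else np.arange(curves.shape[1]) * 1e-3
        m = curves.mean(axis=0)
        se = curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]) if curves.shape[0] > 1 else 0
        ax.plot(g * 1e3, m, label=name)
        if np.ndim(se):
            ax.fill_between(g * 1e3, m - se, m + se, alpha=0.3)
    ax.set_xlabel("time since spike (ms)")
    ax.set_ylabel("normalized PSF")
    ax.legend()
    return ax


def plot_coherence_moving_average(coherence_by_group: dict[str, np.ndarray], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, vals in coherence_by_group.items():
        centers, smooth = moving_average_histogram(vals)
        ax.plot(centers, smooth, label=name)
    ax.set_xlabel("spatial coherence")
    ax.set_ylabel("fraction of cells (4-bin moving average)")
    ax.legend()
    return ax


def plot_predicted_vs_observed(predicted, observed, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(observed, predicted, s=12, alpha=0.7)
    lims = [min(np.min(observed), np.min(predicted)), max(np.max(observed), np.max(predicted))]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("observed coherence")
    ax.set_ylabel("predicted coherence")
    return ax
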