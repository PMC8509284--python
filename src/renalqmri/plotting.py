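"""Convenience plots for maps and ADC histograms (matplotlib)."""

from __future__ import annotations

import numpy as np

from .histogram import HistogramMetrics
from .relaxometry import ParameterMap


def plot_map(pmap: ParameterMap, ax=None, **imshow_kwargs):
    """Show a parameter map with unfitted voxels blanked out."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    shown = np.where(pmap.mask, pmap.values, np.nan)
    im = ax.imshow(shown.T, origin="lower", **imshow_kwargs)
    ax.set_title(f"{pmap.kind} ({pmap.units})")
    plt.colorbar(im, ax=ax)
    return ax


def plot_kde(metrics: HistogramMetrics, ax=None, label: str | None = None):
    """Overlay-ready ADC density curve with the IQR shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(metrics.kde_grid, metrics.kde_density, label=label)
    lo = metrics.mean - metrics.iqr / 2
    ax.axvspan(lo, lo + metrics.iqr, alpha=0.15)
    ax.set_xlabel("ADC (1e-3 mm$^2$/s)")
    ax.set_ylabel("probability density")
    if label:
        ax.legend()
    return ax
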