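"""Minimal plotting helpers (matplotlib) for contact maps and histograms."""

from __future__ import annotations

import numpy as np

from .contacts import ContactMap


def plot_contact_map(cmap: ContactMap, log: bool = True, ax=None, **imshow_kwargs):
    """Render a contact map; by default the decimal log of the probability.

    Pairs with zero probability (and excluded near-diagonal pairs) are left
    blank.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = cmap.matrix()
    if log:
        with np.errstate(divide="ignore"):
            m = np.log10(m)
        m[np.isneginf(m)] = np.nan
        label = "log10 contact probability"
    else:
        label = "contact probability"
    im = ax.imshow(m, origin="lower", **imshow_kwargs)
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax


def plot_series_histogram(summary, ax=None, **step_kwargs):
    """Plot the normalised histogram stored in a :class:`SeriesSummary`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges, dens = summary.hist_edges, summary.hist_density
    ax.stairs(dens, edges, **step_kwargs)
    ax.set_ylabel("probability density")
    return ax
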