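"""Plot helpers (matplotlib is imported lazily; install the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .io import ContactMatrix

__all__ = ["plot_contact_map", "plot_pearson_by_distance"]


def plot_contact_map(matrix: ContactMatrix, ax=None, log: bool = True, **imshow_kw):
    """Heat map of a contact matrix (log1p color scale by default)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = np.log1p(matrix.counts) if log else matrix.counts
    im = ax.imshow(data, cmap=imshow_kw.pop("cmap", "Reds"), **imshow_kw)
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    ax.figure.colorbar(im, ax=ax, label="log1p(count)" if log else "count")
    return ax


def plot_pearson_by_distance(curves: dict[str, np.ndarray], resolution: int = 10_000, ax=None):
    """Overlay per-distance Pearson curves, e.g. enhanced vs baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, values in curves.items():
        values = np.asarray(values, dtype=float)
        d = np.arange(len(values)) * resolution / 1e6
        ax.plot(d, values, label=label)
    ax.set_xlabel("genomic distance (Mb)")
    ax.set_ylabel("Pearson correlation")
    ax.set_ylim(-0.1, 1.0)
    ax.legend()
    return ax
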