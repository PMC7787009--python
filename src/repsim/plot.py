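"""Minimal visualization: an RDM heatmap."""

from __future__ import annotations

import numpy as np

from .rdm import RDM


def plot_rdm(rdm, ax=None, cmap: str = "viridis", labels=None, colorbar: bool = True):
    """Draw an RDM as a heatmap and return the matplotlib Axes.

    Accepts an :class:`~repsim.rdm.RDM` or a square array. Requires
    matplotlib (the ``plot`` extra).
    """
    import matplotlib.pyplot as plt

    values = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(values, cmap=cmap, interpolation="nearest")
    ax.set_xlabel("condition")
    ax.set_ylabel("condition")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90)
        ax.set_yticks(range(len(labels)), labels)
    if colorbar:
        ax.figure.colorbar(im, ax=ax, label="dissimilarity")
    return ax
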