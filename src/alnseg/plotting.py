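"""Diagnostic plots: GC-vs-conservation 'blob' plots and DICV curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_class_blobs(results, ax=None):
    """Scatter post-burn-in GC content against conservation level per
    class: tight blobs indicate a converged, well-separated class."""
    series = results.convergence_series().iloc[results.post_slice]
    K = results.n_classes
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("tab20")
    for c in range(K):
        ckey, gkey = f"conservation_{c}", f"gc_{c}"
        if ckey not in series or gkey not in series:
            raise ValueError("blob plot needs both conservation and GC series")
        ax.scatter(series[ckey], series[gkey], s=4, alpha=0.5,
                   color=cmap(c % 20), label=f"class {c}")
    ax.set_xlabel("conservation level")
    ax.set_ylabel("GC content")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, markerscale=2)
    return ax


def plot_dicv_curve(curve, selected=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.index, curve.values, "o-")
    if selected is not None:
        ax.axvline(selected, color="red", ls="--", lw=1)
    ax.set_xlabel("number of classes K")
    ax.set_ylabel("DICV")
    return ax
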