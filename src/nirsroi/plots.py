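"""Matplotlib figures for ROC curves, calibration, and sweep heatmaps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_roc", "plot_fpr_calibration", "plot_sweep_heatmap"]


def plot_roc(rocs: dict, ax=None):
    """Overlay ROC curves; ``rocs`` maps label -> ROCResult."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize="small")
    return ax


def plot_fpr_calibration(curves: dict, ax=None):
    """Empirical FPR vs nominal level; ``curves`` maps label -> (alpha, fpr)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, (alpha, fpr) in curves.items():
        ax.plot(alpha, fpr, label=label)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("reported p-value")
    ax.set_ylabel("empirical FPR")
    ax.legend(loc="upper left", fontsize="small")
    return ax


def plot_sweep_heatmap(summary, value="auc", ax=None):
    """Radius x separation heatmap of a two-ROI sweep summary column."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = summary.pivot_table(
        index="separation", columns="radius", values=value, aggfunc="mean"
    )
    im = ax.imshow(
        pivot.values, origin="lower", aspect="auto",
        extent=[
            pivot.columns.min(), pivot.columns.max(),
            pivot.index.min(), pivot.index.max(),
        ],
    )
    ax.figure.colorbar(im, ax=ax, label=value)
    ax.set_xlabel("ROI radius (mm)")
    ax.set_ylabel("ROI separation (mm)")
    return ax


def save_figure(ax, path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(ax.figure)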