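"""Plot helpers for fit histories and cross-validation reports."""

from __future__ import annotations

import numpy as np


def plot_history(result, ax=None):
    """Train/validation loss curves from a FitResult."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    epochs = [h["epoch"] for h in result.history]
    ax.plot(epochs, [h["train_loss"] for h in result.history], label="train")
    ax.plot(epochs, [h["valid_loss"] for h in result.history], label="valid")
    ax.axvline(result.best_epoch, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("BCE loss")
    ax.legend()
    return ax


def plot_fold_metric(reports: dict[str, "MetricsReport"], metric: str = "roc_auc", ax=None):
    """Per-fold metric values for several variants, one line each."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, report in reports.items():
        vals = report.fold_values(metric)
        ax.plot(np.arange(vals.size), vals, marker="o", label=name)
    ax.set_xlabel("fold")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
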