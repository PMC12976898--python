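"""Diagnostic plots for screen traces and training histories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_screen_trace", "plot_training_history"]


def plot_screen_trace(trace, ax=None):
    """AUC of each sampled module over screening iterations."""
    df = trace.to_frame() if hasattr(trace, "to_frame") else pd.DataFrame(trace)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(df["iteration"], df["auc"], ".", ms=3, alpha=0.6)
    ax.plot(df["iteration"], df["auc"].cummax(), lw=1.5, label="best so far")
    ax.set_xlabel("screening iteration")
    ax.set_ylabel("module AUC")
    ax.legend(frameon=False)
    return ax


def plot_training_history(history: pd.DataFrame, ax=None):
    """Train/validation total loss and AUC per epoch."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(history["epoch"], history["train_total"], label="train loss")
    ax.plot(history["epoch"], history["val_total"], label="val loss")
    ax2 = ax.twinx()
    ax2.plot(history["epoch"], history["val_auc"], "k--", lw=1, label="val AUC")
    ax2.set_ylabel("validation AUC")
    ax.set_xlabel("epoch")
    ax.set_ylabel("total loss")
    ax.legend(frameon=False, loc="upper left")
    return ax
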