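"""Diagnostic figures: jerk-norm contact detection and pooled ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_jerk_detection(jerk, contacts, sample_rate_hz, path: str | Path):
    """Jerk-norm trace with detected cane contacts marked."""
    t = np.arange(len(jerk)) / sample_rate_hz
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, jerk, lw=0.8, label="jerk norm")
    ax.plot(t[contacts], np.asarray(jerk)[contacts], "rv", label="cane contact")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("jerk norm (m/s³)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(report, path: str | Path):
    """Pooled ROC curves for every model in a classification report."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in report.results.items():
        fpr, tpr, _ = res.pooled_roc
        ax.plot(fpr, tpr, label=f"{name} (AUC {res.pooled_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
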