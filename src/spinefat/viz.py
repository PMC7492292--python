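"""Evaluation plots: Bland-Altman, ROC and precision-recall curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import BlandAltmanResult, pr_auc, roc_auc_delong


def bland_altman_plot(result: BlandAltmanResult, dest: str | Path,
                      title: str = "Bland-Altman") -> Path:
    """Difference-vs-mean plot with bias and 1.96 SD limits of agreement."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(result.means, result.differences, s=18, alpha=0.7, edgecolors="none")
    ax.axhline(result.bias, color="tab:blue", label=f"bias {result.bias:+.3f}%")
    for y, lab in ((result.loa_low, f"LOA {result.loa_low:+.3f}%"),
                   (result.loa_high, f"LOA {result.loa_high:+.3f}%")):
        ax.axhline(y, color="tab:red", linestyle="--", label=lab)
    ax.set_xlabel("mean BMF of methods (%)")
    ax.set_ylabel("manual − automatic (%)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(dest)
    plt.close(fig)
    return dest


def roc_curve_plot(scores: np.ndarray, labels: np.ndarray, dest: str | Path) -> Path:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels).ravel(), np.asarray(scores).ravel())
    auc, lo, hi = roc_auc_delong(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, label=f"AUC {auc:.3f} (95% CI {lo:.4f}, {hi:.4f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(dest)
    plt.close(fig)
    return dest


def pr_curve_plot(scores: np.ndarray, labels: np.ndarray, dest: str | Path) -> Path:
    from sklearn.metrics import precision_recall_curve

    prec, rec, _ = precision_recall_curve(
        np.asarray(labels).ravel(), np.asarray(scores).ravel()
    )
    ap = pr_auc(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(rec, prec, label=f"PR AUC {ap:.3f}")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(fontsize=8)
    fig.tight_layout()
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(dest)
    plt.close(fig)
    return dest
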