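"""Optional plotting helpers for ROC and component-reconnection curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .evaluate import ReconnectionCurve, RocResult


def plot_roc(results: Mapping[str, RocResult], path: str | Path) -> None:
    """One ROC curve per labelled result, AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, res in results.items():
        ax.plot(res.curve[:, 0], res.curve[:, 1],
                label=f"{label} (AUC={res.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_reconnection(curves: Mapping[str, ReconnectionCurve], path: str | Path) -> None:
    """Component counts against the predicted-positive fraction rho."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, cur in curves.items():
        line, = ax.plot(cur.rho_values, cur.component_counts, marker="o", label=label)
        ax.axhline(cur.baseline_components, ls="--", lw=0.8, color=line.get_color())
    ax.set_xlabel(r"top fraction $\rho$ of ranked pairs")
    ax.set_ylabel("connected components")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
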