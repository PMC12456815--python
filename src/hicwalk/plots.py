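"""Convenience plots for evaluation reports (violin of ARI by condition)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless backend; plots are file output only
import matplotlib.pyplot as plt

from .evaluation import EvaluationReport

__all__ = ["plot_ari_violins"]


def plot_ari_violins(report: EvaluationReport, path, caller: str | None = None) -> None:
    """Violin plot of the per-replicate ARI distribution per condition.

    One panel per caller unless ``caller`` restricts to a single one.
    """
    table = report.table
    callers = [caller] if caller else sorted(table["caller"].unique())
    conditions = report.conditions
    fig, axes = plt.subplots(
        len(callers), 1, figsize=(max(6, 0.8 * len(conditions)), 3 * len(callers)),
        squeeze=False,
    )
    for ax, name in zip(axes[:, 0], callers):
        sub = table[table["caller"] == name]
        data = [sub[sub["condition"] == c]["ari"].to_numpy() for c in conditions]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(conditions) + 1))
        ax.set_xticklabels(conditions, rotation=45, ha="right")
        ax.set_ylabel("ARI")
        ax.set_title(name)
        ax.set_ylim(-0.1, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
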