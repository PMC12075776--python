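"""Minimal plot exports (violin-style growth-rate and morphology panels)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .growth import ConditionSummary
from .morphology import PopulationMorphology

__all__ = ["plot_condition_rates", "plot_population_morphology"]


def plot_condition_rates(
    summaries: Sequence[ConditionSummary], variable: str, out: str | Path
) -> Path:
    """Violin of exponential-phase rates per condition value, median bars."""
    ordered = sorted(summaries, key=lambda s: s.condition[variable])
    data = [[r for _, r in s.exp_phase_rates] for s in ordered]
    labels = [f"{s.condition[variable]:g}" for s in ordered]
    fig, ax = plt.subplots(figsize=(1.2 * len(ordered) + 2, 4))
    parts = ax.violinplot(data, showmedians=True, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.5)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_xlabel(variable)
    ax.set_ylabel("instantaneous rate (doublings/day)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_population_morphology(pop: PopulationMorphology, out: str | Path) -> Path:
    """One violin per geometric parameter over per-cell representatives."""
    params = list(pop.per_cell.columns)
    fig, axes = plt.subplots(1, len(params), figsize=(2.2 * len(params), 3.5))
    for ax, p in zip(axes, params):
        ax.violinplot(pop.per_cell[p].to_numpy(), showmedians=True, showextrema=False)
        ax.set_title(p)
        ax.set_xticks([])
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
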