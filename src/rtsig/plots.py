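"""Convenience renderings of the signature statistics (box / violin / bar).

Plotting is a thin layer over matplotlib; all statistics shown are computed
by :mod:`rtsig.analysis`, never here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first

import matplotlib.pyplot as plt  # noqa: E402

from .analysis import PositionDelta  # noqa: E402


def feature_boxplot(
    values_by_condition: Mapping[str, Sequence[float]],
    feature: str,
    title: str = "",
):
    """Boxplot of one feature's per-position values, one box per condition."""
    fig, ax = plt.subplots(figsize=(1.2 * len(values_by_condition) + 2, 4))
    labels = list(values_by_condition)
    ax.boxplot([values_by_condition[k] for k in labels], tick_labels=labels)
    ax.set_ylabel(feature)
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def jump_violin(
    values_by_condition: Mapping[str, Sequence[float]],
    title: str = "",
):
    """Violin plot for the jump rate (its mass near zero defeats a boxplot)."""
    fig, ax = plt.subplots(figsize=(1.2 * len(values_by_condition) + 2, 4))
    labels = list(values_by_condition)
    ax.violinplot([list(values_by_condition[k]) for k in labels],
                  showmedians=True, widths=0.8)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("jump rate")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def delta_bars(deltas: Sequence[PositionDelta], title: str = ""):
    """Per-position bars of treated - reference differences."""
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(deltas)), 4))
    labels = [f"{d.ref_seg.split('|')[0]}:{d.pos}" for d in deltas]
    ax.bar(range(len(deltas)), [d.delta for d in deltas])
    ax.set_xticks(range(len(deltas)), labels, rotation=90, fontsize=7)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel(f"delta {deltas[0].feature}" if deltas else "delta")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
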