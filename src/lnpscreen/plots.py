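"""Plotting hooks (matplotlib imported lazily; optional dependency)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_ranked_delivery(aggregates: pd.Series, control_barcode_id: str | None,
                         path: str | Path) -> None:
    """Ranked bar chart of aggregate normalized delivery (log scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = aggregates.sort_values(ascending=False)
    colors = ["crimson" if b == control_barcode_id else "steelblue"
              for b in ordered.index]
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.bar(range(len(ordered)), ordered.to_numpy(), color=colors, width=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("LNP rank")
    ax.set_ylabel("normalized delivery")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment(table: pd.DataFrame, axis: str, path: str | Path) -> None:
    """Top/bottom-decile fold-enrichment bars for one component axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["axis"] == axis]
    levels = sorted(sub["level"].unique())
    x = range(len(levels))
    fig, ax = plt.subplots(figsize=(1.2 * len(levels) + 2, 3.5))
    for direction, offset, color in (("top", -0.2, "seagreen"),
                                     ("bottom", 0.2, "indianred")):
        folds = [
            sub[(sub.level == lv) & (sub.direction == direction)]["fold"].iloc[0]
            for lv in levels
        ]
        ax.bar([xi + offset for xi in x], folds, width=0.38, color=color,
               label=f"{direction} decile")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(list(x))
    ax.set_xticklabels(levels, rotation=30, ha="right")
    ax.set_ylabel("fold enrichment")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
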