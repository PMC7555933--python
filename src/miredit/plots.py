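"""Optional figure output: doughnut charts of edited-miRNA shares and a
signed -log10 p heatmap across comparisons."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def doughnut_chart(summary, path: str | Path) -> None:
    """Doughnut chart: each retained edited miRNA is one slice."""
    plt = _mpl()
    t = summary.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(
        t["doughnut_share"],
        labels=t["mirna_id"],
        wedgeprops={"width": 0.4},
        startangle=90,
        counterclock=False,
    )
    ax.set_title(f"Edited miRNA shares — {summary.group}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def de_heatmap(signed_log10p: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of signed -log10 p per miRNA x comparison."""
    plt = _mpl()
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * signed_log10p.shape[1], 1 + 0.25 * signed_log10p.shape[0])
    )
    vmax = float(abs(signed_log10p.to_numpy()).max() or 1.0)
    im = ax.imshow(
        signed_log10p.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        aspect="auto",
    )
    ax.set_xticks(range(signed_log10p.shape[1]), signed_log10p.columns, rotation=90)
    ax.set_yticks(range(signed_log10p.shape[0]), signed_log10p.index)
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
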