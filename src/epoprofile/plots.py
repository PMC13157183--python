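"""Optional figure rendering (proportion plot, PCA scores)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["proportion_plot", "pca_score_plot"]

_CLASS_COLORS = {"foetal": "#b2182b", "mixed": "#fddbc7", "adult": "#2166ac"}


def proportion_plot(percentages: pd.DataFrame, path) -> None:
    """Stacked percentage bars of profile classes per age group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    bottom = None
    for cls in percentages.columns:
        vals = percentages[cls].to_numpy()
        ax.bar(
            percentages.index.astype(str),
            vals,
            bottom=bottom,
            label=cls,
            color=_CLASS_COLORS.get(cls),
        )
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("% of samples")
    ax.set_xlabel("developmental age group (weeks)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pca_score_plot(scores: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """PC1/PC2 scores coloured by day, marker shape by condition."""
    m = meta.set_index("sample_id").loc[scores.index]
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {"normoxia": "o", "hypoxia": "^"}
    for cond, mk in markers.items():
        mask = (m["condition"] == cond).to_numpy()
        if mask.any():
            sc = ax.scatter(
                scores.iloc[mask, 0],
                scores.iloc[mask, 1],
                c=m.loc[mask, "day"],
                marker=mk,
                cmap="viridis",
                label=cond,
            )
    fig.colorbar(sc, ax=ax, label="day")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
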