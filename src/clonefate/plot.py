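"""Schematic plots of fitted clone-fate results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .classify import CATEGORIES


def fate_heatmap(results, timepoint: str = "TP2", ax=None):
    """Category-blocked heatmap of shifted-log profiles.

    Rows are barcodes grouped by fate category and Ward-ordered within
    each category; columns are the merged well samples.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 9))
    order: list[str] = []
    boundaries = []
    for cat in CATEGORIES:
        members = results.order_barcodes(cat, timepoint)
        order.extend(members)
        boundaries.append(len(order))
    mat = results.shifted_log.loc[order]
    im = ax.imshow(mat.to_numpy(), aspect="auto", interpolation="nearest",
                   cmap="viridis")
    for b in boundaries[:-1]:
        ax.axhline(b - 0.5, color="white", linewidth=0.8)
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("barcodes (grouped by fate, Ward-ordered)")
    ax.figure.colorbar(im, ax=ax, label="log2(normalised count + 1)")
    return ax


def secondary_bubble_plot(results, timepoint: str = "TP2", ax=None):
    """Per-well abundance bubbles for secondary-resistant clones."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    calls = results.fate_calls[timepoint]
    members = calls.index[calls == "secondary_resistant"]
    meta = results.merged.samples
    nk_ids = meta.index[(meta["condition"] == "nk")
                        & (meta["timepoint"] == timepoint)]
    sub = results.shifted_log.loc[members, nk_ids]
    for yi, (_barcode, row) in enumerate(sub.iterrows()):
        sizes = 20.0 * (row.to_numpy() + 0.3)
        ax.scatter(np.arange(len(row)), np.full(len(row), yi), s=sizes,
                   alpha=0.7, color="tab:red", edgecolor="none")
    ax.set_xticks(range(len(nk_ids)))
    ax.set_xticklabels(nk_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(members)))
    ax.set_yticklabels(members, fontsize=5)
    ax.set_title(f"secondary resistant clones ({timepoint})")
    return ax
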