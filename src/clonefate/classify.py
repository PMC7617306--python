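"""Rule-based clone fate classification and fate-set summaries.

Each retained barcode is assigned exactly one of five categories per
timepoint, with the rules evaluated in order (first match wins):

i)   primary_resistant : padj < 0.05 and log2fc >= +1 (NK vs alone)
ii)  eliminated        : padj < 0.05 and log2fc <= -1
iii) static            : v <= 0.5 in the alone arm and v < 1 in the NK arm
iv)  secondary_resistant: v <= 0.5 alone, v >= 1 in NK, and the barcode is
     high in exactly one of the NK wells ("high" = at least one doubling
     above the +1-shifted minimum well)
v)   other             : none of the above
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist

from .errors import ClassificationError

CATEGORIES = ("eliminated", "primary_resistant", "static",
              "secondary_resistant", "other")


@dataclass
class Thresholds:
    """Decision-tree thresholds (defaults are the analysis constants)."""

    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    v_alone_cut: float = 0.5
    v_nk_cut: float = 1.0
    high_well_bar: float = 1.0

    def validate(self) -> None:
        if not 0 < self.padj_cut <= 1:
            raise ValueError("padj_cut must be in (0, 1]")
        for name in ("lfc_cut", "v_alone_cut", "v_nk_cut", "high_well_bar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def high_well_count(x_nk, bar: float = 1.0) -> int:
    """Number of NK wells at least ``bar`` doublings above the minimum.

    Well i is high iff log2((x_i + 1) / (min(x) + 1)) >= bar, on the same
    normalised scale as the variability statistic.
    """
    x = np.asarray(x_nk, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one well")
    ratio = np.log2((x + 1.0) / (x.min() + 1.0))
    return int((ratio >= bar).sum())


def _high_well_counts(normalized_nk: pd.DataFrame, bar: float) -> pd.Series:
    x = normalized_nk.to_numpy(dtype=float)
    ratio = np.log2((x + 1.0) / (x.min(axis=1, keepdims=True) + 1.0))
    return pd.Series((ratio >= bar).sum(axis=1), index=normalized_nk.index,
                     name="n_high_wells")


REQUIRED_STATS = ("padj", "log2fc", "v_alone", "v_nk", "n_high_wells")


def classify_clones(stats: pd.DataFrame,
                    thresholds: Thresholds | None = None) -> pd.Series:
    """Apply the decision tree to a per-barcode stats table.

    ``stats`` needs columns padj, log2fc, v_alone, v_nk, n_high_wells.
    Returns the category per barcode.  Missing values raise
    :class:`ClassificationError`.
    """
    th = thresholds or Thresholds()
    th.validate()
    missing = [c for c in REQUIRED_STATS if c not in stats.columns]
    if missing:
        raise ClassificationError(f"missing statistics: {missing}")
    if stats[list(REQUIRED_STATS)].isna().any().any():
        bad = stats.index[stats[list(REQUIRED_STATS)].isna().any(axis=1)]
        raise ClassificationError(
            f"incomplete statistics for {len(bad)} barcodes (e.g. {bad[0]!r})")

    padj = stats["padj"].to_numpy(dtype=float)
    lfc = stats["log2fc"].to_numpy(dtype=float)
    v_alone = stats["v_alone"].to_numpy(dtype=float)
    v_nk = stats["v_nk"].to_numpy(dtype=float)
    high = stats["n_high_wells"].to_numpy()

    significant = padj < th.padj_cut
    rules = [
        ("primary_resistant", significant & (lfc >= th.lfc_cut)),
        ("eliminated", significant & (lfc <= -th.lfc_cut)),
        ("static", (v_alone <= th.v_alone_cut) & (v_nk < th.v_nk_cut)),
        ("secondary_resistant",
         (v_alone <= th.v_alone_cut) & (v_nk >= th.v_nk_cut) & (high == 1)),
    ]
    category = np.full(len(stats), "other", dtype=object)
    unassigned = np.ones(len(stats), dtype=bool)
    for name, mask in rules:  # first match wins
        take = unassigned & mask
        category[take] = name
        unassigned &= ~take
    return pd.Series(category, index=stats.index, name="category")


def classify_clone(stats_row, thresholds: Thresholds | None = None) -> str:
    """Single-clone convenience wrapper around :func:`classify_clones`."""
    frame = pd.DataFrame([dict(stats_row)])
    return classify_clones(frame, thresholds).iloc[0]


def summarize_fates(calls: pd.Series | pd.DataFrame,
                    by: list[str] | None = None) -> pd.DataFrame:
    """Category counts and proportions.

    ``calls`` is a category Series (or a DataFrame with a 'category'
    column plus grouping columns).  With ``by``, proportions are computed
    within each group and a pooled mean +/- SD across groups is appended
    as rows labelled ('pooled_mean', 'pooled_sd').
    """
    if isinstance(calls, pd.Series):
        frame = calls.to_frame("category")
    else:
        frame = calls
    if by:
        parts = {}
        for key, grp in frame.groupby(by, sort=True):
            parts[key] = _proportions(grp["category"])["proportion"]
        table = pd.DataFrame(parts).T
        table.loc["pooled_mean"] = table.mean(axis=0)
        table.loc["pooled_sd"] = table.drop(index=["pooled_mean"]).std(axis=0, ddof=1)
        return table
    return _proportions(frame["category"])


def _proportions(categories: pd.Series) -> pd.DataFrame:
    counts = categories.value_counts().reindex(CATEGORIES, fill_value=0)
    total = int(counts.sum())
    prop = counts / total if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "proportion": prop})


def overlap_fates(calls_a: pd.Series, calls_b: pd.Series) -> pd.DataFrame:
    """Per-category overlap between two experiments' fate calls.

    Returns intersection / exclusive sizes and the Jaccard index
    (0 when both sets are empty), per category.
    """
    rows = {}
    for cat in CATEGORIES:
        a = set(calls_a.index[calls_a == cat])
        b = set(calls_b.index[calls_b == cat])
        union = a | b
        inter = a & b
        rows[cat] = dict(
            n_a=len(a), n_b=len(b), intersection=len(inter),
            a_only=len(a - b), b_only=len(b - a),
            jaccard=len(inter) / len(union) if union else 0.0,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def order_barcodes(normalized: pd.DataFrame) -> list[str]:
    """Display ordering by Ward-linkage clustering of normalised profiles.

    Agglomerative clustering on Euclidean distances (hclust ward.D2
    equivalent); returns the leaf order.  Fewer than two rows are returned
    as-is.
    """
    if len(normalized) < 2:
        return list(normalized.index)
    dist = pdist(normalized.to_numpy(dtype=float), metric="euclidean")
    order = leaves_list(linkage(dist, method="ward"))
    return [normalized.index[i] for i in order]
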