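"""Model/Results surface over the clone-fate analysis.

:class:`CloneFateModel` is built from a technical-replicate-level count
matrix (or directly from FASTQ files plus a sample sheet); ``fit()`` runs
replicate merging, the detection filter, size-factor normalisation, the NB
differential-abundance test, the variability statistics and the decision
tree, and returns a :class:`CloneFateResults` carrying per-clone estimates,
fate calls, per-sample diversity and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from . import classify as _classify
from . import counts as _counts
from . import stats as _stats
from .classify import Thresholds, CATEGORIES
from .counts import CountMatrix, ALONE, NK, TP1, TP2
from .errors import ConfigurationError
from .extract import count_sample
from .reference import build_reference, match_to_reference


class CloneFateModel:
    """Clone-fate model for one cell line's co-culture count data.

    Parameters
    ----------
    data : CountMatrix
        Technical-replicate-level counts (rows barcodes, columns samples).
        Counts should already be restricted to the reference library when
        one exists; :meth:`from_fastq` does this automatically.
    thresholds : Thresholds, optional
        Decision-tree cut-offs.
    min_detect_total, reference_timepoint
        Detection-filter settings (>= 1 read in every tumour-alone well at
        the reference timepoint and a summed count >= ``min_detect_total``).
    shrinkage_prior_df : float
        Dispersion-moderation strength of the NB Wald test (0 disables).
    """

    def __init__(self, data: CountMatrix,
                 thresholds: Thresholds | None = None,
                 min_detect_total: int = 9,
                 reference_timepoint: str = TP1,
                 require_all_wells: bool = True,
                 shrinkage_prior_df: float = _stats.DEFAULT_PRIOR_DF):
        self.data = data
        self.thresholds = thresholds or Thresholds()
        self.thresholds.validate()
        self.min_detect_total = min_detect_total
        self.reference_timepoint = reference_timepoint
        self.require_all_wells = require_all_wells
        self.shrinkage_prior_df = shrinkage_prior_df

    @classmethod
    def from_fastq(cls, sample_sheet: pd.DataFrame,
                   library_fastqs: dict[str, str] | None = None,
                   head: str | None = None, tail: str | None = None,
                   barcode_length: int | None = None,
                   min_library_reads: int = 100,
                   **kwargs) -> "CloneFateModel":
        """Build the model straight from raw reads.

        ``sample_sheet`` is indexed by sample_id with a ``fastq`` column
        plus the metadata columns (cell_line, condition, timepoint, well,
        techrep, nk_genotype).  ``library_fastqs`` maps library sample ids
        to FASTQ paths; when given, a reference is built with the
        >= ``min_library_reads`` rule and sample counts are restricted to it.
        """
        from .extract import HEAD_ANCHOR, TAIL_ANCHOR, BARCODE_LENGTH
        head = head or HEAD_ANCHOR
        tail = tail or TAIL_ANCHOR
        barcode_length = barcode_length or BARCODE_LENGTH
        reference = None
        if library_fastqs:
            lib_results = [count_sample(path, head, tail, barcode_length, sid)
                           for sid, path in library_fastqs.items()]
            reference = build_reference(lib_results, min_library_reads)
        results = []
        for sid, row in sample_sheet.iterrows():
            res = count_sample(row["fastq"], head, tail, barcode_length, sid)
            if reference is not None:
                res = match_to_reference(res, reference)
            results.append(res)
        meta = sample_sheet.drop(columns=["fastq"])
        data = _counts.from_extractions(
            results, meta,
            barcodes=reference.barcodes if reference is not None else None)
        model = cls(data, **kwargs)
        model.reference = reference
        model.extractions = results
        return model

    def fit(self, timepoints: tuple[str, ...] = (TP1, TP2)) -> "CloneFateResults":
        merged = _counts.merge_technical_replicates(self.data)
        retained = _counts.detection_filter(
            merged, reference_timepoint=self.reference_timepoint,
            min_total=self.min_detect_total,
            require_all_wells=self.require_all_wells)
        if len(retained) == 0:
            raise ConfigurationError("no barcodes pass the detection filter")
        filtered = merged.subset(retained)
        factors = _counts.size_factors(filtered)
        shifted_log = _counts.shifted_log_normalize(filtered, factors)
        diversity = _stats.diversity_table(filtered.counts)

        meta = filtered.samples
        clone_stats: dict[str, pd.DataFrame] = {}
        fate_calls: dict[str, pd.Series] = {}
        for tp in timepoints:
            nk_ids = list(meta.index[(meta["condition"] == NK)
                                     & (meta["timepoint"] == tp)])
            alone_ids = list(meta.index[(meta["condition"] == ALONE)
                                        & (meta["timepoint"] == tp)])
            da = _stats.diff_abundance(
                filtered.counts, nk_ids, alone_ids, factors,
                shrinkage_prior_df=self.shrinkage_prior_df)
            da["v_alone"] = _stats.variability_table(shifted_log[alone_ids])
            da["v_nk"] = _stats.variability_table(shifted_log[nk_ids])
            da["n_high_wells"] = _classify._high_well_counts(
                shifted_log[nk_ids], self.thresholds.high_well_bar)
            clone_stats[tp] = da
            fate_calls[tp] = _classify.classify_clones(da, self.thresholds)

        return CloneFateResults(
            model=self, merged=filtered, size_factors=factors,
            shifted_log=shifted_log, diversity=diversity,
            clone_stats=clone_stats, fate_calls=fate_calls,
            retained=retained)


@dataclass
class CloneFateResults:
    """Fitted clone-fate analysis for one cell line."""

    model: CloneFateModel
    merged: CountMatrix
    size_factors: pd.Series
    shifted_log: pd.DataFrame
    diversity: pd.DataFrame
    clone_stats: dict[str, pd.DataFrame]
    fate_calls: dict[str, pd.Series]
    retained: pd.Index

    @property
    def timepoints(self) -> list[str]:
        return list(self.fate_calls)

    def fate_table(self, timepoint: str = TP2) -> pd.DataFrame:
        """Per-barcode category with its supporting statistics."""
        stats = self.clone_stats[timepoint]
        out = stats[["log2fc", "padj", "v_alone", "v_nk", "n_high_wells"]].copy()
        out.insert(0, "category", self.fate_calls[timepoint])
        out.insert(0, "timepoint", timepoint)
        return out

    def fate_proportions(self, timepoint: str = TP2,
                         renormalize_four: bool = False) -> pd.Series:
        """Category proportions among retained barcodes.

        ``renormalize_four=True`` drops the 'other' category and rescales
        over the four named fates.
        """
        props = _classify.summarize_fates(self.fate_calls[timepoint])["proportion"]
        if renormalize_four:
            props = props.drop("other")
            props = props / props.sum()
        return props

    def diversity_drop(self, timepoint: str = TP2) -> float:
        """1 - H_nk / H_alone using mean Shannon diversity across wells."""
        meta = self.merged.samples
        h = self.diversity["shannon"]
        h_nk = h[meta.index[(meta["condition"] == NK)
                            & (meta["timepoint"] == timepoint)]].mean()
        h_alone = h[meta.index[(meta["condition"] == ALONE)
                               & (meta["timepoint"] == timepoint)]].mean()
        return float(1.0 - h_nk / h_alone)

    def overlap(self, other: "CloneFateResults",
                timepoint: str = TP2) -> pd.DataFrame:
        """Per-category overlap (intersections, Jaccard) with another run."""
        return _classify.overlap_fates(self.fate_calls[timepoint],
                                       other.fate_calls[timepoint])

    def order_barcodes(self, category: str, timepoint: str = TP2) -> list[str]:
        """Ward-clustering display order of one category's barcodes."""
        calls = self.fate_calls[timepoint]
        members = calls.index[calls == category]
        return _classify.order_barcodes(self.shifted_log.loc[members])

    def summary(self) -> str:
        """Human-readable run summary (statsmodels-style text table)."""
        lines = ["Clone fate analysis", "=" * 55]
        lines.append(f"retained barcodes: {len(self.retained)}")
        th = asdict(self.model.thresholds)
        lines.append("thresholds: " + ", ".join(f"{k}={v}" for k, v in th.items()))
        for tp in self.timepoints:
            lines.append("")
            lines.append(f"-- {tp} " + "-" * 47)
            props = self.fate_proportions(tp)
            counts = _classify.summarize_fates(self.fate_calls[tp])["count"]
            for cat in CATEGORIES:
                lines.append(f"{cat:>20}: {counts[cat]:6d}  ({100 * props[cat]:5.1f}%)")
            lines.append(f"{'diversity drop':>20}: {100 * self.diversity_drop(tp):5.1f}%"
                         f"  (1 - H_nk/H_alone)")
        lines.append("")
        lines.append("per-sample Shannon diversity (ln):")
        for sid, row in self.diversity.iterrows():
            lines.append(f"  {sid:>24}: H={row['shannon']:.3f}"
                         f"  detected={int(row['n_detected'])}")
        return "\n".join(lines)

    def to_tsv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tp in self.timepoints:
            self.fate_table(tp).to_csv(outdir / f"fates_{tp}.tsv", sep="\t",
                                       index_label="barcode")
            self.clone_stats[tp].to_csv(outdir / f"clone_stats_{tp}.tsv",
                                        sep="\t", index_label="barcode")
        self.diversity.to_csv(outdir / "diversity.tsv", sep="\t",
                              index_label="sample_id")
        self.size_factors.rename("size_factor").to_csv(
            outdir / "size_factors.tsv", sep="\t", index_label="sample_id")

    def plot_heatmap(self, timepoint: str = TP2, ax=None):
        from .plot import fate_heatmap
        return fate_heatmap(self, timepoint=timepoint, ax=ax)

    def plot_secondary_bubbles(self, timepoint: str = TP2, ax=None):
        from .plot import secondary_bubble_plot
        return secondary_bubble_plot(self, timepoint=timepoint, ax=ax)
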