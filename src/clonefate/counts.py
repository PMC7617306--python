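"""Count-matrix assembly and normalisation.

The analysis-ready object is a barcodes x samples integer matrix with
per-sample metadata (condition, timepoint, well, technical replicate).
Technical replicates are merged by summing read counts.  A per-cell-line
detection filter keeps only barcodes seen in every tumour-alone well at the
reference timepoint with a minimum summed count.  Depth differences are
removed with median-of-ratios size factors, and normalised values are the
shifted log2 transform log2(count / factor + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .extract import ExtractionResult

log = logging.getLogger(__name__)

META_COLUMNS = ["cell_line", "condition", "nk_genotype", "timepoint", "well", "techrep"]
ALONE, NK = "alone", "nk"
TP1, TP2 = "TP1", "TP2"


@dataclass
class CountMatrix:
    """Barcodes x samples read counts plus sample metadata.

    ``counts``: DataFrame, rows indexed by barcode, columns by sample_id.
    ``samples``: DataFrame indexed by sample_id with METADATA columns
    cell_line, condition ('alone'/'nk'/'library'), nk_genotype, timepoint,
    well, techrep.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ConfigurationError("count columns and sample metadata differ")
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts must be non-negative")
        key_cols = [c for c in META_COLUMNS if c in self.samples.columns]
        if self.samples[key_cols].duplicated().any():
            raise ConfigurationError("duplicate sample metadata keys")

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.index

    def subset(self, barcodes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[barcodes], self.samples)

    def select_samples(self, mask) -> "CountMatrix":
        ids = self.samples.index[mask]
        return CountMatrix(self.counts[ids], self.samples.loc[ids])

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="barcode")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="barcode")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts, samples)


def from_extractions(results: list[ExtractionResult],
                     samples: pd.DataFrame,
                     barcodes=None) -> CountMatrix:
    """Assemble a CountMatrix from per-sample extraction results.

    ``samples`` must be indexed by sample_id, one row per result.  The row
    universe is ``barcodes`` when given (e.g. the reference library),
    otherwise the union of observed barcodes.
    """
    table = pd.DataFrame(
        {r.sample_id: pd.Series(r.raw_counts, dtype="int64") for r in results})
    if barcodes is not None:
        table = table.reindex(sorted(barcodes))
    table = table.fillna(0).astype("int64").sort_index()
    return CountMatrix(table[list(samples.index)], samples)


def merge_technical_replicates(matrix: CountMatrix) -> CountMatrix:
    """Sum counts over technical replicates, one column per well."""
    keys = ["cell_line", "condition", "nk_genotype", "timepoint", "well"]
    meta = matrix.samples
    merged_cols, merged_meta = {}, []
    for key, group in meta.groupby(keys, sort=True, dropna=False):
        if len(group) < 1:
            continue
        cell_line, condition, genotype, timepoint, well = key
        sample_id = f"{cell_line}_{condition}_{timepoint}_w{well}"
        merged_cols[sample_id] = matrix.counts[group.index].sum(axis=1)
        merged_meta.append(dict(sample_id=sample_id, cell_line=cell_line,
                                condition=condition, nk_genotype=genotype,
                                timepoint=timepoint, well=well, techrep=0))
    samples = pd.DataFrame(merged_meta).set_index("sample_id")
    counts = pd.DataFrame(merged_cols)
    return CountMatrix(counts[list(samples.index)], samples)


def detection_filter(matrix: CountMatrix,
                     cell_line: str | None = None,
                     reference_timepoint: str = TP1,
                     min_total: int = 9,
                     require_all_wells: bool = True) -> pd.Index:
    """Barcodes considered detected for one cell line.

    A barcode is retained when it has >=1 read in each tumour-alone well at
    the reference timepoint (all-wells semantics; ``require_all_wells=False``
    relaxes to any well) and the summed count over those wells is at least
    ``min_total``.
    """
    meta = matrix.samples
    mask = (meta["condition"] == ALONE) & (meta["timepoint"] == reference_timepoint)
    if cell_line is not None:
        mask &= meta["cell_line"] == cell_line
    ids = meta.index[mask]
    if len(ids) == 0:
        raise ConfigurationError(
            f"no tumour-alone samples at {reference_timepoint} for detection filter")
    alone = matrix.counts[ids]
    total_ok = alone.sum(axis=1) >= min_total
    detected = (alone > 0).all(axis=1) if require_all_wells else (alone > 0).any(axis=1)
    return matrix.barcodes[total_ok & detected]


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference is the per-barcode geometric mean over samples,
    restricted to barcodes with no zero count anywhere; each sample's
    factor is the median over those barcodes of count / pseudo-reference.
    Falls back to total-count ratios (with a logged warning) when no
    barcode is nonzero in every sample.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns)
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        msg = "no barcode nonzero in all samples; falling back to total-count ratios"
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ConfigurationError("a sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns)
    ref = values[positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geomean
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns)


def normalized_counts(counts: pd.DataFrame | CountMatrix,
                      factors: pd.Series) -> pd.DataFrame:
    """Size-factor-normalised counts on the linear scale (count / factor)."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if (factors <= 0).any():
        raise ConfigurationError("size factors must be positive")
    return counts / factors


def shifted_log_normalize(counts: pd.DataFrame | CountMatrix,
                          factors: pd.Series) -> pd.DataFrame:
    """Shifted log2 transform: log2(count / factor + 1); zeros map to 0."""
    return np.log2(normalized_counts(counts, factors) + 1.0)
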