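"""Reference barcode library: definition and whitelist matching.

The viral barcode library is sequenced in several dedicated samples; a
barcode belongs to the reference when its summed read count across those
library samples reaches a minimum (default 100).  Downstream sample counts
are restricted to this whitelist by exact string match; near-miss rescue by
Hamming distance is available but off by default (``max_mismatch=0``),
since the whitelist is treated as fixed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .extract import ExtractionResult

MIN_LIBRARY_READS = 100


@dataclass
class BarcodeLibrary:
    """The reference barcode set with its library-sample read counts."""

    library_counts: pd.DataFrame  # barcodes x library samples
    min_total_reads: int = 0

    @property
    def barcodes(self) -> frozenset[str]:
        return frozenset(self.library_counts.index)

    @property
    def n_library_samples(self) -> int:
        return self.library_counts.shape[1]

    def __len__(self) -> int:
        return self.library_counts.shape[0]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.library_counts.index

    def to_tsv(self, path) -> None:
        out = self.library_counts.copy()
        out["total"] = out.sum(axis=1)
        out.to_csv(path, sep="\t", index_label="barcode")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, barcode in enumerate(self.library_counts.index):
                fh.write(f">bc{i:05d}\n{barcode}\n")


def build_reference(library_results: list[ExtractionResult],
                    min_total_reads: int = MIN_LIBRARY_READS) -> BarcodeLibrary:
    """Keep barcodes whose summed count across library samples reaches the
    threshold (inclusive: "at least")."""
    if len(library_results) < 1:
        raise ValueError("at least one library sample is required")
    table = pd.DataFrame(
        {r.sample_id: pd.Series(r.raw_counts, dtype="int64") for r in library_results}
    ).fillna(0).astype("int64")
    totals = table.sum(axis=1)
    kept = table.loc[totals >= min_total_reads].sort_index()
    return BarcodeLibrary(library_counts=kept, min_total_reads=min_total_reads)


def match_to_reference(result: ExtractionResult,
                       library: BarcodeLibrary) -> ExtractionResult:
    """Restrict a sample's counts to reference barcodes.

    Counts for barcodes absent from the reference are dropped and tallied
    in ``off_reference`` so that matched counts + off-reference equal the
    input accepted total (conservation).
    """
    whitelist = library.barcodes
    kept = Counter()
    dropped = 0
    for barcode, count in result.raw_counts.items():
        if barcode in whitelist:
            kept[barcode] = count
        else:
            dropped += count
    matched = ExtractionResult(
        sample_id=result.sample_id,
        raw_counts=kept,
        qc=dict(result.qc),
        off_reference=result.off_reference + dropped,
    )
    matched.validate()
    return matched
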