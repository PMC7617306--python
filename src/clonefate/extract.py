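"""Barcode extraction from raw amplicon reads.

Each sequencing read is expected to carry a clone barcode enclosed between
two fixed anchor sequences: the head (vector backbone upstream of the
insert) and the tail (non-variable region downstream).  The barcode is the
substring strictly between the first occurrence of the head and the first
occurrence of the tail downstream of it.  A read is rejected when either
anchor is absent, the insert length differs from the expected barcode
length, or the insert contains an uncalled base ("N").  Base qualities are
ignored: the filter is purely sequence based.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError

# Fixed anchor sequences of the LG2.1-style lentiviral barcode amplicon.
HEAD_ANCHOR = "GAACACTCGAGATCAG"
TAIL_ANCHOR = "TGTGGTATGATGT"
BARCODE_LENGTH = 21

#: QC classes, in the order they are tested.
ACCEPTED = "accepted"
REJECTED_NO_HEAD = "rejected_no_head"
REJECTED_NO_TAIL = "rejected_no_tail"
REJECTED_LENGTH = "rejected_length"
REJECTED_UNCALLED = "rejected_uncalled"
QC_CLASSES = (ACCEPTED, REJECTED_NO_HEAD, REJECTED_NO_TAIL,
              REJECTED_LENGTH, REJECTED_UNCALLED)


def extract_barcode(read_sequence: str,
                    head: str = HEAD_ANCHOR,
                    tail: str = TAIL_ANCHOR,
                    expected_length: int = BARCODE_LENGTH) -> tuple[str | None, str]:
    """Locate the barcode in one read.

    Returns ``(barcode, "accepted")`` on success, else ``(None, reason)``
    with ``reason`` one of the rejection QC classes.  Rejections are
    results, not errors.
    """
    if not head or not tail:
        raise ValueError("anchor sequences must be non-empty")
    if expected_length < 1:
        raise ValueError("expected_length must be >= 1")
    i = read_sequence.find(head)
    if i < 0:
        return None, REJECTED_NO_HEAD
    start = i + len(head)
    j = read_sequence.find(tail, start)
    if j < 0:
        return None, REJECTED_NO_TAIL
    insert = read_sequence[start:j]
    if len(insert) != expected_length:
        return None, REJECTED_LENGTH
    if "N" in insert:
        return None, REJECTED_UNCALLED
    return insert, ACCEPTED


@dataclass
class ExtractionResult:
    """Per-sample barcode tallies plus extraction QC.

    ``raw_counts`` maps barcode string to its accepted read count.  The QC
    counters partition the total number of reads; ``off_reference`` is
    populated by :func:`clonefate.reference.match_to_reference` and counts
    accepted reads whose barcode is absent from the reference library.
    """

    sample_id: str
    raw_counts: Counter = field(default_factory=Counter)
    qc: dict[str, int] = field(default_factory=lambda: {c: 0 for c in QC_CLASSES})
    off_reference: int = 0

    @property
    def total_reads(self) -> int:
        return sum(self.qc.values())

    @property
    def discard_fraction(self) -> float:
        total = self.total_reads
        if total == 0:
            return 0.0
        return 1.0 - self.qc[ACCEPTED] / total

    def validate(self) -> None:
        if sum(self.raw_counts.values()) + self.off_reference != self.qc[ACCEPTED]:
            raise AssertionError("accepted reads do not match barcode tallies")


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_sample(fastq_path,
                 head: str = HEAD_ANCHOR,
                 tail: str = TAIL_ANCHOR,
                 expected_length: int = BARCODE_LENGTH,
                 sample_id: str | None = None) -> ExtractionResult:
    """Stream one FASTQ file (plain or gzip) and tally extracted barcodes.

    Memory use is bounded by the number of distinct accepted barcodes.
    Raises :class:`FastqParseError` naming the record index when the stream
    is not valid 4-line FASTQ.
    """
    path = Path(fastq_path)
    result = ExtractionResult(sample_id=sample_id or path.name)
    qc = result.qc
    counts = result.raw_counts
    index = 0
    with _open_maybe_gzip(path) as handle:
        try:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                barcode, reason = extract_barcode(seq, head, tail, expected_length)
                qc[reason] += 1
                if barcode is not None:
                    counts[barcode] += 1
                index += 1
        except ValueError as exc:  # Biopython signals malformed records this way
            raise FastqParseError(
                f"malformed FASTQ record at index {index} in {path}: {exc}",
                record_index=index) from exc
    result.validate()
    return result


def write_counts_tsv(result: ExtractionResult, path) -> None:
    """Write per-barcode counts as a two-column TSV (barcode, count)."""
    with open(path, "w") as fh:
        fh.write("barcode\tcount\n")
        for barcode, count in sorted(result.raw_counts.items()):
            fh.write(f"{barcode}\t{count}\n")


def write_qc_tsv(results: list[ExtractionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(QC_CLASSES)
                 + "\toff_reference\tdiscard_fraction\n")
        for r in results:
            fields = [r.sample_id] + [str(r.qc[c]) for c in QC_CLASSES]
            fields += [str(r.off_reference), f"{r.discard_fraction:.6f}"]
            fh.write("\t".join(fields) + "\n")
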