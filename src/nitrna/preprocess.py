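"""Adapter trimming and read-level quality/length filtering.

Small-RNA libraries read through the insert into the 3' sequencing
adapter; a read without a detectable adapter is longer than the cycle
count and its insert length is unknown, so it is discarded.  The
cascade is:

1. locate the 3' adapter (3'-anchored, partial suffix overlap allowed,
   small mismatch fraction tolerated) and keep the insert upstream;
2. require >= 80% of insert bases with Phred quality strictly above 20;
3. require an insert length of 15-45 nt inclusive.

The three criteria are conjunctive; the order only structures the
report counts.  Quality is assessed on the trimmed insert, the entity
actually retained.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "DEFAULT_ADAPTER",
    "ReadRecord",
    "PreprocessReport",
    "TrimParams",
    "FilterParams",
    "trim_adapter",
    "quality_length_filter",
    "preprocess_fastq",
    "preprocess_reads",
]

# Illumina TruSeq small-RNA 3' adapter as printed in the library protocol.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ"
            )


@dataclass
class PreprocessReport:
    total_reads: int = 0
    with_adapter: int = 0
    passed_quality: int = 0
    passed_length: int = 0

    @property
    def retained(self) -> int:
        return self.passed_length

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.total_reads if self.total_reads else 0.0

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "with_adapter": self.with_adapter,
            "passed_quality": self.passed_quality,
            "passed_length": self.passed_length,
            "retained": self.retained,
            "retained_fraction": self.retained_fraction,
        }


@dataclass(frozen=True)
class TrimParams:
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class FilterParams:
    min_len: int = 15
    max_len: int = 45
    q_threshold: int = 20
    q_fraction: float = 0.8


def trim_adapter(read: ReadRecord, params: TrimParams = TrimParams()) -> ReadRecord | None:
    """Trim the 3' adapter; return the insert, or None when no adapter found.

    The adapter may occur in full anywhere in the read, or as a prefix of
    itself overlapping the read's 3' end by at least ``min_overlap``
    bases.  Up to ``floor(max_error_rate * overlap)`` mismatches are
    allowed.  Among candidate positions the longest-overlap, then
    fewest-mismatch, match wins (i.e. the leftmost viable start).
    """
    if not read.sequence:
        return None
    seq = read.sequence
    adapter = params.adapter
    n, m = len(seq), len(adapter)
    best: tuple[int, int] | None = None  # (start, mismatches)
    for start in range(0, n - params.min_overlap + 1):
        overlap = min(m, n - start)
        if overlap < params.min_overlap:
            break
        # a full match must be the adapter itself; a partial match must
        # reach the read's 3' end (3'-anchored semantics)
        if overlap < m and start + overlap != n:
            continue
        allowed = int(params.max_error_rate * overlap)
        mism = 0
        for a, b in zip(seq[start:start + overlap], adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            best = (start, mism)
            break  # leftmost viable start has the longest overlap
    if best is None:
        return None
    start = best[0]
    return ReadRecord(read.read_id, seq[:start], read.qualities[:start])


def quality_length_filter(
    read: ReadRecord, params: FilterParams = FilterParams()
) -> bool:
    """Keep iff length within [min_len, max_len] and >= q_fraction of
    bases have quality strictly above q_threshold."""
    n = len(read.sequence)
    if not (params.min_len <= n <= params.max_len):
        return False
    good = sum(q > params.q_threshold for q in read.qualities)
    return good >= params.q_fraction * n


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_fastq(handle: Iterable[str]) -> Iterator[ReadRecord]:
    """Minimal streaming 4-line FASTQ parser (Phred+33)."""
    lines = iter(handle)
    index = 0
    while True:
        header = next(lines, None)
        if header is None:
            return
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ record at record {index}: "
                             f"header {header[:30]!r}")
        seq = next(lines, None)
        plus = next(lines, None)
        qual = next(lines, None)
        if qual is None or not plus.startswith("+"):
            raise ValueError(f"truncated FASTQ record at record {index}")
        seq = seq.strip().upper()
        qual = qual.strip()
        if len(seq) != len(qual):
            raise ValueError(
                f"sequence/quality length mismatch at record {index}"
            )
        yield ReadRecord(
            read_id=header[1:].strip().split()[0] if header[1:].strip() else f"read{index}",
            sequence=seq,
            qualities=tuple(ord(c) - 33 for c in qual),
        )
        index += 1


def preprocess_reads(
    reads: Iterable[ReadRecord],
    trim: TrimParams = TrimParams(),
    filt: FilterParams = FilterParams(),
) -> tuple[list[ReadRecord], PreprocessReport]:
    """Apply the adapter -> quality -> length cascade to a read stream.

    Per-read and order-independent: streaming equals batch processing.
    """
    report = PreprocessReport()
    retained: list[ReadRecord] = []
    for read in reads:
        report.total_reads += 1
        trimmed = trim_adapter(read, trim)
        if trimmed is None:
            continue
        report.with_adapter += 1
        n = len(trimmed.sequence)
        good = sum(q > filt.q_threshold for q in trimmed.qualities)
        if n and good < filt.q_fraction * n:
            continue
        report.passed_quality += 1
        if not (filt.min_len <= n <= filt.max_len):
            continue
        report.passed_length += 1
        retained.append(trimmed)
    return retained, report


def preprocess_fastq(
    fastq_path: str | Path,
    out_fasta: str | Path | None = None,
    report_json: str | Path | None = None,
    trim: TrimParams = TrimParams(),
    filt: FilterParams = FilterParams(),
) -> tuple[list[ReadRecord], PreprocessReport]:
    """Preprocess a FASTQ file (optionally gzipped).

    The report's ``total_reads`` is the raw read count of the file and
    is the RPM denominator downstream.  Retained reads are optionally
    written as FASTA, the report as JSON.
    """
    with _open_text(fastq_path) as handle:
        retained, report = preprocess_reads(parse_fastq(handle), trim, filt)
    if out_fasta is not None:
        with open(out_fasta, "w") as out:
            for read in retained:
                out.write(f">{read.read_id}\n{read.sequence}\n")
    if report_json is not None:
        Path(report_json).write_text(json.dumps(report.to_dict(), indent=2))
    return retained, report
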