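"""Fragment collapse, exact tRNA-space mapping, RPM normalization, filters.

Retained reads are collapsed to unique fragment sequences with counts,
then each fragment is searched as an exact, sense-strand substring of
every reference tRNA (the fragment space of a mature-tRNA mapper is
exact substrings; no mismatches or indels).  A fragment matching more
than one gene is a multimapper; for reporting it is assigned the *best*
gene -- the aligned gene with the highest total RPM coverage summed
over all samples -- with lexicographic gene_id as the deterministic
tie-break.

RPM uses the total raw read count of the original FASTQ as denominator,
not the mapped count, so unmappable library content dilutes RPM
realistically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ReadRecord
from .reference import TRNAGene, TRNAReference

__all__ = [
    "Alignment",
    "Fragment",
    "SampleInfo",
    "ExpressionTable",
    "TIMEPOINTS",
    "map_fragments",
    "count_fragments",
    "assign_best_gene",
    "normalize_rpm",
    "coverage_filter",
    "build_expression_table",
]

TIMEPOINTS = ("Start", "Healthy", "Sugar")


@dataclass(frozen=True)
class Alignment:
    """Exact placement of a fragment on one gene (0-based, half-open)."""

    gene_id: str
    start: int
    end: int


@dataclass
class Fragment:
    """A unique small-RNA sequence and its placements in tRNA space."""

    sequence: str
    alignments: tuple[Alignment, ...]
    best_gene: str | None = None

    @property
    def multimap_count(self) -> int:
        return len({a.gene_id for a in self.alignments})

    @property
    def exclusive(self) -> bool:
        """Maps to a single gene within this reference (genome-wide
        exclusivity is unknowable without a genome and reported as such)."""
        return self.multimap_count == 1

    def alignment_to(self, gene_id: str) -> Alignment:
        for a in self.alignments:
            if a.gene_id == gene_id:
                return a
        raise KeyError(f"fragment has no alignment to {gene_id}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    participant_id: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"{self.sample_id}: unknown timepoint {self.timepoint!r}; "
                f"expected one of {TIMEPOINTS}"
            )


@dataclass
class ExpressionTable:
    """Fragments x samples abundance matrix with sample metadata.

    ``rpm[f, s] = raw_counts[f, s] * 1e6 / library_totals[s]`` where the
    library total is the raw FASTQ read count of the sample.
    """

    fragments: list[Fragment]
    samples: list[SampleInfo]
    raw_counts: np.ndarray       # (n_fragments, n_samples) int
    library_totals: np.ndarray   # (n_samples,) int
    rpm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts)
        self.library_totals = np.asarray(self.library_totals)
        if self.raw_counts.shape != (len(self.fragments), len(self.samples)):
            raise ValueError("raw_counts shape does not match fragments x samples")
        self.rpm = normalize_rpm(self.raw_counts, self.library_totals)

    @property
    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]

    def sample_index(self, participant_id: str, timepoint: str) -> int:
        for i, s in enumerate(self.samples):
            if s.participant_id == participant_id and s.timepoint == timepoint:
                return i
        raise KeyError(f"no sample for {participant_id}/{timepoint}")

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    def complete_participants(self, timepoints: Sequence[str] = TIMEPOINTS) -> list[str]:
        """Participants contributing every requested timepoint."""
        have: dict[str, set[str]] = {}
        for s in self.samples:
            have.setdefault(s.participant_id, set()).add(s.timepoint)
        return [p for p in self.participants() if set(timepoints) <= have[p]]

    def subset(self, keep: np.ndarray) -> "ExpressionTable":
        keep = np.asarray(keep)
        return ExpressionTable(
            fragments=[f for f, k in zip(self.fragments, keep) if k],
            samples=self.samples,
            raw_counts=self.raw_counts[keep],
            library_totals=self.library_totals,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rpm,
            index=pd.Index(self.sequences, name="sequence"),
            columns=[s.sample_id for s in self.samples],
        )
        return df


def find_alignments(sequence: str, ref: TRNAReference) -> tuple[Alignment, ...]:
    """All exact, sense-strand placements of ``sequence`` in the reference."""
    hits: list[Alignment] = []
    for gene in ref:
        start = gene.sequence.find(sequence)
        while start >= 0:
            hits.append(Alignment(gene.gene_id, start, start + len(sequence)))
            start = gene.sequence.find(sequence, start + 1)
    return tuple(hits)


def count_fragments(reads: Iterable[ReadRecord | str]) -> Counter[str]:
    """Collapse identical read sequences to a fragment -> count table."""
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        counts[seq] += 1
    return counts


def map_fragments(
    reads: Iterable[ReadRecord | str],
    ref: TRNAReference,
) -> tuple[list[Fragment], Counter[str], int]:
    """Collapse reads and map each unique sequence into tRNA space.

    Returns (mapped fragments, per-fragment read counts, number of
    unmapped reads).  Unmapped sequences are discarded but tallied.
    Order-invariant: any count-preserving shuffle of the reads yields
    the same result.
    """
    counts = count_fragments(reads)
    fragments: list[Fragment] = []
    mapped_counts: Counter[str] = Counter()
    unmapped_reads = 0
    for seq in sorted(counts):
        alignments = find_alignments(seq, ref)
        if alignments:
            fragments.append(Fragment(sequence=seq, alignments=alignments))
            mapped_counts[seq] = counts[seq]
        else:
            unmapped_reads += counts[seq]
    return fragments, mapped_counts, unmapped_reads


def normalize_rpm(
    raw_counts: np.ndarray, library_totals: np.ndarray
) -> np.ndarray:
    """Reads-per-million against the raw library totals."""
    raw_counts = np.asarray(raw_counts, dtype=float)
    library_totals = np.asarray(library_totals, dtype=float)
    if np.any(library_totals <= 0):
        raise ValueError("library totals must be strictly positive")
    return raw_counts * 1e6 / library_totals


def gene_rpm_coverage(
    fragments: Sequence[Fragment], rpm: np.ndarray
) -> dict[str, float]:
    """Total RPM (summed over samples) of fragments aligning to each gene.

    Every alignment contributes its fragment's full RPM: coverage here
    answers "how much signal could this gene explain", the quantity the
    best-gene rule ranks.
    """
    totals: dict[str, float] = {}
    frag_totals = np.asarray(rpm).sum(axis=1)
    for frag, total in zip(fragments, frag_totals):
        for gene_id in {a.gene_id for a in frag.alignments}:
            totals[gene_id] = totals.get(gene_id, 0.0) + float(total)
    return totals


def assign_best_gene(
    fragments: Sequence[Fragment], rpm: np.ndarray
) -> list[Fragment]:
    """Set ``best_gene`` = aligned gene with the highest total RPM coverage.

    Ties break lexicographically by gene_id.  Mutates and returns the
    fragment list.
    """
    coverage = gene_rpm_coverage(fragments, rpm)
    for frag in fragments:
        candidates = sorted({a.gene_id for a in frag.alignments})
        frag.best_gene = sorted(
            candidates, key=lambda g: (-coverage.get(g, 0.0), g)
        )[0]
    return list(fragments)


def coverage_filter(
    table: ExpressionTable,
    min_rpm: float = 1.0,
    min_sample_fraction: float = 0.33,
    min_len: int = 16,
    max_len: int = 45,
) -> ExpressionTable:
    """Abundance and size filter on the fragment table.

    Keep a fragment iff it reaches ``min_rpm`` in at least
    ``ceil(min_sample_fraction * n_samples)`` samples and its length is
    within [min_len, max_len].  ``min_rpm=1`` is the tRNA-space default;
    0.01 is the permissive preset used for whole-library biotype scans.
    """
    n_samples = len(table.samples)
    need = int(np.ceil(min_sample_fraction * n_samples))
    enough = (table.rpm >= min_rpm).sum(axis=1) >= need
    sized = np.array(
        [min_len <= len(f.sequence) <= max_len for f in table.fragments]
    )
    return table.subset(enough & sized)


def build_expression_table(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    samples: Sequence[SampleInfo],
    library_totals: Mapping[str, int],
    ref: TRNAReference,
) -> tuple[ExpressionTable, dict[str, int]]:
    """Assemble an ExpressionTable from per-sample fragment counts.

    ``per_sample_counts`` maps sample_id -> {fragment sequence: count}.
    Fragments are mapped once against the reference; unmapped sequences
    are tallied per sample.  Best genes are assigned from the pooled RPM.
    """
    all_seqs = sorted({s for c in per_sample_counts.values() for s in c})
    fragments: list[Fragment] = []
    unmapped: dict[str, int] = {s.sample_id: 0 for s in samples}
    kept_seqs: list[str] = []
    for seq in all_seqs:
        alignments = find_alignments(seq, ref)
        if alignments:
            fragments.append(Fragment(sequence=seq, alignments=alignments))
            kept_seqs.append(seq)
        else:
            for s in samples:
                unmapped[s.sample_id] += per_sample_counts.get(s.sample_id, {}).get(seq, 0)
    counts = np.array(
        [
            [per_sample_counts.get(s.sample_id, {}).get(seq, 0) for s in samples]
            for seq in kept_seqs
        ],
        dtype=int,
    ).reshape(len(kept_seqs), len(samples))
    totals = np.array([library_totals[s.sample_id] for s in samples], dtype=int)
    table = ExpressionTable(
        fragments=fragments, samples=list(samples),
        raw_counts=counts, library_totals=totals,
    )
    assign_best_gene(table.fragments, table.rpm)
    return table, unmapped
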