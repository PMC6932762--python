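"""Mature tRNA reference space with cloverleaf loop annotation.

A mature tRNA is modelled as its nucleotide sequence (ending in the
universal 3' CCA tail) plus three annotated loop spans -- D-loop,
anticodon loop and T-loop (the TpsiC loop) -- given as 0-based,
half-open intervals on the mature sequence.  The T-loop carries two
derived attributes used throughout the cleavage analysis:

* a *standardized start*: the first occurrence of the conserved TTC
  motif inside the loop, falling back to ATC, then to the loop's first
  5' nucleotide;
* a flag for the TTCGA motif, the pseudouridine-synthase recognition
  sequence that defines the sugar-sensitive nitRNA class.

Coordinates are 0-based half-open everywhere in code; human-readable
reports convert to 1-based closed form.  Coverage plots optionally pad
the coordinate axis by ``padding`` positions at each end (mirroring the
NNN padding convention of tRNA-space mappers); padding never affects
sequence matching.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Origin",
    "TRNAGene",
    "TRNAReference",
    "ReferenceError",
    "load_reference",
    "write_reference",
    "standardize_t_loop_start",
    "t_loop_motif_census",
]

ANNOTATION_COLUMNS = [
    "gene_id",
    "isodecoder",
    "origin",
    "d_loop_start",
    "d_loop_end",
    "ac_loop_start",
    "ac_loop_end",
    "t_loop_start",
    "t_loop_end",
]


class ReferenceError(ValueError):
    """Raised when a reference bundle violates a structural invariant."""


class Origin(str, enum.Enum):
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"
    LOOKALIKE = "lookalike"


@dataclass(frozen=True)
class TRNAGene:
    """One mature tRNA sequence with loop annotation.

    ``d_loop``, ``anticodon_loop`` and ``t_loop`` are 0-based half-open
    spans on ``sequence``; ``t_loop_start`` is the standardized T-loop
    start position (mature coordinates) and ``has_ttcga`` flags a TTCGA
    motif anywhere inside the T-loop span.
    """

    gene_id: str
    isodecoder: str
    origin: Origin
    sequence: str
    d_loop: tuple[int, int]
    anticodon_loop: tuple[int, int]
    t_loop: tuple[int, int]
    t_loop_start: int = field(default=-1)
    has_ttcga: bool = field(default=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq.endswith("CCA"):
            raise ReferenceError(
                f"{self.gene_id}: mature tRNA sequence must end with CCA "
                f"(got ...{seq[-3:]})"
            )
        if set(seq) - set("ACGT"):
            raise ReferenceError(
                f"{self.gene_id}: sequence contains non-ACGT characters"
            )
        spans = [self.d_loop, self.anticodon_loop, self.t_loop]
        for name, (s, e) in zip(("d_loop", "anticodon_loop", "t_loop"), spans):
            if not (0 <= s < e <= len(seq)):
                raise ReferenceError(
                    f"{self.gene_id}: malformed {name} span [{s}, {e}) on a "
                    f"{len(seq)}-nt sequence"
                )
        if not (self.d_loop[1] <= self.anticodon_loop[0]
                and self.anticodon_loop[1] <= self.t_loop[0]):
            raise ReferenceError(
                f"{self.gene_id}: loop spans must be non-overlapping and "
                "ordered D-loop < anticodon loop < T-loop"
            )
        # derive standardized start / motif flag on construction
        object.__setattr__(
            self, "t_loop_start", standardize_t_loop_start(seq, self.t_loop)
        )
        object.__setattr__(
            self, "has_ttcga", "TTCGA" in seq[self.t_loop[0]:self.t_loop[1]]
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def t_loop_seq(self) -> str:
        return self.sequence[self.t_loop[0]:self.t_loop[1]]

    @property
    def anticodon_midpoint(self) -> int:
        """Floor of the anticodon-loop span's centre (mature coordinate).

        Used as the half-boundary: a 5'-half ends at this position and a
        3'-half starts at the next one.
        """
        s, e = self.anticodon_loop
        return (s + e - 1) // 2

    @property
    def start_anchor(self) -> str:
        """Which motif rule fixed the standardized T-loop start."""
        loop = self.t_loop_seq
        off = self.t_loop_start - self.t_loop[0]
        if loop[off:off + 3] == "TTC" and loop.find("TTC") == off:
            return "TTC"
        if loop[off:off + 3] == "ATC" and "TTC" not in loop:
            return "ATC"
        return "first_nt"


def standardize_t_loop_start(sequence: str, t_loop: tuple[int, int]) -> int:
    """Standardized T-loop start position in mature-tRNA coordinates.

    First occurrence of TTC inside the T-loop span; if absent, first ATC;
    if both absent, the loop's first 5' nucleotide.  Depends only on the
    subsequence inside the span, and is idempotent by construction.
    """
    s, e = t_loop
    loop = sequence[s:e]
    for motif in ("TTC", "ATC"):
        off = loop.find(motif)
        if off >= 0:
            return s + off
    return s


@dataclass(frozen=True)
class TRNAReference:
    """A collection of annotated tRNA genes with unique identifiers."""

    genes: tuple[TRNAGene, ...]
    padding: int = 3

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceError(f"duplicate gene_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> TRNAGene:
        return self._by_id[gene_id]

    @property
    def _by_id(self) -> dict[str, TRNAGene]:
        return {g.gene_id: g for g in self.genes}

    def analysis_genes(self) -> tuple[TRNAGene, ...]:
        """Genes entering nuclear/mitochondrial contrasts (no lookalikes)."""
        return tuple(g for g in self.genes if g.origin is not Origin.LOOKALIKE)


def _parse_origin(value: str, gene_id: str) -> Origin:
    try:
        return Origin(value.strip().lower())
    except ValueError as exc:
        raise ReferenceError(
            f"{gene_id}: unknown origin {value!r} "
            f"(expected nuclear/mitochondrial/lookalike)"
        ) from exc


def load_reference(
    fasta_path: str | Path,
    annotation_path: str | Path,
    *,
    append_cca: bool = False,
    padding: int = 3,
) -> TRNAReference:
    """Load a reference bundle: multi-record FASTA plus a loop-annotation TSV.

    The TSV must carry named columns ``gene_id, isodecoder, origin,
    d_loop_start, d_loop_end, ac_loop_start, ac_loop_end, t_loop_start,
    t_loop_end`` with 0-based half-open spans.  Sequences are uppercased
    and U is converted to T.  ``append_cca=True`` repairs records whose
    mature sequence lacks the terminal CCA instead of rejecting them.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"gene_id": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ReferenceError(f"annotation is missing columns: {missing_cols}")
    ann = ann.set_index("gene_id", verify_integrity=True)

    genes: list[TRNAGene] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = record.id
        if gene_id not in ann.index:
            raise ReferenceError(f"no annotation row for FASTA record {gene_id!r}")
        seen.add(gene_id)
        row = ann.loc[gene_id]
        seq = str(record.seq).upper().replace("U", "T")
        if append_cca and not seq.endswith("CCA"):
            seq += "CCA"
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                isodecoder=str(row["isodecoder"]),
                origin=_parse_origin(str(row["origin"]), gene_id),
                sequence=seq,
                d_loop=(int(row["d_loop_start"]), int(row["d_loop_end"])),
                anticodon_loop=(int(row["ac_loop_start"]), int(row["ac_loop_end"])),
                t_loop=(int(row["t_loop_start"]), int(row["t_loop_end"])),
            )
        )
    orphans = set(ann.index) - seen
    if orphans:
        raise ReferenceError(
            f"annotation rows without FASTA records: {sorted(orphans)}"
        )
    return TRNAReference(genes=tuple(genes), padding=padding)


def write_reference(ref: TRNAReference, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the bundle as ``reference/{trna.fasta, loops.tsv}``; round-trips."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = out / "trna.fasta"
    loops_path = out / "loops.tsv"
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in ref.genes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "gene_id": g.gene_id,
            "isodecoder": g.isodecoder,
            "origin": g.origin.value,
            "d_loop_start": g.d_loop[0],
            "d_loop_end": g.d_loop[1],
            "ac_loop_start": g.anticodon_loop[0],
            "ac_loop_end": g.anticodon_loop[1],
            "t_loop_start": g.t_loop[0],
            "t_loop_end": g.t_loop[1],
        }
        for g in ref.genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        loops_path, sep="\t", index=False
    )
    return fasta_path, loops_path


def t_loop_motif_census(ref: TRNAReference) -> dict[str, float]:
    """T-loop motif census over all genes in the reference.

    Percentages (rounded to one decimal) of genes whose T-loop contains
    TTCGA, whose standardized start anchors on TTC / ATC / the fallback
    first nucleotide, and the mitochondrial share within the TTCGA and
    non-TTCGA groups.  The mutually exclusive anchor categories sum to
    100% within rounding.
    """
    if len(ref) == 0:
        raise ReferenceError("cannot compute a census of an empty reference")
    n = len(ref)

    def pct(k: int, d: int) -> float:
        return round(100.0 * k / d, 1) if d else float("nan")

    ttcga = [g for g in ref if g.has_ttcga]
    non_ttcga = [g for g in ref if not g.has_ttcga]
    anchors = [g.start_anchor for g in ref]
    return {
        "n_genes": n,
        "pct_ttcga": pct(len(ttcga), n),
        "pct_start_ttc": pct(anchors.count("TTC"), n),
        "pct_start_atc": pct(anchors.count("ATC"), n),
        "pct_start_fallback": pct(anchors.count("first_nt"), n),
        "pct_mito_among_ttcga": pct(
            sum(g.origin is Origin.MITOCHONDRIAL for g in ttcga), len(ttcga)
        ),
        "pct_mito_among_non_ttcga": pct(
            sum(g.origin is Origin.MITOCHONDRIAL for g in non_ttcga),
            len(non_ttcga),
        ),
    }
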