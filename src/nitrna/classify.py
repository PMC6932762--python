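"""tsRNA subtype calls, T-loop cleavage distances and coverage profiles.

Subtype definitions follow the mature-tRNA fragment convention:

* 5'-fragments align with their first position at mature position 1;
  a 5'-half ends exactly at the anticodon-loop midpoint, any other
  start-anchored fragment is a 5'-tsRNA.
* 3'-fragments carry the terminal CCA; a 3'-half starts exactly one
  nucleotide after the midpoint, any other CCA-terminal fragment is a
  3'-tsRNA.
* everything else -- neither start- nor CCA-anchored -- is an internal
  fragment (i-tsRNA).

The midpoint is the floor of the anticodon-loop span's centre, the
position adjacent to the wobble base, i.e. the canonical anticodon
cleavage site derivable from the loop span alone.

A *nitRNA* (nuclear internal T-loop tsRNA) is an i-tsRNA of a nuclear
gene whose T-loop contains the TTCGA motif and whose 3' end falls
inside the T-loop span.  The cleavage-distance coordinate is
``3'-terminal position - standardized T-loop start`` (0 at the start
nucleotide, negative upstream, positive downstream).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import Alignment, ExpressionTable, Fragment, TIMEPOINTS
from .reference import Origin, TRNAGene, TRNAReference

__all__ = [
    "Subtype",
    "SubtypeCall",
    "CoverageProfile",
    "discretize_rpm",
    "classify_subtype",
    "t_loop_distance",
    "consensus_distance",
    "annotate_fragments",
    "build_coverage_profiles",
    "cut_site_significance_map",
]


class Subtype(str, enum.Enum):
    FIVE_HALF = "five_half"
    FIVE_TSRNA = "five_tsRNA"
    I_TSRNA = "i_tsRNA"
    THREE_TSRNA = "three_tsRNA"
    THREE_HALF = "three_half"


@dataclass(frozen=True)
class SubtypeCall:
    subtype: Subtype
    is_nitrna: bool
    t_loop_distance: int | None
    origin: Origin

    def __post_init__(self) -> None:
        if self.is_nitrna and (
            self.origin is not Origin.NUCLEAR or self.subtype is not Subtype.I_TSRNA
        ):
            raise ValueError("nitRNA implies a nuclear internal fragment")


def discretize_rpm(rpm: np.ndarray | float) -> np.ndarray | int:
    """Round RPM half-away-from-zero to integers for count modelling."""
    arr = np.asarray(rpm, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    out = out.astype(int)
    return int(out) if out.ndim == 0 else out


def classify_subtype(
    fragment: Fragment | Alignment, gene: TRNAGene,
    alignment: Alignment | None = None,
) -> SubtypeCall:
    """Classify one fragment placement on its (best) gene.

    Accepts a Fragment (using its alignment to ``gene``) or a bare
    Alignment.  Start-anchored rules are checked before CCA-anchored
    ones, so a hypothetical full-length placement is start-classified.
    """
    if alignment is None:
        alignment = (
            fragment if isinstance(fragment, Alignment)
            else fragment.alignment_to(gene.gene_id)
        )
    if not (0 <= alignment.start < alignment.end <= len(gene)):
        raise ValueError(
            f"alignment [{alignment.start}, {alignment.end}) outside "
            f"{gene.gene_id} (length {len(gene)})"
        )
    last = alignment.end - 1  # 3'-terminal nucleotide position
    mid = gene.anticodon_midpoint
    if alignment.start == 0:
        subtype = Subtype.FIVE_HALF if last == mid else Subtype.FIVE_TSRNA
    elif alignment.end == len(gene):
        subtype = Subtype.THREE_HALF if alignment.start == mid + 1 else Subtype.THREE_TSRNA
    else:
        subtype = Subtype.I_TSRNA
    dist = t_loop_distance(alignment, gene)
    in_t_loop = gene.t_loop[0] <= last < gene.t_loop[1]
    is_nitrna = (
        subtype is Subtype.I_TSRNA
        and gene.origin is Origin.NUCLEAR
        and gene.has_ttcga
        and in_t_loop
    )
    return SubtypeCall(
        subtype=subtype, is_nitrna=is_nitrna,
        t_loop_distance=dist, origin=gene.origin,
    )


def t_loop_distance(alignment: Alignment, gene: TRNAGene) -> int:
    """Signed distance from the fragment 3' end to the standardized
    T-loop start: 0 on the start nucleotide, negative upstream."""
    return (alignment.end - 1) - gene.t_loop_start


def five_prime_distance(alignment: Alignment, gene: TRNAGene) -> int:
    """Companion coordinate for 5' cut-sites (start vs T-loop start)."""
    return alignment.start - gene.t_loop_start


def consensus_distance(fragment: Fragment, ref: TRNAReference) -> int:
    """Modal T-loop distance across a fragment's alignments.

    Multimapping fragments take the most common distance over all their
    placements; on a tie the distance of the best-gene placement wins
    (falling back to the smallest tied value if best_gene is unset).
    """
    if not fragment.alignments:
        raise ValueError("fragment has no alignments")
    dists = [t_loop_distance(a, ref[a.gene_id]) for a in fragment.alignments]
    counts: dict[int, int] = {}
    for d in dists:
        counts[d] = counts.get(d, 0) + 1
    top = max(counts.values())
    modes = sorted(d for d, c in counts.items() if c == top)
    if len(modes) == 1:
        return modes[0]
    if fragment.best_gene is not None:
        best_d = t_loop_distance(
            fragment.alignment_to(fragment.best_gene), ref[fragment.best_gene]
        )
        if best_d in modes:
            return best_d
    return modes[0]


def annotate_fragments(
    fragments: Sequence[Fragment], ref: TRNAReference
) -> pd.DataFrame:
    """Per-fragment annotation table on the best-gene placement."""
    rows = []
    for frag in fragments:
        gene = ref[frag.best_gene]
        call = classify_subtype(frag, gene)
        rows.append(
            {
                "sequence": frag.sequence,
                "length": len(frag.sequence),
                "best_gene": frag.best_gene,
                "isodecoder": gene.isodecoder,
                "origin": gene.origin.value,
                "subtype": call.subtype.value,
                "is_nitrna": call.is_nitrna,
                "t_loop_distance": consensus_distance(frag, ref),
                "has_ttcga": gene.has_ttcga,
                "multimap_count": frag.multimap_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "length", "best_gene", "isodecoder", "origin",
            "subtype", "is_nitrna", "t_loop_distance", "has_ttcga",
            "multimap_count",
        ],
    )


@dataclass
class CoverageProfile:
    """Discretized-RPM coverage of one gene in padded coordinates.

    Arrays span positions ``-padding .. L+padding-1``; index ``i``
    corresponds to mature position ``i - padding``.  The padding mirrors
    the NNN-extension convention of tRNA-space mappers and exists only
    for plotting alignment; fragments never cover padded positions, so
    sums over the padded axis equal sums over mature positions.
    """

    gene_id: str
    condition: str
    padding: int
    coverage: np.ndarray
    start_site_expression: np.ndarray
    end_site_expression: np.ndarray

    def position_axis(self) -> np.ndarray:
        return np.arange(len(self.coverage)) - self.padding


def build_coverage_profiles(
    table: ExpressionTable,
    ref: TRNAReference,
    by_condition: bool = True,
) -> dict[tuple[str, str], CoverageProfile]:
    """Per-gene, per-condition coverage and cut-site profiles.

    Each fragment contributes its discretized RPM (summed over the
    condition's samples) to every mature position it covers on its best
    gene, and to its 5' start and 3' end positions.  Conservation holds
    by construction: total start-site = total end-site = total assigned
    fragment RPM per gene and condition.
    """
    conditions: dict[str, list[int]]
    if by_condition:
        conditions = {t: [] for t in TIMEPOINTS}
        for j, s in enumerate(table.samples):
            conditions.setdefault(s.timepoint, []).append(j)
        conditions = {t: idx for t, idx in conditions.items() if idx}
    else:
        conditions = {"all": list(range(len(table.samples)))}

    profiles: dict[tuple[str, str], CoverageProfile] = {}
    pad = ref.padding
    disc = discretize_rpm(table.rpm)
    for cond, cols in conditions.items():
        per_gene: dict[str, CoverageProfile] = {}
        for frag, row in zip(table.fragments, disc):
            gene = ref[frag.best_gene]
            total = int(row[cols].sum())
            if gene.gene_id not in per_gene:
                n = len(gene) + 2 * pad
                per_gene[gene.gene_id] = CoverageProfile(
                    gene_id=gene.gene_id, condition=cond, padding=pad,
                    coverage=np.zeros(n, dtype=int),
                    start_site_expression=np.zeros(n, dtype=int),
                    end_site_expression=np.zeros(n, dtype=int),
                )
            prof = per_gene[gene.gene_id]
            aln = frag.alignment_to(gene.gene_id)
            prof.coverage[aln.start + pad:aln.end + pad] += total
            prof.start_site_expression[aln.start + pad] += total
            prof.end_site_expression[aln.end - 1 + pad] += total
        for gene_id, prof in per_gene.items():
            profiles[(gene_id, cond)] = prof
    return profiles


def cut_site_significance_map(
    diff_results: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-fragment cleavage coordinates with differential results.

    The output is the table behind the positional significance plots:
    one row per fragment with its consensus T-loop distance, origin,
    TTCGA status of the best gene, the contrast p-value/fold change and
    per-condition mean RPM.  Empty differential input yields an empty
    table with the same columns.
    """
    cols = [
        "sequence", "t_loop_distance", "origin", "has_ttcga", "subtype",
        "is_nitrna",
    ]
    base = annotations[cols] if len(annotations) else pd.DataFrame(columns=cols)
    keep = [
        c for c in ("unit_id", "p_value", "fold_change", "log_fold_change")
        if c in diff_results.columns
    ] + [c for c in diff_results.columns if c.startswith("mean_rpm")]
    if len(diff_results) == 0:
        merged = base.iloc[0:0].reindex(
            columns=cols + [c for c in keep if c != "unit_id"]
        )
        return merged
    merged = base.merge(
        diff_results[keep], left_on="sequence", right_on="unit_id", how="inner"
    ).drop(columns=["unit_id"])
    return merged
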