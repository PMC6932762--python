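"""Worked example: the sugar-sensitive human tRNA-Lys-CTT nitRNA.

The best-characterized sugar-sensitive fragment is a 30-nt internal
fragment of nuclear tRNA-Lys-CTT whose 5' cut lies in the anticodon arm
between the D-loop and the anticodon loop and whose 3' cut lies inside
the TTCGA-containing T-loop.  Its 3' end is fixed by the stem-loop
RT primer used for its qPCR validation (3' overhang AACCCA, i.e. the
fragment ends ...TGGGTT) and its body contains the forward qPCR primer
TGGGACTCTTAATCCCAGGG, which anchors both cut sites on the public human
tRNA-Lys-CTT sequence reproduced below.

Loop spans follow the canonical cloverleaf numbering of this tRNA:
D-loop around positions 14-21, anticodon loop 32-38 (anticodon CTT at
34-36) and T-loop 53-59, all 1-based; stored 0-based half-open.
"""

from __future__ import annotations

from .mapping import Alignment, Fragment
from .reference import Origin, TRNAGene, TRNAReference

__all__ = [
    "LYS_CTT_GENE",
    "LYS_CTT_FRAGMENT_SEQ",
    "lys_ctt_reference",
    "lys_ctt_fragment",
]

# Mature human tRNA-Lys-CTT (nuclear), 3' CCA appended.
_LYS_CTT_SEQ = (
    "GCCCGGCTAGCTCAGTCGGTAGAGCATGGGACTCTTAATCCCAGGGTCGTGGGTTCGAGCCCCACGTTGGGCG"
    "CCA"
)

LYS_CTT_GENE = TRNAGene(
    gene_id="tRNA-Lys-CTT-1-1",
    isodecoder="LysCTT",
    origin=Origin.NUCLEAR,
    sequence=_LYS_CTT_SEQ,
    d_loop=(13, 22),          # AGTCGGTAG
    anticodon_loop=(31, 38),  # CTCTTAA, anticodon CTT at 33-35 (0-based)
    t_loop=(52, 59),          # GTTCGAG, contains TTCGA
)

# The 30-nt sugar-sensitive fragment: anticodon-arm 5' cut, T-loop 3' cut.
LYS_CTT_FRAGMENT_SEQ = "ATGGGACTCTTAATCCCAGGGTCGTGGGTT"


def lys_ctt_reference() -> TRNAReference:
    return TRNAReference(genes=(LYS_CTT_GENE,))


def lys_ctt_fragment() -> Fragment:
    start = _LYS_CTT_SEQ.find(LYS_CTT_FRAGMENT_SEQ)
    assert start >= 0
    return Fragment(
        sequence=LYS_CTT_FRAGMENT_SEQ,
        alignments=(
            Alignment(LYS_CTT_GENE.gene_id, start,
                      start + len(LYS_CTT_FRAGMENT_SEQ)),
        ),
        best_gene=LYS_CTT_GENE.gene_id,
    )
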