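"""Synthetic references, reads and truth sets for pipeline validation.

The generator emulates the statistical structure the analysis assumes:

* a reference of cloverleaf-annotated genes -- nuclear (~76 nt) and
  mitochondrial (~68 nt) -- whose T-loops carry a TTCGA motif, a TTC
  motif without the GA extension, an ATC anchor, or no anchor at all;
* a fragment population per gene covering the five positional subtypes,
  where the internal fragments of TTCGA nuclear genes end inside the
  T-loop (the nitRNA configuration);
* negative-binomial counts (variance mu + mu^2/theta) with a log-normal
  per-participant random intercept, a Sugar-only fold change on the
  designated sugar-sensitive fragments, and a monotone
  Start -> Healthy -> Sugar trend on mitochondrial fragments;
* FASTQ reads (fragment + 3' adapter + filler) padded with unmappable
  decoy reads so that RPM denominators reflect raw library totals.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER
from .mapping import SampleInfo, TIMEPOINTS
from .reference import Origin, TRNAGene, TRNAReference, write_reference

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_reference",
    "simulate_reads",
    "simulate_counts",
    "simulate_paired_counts",
    "simulate_motility",
]

_NUCLEAR_ISODECODERS = [
    "LysCTT", "ArgCCG", "ArgCCT", "LeuCAA", "GlyGCC", "GlyCCC",
    "GluCTC", "GluTTC", "ValAAC", "AspGTC", "HisGTG", "SerGCT",
]
_MITO_ISODECODERS = [
    "MT_SerTGA", "MT_LeuTAA", "MT_ValTAC", "MT_GluTTC", "MT_LysTTT",
    "MT_HisGTG",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation settings.

    ``baseline_mean`` is the expected RPM of a fragment in a null
    sample; with ``library_size`` raw reads per sample the expected read
    count is ``baseline_mean * library_size / 1e6``.  ``effect_fc``
    multiplies sugar-sensitive fragment means at the Sugar timepoint
    only; ``mito_trend_fc`` multiplies mitochondrial fragment means once
    at Healthy and twice at Sugar (a progressive rise over the diet
    course).
    """

    n_nuclear_genes: int = 10
    n_mito_genes: int = 4
    fraction_ttcga: float = 0.5
    n_participants: int = 15
    timepoints: tuple[str, ...] = TIMEPOINTS
    fragments_per_gene: int = 4
    baseline_mean: float = 500.0       # RPM
    dispersion: float = 5.0            # NB size parameter theta
    participant_sd: float = 0.3        # SD of log-scale random intercept
    effect_fc: float = 4.0
    mito_trend_fc: float = 1.5
    library_size: int = 20_000         # raw reads per sample
    decoy_fraction: float = 0.3        # used when library_size is None
    quality_pass_rate: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nuclear_genes, self.n_mito_genes, self.n_participants,
               self.fragments_per_gene) <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.fraction_ttcga <= 1):
            raise ValueError("fraction_ttcga must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth for one simulated dataset."""

    fragments: pd.DataFrame          # sequence, gene_id, subtype, is_nitrna,
                                     # effect_class, true_fc
    participant_intercepts: pd.Series  # participant -> b_i (log scale)
    expected_counts: pd.DataFrame | None = None
    motility: pd.DataFrame | None = None
    true_motility_r: float | None = None


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _t_loop_seq(rng: np.random.Generator, kind: str) -> str:
    """An 8-nt T-loop with a controlled anchor motif."""
    if kind == "ttcga":
        return "G" + "TTCGA" + _rand_seq(rng, 2)
    if kind == "ttc":
        # TTC anchor but never TTCGA
        while True:
            loop = "G" + "TTCA" + _rand_seq(rng, 3)
            if "TTCGA" not in loop:
                return loop
    if kind == "atc":
        while True:
            loop = "GG" + "ATC" + _rand_seq(rng, 3)
            if "TTC" not in loop and "TTCGA" not in loop:
                return loop
    # fallback: purine-only loop, cannot contain TTC or ATC
    return _rand_seq(rng, 8, alphabet="AG")


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    isodecoder: str,
    origin: Origin,
    t_loop_kind: str,
) -> TRNAGene:
    if origin is Origin.MITOCHONDRIAL:
        seg = [12, 8, 9, 7, 9, 8, 12]   # total 65 + CCA = 68
    else:
        seg = [14, 9, 10, 7, 12, 8, 13]  # total 73 + CCA = 76
    s1 = _rand_seq(rng, seg[0])
    d_loop = _rand_seq(rng, seg[1])
    s2 = _rand_seq(rng, seg[2])
    ac_loop = _rand_seq(rng, seg[3])
    s3 = _rand_seq(rng, seg[4])
    t_loop = _t_loop_seq(rng, t_loop_kind)
    s4 = _rand_seq(rng, seg[6])
    seq = s1 + d_loop + s2 + ac_loop + s3 + t_loop + s4 + "CCA"
    o = np.cumsum([0] + [len(p) for p in (s1, d_loop, s2, ac_loop, s3, t_loop)])
    return TRNAGene(
        gene_id=gene_id,
        isodecoder=isodecoder,
        origin=origin,
        sequence=seq,
        d_loop=(int(o[1]), int(o[2])),
        anticodon_loop=(int(o[3]), int(o[4])),
        t_loop=(int(o[5]), int(o[6])),
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def simulate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    multimap_fixture: bool = False,
    max_retries: int = 200,
) -> TRNAReference:
    """Generate an annotated reference with pairwise-unique 16-mers.

    Nuclear genes receive TTCGA T-loops for ``fraction_ttcga`` of their
    number (the rest split among TTC / ATC / fallback anchors);
    mitochondrial genes get non-TTCGA TTC loops.  With
    ``multimap_fixture=True`` the first two nuclear genes share a
    deliberate 20-mer so multimapping paths can be exercised.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes: list[TRNAGene] = []
    used_kmers: set[str] = set()
    n_ttcga = round(config.fraction_ttcga * config.n_nuclear_genes)
    kinds = ["ttcga"] * n_ttcga
    rest = config.n_nuclear_genes - n_ttcga
    for i in range(rest):
        kinds.append(["ttc", "atc", "fallback"][i % 3])
    specs = [
        (f"tRNA-{_NUCLEAR_ISODECODERS[i % len(_NUCLEAR_ISODECODERS)]}-{i + 1}",
         _NUCLEAR_ISODECODERS[i % len(_NUCLEAR_ISODECODERS)],
         Origin.NUCLEAR, kinds[i])
        for i in range(config.n_nuclear_genes)
    ] + [
        (f"tRNA-{_MITO_ISODECODERS[j % len(_MITO_ISODECODERS)]}-{j + 1}",
         _MITO_ISODECODERS[j % len(_MITO_ISODECODERS)],
         Origin.MITOCHONDRIAL, "ttc")
        for j in range(config.n_mito_genes)
    ]
    for gene_id, isodecoder, origin, kind in specs:
        for attempt in range(max_retries):
            gene = _build_gene(rng, gene_id, isodecoder, origin, kind)
            km = _kmers(gene.sequence, 16)
            if not (km & used_kmers):
                used_kmers |= km
                genes.append(gene)
                break
        else:
            raise RuntimeError(
                "could not generate pairwise-unique 16-mers; request fewer "
                "or longer genes"
            )
    if multimap_fixture and len(genes) >= 2:
        a, b = genes[0], genes[1]
        shared = a.sequence[20:40]  # 20-mer from the first gene's body
        seq_b = b.sequence[:20] + shared + b.sequence[40:]
        genes[1] = replace(b, sequence=seq_b[:-3] + "CCA")
    return TRNAReference(genes=tuple(genes))


def _design_fragments(ref: TRNAReference, per_gene: int) -> pd.DataFrame:
    """Deterministic fragment population covering the subtype space.

    Per gene: a 5'-tsRNA, a 5'-half, an internal fragment ending inside
    the T-loop (a nitRNA when the gene is nuclear with a TTCGA loop),
    and a 3'-tsRNA; more slots cycle through extra internal fragments.
    """
    rows = []
    for gene in ref:
        L = len(gene)
        mid = gene.anticodon_midpoint
        spans = [
            ("five_tsRNA", 0, 20),
            ("five_half", 0, mid + 1),
            ("i_tsRNA", gene.anticodon_loop[0] - 4, gene.t_loop_start + 3),
            ("three_tsRNA", L - 22, L),
        ]
        extra = 0
        while len(spans) < per_gene:
            extra += 1
            spans.append(
                ("i_tsRNA", gene.d_loop[1] + extra, gene.t_loop[0] - 2 + extra)
            )
        for subtype, start, end in spans[:per_gene]:
            start, end = max(start, 0), min(end, L)
            if not (16 <= end - start <= 45):
                continue
            seq = gene.sequence[start:end]
            ends_in_t_loop = gene.t_loop[0] <= end - 1 < gene.t_loop[1]
            is_nitrna = (
                subtype == "i_tsRNA"
                and gene.origin is Origin.NUCLEAR
                and gene.has_ttcga
                and ends_in_t_loop
            )
            if gene.origin is Origin.MITOCHONDRIAL:
                effect_class = "mito_trend"
                block = "mito_response"
            elif is_nitrna:
                effect_class = "sugar_sensitive"
                block = "nuclear_response"
            else:
                effect_class = "null"
                block = f"solo_{gene.gene_id}_{start}_{end}"
            rows.append(
                {
                    "sequence": seq, "gene_id": gene.gene_id,
                    "isodecoder": gene.isodecoder,
                    "origin": gene.origin.value, "start": start, "end": end,
                    "subtype": subtype, "is_nitrna": is_nitrna,
                    "effect_class": effect_class,
                    "co_regulation_block": block,
                }
            )
    df = pd.DataFrame(rows).drop_duplicates(subset="sequence").reset_index(drop=True)
    return df


def _effect_multiplier(
    effect_class: str, timepoint: str, config: SimulationConfig
) -> float:
    step = {"Start": 0, "Healthy": 1, "Sugar": 2}[timepoint]
    if effect_class == "sugar_sensitive":
        return config.effect_fc if timepoint == "Sugar" else 1.0
    if effect_class == "mito_trend":
        return config.mito_trend_fc ** step
    return 1.0


def simulate_counts(
    config: SimulationConfig,
    ref: TRNAReference,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SampleInfo], TruthSet]:
    """NB fragment read counts for every sample, plus the truth set.

    Returns (counts long DataFrame with sample_id/sequence/count,
    samples, truth).  The expected count of fragment f in sample (i, t)
    is ``baseline_mean * library_size/1e6 * exp(b_i) * effect(f, t)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    frags = _design_fragments(ref, config.fragments_per_gene)
    frags["true_fc"] = [
        config.effect_fc if c == "sugar_sensitive"
        else (config.mito_trend_fc if c == "mito_trend" else 1.0)
        for c in frags["effect_class"]
    ]
    participants = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    intercepts = pd.Series(
        rng.normal(0.0, config.participant_sd, size=config.n_participants),
        index=participants, name="b_i",
    )
    samples = [
        SampleInfo(f"{p}_{t}", p, t)
        for p in participants for t in config.timepoints
    ]
    base_count = config.baseline_mean * config.library_size / 1e6
    theta = config.dispersion
    rows = []
    for s in samples:
        b = intercepts[s.participant_id]
        # one Gamma overdispersion draw per co-regulation block per sample:
        # fragments processed together fluctuate together, while each
        # fragment remains marginally NB(mu, theta)
        gammas = {
            blk: rng.gamma(shape=theta, scale=1.0 / theta)
            for blk in frags["co_regulation_block"].unique()
        }
        for _, f in frags.iterrows():
            mu = base_count * math.exp(b) * _effect_multiplier(
                f["effect_class"], s.timepoint, config
            )
            count = int(rng.poisson(mu * gammas[f["co_regulation_block"]]))
            rows.append((s.sample_id, f["sequence"], count, mu))
    counts = pd.DataFrame(rows, columns=["sample_id", "sequence", "count", "expected"])
    truth = TruthSet(
        fragments=frags,
        participant_intercepts=intercepts,
        expected_counts=counts[["sample_id", "sequence", "expected"]],
    )
    return counts[["sample_id", "sequence", "count"]], samples, truth


def truth_expression_table(
    counts: pd.DataFrame,
    samples: list[SampleInfo],
    truth: TruthSet,
    ref: TRNAReference,
    library_size: int,
):
    """Assemble an ExpressionTable straight from simulated counts.

    Skips the FASTQ round trip: fragment placements come from the truth
    set and the raw library total is taken as ``library_size`` for every
    sample (decoy reads implied).  Convenient for statistical studies
    where read-level simulation adds nothing.
    """
    from .mapping import Alignment, ExpressionTable, Fragment

    wide = counts.pivot(index="sequence", columns="sample_id", values="count")
    frags_meta = truth.fragments.set_index("sequence")
    order = [s for s in wide.index]
    fragments = [
        Fragment(
            sequence=s,
            alignments=(
                Alignment(
                    frags_meta.loc[s, "gene_id"],
                    int(frags_meta.loc[s, "start"]),
                    int(frags_meta.loc[s, "end"]),
                ),
            ),
            best_gene=frags_meta.loc[s, "gene_id"],
        )
        for s in order
    ]
    raw = wide.loc[order, [s.sample_id for s in samples]].to_numpy()
    totals = np.full(len(samples), library_size, dtype=int)
    return ExpressionTable(
        fragments=fragments, samples=list(samples),
        raw_counts=raw, library_totals=totals,
    )


def _decoy_read(rng: np.random.Generator, ref_kmers: set[str], length: int = 30) -> str:
    """A random insert guaranteed not to map into the reference."""
    while True:
        seq = _rand_seq(rng, length)
        if not (_kmers(seq, 16) & ref_kmers):
            return seq


def simulate_reads(
    config: SimulationConfig,
    ref: TRNAReference,
    out_dir: str | Path,
    gzip_fastq: bool = False,
    read_length: int = 75,
) -> tuple[pd.DataFrame, TruthSet]:
    """Emit per-sample FASTQ files, a sample sheet and the truth set.

    Each fragment read is ``fragment + adapter + random filler``
    truncated to ``read_length``; qualities are high (Q37-40) for
    passing reads and low (Q8-12) for a ``1 - quality_pass_rate``
    share.  Libraries are padded to ``library_size`` raw reads with
    unmappable decoys.  Deterministic under ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)  # read-level randomness only
    counts, samples, truth = simulate_counts(config, ref)
    write_reference(ref, out / "reference")
    ref_kmers: set[str] = set()
    for g in ref:
        ref_kmers |= _kmers(g.sequence, 16)

    sheet_rows = []
    wide = counts.pivot(index="sequence", columns="sample_id", values="count")
    for s in samples:
        frag_counts = wide[s.sample_id]
        mapped = int(frag_counts.sum())
        if config.library_size:
            n_decoys = max(config.library_size - mapped, 0)
        else:
            n_decoys = int(round(
                mapped * config.decoy_fraction / (1 - config.decoy_fraction)
            ))
        total = mapped + n_decoys
        path = out / (f"{s.sample_id}.fastq.gz" if gzip_fastq else f"{s.sample_id}.fastq")
        opener = gzip.open if gzip_fastq else open
        with opener(path, "wt") as fh:
            idx = 0
            for seq, c in frag_counts.items():
                for _ in range(int(c)):
                    _write_read(fh, rng, f"{s.sample_id}:frag{idx}", seq,
                                config, read_length)
                    idx += 1
            for _ in range(n_decoys):
                _write_read(fh, rng, f"{s.sample_id}:decoy{idx}",
                            _decoy_read(rng, ref_kmers), config, read_length)
                idx += 1
        sheet_rows.append(
            {
                "sample_id": s.sample_id, "participant_id": s.participant_id,
                "timepoint": s.timepoint, "library_total": total,
                "fastq": path.name,
            }
        )
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth.fragments.to_csv(out / "truth_fragments.tsv", sep="\t", index=False)
    return sheet, truth


def _write_read(fh, rng, read_id: str, insert: str,
                config: SimulationConfig, read_length: int) -> None:
    seq = (insert + DEFAULT_ADAPTER + _rand_seq(rng, read_length))[:read_length]
    if rng.random() < config.quality_pass_rate:
        quals = rng.integers(37, 41, size=len(seq))
    else:
        quals = rng.integers(8, 13, size=len(seq))
    qual = "".join(chr(q + 33) for q in quals)
    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def simulate_paired_counts(
    n_participants: int,
    baseline_mean: float,
    dispersion: float,
    fc: float,
    participant_sd: float = 0.3,
    rng: np.random.Generator | None = None,
    conditions: tuple[str, str] = ("Healthy", "Sugar"),
) -> pd.DataFrame:
    """Paired two-condition NB counts for one unit (calibration tool).

    Condition 2 means are multiplied by ``fc``.  Returns the long table
    nb_repeated_test consumes.
    """
    rng = rng if rng is not None else np.random.default_rng()
    b = rng.normal(0.0, participant_sd, size=n_participants)
    rows = []
    for i in range(n_participants):
        for j, cond in enumerate(conditions):
            mu = baseline_mean * math.exp(b[i]) * (fc if j == 1 else 1.0)
            lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
            rows.append((f"P{i + 1:02d}", cond, int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["participant", "condition", "count"])


def simulate_motility(
    group_change: np.ndarray,
    noise_sd: float,
    participants: Sequence[str],
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
    baseline: float = 50.0,
) -> pd.DataFrame:
    """Per-participant motility built from a group-mean RPM change.

    Motility change (Sugar - Start) = ``scale * standardized group
    change + noise``; with ``noise_sd=0`` the correlation with the group
    change is exactly 1.  Returns a long table (participant, timepoint,
    motility) over Start and Sugar.
    """
    rng = rng if rng is not None else np.random.default_rng()
    g = np.asarray(group_change, dtype=float)
    gs = (g - g.mean()) / (g.std(ddof=1) if g.std(ddof=1) > 0 else 1.0)
    change = scale * gs + rng.normal(0.0, noise_sd, size=len(g))
    rows = []
    for p, c in zip(participants, change):
        rows.append((p, "Start", baseline))
        rows.append((p, "Sugar", baseline + float(c)))
    return pd.DataFrame(rows, columns=["participant", "timepoint", "motility"])
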