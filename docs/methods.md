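# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of a statistical software vignette. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and the tRNA reference

All spans are 0-based, half-open internally; human-readable output is
1-based closed. A reference gene is a mature tRNA: uppercase DNA
alphabet (U→T on load), terminal CCA required (a config flag can
repair references that omit it), and three annotated loops ordered
D-loop < anticodon loop < T-loop. Loop spans are *inputs* (a TSV with
named columns), never inferred: secondary-structure prediction is out
of scope.

Coverage arrays are padded by 3 positions at each end (positions −3…−1
and L…L+2), mirroring the NNN-extension convention of tRNA-space
mappers, but padding exists only on the plotting axis — matching is
always against the unpadded sequence, so padded positions carry zero
coverage and conservation sums are unaffected.

Genes marked `lookalike` (tRNA-like genomic sequences) load and map
like any other gene but are excluded from nuclear/mitochondrial
contrasts via `TRNAReference.analysis_genes()`.

### Standardized T-loop start

The anchor is the first TTC in the T-loop subsequence, else the first
ATC, else the loop's first 5′ base. The rule depends only on the
subsequence inside the span and is idempotent. The motif census
reports, as percentages to one decimal: TTCGA prevalence, the three
anchor categories (which partition the reference), and the
mitochondrial share within the TTCGA and non-TTCGA groups. The census
is computed over *all* loaded genes including lookalikes; excluding
lookalikes is a one-line filter and, on the synthetic references used
in tests, shifts the fractions by at most one gene's weight.

## Preprocessing

Adapter search is 3′-anchored: the full adapter anywhere in the read,
or a prefix of it overlapping the read's 3′ end, minimum overlap 3,
mismatch fraction ≤ 0.1 (all three exposed in `TrimParams`). Reads
without a detectable adapter are discarded — in a small-RNA protocol
such reads have unknown insert length. Quality ("≥80% of bases with
Q>20", strictly greater) is evaluated on the trimmed insert, the
entity actually retained; length bounds (15–45 nt) are inclusive. The
three criteria are conjunctive, so the adapter→quality→length order
only structures the report counts; per-read processing makes the
result independent of read order. The report's raw read total is the
RPM denominator downstream.

## Mapping and normalization

Fragment space is exact substrings of mature tRNAs, so mapping is
exact, sense-strand substring search; no mismatches or indels.
Exclusivity is defined within the supplied reference — genome-wide
ambiguity screening would require a genome and is out of scope.

RPM uses the raw FASTQ total (not the mapped total) as denominator.
The coverage filter keeps a fragment reaching `min_rpm` in at least
`ceil(0.33 · n_samples)` samples; the 33% wording is ambiguous between
"≥33% of samples above" and "<33% below", and the first reading was
chosen as the one matching retain-semantics. `min_rpm=1` is the
tRNA-space default; `0.01` is available for permissive whole-library
scans.

Multimapping fragments are reported under the aligned gene with the
highest total RPM coverage (summed over samples, each alignment
crediting the fragment's full RPM), ties broken lexicographically by
gene id — deterministic and documented, since no convention is
universal.

## Subtype classification and nitRNA calls

5′-anchored fragments start at mature position 0; CCA-anchored
fragments end at the gene's 3′ end. The half boundary is the floor of
the anticodon-loop span's centre — the wobble-adjacent position, the
only anticodon-cleavage proxy derivable from the loop span alone; a
5′-half ends exactly there and a 3′-half starts one base later. All
other start-anchored fragments are 5′-tsRNAs, CCA-anchored ones
3′-tsRNAs, and everything else is internal (i-tsRNA). A hypothetical
full-length placement is start-classified (5′ rules take precedence).
The exact half boundary convention of public tRNA-fragment databases
is not printed anywhere authoritative; this midpoint convention is
validated against the embedded 30-nt LysCTT worked example and is a
per-reference annotation away from being overridden.

A nitRNA is an i-tsRNA of a nuclear gene whose T-loop contains TTCGA
and whose 3′ terminus lies anywhere inside the T-loop span. The span —
not a stricter TTCGA-internal window — is the call boundary because
observed sugar-sensitive cleavages sit "in or very close to" the
motif; the signed cleavage distance (3′ terminus − standardized start;
0 on the anchor, negative upstream) is always reported so stricter
windows can be applied downstream. Multimapping fragments take the
modal distance across placements, ties resolved by the best-gene
placement.

RPM is discretized for counting analyses by rounding half away from
zero; the rounding rule is a package choice (no authoritative
convention exists) and only affects values exactly at .5.

## The repeated-measures NB model

Each unit (fragment or isodecoder) is tested with

    y_it ~ NB(μ_it, θ),   Var(y) = μ + μ²/θ
    log μ_it = β₀ + β_cond·x_it + u_i,   u_i ~ N(0, σ²)

where i indexes participants and t the paired condition. The marginal
likelihood integrates u_i by 21-node Gauss–Hermite quadrature and is
maximized by L-BFGS-B over (β₀, β_cond, log θ, log σ). The condition
effect is reported as FC = exp(β_cond) with a two-sided Wald test.

Two numerical choices matter:

* **Curvature.** Standard errors come from the inverse of a
  *central-difference* Hessian of the negative log-likelihood;
  forward-difference Hessians visibly understate curvature here and
  inflate the type-I rate.
* **Reference distribution.** The Wald statistic is compared to
  t(n_participants − 1), the usual small-sample correction for
  mixed-model Wald tests; a normal reference is anti-conservative at
  n ≈ 15 because θ and σ are estimated.

Fallback hierarchy, flagged per unit in `converged`/`method`: random
intercept → fixed participant intercepts (statsmodels NB regression
with participant dummies) → paired sign test. All-zero units are
flagged undefined. P-values are *not* multiple-testing corrected:
fragments of one tRNA are strongly dependent, and independence-based
corrections would inflate type-II error; a Benjamini–Hochberg column
is emitted for reference only and never used for calls.

Descriptive fold changes use a 0.5 pseudocount on both condition
means; the model-based FC needs none.

The exact one-sided paired Wilcoxon signed-rank test drops zero
differences (flagging all-zero input undefined), uses average ranks
for ties, and computes the exact tail by a generating-function
convolution over doubled ranks for n ≤ 25 (scipy's exact path rejects
ties), switching to the tie-corrected normal approximation with
continuity correction above.

"Sugar-sensitive" membership for group contrasts means p < 0.05 with
FC > 1 in the Sugar-vs-Healthy contrast. Group trajectories are
per-participant means of group RPM per timepoint, contrasted against
the Start timepoint with the one-sided Wilcoxon test; the motility
association is a Pearson correlation of per-participant
(Sugar − Start) changes (Spearman via config — the choice is genuinely
open, and Pearson matches the linear-trend visualisation it supports).

## Clustering

Rows are per-unit vectors of per-participant paired RPM differences,
centred and scaled to unit sample SD (n−1); zero-variance rows carry
no relational signal and are dropped with a log. Distances are
Euclidean; linkage is complete by default (single/average/ward
available) — the linkage is unstated in the lineage this follows, and
the block-separation conclusions the package tests are robust across
linkages on simulated designs. Dendrograms export to Newick with
branch lengths from merge heights; k-cut purity is the fraction of
leaves whose flat cluster's majority label matches their own.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, with
ground truth for every stage:

* **Reference**: nuclear genes of 76 nt and mitochondrial genes of
  68 nt with ordered loop spans and CCA tails; T-loops carry TTCGA, a
  TTC-without-GA variant, an ATC anchor, or a purine-only loop
  (fallback anchor). By default half the nuclear genes are TTCGA and
  all mitochondrial loops are TTC-non-TTCGA, matching the observed
  scarcity of mitochondrial TTCGA loops. Genes are regenerated until
  all 16-mers are pairwise unique, so fragments ≥16 nt map uniquely;
  a fixture mode plants a shared 20-mer to exercise multimapping.
* **Fragments**: per gene a 5′-tsRNA, a 5′-half, an internal fragment
  ending inside the T-loop (a nitRNA when the gene is nuclear-TTCGA)
  and a 3′-tsRNA; extra slots add internal fragments ending before the
  T-loop.
* **Counts**: NB(μ, θ) via a Gamma–Poisson mixture with a log-normal
  participant intercept (SD 0.3). The Gamma overdispersion draw is
  *shared per co-regulation block per sample* — all nitRNA fragments
  form one block, all mitochondrial fragments another, null fragments
  are solo — keeping every fragment marginally NB while giving blocks
  the correlated cross-participant responses the cluster analysis is
  designed to detect. Default dispersion θ = 5 (biological CV ≈ 45%,
  realistic for abundant fragments across individuals); the harsher
  θ = 0.5 appears only in the statistical stress tests. Effects:
  sugar-sensitive fragments ×4 at the Sugar timepoint only;
  mitochondrial fragments ×1.5 per diet step (progressive rise).
* **Reads**: fragment + adapter + random filler truncated to 75 nt,
  high-quality Phred strings for a configurable pass rate (default
  98%), libraries padded to `library_size` raw reads (default 20,000
  per sample — a desk-scale stand-in for production depths; RPM
  arithmetic is depth-invariant) with decoy inserts verified to share
  no 16-mer with the reference. One integer seed makes all outputs
  byte-identical.
* **Motility**: per-participant change built as a scaled, standardized
  group-mean RPM change plus Gaussian noise, with the noiseless case
  giving correlation exactly 1.

What the generator does **not** emulate: sequencing errors beyond
quality strings, ragged fragment ends within one cleavage population,
non-tRNA small-RNA classes, GC or length biases, and real tRNA
sequence families with shared substrings (except in fixture mode).
Passing tests therefore demonstrate correctness of the pipeline's
logic and calibration of its statistics under the stated model — not
robustness to alignment ambiguity or library artefacts in real data.

## Problem sizes and numerical tolerances

Simulation studies in the test suite use: 2,000 null cohorts and 500
effect cohorts (15 participants, baseline 50, dispersion 0.5) for test
calibration; 100 cohorts for the dendrogram separation rate; one
15-participant cohort for the cut-site and trajectory structure.
Center-scaling tolerance is 1e-9; optimizer bounds keep log θ in
[−8, 12] and log σ in [−8, 3]; quadrature uses 21 nodes (results are
stable against 31). Degenerate inputs (all-zero units, zero-variance
rows, all-zero difference vectors) are flagged or dropped explicitly
rather than propagated.

## Known limitations

* The NB random-intercept Wald test is approximate at small n despite
  the t correction; its measured type-I rate is reported by the
  acceptance script rather than assumed.
* Exclusivity of fragments is relative to the supplied reference; no
  genome-wide screen is attempted.
* The half-boundary convention is a documented substitute for an
  unpublished database convention and is configurable per reference.
* The census of the real 640-gene tRNA space requires a locally
  supplied bundle (sequences plus loop annotation); the packaged tests
  cover synthetic references and the embedded LysCTT gene only.
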