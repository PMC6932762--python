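import numpy as np
import pandas as pd
import pytest

from nitrna.classify import (
    Subtype,
    build_coverage_profiles,
    classify_subtype,
    consensus_distance,
    cut_site_significance_map,
    discretize_rpm,
    t_loop_distance,
)
from nitrna.examples import LYS_CTT_GENE, lys_ctt_fragment, lys_ctt_reference
from nitrna.mapping import (
    Alignment,
    ExpressionTable,
    Fragment,
    SampleInfo,
    find_alignments,
)
from nitrna.reference import Origin


def brute_force_subtype(start, end, gene):
    """Independent re-derivation of the positional subtype rules."""
    mid = (gene.anticodon_loop[0] + gene.anticodon_loop[1] - 1) // 2
    if start == 0:
        return "five_half" if end - 1 == mid else "five_tsRNA"
    if end == len(gene.sequence):
        return "three_half" if start == mid + 1 else "three_tsRNA"
    return "i_tsRNA"


class TestClassifySubtype:
    def test_exhaustive_oracle_on_toy_reference(self, toy_reference):
        """Every 16-45 nt substring of every gene matches the brute force."""
        n_checked = 0
        for gene in toy_reference:
            L = len(gene)
            for start in range(L):
                for end in range(start + 16, min(start + 46, L + 1)):
                    call = classify_subtype(
                        Alignment(gene.gene_id, start, end), gene
                    )
                    assert call.subtype.value == brute_force_subtype(start, end, gene)
                    # nitRNA implies nuclear internal TTCGA-T-loop ending
                    if call.is_nitrna:
                        assert call.subtype is Subtype.I_TSRNA
                        assert gene.origin is Origin.NUCLEAR and gene.has_ttcga
                        assert gene.t_loop[0] <= end - 1 < gene.t_loop[1]
                    n_checked += 1
        assert n_checked > 1000

    def test_every_fragment_gets_exactly_one_subtype(self, toy_reference):
        subtypes = set()
        gene = toy_reference.genes[0]
        for start, end in [(0, 30), (0, 37), (5, 40), (50, len(gene)), (37, len(gene))]:
            call = classify_subtype(Alignment(gene.gene_id, start, end), gene)
            assert call.subtype in Subtype
            subtypes.add(call.subtype)
        assert subtypes == set(Subtype)

    def test_start_anchored_not_half(self, toy_reference):
        gene = toy_reference.genes[0]  # anticodon loop [33, 40) -> midpoint 36
        call = classify_subtype(Alignment(gene.gene_id, 0, 30), gene)
        assert call.subtype is Subtype.FIVE_TSRNA
        call = classify_subtype(Alignment(gene.gene_id, 0, 37), gene)
        assert call.subtype is Subtype.FIVE_HALF

    def test_cca_terminal_split_by_five_prime_rule(self, toy_reference):
        gene = toy_reference.genes[0]
        L = len(gene)
        assert classify_subtype(Alignment(gene.gene_id, 37, L), gene).subtype is Subtype.THREE_HALF
        assert classify_subtype(Alignment(gene.gene_id, 40, L), gene).subtype is Subtype.THREE_TSRNA

    def test_alignment_outside_gene_errors(self, toy_reference):
        gene = toy_reference.genes[0]
        with pytest.raises(ValueError, match="outside"):
            classify_subtype(Alignment(gene.gene_id, 50, len(gene) + 5), gene)

    def test_lys_ctt_worked_example(self):
        frag = lys_ctt_fragment()
        call = classify_subtype(frag, LYS_CTT_GENE)
        assert len(frag.sequence) == 30
        assert call.subtype is Subtype.I_TSRNA
        assert call.is_nitrna and call.origin is Origin.NUCLEAR
        aln = frag.alignments[0]
        # 5' cut in the anticodon arm between D-loop and anticodon loop
        assert LYS_CTT_GENE.d_loop[1] <= aln.start < LYS_CTT_GENE.anticodon_loop[0]
        # 3' cut inside the TTCGA T-loop
        assert LYS_CTT_GENE.t_loop[0] <= aln.end - 1 < LYS_CTT_GENE.t_loop[1]


class TestTLoopDistance:
    def test_sign_convention(self, toy_reference):
        gene = toy_reference.genes[0]  # t_loop_start at 52 (TTC at offset 0)
        ts = gene.t_loop_start
        assert t_loop_distance(Alignment(gene.gene_id, 20, ts + 1), gene) == 0
        assert t_loop_distance(Alignment(gene.gene_id, 20, ts + 4), gene) == 3
        assert t_loop_distance(Alignment(gene.gene_id, 10, ts - 4), gene) == -5

    def test_batch_matches_index_arithmetic(self, sim_reference):
        rng = np.random.default_rng(5)
        for gene in sim_reference:
            for _ in range(20):
                start = int(rng.integers(0, len(gene) - 16))
                end = int(rng.integers(start + 16, min(start + 45, len(gene)) + 1))
                d = t_loop_distance(Alignment(gene.gene_id, start, end), gene)
                assert d == (end - 1) - gene.t_loop_start


class TestConsensusDistance:
    def _frag(self, ref, placements, best=None):
        alns = tuple(Alignment(g, s, e) for g, s, e in placements)
        return Fragment(sequence="X" * 20, alignments=alns, best_gene=best)

    def test_mode(self, toy_reference):
        g = {gene.gene_id: gene for gene in toy_reference}
        ids = list(g)
        # craft placements whose distances are {+2, +2, -5}
        placements = []
        for gid, d in zip([ids[0], ids[1], ids[2]], [2, 2, -5]):
            ts = g[gid].t_loop_start
            placements.append((gid, 10, ts + d + 1))
        frag = self._frag(toy_reference, placements)
        assert consensus_distance(frag, toy_reference) == 2

    def test_tie_resolved_by_best_gene(self, toy_reference):
        g = {gene.gene_id: gene for gene in toy_reference}
        ids = list(g)
        p1 = (ids[0], 10, g[ids[0]].t_loop_start + 2)   # distance +1
        p2 = (ids[1], 10, g[ids[1]].t_loop_start + 0)   # distance -1
        frag = self._frag(toy_reference, [p1, p2], best=ids[0])
        assert consensus_distance(frag, toy_reference) == 1
        frag = self._frag(toy_reference, [p1, p2], best=ids[1])
        assert consensus_distance(frag, toy_reference) == -1

    def test_random_sets_match_counting_oracle(self, sim_reference):
        rng = np.random.default_rng(9)
        genes = list(sim_reference)
        for _ in range(50):
            k = int(rng.integers(1, 6))
            chosen = rng.choice(len(genes), size=k, replace=False)
            placements = []
            for gi in chosen:
                gene = genes[gi]
                end = int(rng.integers(30, len(gene)))
                placements.append((gene.gene_id, 5, end))
            frag = self._frag(sim_reference, placements, best=genes[chosen[0]].gene_id)
            dists = [
                (e - 1) - sim_reference[g].t_loop_start for g, s, e in placements
            ]
            counts = {d: dists.count(d) for d in dists}
            top = max(counts.values())
            modes = [d for d, c in counts.items() if c == top]
            got = consensus_distance(frag, sim_reference)
            assert got in modes
            if len(modes) == 1:
                assert got == modes[0]
            elif dists[0] in modes:
                assert got == dists[0]  # best-gene placement breaks the tie
            else:
                assert got == min(modes)


class TestDiscretizeRPM:
    @pytest.mark.parametrize(
        "x, expected", [(0.4, 0), (0.5, 1), (1.5, 2), (2.49, 2), (10.0, 10)]
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert discretize_rpm(x) == expected


def _one_gene_table(gene, placements, rpms, ref):
    frags, rows = [], []
    for (start, end), rpm in zip(placements, rpms):
        seq = gene.sequence[start:end]
        frags.append(
            Fragment(seq, (Alignment(gene.gene_id, start, end),), best_gene=gene.gene_id)
        )
        rows.append([rpm])
    counts = (np.array(rows) * 1).astype(int)
    return ExpressionTable(
        fragments=frags,
        samples=[SampleInfo("s1", "P1", "Start")],
        raw_counts=counts,
        library_totals=np.array([1_000_000]),
    )


class TestCoverageProfiles:
    def test_single_fragment_block(self, toy_reference):
        gene = toy_reference.genes[0]
        table = _one_gene_table(gene, [(5, 35)], [10], toy_reference)
        profiles = build_coverage_profiles(table, toy_reference)
        prof = profiles[(gene.gene_id, "Start")]
        pad = prof.padding
        assert (prof.coverage[5 + pad:35 + pad] == 10).all()
        assert prof.coverage[4 + pad] == 0 and prof.coverage[35 + pad] == 0
        assert prof.start_site_expression[5 + pad] == 10
        assert prof.end_site_expression[34 + pad] == 10

    def test_overlap_additive_and_conserved(self, toy_reference):
        gene = toy_reference.genes[0]
        table = _one_gene_table(gene, [(5, 35), (20, 50)], [10, 4], toy_reference)
        prof = build_coverage_profiles(table, toy_reference)[(gene.gene_id, "Start")]
        pad = prof.padding
        assert (prof.coverage[20 + pad:35 + pad] == 14).all()
        total = prof.start_site_expression.sum()
        assert total == prof.end_site_expression.sum() == 14

    def test_brute_force_oracle(self, sim_reference):
        rng = np.random.default_rng(13)
        gene = list(sim_reference)[0]
        placements, rpms = [], []
        for _ in range(12):
            s = int(rng.integers(0, len(gene) - 20))
            e = int(rng.integers(s + 16, min(s + 45, len(gene)) + 1))
            placements.append((s, e))
            rpms.append(int(rng.integers(1, 50)))
        # collapse duplicate sequences the way the table would
        seen = {}
        for (s, e), r in zip(placements, rpms):
            seq = gene.sequence[s:e]
            if seq in seen:
                seen[seq] = (seen[seq][0], seen[seq][1] + r)
            else:
                seen[seq] = ((s, e), r)
        placements = [v[0] for v in seen.values()]
        rpms = [v[1] for v in seen.values()]
        table = _one_gene_table(gene, placements, rpms, sim_reference)
        prof = build_coverage_profiles(table, sim_reference)[(gene.gene_id, "Start")]
        pad = prof.padding
        expected = np.zeros(len(gene))
        for (s, e), r in zip(placements, rpms):
            expected[s:e] += r
        np.testing.assert_array_equal(
            prof.coverage[pad:pad + len(gene)], expected
        )


class TestCutSiteMap:
    def test_empty_diff_results(self, toy_reference):
        ann = pd.DataFrame(
            columns=["sequence", "t_loop_distance", "origin", "has_ttcga",
                     "subtype", "is_nitrna"]
        )
        out = cut_site_significance_map(pd.DataFrame(), ann)
        assert len(out) == 0

    def test_joins_positions_with_significance(self, toy_reference):
        ann = pd.DataFrame(
            {
                "sequence": ["AAA", "CCC"],
                "t_loop_distance": [1, -20],
                "origin": ["nuclear", "mitochondrial"],
                "has_ttcga": [True, False],
                "subtype": ["i_tsRNA", "three_tsRNA"],
                "is_nitrna": [True, False],
            }
        )
        diff = pd.DataFrame(
            {"unit_id": ["AAA", "CCC"], "p_value": [0.01, 0.8],
             "fold_change": [3.0, 1.0], "mean_rpm_Sugar": [30.0, 5.0]}
        )
        out = cut_site_significance_map(diff, ann)
        assert len(out) == 2
        row = out.set_index("sequence").loc["AAA"]
        assert row["p_value"] == 0.01 and row["t_loop_distance"] == 1
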