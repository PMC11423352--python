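"""Contingency building, hypergeometric homology calls, painting, dot plots."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from karyoevol.io_formats import ALGAssignment, GeneRecord, OrthologPair
from karyoevol.synteny import (
    ContingencyMatrix,
    build_contingency,
    derive_homology_map,
    export_dotplot,
    paint_genome,
    test_homology as call_homology,
)


def genes(genome, placements):
    """placements: list of (chrom, gene_id)."""
    return [
        GeneRecord(genome, chrom, i * 100, i * 100 + 50, gid)
        for i, (chrom, gid) in enumerate(placements)
    ]


def hypergeom_upper_tail_by_enumeration(N, K, n, k):
    """P[X >= k] by counting all C(N, n) draws from K successes in N items."""
    if n == 0:
        return 1.0 if k <= 0 else 0.0
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestBuildContingency:
    def test_single_cell(self):
        ga = genes("A", [("chr1", f"a{i}") for i in range(10)])
        alg = [ALGAssignment(f"r{i}", "ALG1") for i in range(10)]
        pairs = [OrthologPair(f"a{i}", f"r{i}") for i in range(10)]
        m = build_contingency(ga, alg, pairs)
        assert m.table.shape == (1, 1) and m.table.iloc[0, 0] == 10

    def test_unknown_gene_pairs_dropped_and_counted(self):
        ga = genes("A", [("chr1", "a1")])
        alg = [ALGAssignment("r1", "ALG1")]
        m = build_contingency(ga, alg, [OrthologPair("a1", "r1"), OrthologPair("zz", "r1")])
        assert m.grand_total == 1 and m.n_dropped == 1

    def test_zero_usable_pairs_errors(self):
        ga = genes("A", [("chr1", "a1")])
        alg = [ALGAssignment("r1", "ALG1")]
        with pytest.raises(ValueError, match="usable"):
            build_contingency(ga, alg, [OrthologPair("zz", "r9")])

    def test_margins_are_sums_and_total_is_pair_count(self, case_sim):
        tip = "littorinid"
        m = build_contingency(
            case_sim.gene_records[tip], case_sim.alg_table,
            case_sim.ortholog_pairs[(tip, "alg_ref")],
        )
        assert (m.row_margins == m.table.sum(axis=1)).all()
        assert m.grand_total == len(case_sim.ortholog_pairs[(tip, "alg_ref")])

    def test_matches_simulators_own_tally(self, case_sim):
        tip = "scallop"
        m = build_contingency(
            case_sim.gene_records[tip], case_sim.alg_table,
            case_sim.ortholog_pairs[(tip, "alg_ref")],
        )
        tally = case_sim.truth.pair_tally(tip, "alg_ref")
        for (ca, cb), n in tally.items():
            assert m.table.loc[ca, cb] == n
        assert m.grand_total == sum(tally.values())


class TestHomologyTest:
    def test_forced_configuration_p_is_one_but_counts_significant(self):
        m = ContingencyMatrix(pd.DataFrame([[20]], index=["chr1"], columns=["ALG1"]))
        with pytest.warns(UserWarning, match="degenerate"):
            (call,) = call_homology(m)
        assert call.p_raw == 1.0
        assert call.significant  # forced configuration: count gates decide

    def test_diagonal_2x2_matches_enumeration(self):
        m = ContingencyMatrix(
            pd.DataFrame([[5, 0], [0, 5]], index=["a1", "a2"], columns=["b1", "b2"])
        )
        calls = {(c.chrom_a, c.chrom_b_or_alg): c for c in call_homology(m, min_genes=1)}
        expected = 1 / math.comb(10, 5)  # only one of C(10,5) draws is all-successes
        assert calls[("a1", "b1")].p_raw == pytest.approx(expected)
        assert calls[("a2", "b2")].p_raw == pytest.approx(expected)
        assert hypergeom_upper_tail_by_enumeration(10, 5, 5, 5) == pytest.approx(expected)

    def test_count_below_min_genes_is_not_significant(self):
        m = ContingencyMatrix(
            pd.DataFrame([[5, 0], [0, 500]], index=["a1", "a2"], columns=["b1", "b2"])
        )
        calls = {(c.chrom_a, c.chrom_b_or_alg): c for c in call_homology(m, min_genes=10)}
        call = calls[("a1", "b1")]
        assert call.q_fdr <= 0.05 and not call.significant

    @pytest.mark.parametrize("N", [4, 7, 9])
    def test_p_values_match_enumeration_at_small_n(self, N):
        """Spot-check the implementation against the draw-counting oracle."""
        rng = np.random.default_rng(5)
        for _ in range(8):
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k_max = min(K, n)
            k = int(rng.integers(max(0, n + K - N), k_max + 1))
            table = pd.DataFrame(
                [[k, n - k], [K - k, N - K - n + k]], index=["a1", "a2"], columns=["b1", "b2"]
            )
            calls = {(c.chrom_a, c.chrom_b_or_alg): c
                     for c in call_homology(ContingencyMatrix(table))}
            assert calls[("a1", "b1")].p_raw == pytest.approx(
                hypergeom_upper_tail_by_enumeration(N, K, n, k)
            )


class TestHomologyMap:
    def _calls(self, sig_pairs):
        from karyoevol.synteny import HomologyCall

        return [HomologyCall(a, b, 50, 1e-9, 1e-8, True) for a, b in sig_pairs]

    def test_two_to_one_relation(self):
        hmap = derive_homology_map(self._calls([("PY8", "L1"), ("PY9", "L1")]))
        assert hmap.inverse["L1"] == {"PY8", "PY9"}
        assert hmap.relation[("PY8", "L1")] == "2:1"

    def test_one_to_two_relation(self):
        hmap = derive_homology_map(self._calls([("PY1", "L13"), ("PY1", "L15")]))
        assert hmap.forward["PY1"] == {"L13", "L15"}
        assert hmap.relation[("PY1", "L13")] == "1:2"

    def test_empty_calls_give_empty_map(self):
        hmap = derive_homology_map([])
        assert hmap.forward == {} and hmap.inverse == {}

    def test_case_study_matches_published_homologies(self, case_sim):
        pairs = case_sim.ortholog_pairs[("littorinid", "scallop")]
        m = build_contingency(
            case_sim.gene_records["littorinid"], case_sim.gene_records["scallop"], pairs
        )
        hmap = derive_homology_map(call_homology(m))
        assert hmap.forward["L1"] == {"PY8", "PY9"}
        assert hmap.forward["L2"] == {"PY2", "PY19"}
        assert hmap.forward["L3"] == {"PY11", "PY13"}
        assert hmap.inverse["PY1"] == {"L13", "L15"}


class TestPainting:
    def test_single_alg_genome(self):
        ga = genes("A", [("chr1", f"a{i}") for i in range(30)])
        alg = [ALGAssignment(f"r{i}", "ALG7") for i in range(30)]
        pairs = [OrthologPair(f"a{i}", f"r{i}") for i in range(30)]
        with pytest.warns(UserWarning, match="degenerate"):
            p = paint_genome(ga, alg, pairs)
        assert p.composition == {"chr1": ["ALG7"]}
        assert p.support["ALG7"] == 30

    def test_noise_free_case_sim_reproduces_generating_composition(self):
        from karyoevol import fixtures

        sim = fixtures.simulate_case(seed=3, translocation_rate=0.0, gene_loss_rate=0.0)
        for tip in sim.config.tips:
            p = paint_genome(
                sim.gene_records[tip], sim.alg_table, sim.ortholog_pairs[(tip, "alg_ref")]
            )
            assert p.composition == sim.truth.paintings[tip].composition
            assert p.support == sim.truth.paintings[tip].support

    def test_l2_composition_from_fixture_orthologs(self, case_sim):
        p = paint_genome(
            case_sim.gene_records["littorinid"], case_sim.alg_table,
            case_sim.ortholog_pairs[("littorinid", "alg_ref")],
        )
        assert p.composition["L2"] == ["ALG2-1", "ALG5", "ALG16"]

    def test_support_totals_conserved_per_chromosome(self, case_sim):
        tip = "littorinid"
        m = build_contingency(
            case_sim.gene_records[tip], case_sim.alg_table,
            case_sim.ortholog_pairs[(tip, "alg_ref")],
        )
        p = paint_genome(
            case_sim.gene_records[tip], case_sim.alg_table,
            case_sim.ortholog_pairs[(tip, "alg_ref")],
        )
        for chrom, units in p.composition.items():
            painted = sum(p.support[u] for u in units)
            row_total = int(m.table.loc[chrom].sum())
            # painted genes on a chromosome never exceed its mapped genes
            assert painted <= row_total

    def test_raising_min_frac_never_adds_an_alg(self, case_sim):
        tip = "littorinid"
        args = (case_sim.gene_records[tip], case_sim.alg_table,
                case_sim.ortholog_pairs[(tip, "alg_ref")])
        prev = None
        for frac in (0.01, 0.05, 0.20, 0.45):
            p = paint_genome(*args, min_frac=frac)
            algs = {c: {u.split("-")[0] for u in us} for c, us in p.composition.items()}
            if prev is not None:
                for c in algs:
                    assert algs[c] <= prev[c]
            prev = algs

    def test_noise_robustness_recovers_composition(self):
        """2% translocation, 50+ genes per ALG: every chromosome painted true."""
        from karyoevol.simulate import SimulationConfig, simulate

        for seed in range(4):
            sim = simulate(SimulationConfig(seed=seed, genes_per_alg=60,
                                            translocation_rate=0.02, gene_loss_rate=0.0))
            for tip in sim.config.tips:
                p = paint_genome(
                    sim.gene_records[tip], sim.alg_table,
                    sim.ortholog_pairs[(tip, "alg_ref")],
                )
                assert p.composition == sim.truth.paintings[tip].composition


class TestDotplot:
    def test_single_pair_single_row(self):
        ga = genes("A", [("chr1", "a1")])
        gb = genes("B", [("chrX", "b1")])
        df = export_dotplot(ga, gb, [OrthologPair("a1", "b1")])
        assert len(df) == 1
        assert df.iloc[0]["chrom_a"] == "chr1" and df.iloc[0]["chrom_b"] == "chrX"

    def test_permuting_order_preserves_dot_count(self, case_sim):
        ga = case_sim.gene_records["littorinid"]
        gb = case_sim.gene_records["scallop"]
        pairs = case_sim.ortholog_pairs[("littorinid", "scallop")]
        df1 = export_dotplot(ga, gb, pairs)
        order = sorted({g.chromosome for g in ga})[::-1]
        df2 = export_dotplot(ga, gb, pairs, order_a=order)
        assert len(df1) == len(df2) == len(pairs)
        assert set(df1["pair_id"]) == set(df2["pair_id"])

    def test_block_structure_matches_simulated_homology(self, case_sim):
        ga = case_sim.gene_records["littorinid"]
        gb = case_sim.gene_records["scallop"]
        pairs = case_sim.ortholog_pairs[("littorinid", "scallop")]
        df = export_dotplot(ga, gb, pairs)
        sub = df[df["chrom_a"] == "L5"]["chrom_b"].value_counts(normalize=True)
        assert sub.idxmax() == "PY5" and sub.max() > 0.9
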