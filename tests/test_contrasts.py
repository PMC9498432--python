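"""Contrast pipeline: scenario enumeration, MDS screening, pooling,
consensus logic and gene-window annotation."""

import numpy as np
import pytest

from fstscan import simulate
from fstscan.contrasts import (
    META_LABEL,
    ContrastResult,
    Criteria,
    GeneAnnotation,
    ScenarioConfig,
    annotate_windows,
    consensus,
    enumerate_contrasts,
    ibs_distance,
    mds_cohort_check,
    pool_meta_population,
    read_annotation,
    run_contrast,
)
from fstscan.genotype_io import LocusRecord

from conftest import make_matrix

GREY = [c.label for c in simulate.PAPER_COHORTS if c.grey]
TAURINE_REFS = ["Angus", "Holstein", "Charolais", "Limousin"]


class TestScenarios:
    def test_scenario1_full_grid(self):
        cfg = ScenarioConfig(1, GREY, TAURINE_REFS)
        pairs = enumerate_contrasts(cfg)
        assert len(pairs) == 28
        assert pairs[0] == ("Bhagnari", "Angus")  # test-major config order
        assert pairs[-1] == ("Tharparkar", "Limousin")

    def test_scenario2_meta_vs_each_reference(self):
        cfg = ScenarioConfig(2, GREY, TAURINE_REFS)
        pairs = enumerate_contrasts(cfg)
        assert pairs == [(META_LABEL, r) for r in TAURINE_REFS]

    def test_scenario3_single_reference(self):
        cfg = ScenarioConfig(3, GREY, ["Sahiwal"])
        pairs = enumerate_contrasts(cfg)
        assert len(pairs) == 7
        assert {r for _t, r in pairs} == {"Sahiwal"}

    def test_one_by_one(self):
        assert enumerate_contrasts(ScenarioConfig(1, ["t"], ["r"])) == [("t", "r")]

    def test_exclusions_remove_test_cohorts(self):
        cfg = ScenarioConfig(1, GREY, TAURINE_REFS, excluded_cohorts=["Hariana"])
        assert len(enumerate_contrasts(cfg)) == 24

    def test_scenario3_requires_single_reference(self):
        with pytest.raises(ValueError):
            ScenarioConfig(3, GREY, TAURINE_REFS)

    def test_disjoint_test_and_reference(self):
        with pytest.raises(ValueError):
            ScenarioConfig(1, ["a"], ["a"])


class TestMds:
    def test_identical_samples_have_zero_distance(self):
        gm = make_matrix([[1, 0, 2], [1, 0, 2], [0, 1, 1]])
        d = ibs_distance(gm)
        assert d[0, 1] == 0.0
        assert d[0, 2] > 0

    def test_null_simulation_flags_nothing(self):
        cfg = simulate.SimulationConfig(
            n_loci=400,
            cohorts=[simulate.CohortSpec(f"c{i}", 8, "x") for i in range(5)],
            f_between=0.02,
            f_within=0.02,
            missing_rate=0.0,
            seed=17,
        )
        gm, _ = simulate.simulate(cfg)
        res = mds_cohort_check(gm)
        assert res.flagged == []

    def test_planted_outlier_cohort_flagged(self):
        cohorts = [simulate.CohortSpec(f"c{i}", 8, "x") for i in range(5)]
        cohorts.append(simulate.CohortSpec("weird", 8, "far"))
        cfg = simulate.SimulationConfig(
            n_loci=400,
            cohorts=cohorts,
            f_between=0.3,  # the lone far-lineage cohort sits 10x away
            f_within=0.02,
            missing_rate=0.0,
            seed=18,
        )
        gm, _ = simulate.simulate(cfg)
        res = mds_cohort_check(gm)
        assert res.flagged == ["weird"]


class TestPooling:
    def test_table_shaped_pool_is_52(self):
        cfg = simulate.make_paper_shaped_config(n_loci=60, n_planted=0, seed=1)
        gm, _ = simulate.simulate(cfg)
        pooled, n = pool_meta_population(gm, GREY, excluded=["Hariana"])
        assert n == 52
        assert META_LABEL in pooled.cohorts
        assert "Hariana" not in pooled.cohorts

    def test_no_exclusion_pools_everything(self):
        gm = make_matrix(
            np.ones((9, 3), dtype=np.int8), cohorts=["a"] * 4 + ["b"] * 5
        )
        pooled, n = pool_meta_population(gm, ["a", "b"])
        assert n == 9

    def test_three_cohort_fixture_arithmetic(self):
        gm = make_matrix(
            np.ones((15, 2), dtype=np.int8),
            cohorts=["a"] * 4 + ["b"] * 5 + ["c"] * 6,
        )
        pooled, n = pool_meta_population(gm, ["a", "b", "c"], excluded=["b"])
        assert n == 10
        assert pooled.n_samples == 10

    def test_excluded_must_be_subset(self):
        gm = make_matrix(np.ones((4, 2), dtype=np.int8), cohorts=["a"] * 4)
        with pytest.raises(ValueError):
            pool_meta_population(gm, ["a"], excluded=["z"])


class TestRunContrast:
    def test_planted_loci_enriched_in_top_flags(self):
        cfg = simulate.make_paper_shaped_config(n_loci=1500, n_planted=15, seed=23)
        gm, truth = simulate.simulate(cfg)
        res = run_contrast(gm, "Tharparkar", "Angus", engine="wc")
        planted = set(truth.loc[truth.is_planted, "locus"])
        flagged = {l for l, f in zip(res.locus_ids, res.sig_top) if f}
        frac_planted_flagged = len(flagged & planted) / len(planted)
        base_rate = len(flagged) / len(res.locus_ids)
        assert frac_planted_flagged > 5 * base_rate

    def test_top_flag_count_is_ceil_of_defined(self):
        cfg = simulate.make_paper_shaped_config(n_loci=777, n_planted=0, seed=24)
        gm, _ = simulate.simulate(cfg)
        res = run_contrast(gm, "Dajal", "Holstein", engine="wc")
        n_def = np.isfinite(res.score).sum()
        assert res.sig_top.sum() == int(np.ceil(0.01 * n_def))

    def test_default_criteria_are_study_thresholds(self):
        c = Criteria()
        assert c.q_max == 0.05
        assert c.top_fraction == 0.01

    def test_identical_cohorts_have_no_q_significance(self):
        # same cohort duplicated under two labels: the null contrast
        cfg = simulate.SimulationConfig(
            n_loci=120,
            cohorts=[
                simulate.CohortSpec("a", 12, "x"),
                simulate.CohortSpec("b", 12, "x"),
            ],
            f_between=0.02,
            f_within=0.02,
            missing_rate=0.0,
            seed=25,
        )
        gm, _ = simulate.simulate(cfg)
        from fstscan.bayes_outlier import McmcConfig

        res = run_contrast(
            gm,
            "a",
            "b",
            engine="bayes",
            mcmc=McmcConfig(n_iter=600, burn_in=100, thin=5, n_pilot=3, pilot_len=60, seed=2),
        )
        assert not res.sig_q.any()


def grid_results(flag_grid, tests, refs, n_loci=6):
    """Build ContrastResults from a boolean flag grid indexed
    [test][ref][locus]."""
    loci = [LocusRecord(f"l{j}", "1", (j + 1) * 10, "A", "B") for j in range(n_loci)]
    out = []
    for ti, t in enumerate(tests):
        for ri, r in enumerate(refs):
            flags = np.asarray(flag_grid[ti][ri], dtype=bool)
            out.append(
                ContrastResult(
                    test=t,
                    reference=r,
                    loci=loci,
                    score=np.linspace(0, 1, n_loci),
                    q=None,
                    sig_q=np.zeros(n_loci, dtype=bool),
                    sig_top=flags,
                )
            )
    return out


class TestConsensus:
    def test_defaults_match_sharing_rule(self):
        import inspect

        sig = inspect.signature(consensus)
        assert sig.parameters["min_tests"].default == 4
        assert sig.parameters["min_refs"].default == 3

    def test_locus_significant_everywhere_counts_full_grid(self):
        tests, refs = ["t1", "t2"], ["r1", "r2"]
        grid = [[[True] * 3 for _ in refs] for _ in tests]
        table = consensus(grid_results(grid, tests, refs, 3), 2, 2).table
        assert (table["n_tests_r1"] == 2).all()
        assert (table["n_refs"] == 2).all()
        assert table["retained"].all()

    def test_random_grid_matches_brute_force(self, rng):
        tests = [f"t{i}" for i in range(7)]
        refs = [f"r{i}" for i in range(4)]
        n_loci = 40
        grid = rng.random((7, 4, n_loci)) < 0.25
        results = grid_results(grid, tests, refs, n_loci)
        table = consensus(results, 4, 3).table
        for j in range(n_loci):
            n_refs = 0
            for ri in range(4):
                n_tests = sum(grid[ti][ri][j] for ti in range(7))
                if n_tests >= 4:
                    n_refs += 1
            assert table["n_refs"][j] == n_refs
            assert table["retained"][j] == (n_refs >= 3)

    def test_monotone_in_thresholds(self, rng):
        tests = [f"t{i}" for i in range(5)]
        refs = [f"r{i}" for i in range(3)]
        grid = rng.random((5, 3, 25)) < 0.4
        results = grid_results(grid, tests, refs, 25)
        base = set(consensus(results, 2, 2).retained_loci())
        assert set(consensus(results, 3, 2).retained_loci()) <= base
        assert set(consensus(results, 2, 3).retained_loci()) <= base

    def test_inconsistent_locus_sets_intersected(self):
        tests, refs = ["t1"], ["r1", "r2"]
        grid = [[[True] * 4, [True] * 4]]
        results = grid_results(grid, tests, refs, 4)
        results[1].loci = results[1].loci[:3]
        results[1].score = results[1].score[:3]
        results[1].sig_q = results[1].sig_q[:3]
        results[1].sig_top = results[1].sig_top[:3]
        table = consensus(results, 1, 1).table
        assert len(table) == 3


class TestAnnotation:
    def test_default_half_window(self):
        import inspect

        sig = inspect.signature(annotate_windows)
        assert sig.parameters["half_window"].default == 250_000

    def test_closed_interval_boundary(self):
        locus = LocusRecord("snp", "1", 1_000_000, "A", "B")
        gene = GeneAnnotation("EDGE", "1", 500_000, 750_000)
        hits = annotate_windows([locus], [gene], half_window=250_000)
        assert hits["snp"] == [("EDGE", False)]  # ends exactly at bp - 250 kb

    def test_within_gene_flagged(self):
        locus = LocusRecord("snp", "1", 600_000, "A", "B")
        gene = GeneAnnotation("HOST", "1", 500_000, 750_000)
        hits = annotate_windows([locus], [gene])
        assert hits["snp"] == [("HOST", True)]

    def test_matches_all_pairs_overlap_scan(self, rng):
        genes = []
        for i in range(100):
            start = int(rng.integers(1, 5_000_000))
            genes.append(
                GeneAnnotation(
                    f"g{i}",
                    str(rng.integers(1, 4)),
                    start,
                    start + int(rng.integers(1, 400_000)),
                )
            )
        loci = [
            LocusRecord(f"s{i}", str(rng.integers(1, 4)), int(rng.integers(1, 5_000_000)), "A", "B")
            for i in range(10)
        ]
        hits = annotate_windows(loci, genes, half_window=250_000)
        for locus in loci:
            expect = sorted(
                (g.gene, g.start <= locus.bp <= g.end)
                for g in genes
                if g.chrom == locus.chrom
                and g.start <= locus.bp + 250_000
                and g.end >= locus.bp - 250_000
            )
            assert sorted(hits[locus.id]) == expect

    def test_invariant_to_annotation_order(self, rng):
        genes = [
            GeneAnnotation("a", "1", 100, 500),
            GeneAnnotation("b", "1", 300, 900),
            GeneAnnotation("c", "1", 950, 1200),
        ]
        locus = LocusRecord("s", "1", 600, "A", "B")
        h1 = annotate_windows([locus], genes, half_window=300)
        h2 = annotate_windows([locus], genes[::-1], half_window=300)
        assert h1 == h2

    def test_chromosome_absent_gives_empty_list(self):
        locus = LocusRecord("s", "99", 600, "A", "B")
        hits = annotate_windows([locus], [GeneAnnotation("a", "1", 100, 500)])
        assert hits["s"] == []

    def test_bed_read_converts_to_one_based(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t200\tGENE1\n")
        ann = read_annotation(bed)
        assert ann[0].start == 100 and ann[0].end == 200

    def test_gff3_read_keeps_one_based(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n1\t.\tgene\t100\t200\t.\t+\t.\tID=g1;Name=GENE1\n"
        )
        ann = read_annotation(gff)
        assert ann[0].start == 100 and ann[0].end == 200
        assert ann[0].gene == "GENE1"
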