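"""ABBA/BABA counting, D, f, reference bias and population-frequency D."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radmix import (
    GenotypeMatrix,
    PopulationMap,
    QuartetConfig,
    bootstrap_population_d,
    count_site_patterns,
    d_from_counts,
    enumerate_tests,
    population_dstat,
    reference_bias_analysis,
    run_individual_dstat,
)
from radmix.dstat import ROLE_CONTROL_MAX
from radmix.simulate import ScenarioParams, simulate_frequency_scenario, simulate_mosaic_hybrids

from conftest import matrix_from_genotypes


def _brute_force_patterns(h1, h2, h3, h4):
    """Independent per-site enumeration with explicit two-allele logic."""
    n_abba = n_baba = n_other = 0
    for a, b, c, d in zip(h1, h2, h3, h4):
        if len({a, b, c, d}) != 2:
            n_other += 1
        elif a == d and b == c and a != b:
            n_abba += 1
        elif b == d and a == c and a != b:
            n_baba += 1
        else:
            n_other += 1
    return n_abba, n_baba, n_other


class TestSitePatterns:
    def test_canonical_patterns(self):
        assert count_site_patterns(["A"], ["G"], ["G"], ["A"]) == (1, 0, 0)
        assert count_site_patterns(["G"], ["A"], ["G"], ["A"]) == (0, 1, 0)

    def test_matches_brute_force_on_random_quartets(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            haps = rng.choice(list("ACGT"), size=(4, 50))
            assert count_site_patterns(*haps) == _brute_force_patterns(*haps)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_site_patterns(["A", "A"], ["G"], ["G"], ["A"])


@given(
    n_abba=st.integers(min_value=0, max_value=10_000),
    n_baba=st.integers(min_value=0, max_value=10_000),
)
@settings(derandomize=True, max_examples=200)
def test_d_is_bounded_and_antisymmetric(n_abba, n_baba):
    d = d_from_counts(n_abba, n_baba)
    if n_abba + n_baba == 0:
        assert np.isnan(d)
    else:
        assert -1.0 <= d <= 1.0
        assert d == -d_from_counts(n_baba, n_abba)
        assert (d > 0) == (n_abba > n_baba)


class TestDFromCounts:
    def test_reported_mean_counts_reproduce_reported_d(self):
        # published mean site counts for the two putative hybrid taxa
        assert round(d_from_counts(16.63, 5.56), 2) == 0.50
        assert round(d_from_counts(9.71, 5.99), 2) == 0.24

    def test_symmetry_and_extremes(self):
        assert d_from_counts(7, 7) == 0.0
        assert d_from_counts(5, 0) == 1.0
        assert np.isnan(d_from_counts(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            d_from_counts(-1, 2)


class TestEnumeration:
    PM = PopulationMap(
        {
            "k1": "P1",
            "k2": "P1",
            "k3": "P1",
            "h1": "HYB",
            "r1": "P3",
            "r2": "P3",
            "o1": "OUT",
        }
    )

    def test_paired_scheme_count(self):
        cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT", p2_candidates=["HYB"])
        tests = enumerate_tests(self.PM, cfg, "h1")
        assert len(tests) == 3 * 2 * 1 * 2
        assert {t.haps for t in tests} == {(0, 0, 0, 0), (1, 1, 1, 1)}

    def test_all_haplotypes_scheme_count(self):
        cfg = QuartetConfig(
            p1="P1", p3="P3", outgroup="OUT", p2_candidates=["HYB"],
            allele_scheme="all_haplotypes",
        )
        assert len(enumerate_tests(self.PM, cfg, "h1")) == 3 * 2 * 1 * 16

    def test_leave_one_out_for_controls(self):
        cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
        tests = enumerate_tests(self.PM, cfg, "k1")
        assert all(t.p1 != "k1" for t in tests)
        assert len(tests) == 2 * 2 * 1 * 2

    def test_empty_pool_is_an_error(self):
        cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
        with pytest.raises(ValueError, match="empty"):
            enumerate_tests(self.PM, cfg, "o1")


def test_p2_copied_from_p3_gives_maximal_d(freq_dataset):
    # P3 group of two where one individual's calls are a verbatim copy of the
    # other's: in its control tests the only remaining reference is the donor,
    # so no site can show BABA and every informative test has D = 1.
    gm, _, _ = freq_dataset
    sub = gm.subset_loci(range(500))
    calls = sub.calls.copy()
    pm = PopulationMap(
        {
            **{f"P1_{i:02d}": "P1" for i in range(1, 4)},
            "P3_01": "P3",
            "P3_02": "P3",
            "O_01": "OUT",
        }
    )
    keep = list(pm.assignments)
    idx = [sub.individual_index(i) for i in keep]
    calls = calls[:, idx, :]
    donor, copy = keep.index("P3_01"), keep.index("P3_02")
    calls[:, copy, :] = calls[:, donor, :]
    gm2 = GenotypeMatrix(sub.locus_ids, keep, calls, sub.allele_labels)
    from radmix import filter_complete_biallelic

    gm2 = filter_complete_biallelic(gm2)
    cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
    summary = run_individual_dstat(gm2, pm, cfg)
    rows = summary.per_test.query("role == @ROLE_CONTROL_MAX and p2_individual == 'P3_02'")
    assert len(rows) > 0
    assert (rows["nBABA"] == 0).all()
    assert rows["D"].dropna().eq(1.0).all()


def test_p1_p2_swap_negates_population_d(freq_dataset):
    gm, pm, _ = freq_dataset
    cfg_fwd = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
    cfg_rev = QuartetConfig(p1="H", p3="P3", outgroup="OUT")
    d_fwd = population_dstat(gm, pm, cfg_fwd, "H").d
    d_rev = population_dstat(gm, pm, cfg_rev, "P1").d
    assert d_fwd == pytest.approx(-d_rev, abs=1e-12)


def test_p1_p2_swap_negates_individual_d():
    h = [list("AGGA"), list("GAGA"), list("AAGA"), list("AGAA")]
    a, b, c, d = (np.array(x) for x in h)
    n1, n2, _ = count_site_patterns(a, b, c, d)
    m1, m2, _ = count_site_patterns(b, a, c, d)
    assert (n1, n2) == (m2, m1)


def test_population_d_equals_individual_d_for_haploids():
    # 20 random single-individual homozygous ("haploid") instances
    rng = np.random.default_rng(13)
    checked = 0
    for _ in range(30):
        haps = rng.integers(0, 2, size=(4, 30))
        labels = np.empty((30, 4, 2), dtype=object)
        for l in range(30):
            pair = rng.choice(list("ACGT"), size=2, replace=False)
            for i in range(4):
                labels[l, i, :] = pair[haps[i, l]]
        gm = GenotypeMatrix.from_labels(
            [f"L{l}:1" for l in range(30)], ["i1", "i2", "i3", "i4"], labels
        )
        from radmix import filter_complete_biallelic

        gm = filter_complete_biallelic(gm)
        if gm.n_loci == 0:
            continue
        pm = PopulationMap({"i1": "A", "i2": "B", "i3": "C", "i4": "D"})
        cfg = QuartetConfig(p1="A", p3="C", outgroup="D")
        pop = population_dstat(gm, pm, cfg, "B")
        seqs = [gm.calls[:, i, 0] for i in range(4)]
        n_abba, n_baba, _ = count_site_patterns(*seqs)
        expected = d_from_counts(n_abba, n_baba)
        if np.isnan(expected):
            assert np.isnan(pop.d)
        else:
            assert pop.d == pytest.approx(expected, abs=1e-12)
        checked += 1
    assert checked >= 20


def test_population_d_zero_when_p1_equals_p2():
    # P2 individuals are verbatim copies of P1's: per-locus terms cancel
    gm = matrix_from_genotypes(
        {
            "a1": ["A/G", "C/T", "G/G"],
            "a2": ["A/A", "C/C", "G/T"],
            "b1": ["A/G", "C/T", "G/G"],
            "b2": ["A/A", "C/C", "G/T"],
            "c1": ["G/G", "T/T", "T/T"],
            "o1": ["A/G", "C/C", "G/T"],
        }
    )
    pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "o1": "O"})
    cfg = QuartetConfig(p1="A", p3="C", outgroup="O")
    assert population_dstat(gm, pm, cfg, "B").d == 0.0


def test_all_abba_fixed_configuration_gives_d_one():
    gm = matrix_from_genotypes(
        {
            "p1": ["A/A", "C/C"],
            "p2": ["G/G", "T/T"],
            "p3": ["G/G", "T/T"],
            "o": ["A/A", "C/C"],
        }
    )
    pm = PopulationMap({"p1": "A", "p2": "B", "p3": "C", "o": "O"})
    cfg = QuartetConfig(p1="A", p3="C", outgroup="O")
    assert population_dstat(gm, pm, cfg, "B").d == pytest.approx(1.0)


def test_count_conservation(freq_dataset, default_quartet):
    gm, pm, _ = freq_dataset
    sub = gm.subset_loci(range(300))
    summary = run_individual_dstat(sub, pm, default_quartet)
    assert (summary.per_test["nABBA"] + summary.per_test["nBABA"] <= sub.n_loci).all()
    assert (summary.per_test[["nABBA", "nBABA"]] >= 0).all().all()
    d = summary.per_test["D"].dropna()
    assert d.between(-1, 1).all()


def test_taxon_means_weight_individuals_equally(freq_dataset, default_quartet):
    gm, pm, _ = freq_dataset
    sub = gm.subset_loci(range(300))
    summary = run_individual_dstat(sub, pm, default_quartet)
    for (grp, role), taxon_row in summary.per_taxon.set_index(["p2_group", "role"]).iterrows():
        members = summary.per_individual.query("p2_group == @grp and role == @role")
        assert taxon_row["D_mean"] == pytest.approx(members["D_mean"].mean())
        # paired scheme: N = N1 * N3 * NO * 2 per P2 individual
    h_row = summary.per_individual.query("role == 'candidate'").iloc[0]
    assert h_row["n_tests"] == 8 * 12 * 3 * 2


class TestAdmixtureFraction:
    def test_endpoints(self, freq_dataset, default_quartet):
        gm, pm, _ = freq_dataset
        sub = gm.subset_loci(range(400))
        summary = run_individual_dstat(sub, pm, default_quartet)
        per_ind = summary.per_individual
        # controls at the endpoints: P3-as-P2 near 100%, P1-as-P2 near 0
        assert per_ind.query("role == 'control_max'")["f"].mean() == pytest.approx(100, abs=15)
        assert abs(per_ind.query("role == 'control_zero'")["f"].mean()) < 15

    def test_requires_controls(self, freq_dataset):
        from radmix import admixture_fraction

        gm, pm, _ = freq_dataset
        cfg = QuartetConfig(
            p1="P1", p3="P3", outgroup="OUT", p2_candidates=["H"], include_controls=False
        )
        summary = run_individual_dstat(gm.subset_loci(range(100)), pm, cfg)
        with pytest.raises(ValueError, match="control"):
            admixture_fraction(summary)


class TestReferenceBias:
    def test_weighted_deviations_sum_to_zero(self, freq_dataset, default_quartet):
        gm, pm, _ = freq_dataset
        summary = run_individual_dstat(gm.subset_loci(range(300)), pm, default_quartet)
        tab, pvals = reference_bias_analysis(summary.per_test)
        for role, sub in tab.groupby("role"):
            weighted = (sub["deviation"] * sub["n_tests"]).sum()
            assert weighted == pytest.approx(0.0, abs=1e-9)
        assert set(pvals) == {"p1", "p3", "outgroup"}

    def test_introgressed_p1_individual_is_the_signed_outlier(self):
        # give one P1 individual 30% P3-mosaic haplotypes: its excess P3
        # sharing inflates BABA in tests it anchors, so its deviation is the
        # largest in magnitude and negative
        gm, pm, _ = simulate_frequency_scenario(ScenarioParams(n_loci=1500, f=0.1, seed=9))
        rng = np.random.default_rng(0)
        tgt = gm.individual_index("P1_01")
        p3_idx = [gm.individual_index(i) for i in pm.members("P3")]
        pool = gm.calls[:, p3_idx, :].reshape(gm.n_loci, -1)
        mask = rng.random((gm.n_loci, 2)) < 0.3
        donor = rng.integers(0, pool.shape[1], size=(gm.n_loci, 2))
        calls = gm.calls.copy()
        calls[:, tgt, :] = np.where(
            mask, pool[np.arange(gm.n_loci)[:, None], donor], calls[:, tgt, :]
        )
        gm2 = GenotypeMatrix(gm.locus_ids, gm.individual_ids, calls, gm.allele_labels)
        cfg = QuartetConfig(
            p1="P1", p3="P3", outgroup="OUT", p2_candidates=["H"], include_controls=False
        )
        summary = run_individual_dstat(gm2, pm, cfg)
        tab, pvals = reference_bias_analysis(summary.per_test)
        p1_tab = tab.query("role == 'p1'").set_index("individual")
        dev = p1_tab.loc["P1_01", "deviation"]
        assert dev < 0
        assert abs(dev) == p1_tab["deviation"].abs().max()
        assert p1_tab.loc["P1_01", "outlier"]
        assert pvals["p1"] < 0.05


class TestBootstrap:
    def test_degenerate_frequencies_give_zero_width_range(self):
        gm = matrix_from_genotypes(
            {
                "p1": ["A/A", "C/C"],
                "p2": ["G/G", "T/T"],
                "p3": ["G/G", "T/T"],
                "o": ["A/A", "C/C"],
            }
        )
        pm = PopulationMap({"p1": "A", "p2": "B", "p3": "C", "o": "O"})
        cfg = QuartetConfig(p1="A", p3="C", outgroup="O")
        res = bootstrap_population_d(population_dstat(gm, pm, cfg, "B"), n_reps=50, seed=3)
        assert res.d_range == (res.d, res.d)
        assert res.significant

    def test_deterministic_for_seed(self, freq_dataset):
        gm, pm, _ = freq_dataset
        cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
        r1 = bootstrap_population_d(population_dstat(gm, pm, cfg, "H"), n_reps=30, seed=8)
        r2 = bootstrap_population_d(population_dstat(gm, pm, cfg, "H"), n_reps=30, seed=8)
        np.testing.assert_array_equal(r1.replicates, r2.replicates)

    def test_zero_gene_flow_ranges_scatter_around_zero(self):
        # the binomial bootstrap resamples genotype-sampling noise only (not
        # locus-level drift), so individual zero-flow ranges can miss zero;
        # across datasets they must straddle it with no directional bias and
        # stay inside the empirical control band
        covered = 0
        mids = []
        for seed in range(20):
            gm, pm, _ = simulate_frequency_scenario(
                ScenarioParams(n_loci=1000, f=0.0, seed=500 + seed)
            )
            cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
            res = bootstrap_population_d(
                population_dstat(gm, pm, cfg, "H"), n_reps=100, seed=seed
            )
            assert res.d_range[0] <= res.d <= res.d_range[1]
            assert -0.15 < res.d < 0.15
            covered += res.d_range[0] <= 0 <= res.d_range[1]
            mids.append(res.d)
        assert covered >= 10
        assert abs(np.mean(mids)) < 0.05

    def test_strong_gene_flow_is_declared_significant(self):
        gm, pm, _ = simulate_mosaic_hybrids(
            ScenarioParams(n_loci=1000, mode="mosaic", f=0.5, n_generations=2, seed=6)
        )
        cfg = QuartetConfig(p1="P1", p3="P3", outgroup="OUT")
        res = bootstrap_population_d(population_dstat(gm, pm, cfg, "H"), n_reps=100, seed=6)
        assert res.significant and res.d_range[0] > 0
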