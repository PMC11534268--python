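"""Orchestrated trans-ancestry strategies: reductions, equivalences,
determinism and the replicate-sharing hierarchy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapa import simulate, ta_pathway
from tapa.artp_engine import default_gene_thresholds
from tapa.gwas_io import GeneSnpMap, StudySummary
from tapa.stat_combine import EffectiveSampleSizes, two_sided_p
from tapa.ta_pathway import PathwayAnalyzer, sample_null_z


def small_setup(n_genes=2, snps_per_gene=3, seed=0, labels=None):
    """Tiny design + panels + analyzer inputs for fast orchestration tests."""
    design = simulate.default_design(scale=0.05, n_genes=n_genes,
                                     snps_per_gene=snps_per_gene, seed=seed)
    if labels:
        design.populations = [p for p in design.populations if p.label in labels]
    panels = simulate.make_reference_panels(design, seed)
    gmap = simulate.gene_map(design)
    ess = simulate.effective_sizes(design)
    return design, panels, gmap, ess


def null_studies(design, seed):
    """Synthetic summaries with z drawn iid N(0,1) (null, LD-free)."""
    rng = np.random.default_rng(seed)
    studies = {}
    snps = design.snp_table()
    for pop in design.populations:
        z = rng.standard_normal(len(snps))
        t = snps.assign(beta=z, se=1.0, p=two_sided_p(z))
        studies[pop.label] = StudySummary(
            pop.label, t, n_cases=pop.n_cases, n_controls=pop.n_controls)
    return studies


class TestSampleNullZ:
    def test_identity_cov_variance_bounds(self):
        draws = sample_null_z({"x": np.eye(3)}, 10_000, seed=1)["x"]
        v = draws.var(axis=0)
        assert np.all((v > 0.94) & (v < 1.06))

    def test_correlation_recovered(self):
        V = np.array([[1.0, 0.8], [0.8, 1.0]])
        draws = sample_null_z({"x": V}, 100_000, seed=2)["x"]
        assert np.corrcoef(draws.T)[0, 1] == pytest.approx(0.8, abs=0.02)

    def test_bit_identical_under_seed(self):
        a = sample_null_z({"x": np.eye(2), "y": np.eye(2)}, 1000, seed=3)
        b = sample_null_z({"y": np.eye(2), "x": np.eye(2)}, 1000, seed=3)
        np.testing.assert_array_equal(a["x"], b["x"])
        np.testing.assert_array_equal(a["y"], b["y"])


class TestSingleGeneReductions:
    def test_single_snp_gene_tau_matches_analytic_p(self):
        """With one SNP and c=(1,), tau0 is the resampling-calibrated
        version of the TA-SNP p-value."""
        design, panels, gmap, ess = small_setup(n_genes=1, snps_per_gene=1)
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=2000, seed=4)
        studies = null_studies(design, seed=5)
        res = analyzer.run(studies, methods=["SNP-IVW"])
        # equal se: the standardized IVW statistic is sum(z)/sqrt(L)
        z = np.array([s.z[0] for s in studies.values()])
        p_ivw = two_sided_p(z.sum() / np.sqrt(len(z)))
        assert res["SNP-IVW"].p_value == pytest.approx(p_ivw, abs=0.05)

    def test_all_null_z_gives_large_tau(self):
        design, panels, gmap, ess = small_setup(n_genes=2, snps_per_gene=2)
        snps = design.snp_table()
        studies = {}
        for pop in design.populations:
            t = snps.assign(beta=0.0, se=1.0, p=1.0)
            studies[pop.label] = StudySummary(
                pop.label, t, n_cases=pop.n_cases, n_controls=pop.n_controls)
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=500, seed=6)
        res = analyzer.run(studies)
        for m in ("SNP-IVW", "SNP-max", "SNP-wFisher"):
            assert res[m].p_value > 0.9


def test_ivw_shortcut_and_per_ancestry_routes_agree_in_distribution():
    """Drawing IVW statistics from their assembled covariance and
    combining per-ancestry z draws give indistinguishable gene
    p-values under the null (two-sample KS)."""
    design, panels, gmap, ess = small_setup(n_genes=2, snps_per_gene=4, seed=7)
    a_short = PathwayAnalyzer(gmap, panels, ess, n_replicates=400, seed=8,
                              ivw_route="shortcut")
    a_anc = PathwayAnalyzer(gmap, panels, ess, n_replicates=400, seed=8,
                            ivw_route="per-ancestry")
    p_short, p_anc = [], []
    for d in range(250):
        studies = null_studies(design, seed=1000 + d)
        p_short.append(a_short.run(studies, methods=["SNP-IVW"],
                                   dataset=d)["SNP-IVW"].p_value)
        p_anc.append(a_anc.run(studies, methods=["SNP-IVW"],
                               dataset=d)["SNP-IVW"].p_value)
    ks = stats.ks_2samp(p_short, p_anc)
    assert ks.pvalue > 0.01


class TestGeneCentric:
    def test_single_ancestry_identity(self):
        tau = np.random.default_rng(0).random((1, 101, 3))
        avail = np.ones((1, 3), dtype=bool)
        ess1 = EffectiveSampleSizes.from_totals(("a",), [100.0])
        out = ta_pathway.gene_centric_gene_p(tau, avail, "wfisher", ess1)
        np.testing.assert_allclose(out, np.maximum(tau[0], 0.5 / 101),
                                   rtol=1e-10)
        out_min = ta_pathway.gene_centric_gene_p(tau, avail, "minp", ess1)
        np.testing.assert_allclose(out_min, np.maximum(tau[0], 0.5 / 101))

    def test_equal_ess_wfisher_is_fisher(self):
        rng = np.random.default_rng(1)
        tau = rng.uniform(0.02, 1.0, (2, 51, 2))  # above the 0.5/M floor
        avail = np.ones((2, 2), dtype=bool)
        ess = EffectiveSampleSizes.from_totals(("a", "b"), [100.0, 100.0])
        out = ta_pathway.gene_centric_gene_p(tau, avail, "wfisher", ess)
        fisher = stats.chi2.sf(-2 * np.log(tau).sum(axis=0), 4)
        np.testing.assert_allclose(out, fisher, rtol=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ta_pathway.gene_centric_gene_p(
                np.ones((1, 101, 1)), np.ones((1, 1), bool), "median",
                EffectiveSampleSizes.from_totals(("a",), [10.0]))


class TestPathwayLevel:
    def test_default_gene_thresholds_examples(self):
        assert list(default_gene_thresholds(100)) == [5, 10, 15, 20, 25,
                                                      30, 35, 40, 45, 50]
        assert list(default_gene_thresholds(3)) == [1, 2, 3]

    def test_tie_order_of_selected_genes(self):
        """All gene p equal: selection falls back to gene id order."""
        design, panels, gmap, ess = small_setup(n_genes=3, snps_per_gene=2)
        studies = {}
        snps = design.snp_table()
        for pop in design.populations:
            t = snps.assign(beta=0.0, se=1.0, p=1.0)
            studies[pop.label] = StudySummary(
                pop.label, t, n_cases=pop.n_cases, n_controls=pop.n_controls)
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=300, seed=9)
        res = analyzer.run(studies, methods=["SNP-IVW"])
        sel = res["SNP-IVW"].selected_genes
        assert sel == sorted(sel)

    def test_path_joint_and_composite_present(self):
        design, panels, gmap, ess = small_setup()
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=200, seed=10)
        res = analyzer.run(null_studies(design, 11))
        assert set(ta_pathway.ALL_METHODS) <= set(res)
        assert any(k.startswith("Path-") for k in res)
        acat = ta_pathway.acat_composite(res["SNP-IVW"].p_value,
                                         res["Gene-wFisher"].p_value,
                                         n_replicates=200)
        assert res["ACAT-IVW-wFisher"].p_value == pytest.approx(acat)

    def test_acat_composite_equal_inputs(self):
        assert ta_pathway.acat_composite(0.2, 0.2) == pytest.approx(0.2,
                                                                    rel=1e-12)
        # grid zeros are floored before combination
        assert 0 < ta_pathway.acat_composite(0.0, 0.0, n_replicates=999) < 0.01


class TestInvariances:
    def test_results_invariant_to_input_ordering(self):
        design, panels, gmap, ess = small_setup(n_genes=3, snps_per_gene=3,
                                                seed=12)
        studies = null_studies(design, 13)
        analyzer1 = PathwayAnalyzer(gmap, panels, ess, n_replicates=300,
                                    seed=14)
        res1 = analyzer1.run(studies)
        # shuffle study rows, gene listing order, and dict insertion order
        studies2 = {}
        for label in reversed(list(studies)):
            t = studies[label].table.sample(frac=1.0, random_state=1)
            studies2[label] = studies[label].replace_table(t)
        gmap2 = GeneSnpMap(
            gmap.genes.iloc[::-1].reset_index(drop=True),
            dict(reversed(list(gmap.assignments.items()))),
            gmap.pathway_name,
        )
        panels2 = dict(reversed(list(panels.items())))
        analyzer2 = PathwayAnalyzer(gmap2, panels2, ess, n_replicates=300,
                                    seed=14)
        res2 = analyzer2.run(studies2)
        for m in res1:
            assert res1[m].p_value == res2[m].p_value
            assert res1[m].selected_genes == res2[m].selected_genes

    def test_repeat_run_identical(self):
        design, panels, gmap, ess = small_setup(seed=15)
        studies = null_studies(design, 16)
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=300, seed=17)
        r1 = analyzer.run(studies)
        r2 = analyzer.run(studies)
        for m in r1:
            assert r1[m].p_value == r2[m].p_value

    def test_missing_gene_in_one_ancestry_handled(self):
        """A gene absent from one study is combined over the rest."""
        design, panels, gmap, ess = small_setup(n_genes=2, snps_per_gene=3,
                                                seed=18)
        studies = null_studies(design, 19)
        # remove gene 0's SNPs from AFR entirely
        afr = studies["AFR"]
        t = afr.table[~afr.table["snp"].str.startswith("rs000")]
        studies["AFR"] = afr.replace_table(t)
        analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=200, seed=20)
        res = analyzer.run(studies)
        assert 0 < res["Gene-wFisher"].p_value <= 1
        assert res["Gene-wFisher"].J_effective == 2


def test_pathway_result_fields():
    design, panels, gmap, ess = small_setup(seed=21)
    analyzer = PathwayAnalyzer(gmap, panels, ess, n_replicates=200, seed=22)
    res = analyzer.run(null_studies(design, 23), methods=["SNP-max"])
    r = res["SNP-max"]
    assert r.method == "SNP-max"
    assert set(r.gene_pvalues) == set(gmap.assignments)
    assert len(r.selected_genes) == min(r.best_threshold, r.J_effective)
    grid = np.arange(201) / 201
    assert np.isclose(grid, r.p_value).any()
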