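"""Per-SNP structure expansion, SNP -> factor estimation, vectorized
multivariate GWAS, and locus clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gibnet import (
    CFAFit,
    FactorGWASError,
    FactorModelSpec,
    clump_loci,
    fit_snp_to_factors,
    multivariate_gwas,
    snp_expanded_structure,
)
from gibnet.factor_gwas import FactorGWASTable, factor_sumstats
from gibnet.simulate import TruthParams, simulate_sumstats
from tests.conftest import standardized, true_spec_for


class TestExpansion:
    def test_zero_effects_and_genotype_variance(self, parity_structures):
        gs = parity_structures["even"]
        betas = {t: 0.0 for t in gs.traits}
        ses = {t: 0.01 for t in gs.traits}
        exp = snp_expanded_structure(gs, betas, ses, maf=0.5)
        assert exp.var_snp == pytest.approx(0.5)
        np.testing.assert_array_equal(exp.s_snp, 0.0)
        mat = exp.expanded_matrix(gs.S)
        assert mat.shape == (9, 9)
        assert mat[8, 8] == pytest.approx(0.5)

    def test_covariance_entries_scale_with_beta(self, parity_structures):
        gs = parity_structures["even"]
        betas = {t: 0.02 for t in gs.traits}
        ses = {t: 0.01 for t in gs.traits}
        exp = snp_expanded_structure(gs, betas, ses, maf=0.25)
        var_g = 2 * 0.25 * 0.75
        np.testing.assert_allclose(exp.s_snp, 0.02 * var_g)
        np.testing.assert_allclose(exp.var_s_snp, (0.01 * var_g) ** 2)

    def test_missing_trait_and_bad_maf_fatal(self, parity_structures):
        gs = parity_structures["even"]
        with pytest.raises(FactorGWASError, match="missing"):
            snp_expanded_structure(gs, {}, {}, 0.3)
        betas = {t: 0.0 for t in gs.traits}
        ses = {t: 0.01 for t in gs.traits}
        with pytest.raises(FactorGWASError, match="maf"):
            snp_expanded_structure(gs, betas, ses, 0.7)

    def test_expansion_matches_individual_level_simulation(self):
        # empirical cov(genotype, trait) in a small raw-data simulation
        rng = np.random.default_rng(9)
        n, maf, beta = 200_000, 0.3, 0.05
        g = rng.binomial(2, maf, size=n).astype(float)
        y = beta * g + rng.standard_normal(n)
        emp_cov = np.cov(g, y)[0, 1]
        var_g = 2 * maf * (1 - maf)
        mc_se = np.sqrt(var_g / n) * 3  # rough MC scale
        assert emp_cov == pytest.approx(beta * var_g, abs=3 * mc_se)


def _passthrough_fit():
    spec = FactorModelSpec(("a", "b"), ("F1",), (("a", "F1"), ("b", "F1")))
    est = {"lambda:a:F1": 1.0, "lambda:b:F1": 1.0, "theta:a": 1e-6, "theta:b": 1e-6}
    return spec, CFAFit(spec, est, {k: 0.1 for k in est}, 0.0, 1, 0.0, 1.0, 0.0, True)


class TestSnpToFactors:
    def test_passthrough_identity(self, parity_structures):
        # a single informative indicator with loading 1: the factor effect
        # equals the trait beta (the second indicator is uninformative)
        spec, fit = _passthrough_fit()
        gs = parity_structures["even"].subset(("region01", "region02"))
        gs = type(gs)(("a", "b"), np.eye(2), np.eye(3) * 1e-4, np.eye(2), standardized=True)
        exp = snp_expanded_structure(
            gs, {"a": 0.0321, "b": 0.0}, {"a": 0.01, "b": 1e6}, 0.3
        )
        out = fit_snp_to_factors(exp, spec, fit)
        assert out["beta_f"][0] == pytest.approx(0.0321, abs=1e-8)

    def test_zero_covariance_gives_zero_effect(self, true_spec, cfa_fit, parity_structures):
        gs = parity_structures["even_std"]
        exp = snp_expanded_structure(
            gs, {t: 0.0 for t in gs.traits}, {t: 0.01 for t in gs.traits}, 0.3
        )
        out = fit_snp_to_factors(exp, true_spec, cfa_fit)
        np.testing.assert_allclose(out["beta_f"], 0.0, atol=1e-12)
        assert np.all(out["pval_f"] == 1.0)


@pytest.fixture(scope="module")
def causal_run(small_truth, true_spec, cfa_fit, parity_structures):
    causal = tuple((i * 251 + 7, 0, 0.05) for i in range(40))
    truth = TruthParams(m=small_truth.m, n_ld_blocks=small_truth.n_ld_blocks,
                        seed=202, causal=causal)
    study = simulate_sumstats(truth, mode="causal")
    gwas = multivariate_gwas(study.tables, parity_structures["even"], true_spec, cfa_fit)
    ids = [study.ld.df["snp_id"].iloc[i] for i, _, _ in causal]
    return study, gwas, ids


class TestMultivariateGWAS:
    def test_causal_effect_recovered(self, causal_run):
        _, gwas, ids = causal_run
        sub = gwas.for_factor("F1").set_index("snp_id").loc[ids]
        assert sub["beta_f"].mean() == pytest.approx(0.05, abs=0.02)

    def test_vectorized_matches_single_snp_path(self, causal_run, true_spec, cfa_fit,
                                                parity_structures):
        study, gwas, ids = causal_run
        gs = parity_structures["even"]
        sub = gs.subset(true_spec.regions)
        snp = ids[0]
        betas, ses = {}, {}
        for t in study.tables:
            row = t.df.set_index("snp_id").loc[snp]
            betas[t.trait_name], ses[t.trait_name] = float(row["beta"]), float(row["se"])
        maf = float(study.tables[0].df.set_index("snp_id").loc[snp, "maf"])
        exp = snp_expanded_structure(gs, betas, ses, maf)
        one = fit_snp_to_factors(exp, true_spec, cfa_fit, np.diag(sub.S))
        for fi, f in enumerate(true_spec.factors):
            vec = gwas.for_factor(f).set_index("snp_id").loc[snp]
            assert one["beta_f"][fi] == pytest.approx(vec["beta_f"], abs=1e-10)
            assert one["se_f"][fi] == pytest.approx(vec["se_f"], abs=1e-10)

    def test_removing_nonindicator_trait_is_local(self, small_truth, parity_structures,
                                                  cfa_fit):
        # spec that never loads the last trait: dropping that trait's table
        # cannot change the factor results
        regions = small_truth.trait_names
        spec = FactorModelSpec(
            regions[:7], ("F1", "F2"),
            tuple((regions[i], "F1") for i in range(4))
            + tuple((regions[i], "F2") for i in range(4, 7)),
        )
        gs = parity_structures["even"]
        study = simulate_sumstats(small_truth)
        fit = CFAFit(spec, {**{f"lambda:{r}:{f}": 0.65 for r, f in spec.free_loadings},
                            **{f"theta:{r}": 0.5 for r in spec.regions},
                            "psi:F1:F2": 0.7},
                     {}, 1.0, 1, 1.0, 1.0, 0.0, True)
        full = multivariate_gwas(study.tables, gs, spec, fit)
        reduced = multivariate_gwas(study.tables[:7], gs, spec, fit)
        pd.testing.assert_frame_equal(full.df, reduced.df, atol=1e-10, rtol=0)

    def test_pvalues_uniform_under_pure_null(self, true_spec, cfa_fit, parity_structures):
        truth = TruthParams(h2=1e-8, m=12_000, n_ld_blocks=480, seed=55)
        study = simulate_sumstats(truth)
        gwas = multivariate_gwas(study.tables, parity_structures["even"], true_spec, cfa_fit)
        for f in gwas.factors:
            p = gwas.for_factor(f)["pval_f"]
            assert stats.kstest(p, "uniform").pvalue > 0.01
            assert 0.93 < gwas.lambdas[f] < 1.07

    def test_factor_sumstats_export_has_capped_neff(self, causal_run):
        _, gwas, _ = causal_run
        tab = factor_sumstats(gwas, "F1")
        var_g = 2 * tab.df["maf"] * (1 - tab.df["maf"])
        expected = 1.0 / (var_g * tab.df["se"] ** 2)
        cap = expected.quantile(0.99)
        assert tab.df["n"].max() <= cap * (1 + 1e-12)


def _gwas_frame(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "pval_f"])
    df["factor"] = "F1"
    return FactorGWASTable(df, ("F1",), {"F1": 1.0})


def _clump_oracle(snps, p_threshold, window):
    """Naive reimplementation: repeated scans over a list, then pairwise
    span merging."""
    gws = sorted([s for s in snps if s[3] < p_threshold], key=lambda s: s[3])
    loci = []
    while gws:
        lead = gws[0]
        members = [s for s in gws if s[1] == lead[1] and abs(s[2] - lead[2]) <= window]
        loci.append({
            "chrom": lead[1],
            "start": min(s[2] for s in members),
            "end": max(s[2] for s in members),
            "min_p": lead[3],
        })
        gws = [s for s in gws if s not in members]
    changed = True
    while changed:
        changed = False
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                a, b = loci[i], loci[j]
                if a["chrom"] == b["chrom"] and a["start"] <= b["end"] and b["start"] <= a["end"]:
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["min_p"] = min(a["min_p"], b["min_p"])
                    del loci[j]
                    changed = True
                    break
            if changed:
                break
    return sorted([(L["chrom"], L["start"], L["end"]) for L in loci])


class TestClumping:
    def test_window_rule_two_snps_one_locus(self):
        g = _gwas_frame([("rs1", 1, 100_000, 1e-9), ("rs2", 1, 200_000, 1e-10)])
        loci = clump_loci(g, window=250_000)
        assert len(loci) == 1
        assert loci.iloc[0]["lead_snp"] == "rs2"
        assert loci.iloc[0]["n_snps"] == 2

    def test_no_significant_snps_empty(self):
        g = _gwas_frame([("rs1", 1, 100, 1e-4)])
        assert len(clump_loci(g)) == 0

    def test_matches_bruteforce_on_random_configs(self):
        rng = np.random.default_rng(17)
        for rep in range(200):
            n = rng.integers(2, 25)
            snps = [(f"rs{i}", int(rng.integers(1, 4)), int(rng.integers(0, 2_000_000)),
                     float(10 ** -rng.uniform(2, 12))) for i in range(n)]
            window = int(rng.integers(50_000, 500_000))
            got = clump_loci(_gwas_frame(snps), p_threshold=5e-8, window=window)
            got_spans = sorted(
                [(int(r["chrom"]), int(r["start"]), int(r["end"])) for _, r in got.iterrows()]
            )
            assert got_spans == _clump_oracle(snps, 5e-8, window)

    def test_locus_count_nonincreasing_in_window(self):
        rng = np.random.default_rng(23)
        for rep in range(30):
            n = rng.integers(3, 30)
            snps = [(f"rs{i}", 1, int(rng.integers(0, 3_000_000)),
                     float(10 ** -rng.uniform(6, 12))) for i in range(n)]
            counts = [len(clump_loci(_gwas_frame(snps), window=w))
                      for w in (50_000, 150_000, 400_000, 1_000_000)]
            assert counts == sorted(counts, reverse=True)
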