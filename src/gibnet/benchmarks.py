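"""Replicated validation benchmarks on the synthetic study conditions.

Each routine regenerates data under the default planted truth (8 traits, two
factors with loading blocks 0.7/0.6, inter-factor correlation 0.7,
h2 = 0.25, N = M = 50,000), runs the corresponding pipeline stage from
scratch, and summarizes recovery/calibration.  They back both the
acceptance-style tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from . import factor_models as fm
from . import factor_gwas as fg
from . import overlap as ov
from . import simulate as sim
from .ldsc import (
    CHI2_WINSOR,
    GeneticCovarianceStructure,
    _block_starts,
    _fit_univariate,
    _jackknife,
    _jackknife_se,
    _merge_arrays,
    build_covariance_structure,
    smooth_to_psd,
    standardize_structure,
    unvech,
    vech,
    vech_indices,
)
from .sumstats import select_chromosome_parity

GWS = 5e-8


def _spawn(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def _standardize(gs: GeneticCovarianceStructure) -> GeneticCovarianceStructure:
    std = standardize_structure(gs)
    S_psd, _ = smooth_to_psd(std.S)
    return GeneticCovarianceStructure(std.traits, S_psd, std.V, std.intercepts,
                                      standardized=True)


def _true_spec(truth: sim.TruthParams) -> fm.FactorModelSpec:
    regions = truth.trait_names
    free = tuple(
        (regions[r], f"F{f + 1}")
        for r in range(truth.p) for f in range(truth.k)
        if truth.lambda_[r, f] != 0
    )
    return fm.FactorModelSpec(regions, tuple(f"F{f + 1}" for f in range(truth.k)), free)


# ---------------------------------------------------------------------------


def ldsc_recovery(n_reps: int = 50, seed: int = 0, n_blocks: int = 200) -> dict:
    """Univariate LDSC on the default fixture: the fraction of per-trait h2
    estimates within +/- 3 jackknife SEs of the planted 0.25, and the mean
    recovered intercept (planted 1.0)."""
    seeds = _spawn(seed, n_reps)
    covered = total = 0
    intercepts = []
    for s in seeds:
        truth = sim.default_truth(seed=s)
        study = sim.simulate_sumstats(truth)
        Z, N, ell = _merge_arrays(study.tables, study.ld)
        starts = _block_starts(len(ell), n_blocks)
        for t in range(truth.p):
            chi2 = np.minimum(Z[:, t] ** 2, CHI2_WINSOR)
            x = N[:, t] / study.ld.m * ell
            _, _, w = _fit_univariate(chi2, ell, x)
            (intercept, h2), theta_del = _jackknife(chi2, x, w, starts)
            se_h2 = _jackknife_se(theta_del)[1]
            covered += int(abs(h2 - truth.h2[t]) <= 3 * se_h2)
            total += 1
            intercepts.append(intercept)
    return {
        "h2_coverage": covered / total,
        "n_checks": total,
        "intercept_mean": float(np.mean(intercepts)),
    }


def factor_structure_recovery(n_reps: int = 50, seed: int = 0,
                              k_max: int = 7) -> dict:
    """Full EFA(odd) -> CFA(even) model discovery on the default fixture.

    Reports the fraction of replicates whose AIC-selected model has the
    planted 2 factors, plus loading error / SRMR / CFI of the true-pattern
    fit on the even-chromosome structure.
    """
    seeds = _spawn(seed, n_reps)
    k_selected, load_err, srmrs, cfis, psis = [], [], [], [], []
    for s in seeds:
        truth = sim.default_truth(seed=s)
        spec_true = _true_spec(truth)
        study = sim.simulate_sumstats(truth)
        gs = {}
        for par in ("odd", "even"):
            tabs = [select_chromosome_parity(t, par) for t in study.tables]
            gs[par] = _standardize(build_covariance_structure(tabs, study.ld))

        fits, seen = [], set()
        for k in range(1, min(k_max, truth.p - 1) + 1):
            efa = fm.run_efa(gs["odd"], k)
            if not efa.converged:
                continue
            for cutoff in (0.3, 0.5):
                try:
                    spec = fm.build_cfa_spec(efa, cutoff)
                except fm.FactorModelError:
                    continue
                key = (spec.factors, spec.free_loadings)
                if key in seen:
                    continue
                seen.add(key)
                fit = fm.fit_cfa(fm.embed_spec(spec, gs["even"].traits), gs["even"])
                if fit.converged:
                    try:
                        fit = fm.prune_loadings(fit, gs["even"])
                    except fm.FactorModelError:
                        pass
                fits.append(fit)
        sel = fm.select_model(fits)
        k_selected.append(sel.n_factors)

        fit_true = fm.fit_cfa(spec_true, gs["even"])
        if fit_true.converged:
            lam = fit_true.loading_matrix()
            err = np.abs(lam - truth.lambda_)[truth.lambda_ != 0]
            load_err.append(float(err.max()))
            srmrs.append(fit_true.srmr)
            cfis.append(fit_true.cfi)
            psis.append(fit_true.factor_correlation_matrix()[0, 1])
    return {
        "k2_rate": float(np.mean(np.asarray(k_selected) == 2)),
        "n_reps": n_reps,
        "loading_max_err_mean": float(np.mean(load_err)),
        "loading_within_0.1_rate": float(np.mean(np.asarray(load_err) <= 0.1)),
        "srmr_mean": float(np.mean(srmrs)),
        "cfi_mean": float(np.mean(cfis)),
        "psi12_mean": float(np.mean(psis)),
    }


def chi2_calibration(n_reps: int = 200, seed: int = 0) -> dict:
    """Mean model chi-square over df for data drawn exactly under the
    2-factor model, with the sampling covariance V taken from one simulated
    even-chromosome structure (scaled-down replicates: the perturbed
    correlation matrices are drawn directly from N(sigma(theta), V))."""
    seeds = _spawn(seed, 2)
    truth = sim.default_truth(seed=seeds[0])
    spec = _true_spec(truth)
    study = sim.simulate_sumstats(truth)
    tabs = [select_chromosome_parity(t, "even") for t in study.tables]
    std = standardize_structure(build_covariance_structure(tabs, study.ld))
    V = std.V
    p = truth.p
    s_true = vech(truth.sigma_corr)

    rng = np.random.default_rng(seeds[1])
    evals, evecs = np.linalg.eigh((V + V.T) / 2.0)
    chol = evecs * np.sqrt(np.clip(evals, 0, None))
    chis, dfs = [], []
    for _ in range(n_reps):
        s = s_true + chol @ rng.standard_normal(len(s_true))
        S = unvech(s, p)
        np.fill_diagonal(S, 1.0)
        gs = GeneticCovarianceStructure(truth.trait_names, S, V, np.eye(p),
                                        standardized=True)
        fit = fm.fit_cfa(spec, gs)
        if fit.converged:
            chis.append(fit.chi2)
            dfs.append(fit.df)
    return {
        "chi2_mean": float(np.mean(chis)),
        "df": int(dfs[0]),
        "chi2_over_df": float(np.mean(chis) / dfs[0]),
        "n_converged": len(chis),
    }


def _reference_fit(seed: int):
    """A converged CFA fit of the true pattern, for fixing the measurement
    model in the factor GWAS benchmarks."""
    truth = sim.default_truth(seed=seed)
    spec = _true_spec(truth)
    study = sim.simulate_sumstats(truth)
    tabs = [select_chromosome_parity(t, "even") for t in study.tables]
    gs = build_covariance_structure(tabs, study.ld)
    fit = fm.fit_cfa(spec, _standardize(gs))
    if not fit.converged:
        raise RuntimeError("reference CFA did not converge")
    return truth, spec, gs, fit


def gwas_null_inflation(seed: int = 0) -> dict:
    """Per-factor genomic inflation of the multivariate GWAS on traits with
    no genetic signal and no confounding (all Z standard normal)."""
    seeds = _spawn(seed, 2)
    truth, spec, gs, fit = _reference_fit(seeds[0])
    null_truth = sim.TruthParams(h2=1e-8, seed=seeds[1])
    null = sim.simulate_sumstats(null_truth)
    gwas = fg.multivariate_gwas(null.tables, gs, spec, fit)
    return {f: float(v) for f, v in gwas.lambdas.items()}


def predicted_power(gamma: float, maf: float, ell: float,
                    truth: sim.TruthParams, factor: int = 0,
                    alpha: float = GWS) -> float:
    """Normal-approximation power of the factor GWAS for a per-allele causal
    effect ``gamma`` acting through one factor, under the generative model:
    mean z = gamma / se_f with se_f from the GLS combination of the
    indicator betas at their exact sampling errors, and variance 1 plus the
    polygenic-background contribution ell/M projected through the same
    combination."""
    lam_cov = np.sqrt(truth.h2)[:, None] * truth.lambda_
    sg2 = 2.0 * maf * (1.0 - maf)
    d = truth.n * sg2
    A = lam_cov.T @ (d[:, None] * lam_cov)
    cov = np.linalg.inv(A)
    se_f = np.sqrt(cov[factor, factor])
    G = cov @ lam_cov.T @ np.diag(d)
    cov_bg = G @ (ell * truth.s_true / (truth.m * sg2)) @ G.T
    v = cov_bg[factor, factor] / se_f**2
    zc = _stats.norm.isf(alpha / 2)
    ncp = gamma / se_f
    s = np.sqrt(1.0 + v)
    return float(_stats.norm.sf((zc - ncp) / s) + _stats.norm.sf((zc + ncp) / s))


def gwas_power(n_reps: int = 50, seed: int = 0, gamma: float = 0.08,
               n_causal: int = 40) -> dict:
    """Empirical vs predicted genome-wide-significance rate for causal SNPs
    acting through the 4-indicator first factor at per-allele effect
    ``gamma``, and the single-best-indicator comparison (multivariate gain)."""
    seeds = _spawn(seed, n_reps + 1)
    truth0, spec, gs, fit = _reference_fit(seeds[-1])
    emp, pred, emp_single = [], [], []
    for s in seeds[:-1]:
        causal = tuple((i * 600 + 7, 0, gamma) for i in range(n_causal))
        truth = sim.TruthParams(seed=s, causal=causal)
        study = sim.simulate_sumstats(truth, mode="causal")
        gwas = fg.multivariate_gwas(study.tables, gs, spec, fit)
        ids = [study.ld.df["snp_id"].iloc[i] for i, _, _ in causal]
        sub = gwas.for_factor("F1").set_index("snp_id").loc[ids]
        emp.append(float((sub["pval_f"] < GWS).mean()))
        mafs = study.tables[0].df.set_index("snp_id").loc[ids, "maf"].to_numpy()
        ells = study.ld.df.set_index("snp_id").loc[ids, "ell"].to_numpy()
        pred.append(float(np.mean([predicted_power(gamma, m, e, truth)
                                   for m, e in zip(mafs, ells)])))
        best = 0.0
        for t in range(4):  # indicators of the first factor
            ptab = study.tables[t].df.set_index("snp_id").loc[ids, "pval"]
            best = max(best, float((ptab < GWS).mean()))
        emp_single.append(best)
    return {
        "power_empirical": float(np.mean(emp)),
        "power_predicted": float(np.mean(pred)),
        "power_best_single_trait": float(np.mean(emp_single)),
        "n_reps": n_reps,
    }


def overlap_oracles(seed: int = 0, n_iter: int = 100_000) -> dict:
    """Permutation p against exact enumeration on a 5-region universe,
    BH-FDR against the hand step-up values, and the unit-weight Dice hand
    example 2*2/(3+3)."""
    import itertools

    universe = tuple("abcde")
    b = ov.RegionSet("b", frozenset("ab"), universe)
    observed = 0.5
    exact = float(np.mean([
        (2 * len(set(c) & b.members) / 4) >= observed - 1e-12
        for c in itertools.combinations(universe, 2)
    ]))
    p_perm = ov.permutation_pvalue(2, b, universe, observed, n_iter=n_iter, seed=seed)

    bh = ov.bh_fdr([0.01, 0.02, 0.03, 0.04])
    bh_err = float(np.max(np.abs(bh - 0.04)))

    u10 = tuple(f"r{i}" for i in range(10))
    a = ov.RegionSet("a", frozenset(["r1", "r2", "r3"]), u10)
    c = ov.RegionSet("c", frozenset(["r2", "r3", "r4"]), u10)
    return {
        "perm_p": float(p_perm),
        "perm_p_exact": exact,
        "perm_abs_error": float(abs(p_perm - exact)),
        "bh_max_abs_error": bh_err,
        "dice_hand": float(ov.dice(a, c)),
    }


def equicorrelated_cfa() -> dict:
    """The analytic single-factor case: equicorrelated 4x4 matrix with
    r = 0.49 has exact ML loadings 0.7."""
    p = 4
    S = np.full((p, p), 0.49)
    np.fill_diagonal(S, 1.0)
    q = p * (p + 1) // 2
    rows, cols = vech_indices(p)
    V = np.eye(q) * 1e-6
    V[rows == cols] = 0.0
    gs = GeneticCovarianceStructure(tuple("abcd"), S, V, np.eye(p), standardized=True)
    spec = fm.FactorModelSpec(tuple("abcd"), ("F1",),
                              tuple((r, "F1") for r in "abcd"))
    fit = fm.fit_cfa(spec, gs)
    lam = fit.loading_matrix().ravel()
    return {
        "loading_max_abs_error": float(np.max(np.abs(lam - 0.7))),
        "srmr": float(fit.srmr),
        "cfi": float(fit.cfi),
        "converged": bool(fit.converged),
    }
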