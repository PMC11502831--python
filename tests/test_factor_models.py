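"""EFA extraction/rotation, CFA specification building, DWLS fitting,
fit indices, pruning, and AIC model selection."""

import itertools

import numpy as np
import pytest

from gibnet import (
    CFAFit,
    FactorModelError,
    FactorModelSpec,
    GeneticCovarianceStructure,
    build_cfa_spec,
    embed_spec,
    fit_cfa,
    fit_indices,
    independence_fit,
    prune_loadings,
    run_efa,
    select_model,
)
from gibnet.factor_models import EFAResult
from gibnet.ldsc import vech, vech_indices


def _structure(S, v_scale=1e-4, traits=None, standardized=True):
    p = S.shape[0]
    q = p * (p + 1) // 2
    traits = traits or tuple(f"r{i}" for i in range(p))
    V = np.eye(q) * v_scale
    if standardized:
        rows, cols = vech_indices(p)
        V[rows == cols] = 0.0
    return GeneticCovarianceStructure(traits, S, V, np.eye(p), standardized=standardized)


class TestEFA:
    def test_equicorrelated_one_factor_analytic(self):
        R = np.full((4, 4), 0.49)
        np.fill_diagonal(R, 1.0)
        efa = run_efa(R, 1)
        assert efa.converged
        np.testing.assert_allclose(efa.loadings.ravel(), 0.7, atol=1e-4)
        assert efa.eigenvalues.sum() == pytest.approx(4.0, abs=1e-6)

    def test_two_block_structure_recovered(self):
        R = np.full((6, 6), 0.1)
        R[:3, :3] = 0.6
        R[3:, 3:] = 0.6
        np.fill_diagonal(R, 1.0)
        efa = run_efa(R, 2)
        lam = efa.loadings
        # each block loads > 0.5 on its own factor, < 0.3 on the other
        own = [np.argmax(np.abs(lam[i])) for i in (0, 3)]
        assert own[0] != own[1]
        for i in range(3):
            assert lam[i, own[0]] > 0.5 and abs(lam[i, own[1]]) < 0.3
        for i in range(3, 6):
            assert lam[i, own[1]] > 0.5 and abs(lam[i, own[0]]) < 0.3

    def test_factor_count_bounds_fatal(self):
        R = np.eye(3)
        with pytest.raises(FactorModelError):
            run_efa(R, 3)
        with pytest.raises(FactorModelError):
            run_efa(R, 0)

    def test_sign_convention_positive_column_sums(self, parity_structures):
        efa = run_efa(parity_structures["odd_std"], 2)
        assert np.all(efa.loadings.sum(axis=0) > 0)


def _efa_result(loadings, regions=None):
    loadings = np.asarray(loadings, dtype=float)
    p, k = loadings.shape
    regions = regions or tuple(f"r{i}" for i in range(p))
    return EFAResult(
        k, loadings, np.eye(k), np.ones(p), 1 - (loadings**2).sum(1),
        True, tuple(regions),
    )


class TestSpecBuilding:
    def test_threshold_is_strict_and_positive_only(self):
        efa = _efa_result([[0.29, 0.0], [0.31, 0.0], [0.8, 0.0],
                           [-0.9, 0.6], [0.0, 0.7], [0.0, 0.55]])
        spec = build_cfa_spec(efa, 0.3)
        pairs = set(spec.free_loadings)
        assert ("r1", "F1") in pairs and ("r0", "F1") not in pairs
        assert ("r3", "F1") not in pairs  # negative loadings never carried forward
        assert ("r3", "F2") in pairs

    def test_cross_loadings_allowed_above_cutoff(self):
        efa = _efa_result([[0.6, 0.45], [0.7, 0.0], [0.0, 0.5], [0.0, 0.62]])
        spec = build_cfa_spec(efa, 0.3)
        assert ("r0", "F1") in spec.free_loadings
        assert ("r0", "F2") in spec.free_loadings

    def test_single_region_factor_removed(self):
        efa = _efa_result([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 0.9]])
        spec = build_cfa_spec(efa, 0.5)
        assert spec.factors == ("F1",)
        assert "r3" not in spec.regions

    def test_no_viable_spec_fatal(self):
        efa = _efa_result([[0.2, 0.1], [0.1, 0.2], [0.15, 0.1]])
        with pytest.raises(FactorModelError, match="no viable spec"):
            build_cfa_spec(efa, 0.3)

    def test_factor_needs_two_indicators(self):
        with pytest.raises(FactorModelError, match="fewer than 2"):
            FactorModelSpec(("a", "b"), ("F1",), (("a", "F1"),))


def _one_factor_spec(p=4, loading=0.7):
    regions = tuple(f"r{i}" for i in range(p))
    return FactorModelSpec(regions, ("F1",), tuple((r, "F1") for r in regions))


class TestCFA:
    def test_perfect_fit_recovers_truth(self):
        lam = np.full((4, 1), 0.7)
        S = lam @ lam.T + np.diag(np.full(4, 1 - 0.49))
        fit = fit_cfa(_one_factor_spec(), _structure(S, v_scale=1e-6))
        assert fit.converged
        for r in ("r0", "r1", "r2", "r3"):
            assert fit.estimates[f"lambda:{r}:F1"] == pytest.approx(0.7, abs=1e-4)
        assert fit.srmr <= 1e-6
        assert fit.cfi == pytest.approx(1.0)

    def test_parameter_recovery_from_pipeline_structure(self, small_truth, cfa_fit):
        lam_hat = cfa_fit.loading_matrix()
        err = np.abs(lam_hat - small_truth.lambda_)[small_truth.lambda_ != 0]
        assert err.max() < 0.1
        psi_hat = cfa_fit.factor_correlation_matrix()[0, 1]
        assert psi_hat == pytest.approx(0.7, abs=0.1)

    def test_ill_conditioned_spec_flagged_not_crashed(self):
        # two factors loading identically on the same two regions
        regions = ("a", "b", "c", "d")
        spec = FactorModelSpec(
            regions, ("F1", "F2"),
            (("a", "F1"), ("b", "F1"), ("a", "F2"), ("b", "F2"),),
        )
        S = np.full((4, 4), 0.3)
        np.fill_diagonal(S, 1.0)
        fit = fit_cfa(spec, _structure(S, traits=regions))
        assert not fit.converged
        assert fit.message

    def test_spec_structure_mismatch_fatal(self, parity_structures):
        spec = _one_factor_spec()
        with pytest.raises(FactorModelError, match="absent"):
            fit_cfa(spec, parity_structures["even_std"])

    def test_srmr_invariant_under_region_reorder(self, true_spec, parity_structures):
        gs = parity_structures["even_std"]
        fit = fit_cfa(true_spec, gs)
        perm = list(reversed(gs.traits))
        gs_perm = gs.subset(tuple(perm))
        spec_perm = FactorModelSpec(
            tuple(perm), true_spec.factors, true_spec.free_loadings
        )
        fit_perm = fit_cfa(spec_perm, gs_perm)
        assert fit.srmr == pytest.approx(fit_perm.srmr, rel=1e-6)


class TestFitIndices:
    def _fit_with(self, chi2, df, n_free, srmr=0.0):
        spec = _one_factor_spec()
        est = {f"x{i}": 0.0 for i in range(n_free)}
        return CFAFit(spec, est, {}, chi2, df, chi2 + 2 * n_free, np.nan, srmr, True)

    def test_aic_formula(self):
        base = self._fit_with(100.0, 20, 8)
        fit = self._fit_with(10.0, 5, 5)
        aic, _, _ = fit_indices(fit, base)
        assert aic == 20.0

    def test_cfi_saturated_numerator(self):
        base = self._fit_with(100.0, 20, 8)
        fit = self._fit_with(5.0, 5, 5)
        _, cfi, _ = fit_indices(fit, base)
        assert cfi == 1.0

    def test_cfi_degenerate_baseline_convention(self):
        base = self._fit_with(3.0, 20, 8)   # baseline no worse than its df
        fit = self._fit_with(4.0, 5, 5)
        _, cfi, _ = fit_indices(fit, base)
        assert cfi == 1.0 - 0.0 / max(4.0 - 5, 0) if False else cfi == 1.0

    def test_independence_baseline_fits_diagonal_exactly(self, parity_structures):
        base = independence_fit(parity_structures["even_std"])
        assert base.df == 36 - 8
        assert base.cfi == 1.0

    def test_cfi_bounded_above_by_one(self, cfa_fit):
        assert cfa_fit.cfi <= 1.0


def _toy_two_factor(null_pair=("r2", "F2")):
    """6 regions, 2 factors, one spurious cross-loading planted at zero."""
    regions = tuple(f"r{i}" for i in range(6))
    lam = np.zeros((6, 2))
    lam[:3, 0] = (0.8, 0.7, 0.6)
    lam[3:, 1] = (0.75, 0.7, 0.65)
    psi = np.array([[1.0, 0.4], [0.4, 1.0]])
    S = lam @ psi @ lam.T + np.diag(1 - np.diag(lam @ psi @ lam.T))
    free = [(regions[i], "F1") for i in range(3)]
    free += [(regions[i], "F2") for i in range(3, 6)]
    free.append(null_pair)  # truth-zero loading
    spec = FactorModelSpec(regions, ("F1", "F2"), tuple(free))
    return spec, S, regions


class TestPruning:
    def test_fixed_point_when_all_significant(self, cfa_fit, parity_structures):
        pruned = prune_loadings(cfa_fit, parity_structures["even_std"])
        assert pruned.spec.free_loadings == cfa_fit.spec.free_loadings

    def test_planted_null_loading_removed(self):
        spec, S, _ = _toy_two_factor()
        rng = np.random.default_rng(3)
        removed = 0
        for rep in range(10):
            q = 21
            A = rng.standard_normal((q, q)) * 0.002
            V = A @ A.T + np.eye(q) * 0.002**2
            rows, cols = vech_indices(6)
            V[rows == cols] = 0.0
            V[:, rows == cols] = 0.0
            s = vech(S).copy()
            off = rows != cols
            pert = np.linalg.cholesky(V[np.ix_(off, off)] + 1e-12 * np.eye(off.sum()))
            s[off] += pert @ rng.standard_normal(off.sum())
            Sn = np.zeros((6, 6))
            Sn[rows, cols] = s
            Sn = Sn + Sn.T
            np.fill_diagonal(Sn, 1.0)
            gs = GeneticCovarianceStructure(spec.regions, Sn, V, np.eye(6), standardized=True)
            fit = fit_cfa(spec, gs)
            if not fit.converged:
                continue
            pruned = prune_loadings(fit, gs, alpha=0.05)
            if ("r2", "F2") not in pruned.spec.free_loadings:
                removed += 1
        assert removed >= 8

    def test_greedy_matches_exhaustive_best_aic(self):
        spec, S, regions = _toy_two_factor()
        gs = _structure(S, v_scale=2e-5, traits=regions)
        fit = fit_cfa(spec, gs)
        pruned = prune_loadings(fit, gs, alpha=0.05)

        # oracle: enumerate all loading subsets that keep both factors viable
        candidates = list(spec.free_loadings)
        best = None
        for size in range(4, len(candidates) + 1):
            for subset in itertools.combinations(candidates, size):
                counts = {f: sum(1 for _, g in subset if g == f) for f in spec.factors}
                if any(c < 2 for c in counts.values()):
                    continue
                sub_spec = FactorModelSpec(spec.regions, spec.factors, subset)
                f = fit_cfa(sub_spec, gs)
                if f.converged and (best is None or f.aic < best.aic):
                    best = f
        assert set(pruned.spec.free_loadings) == set(best.spec.free_loadings)

    def test_pruning_requires_converged_fit(self, parity_structures):
        spec, S, regions = _toy_two_factor()
        bad = CFAFit(spec, {}, {}, np.nan, 1, np.nan, np.nan, np.nan, False)
        with pytest.raises(FactorModelError):
            prune_loadings(bad, parity_structures["even_std"])


class TestSelection:
    def _fit(self, aic, n_free, k, converged=True):
        regions = tuple(f"r{i}" for i in range(4))
        spec = FactorModelSpec(
            regions, tuple(f"F{j+1}" for j in range(k)),
            tuple((r, f"F{j+1}") for j in range(k) for r in regions[:2]),
        )
        est = {f"p{i}": 0.0 for i in range(n_free)}
        return CFAFit(spec, est, {}, 1.0, 1, aic, 0.9, 0.05, converged)

    def test_argmin_aic(self):
        fits = [self._fit(30, 8, 1), self._fit(25, 8, 1), self._fit(40, 8, 1)]
        assert select_model(fits) is fits[1]

    def test_tie_broken_by_fewer_parameters(self):
        fits = [self._fit(25, 8, 1), self._fit(25, 6, 1)]
        assert select_model(fits) is fits[1]

    def test_no_converged_fit_fatal(self):
        fits = [self._fit(25, 8, 1, converged=False)]
        with pytest.raises(FactorModelError, match="no converged"):
            select_model(fits)

    def test_embedding_preserves_loadings_and_universe(self, true_spec):
        emb = embed_spec(
            FactorModelSpec(true_spec.regions[:6], ("F1",),
                            tuple((r, "F1") for r in true_spec.regions[:4])),
            true_spec.regions,
        )
        assert emb.regions == true_spec.regions
        assert len(emb.free_loadings) == 4
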