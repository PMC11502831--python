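"""Spatial overlap of factor-defined region sets with reference parcellations.

A latent factor's network is the set of regions carrying its supra-threshold
loadings.  Overlap with a reference parcellation (resting-state networks,
receptor-density maps, twin-derived clusters, ...) is measured by Dice's
coefficient

    DC = 2 w(A intersect B) / (w(A) + w(B))

with optional per-region weights (e.g. region volumes) emulating
percent-volume overlap; significance comes from a permutation null that
repopulates the network with the same number of randomly selected regions,
and Benjamini-Hochberg FDR is applied across the full comparison grid as one
family.  Cross-trait genetic correlations of factors with external phenotypes
(via LDSC) are reported with the same FDR convention.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ldsc import bivariate_ldsc
from scipy import stats as _stats

__all__ = [
    "OverlapError", "RegionSet", "dice", "permutation_pvalue", "bh_fdr",
    "overlap_grid", "factor_trait_rg",
]


class OverlapError(ValueError):
    """Fatal error in overlap statistics."""


@dataclasses.dataclass(frozen=True)
class RegionSet:
    """A named subset of a declared region universe with optional
    non-negative weights per universe region."""

    name: str
    members: frozenset[str]
    universe: tuple[str, ...]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.members <= set(self.universe):
            extra = sorted(self.members - set(self.universe))
            raise OverlapError(f"{self.name}: members outside the universe: {extra}")
        if self.weights is not None:
            missing = [m for m in self.members if m not in self.weights]
            if missing:
                raise OverlapError(f"{self.name}: weights missing for members {missing}")
            if any(w < 0 for w in self.weights.values()):
                raise OverlapError(f"{self.name}: negative weights")

    def weight_of(self, regions: Iterable[str]) -> float:
        if self.weights is None:
            return float(len(set(regions)))
        return float(sum(self.weights.get(r, 0.0) for r in regions))


def _shared_weights(a: RegionSet, b: RegionSet) -> Mapping[str, float] | None:
    return a.weights if a.weights is not None else b.weights


def dice(a: RegionSet, b: RegionSet) -> float:
    """Dice's coefficient 2 w(A&B) / (w(A) + w(B)); unit weights if none
    supplied.  Undefined (NaN) when both sets are empty."""
    if tuple(a.universe) != tuple(b.universe):
        raise OverlapError("region sets live on different universes")
    w = _shared_weights(a, b)
    weigh = (lambda rs: sum(w.get(r, 0.0) for r in rs)) if w is not None else len
    denom = weigh(a.members) + weigh(b.members)
    if denom == 0:
        return float("nan")
    return 2.0 * weigh(a.members & b.members) / denom


def permutation_pvalue(
    a_size: int,
    b: RegionSet,
    universe: Sequence[str],
    observed: float,
    n_iter: int = 1000,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Permutation p-value for an observed Dice coefficient.

    Draws ``n_iter`` region sets of size ``a_size`` uniformly without
    replacement from the universe and computes the Dice coefficient against
    ``b`` each time; p = (1 + #{DC_perm >= observed}) / (1 + n_iter)
    (add-one estimator, never exactly zero).  Reproducible given the seed.
    """
    u = list(universe)
    if a_size > len(u):
        raise OverlapError(f"a_size {a_size} exceeds universe size {len(u)}")
    if n_iter < 1:
        raise OverlapError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    w = weights if weights is not None else b.weights
    wvec = np.array([w.get(r, 0.0) for r in u]) if w is not None else np.ones(len(u))
    in_b = np.array([r in b.members for r in u], dtype=float)
    w_b = float((wvec * in_b).sum())

    keys = rng.random((n_iter, len(u)))
    sel = np.argpartition(keys, a_size - 1, axis=1)[:, :a_size]
    w_sel = wvec[sel].sum(axis=1)
    w_int = (wvec * in_b)[sel].sum(axis=1)
    denom = w_sel + w_b
    dc = np.where(denom > 0, 2.0 * w_int / np.where(denom > 0, denom, 1.0), np.nan)
    hits = int(np.sum(dc >= observed - 1e-12))
    return (1 + hits) / (1 + n_iter)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone, capped at 1,
    in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise OverlapError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_grid(
    gibns: Sequence[RegionSet],
    references: Sequence[RegionSet],
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise Dice coefficients with permutation p-values and one
    BH-FDR family across the whole grid."""
    if not gibns or not references:
        raise OverlapError("overlap_grid requires non-empty inputs")
    rows = []
    pair_idx = 0
    for g in gibns:
        for ref in references:
            dc = dice(g, ref)
            child = np.random.SeedSequence(entropy=seed, spawn_key=(pair_idx,))
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            p = permutation_pvalue(
                len(g.members), ref, g.universe, dc, n_iter=n_iter, seed=sub_seed,
                weights=_shared_weights(g, ref),
            )
            rows.append(
                {"gibn": g.name, "reference": ref.name, "dice": dc,
                 "p_perm": p, "n_iter": n_iter, "seed": sub_seed}
            )
            pair_idx += 1
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_perm"])
    return out


def factor_trait_rg(factor_tables, external_tables, ld, n_blocks: int = 200) -> pd.DataFrame:
    """Cross-trait LDSC genetic correlation of every factor with every
    external phenotype, with BH-FDR across the full factor x trait family.

    ``factor_tables`` and ``external_tables`` map names to summary-statistics
    tables (factor tables must carry effective sample sizes).
    """
    rows = []
    for fname, ftab in factor_tables.items():
        for tname, ttab in external_tables.items():
            fit = bivariate_ldsc(ftab, ttab, ld, n_blocks=n_blocks)
            if np.isfinite(fit.rg) and np.isfinite(fit.se_rg) and fit.se_rg > 0:
                p = 2.0 * _stats.norm.sf(abs(fit.rg / fit.se_rg))
            else:
                p = float("nan")
            rows.append(
                {"factor": fname, "trait": tname, "rg": fit.rg, "se": fit.se_rg,
                 "gcov": fit.gcov, "p": p}
            )
    out = pd.DataFrame(rows)
    finite = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if finite.any():
        adj[finite.to_numpy()] = bh_fdr(np.clip(out.loc[finite, "p"], 1e-300, 1.0))
    out["p_fdr"] = adj
    return out
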