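"""Multivariate GWAS of latent factors from summary statistics.

For each SNP the genetic covariance structure is expanded with a SNP
row/column — var(SNP) = 2 p (1 - p) on the standardized-genotype scale and
cov(SNP, trait) = beta_t * 2 p (1 - p) — and the SNP -> factor paths are
estimated by weighted least squares with the measurement model (Lambda, Psi,
Theta) held fixed at the CFA estimates:

    gamma_hat = (Lambda' D Lambda)^-1 Lambda' D beta,   D = diag(1 / se_t^2)

per SNP, which is the sandwich form restricted to the SNP parameters when the
per-trait sampling variances are uncorrelated.  Effects are reported on the
standardized-genotype, unit-variance-factor scale with normal-approximation
p-values, per-factor genomic inflation factors, and greedy distance-based
locus clumping of genome-wide-significant hits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .factor_models import CFAFit, FactorModelSpec
from .ldsc import GeneticCovarianceStructure, genomic_inflation
from .sumstats import SumStatsTable

__all__ = [
    "FactorGWASError", "ExpandedStructure", "FactorGWASTable",
    "snp_expanded_structure", "fit_snp_to_factors", "multivariate_gwas",
    "clump_loci", "factor_sumstats",
]

GWS_THRESHOLD = 5e-8


class FactorGWASError(ValueError):
    """Fatal error in the multivariate factor GWAS."""


@dataclasses.dataclass
class ExpandedStructure:
    """One SNP appended to a genetic covariance structure.

    ``s_snp`` holds cov(SNP, trait_t) = beta_t * var_snp, ``var_s_snp`` the
    sampling variances se_t^2 * var_snp^2 of those covariances (cross terms
    taken as zero), and ``var_snp`` = 2 maf (1 - maf).
    """

    traits: tuple[str, ...]
    s_snp: np.ndarray
    var_s_snp: np.ndarray
    var_snp: float

    def expanded_matrix(self, S: np.ndarray) -> np.ndarray:
        p = len(self.traits)
        out = np.zeros((p + 1, p + 1))
        out[:p, :p] = S
        out[p, :p] = out[:p, p] = self.s_snp
        out[p, p] = self.var_snp
        return out


def snp_expanded_structure(
    gs: GeneticCovarianceStructure,
    betas: dict[str, float],
    ses: dict[str, float],
    maf: float,
) -> ExpandedStructure:
    """Append a SNP row/column to the covariance structure for one variant."""
    if not 0.0 < maf <= 0.5:
        raise FactorGWASError(f"maf must lie in (0, 0.5], got {maf}")
    missing = [t for t in gs.traits if t not in betas or t not in ses]
    if missing:
        raise FactorGWASError(f"missing SNP effect for trait(s): {missing}")
    var_snp = 2.0 * maf * (1.0 - maf)
    b = np.array([betas[t] for t in gs.traits], dtype=float)
    s = np.array([ses[t] for t in gs.traits], dtype=float)
    return ExpandedStructure(gs.traits, b * var_snp, (s * var_snp) ** 2, var_snp)


def _factor_loadings_cov_metric(
    spec: FactorModelSpec, fit: CFAFit, trait_variances: np.ndarray | None, traits
) -> np.ndarray:
    """Pattern loadings mapped from the correlation metric the CFA was fit on
    back to the genetic covariance metric of the trait betas."""
    lam = np.zeros((len(traits), len(spec.factors)))
    ridx = {r: i for i, r in enumerate(traits)}
    for (r, f) in spec.free_loadings:
        lam[ridx[r], spec.factors.index(f)] = fit.estimates[f"lambda:{r}:{f}"]
    if trait_variances is not None:
        lam = np.sqrt(np.asarray(trait_variances))[:, None] * lam
    return lam


def fit_snp_to_factors(
    expanded: ExpandedStructure,
    spec: FactorModelSpec,
    fit: CFAFit,
    trait_variances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Estimate the SNP -> factor effects for one variant.

    ``trait_variances`` are the genetic variances (diag of the unstandardized
    S) used to map the correlation-metric CFA loadings onto the scale of the
    trait betas; omit for a structure that is already on that scale.  Returns
    a per-factor frame (beta_f, se_f, z_f, pval_f); a factor with no measured
    nonzero-loading indicator is flagged NaN.
    """
    if not fit.converged:
        raise FactorGWASError("fit_snp_to_factors requires a converged CFA fit")
    lam = _factor_loadings_cov_metric(spec, fit, trait_variances, expanded.traits)
    beta = expanded.s_snp / expanded.var_snp
    se2 = expanded.var_s_snp / expanded.var_snp**2
    d = 1.0 / se2
    A = lam.T @ (d[:, None] * lam)
    b = lam.T @ (d * beta)
    k = len(spec.factors)
    out = np.full(k, np.nan)
    se = np.full(k, np.nan)
    live = np.abs(lam).sum(axis=0) > 0
    if live.any():
        Al = A[np.ix_(live, live)]
        if np.linalg.cond(Al) < 1e12:
            cov = np.linalg.inv(Al)
            out[live] = cov @ b[live]
            se[live] = np.sqrt(np.diag(cov))
    z = out / se
    return pd.DataFrame(
        {
            "factor": list(spec.factors),
            "beta_f": out,
            "se_f": se,
            "z_f": z,
            "pval_f": 2.0 * _stats.norm.sf(np.abs(z)),
        }
    )


@dataclasses.dataclass
class FactorGWASTable:
    """Per-SNP, per-factor association results in long format plus the
    per-factor genomic inflation factors."""

    df: pd.DataFrame  # snp_id chrom pos a1 a2 maf factor beta_f se_f z_f pval_f
    factors: tuple[str, ...]
    lambdas: dict[str, float]

    def for_factor(self, factor: str) -> pd.DataFrame:
        return self.df.loc[self.df["factor"] == factor].reset_index(drop=True)


def multivariate_gwas(
    tables: list[SumStatsTable],
    gs: GeneticCovarianceStructure,
    spec: FactorModelSpec,
    fit: CFAFit,
) -> FactorGWASTable:
    """Run the factor GWAS across all SNPs shared by every indicator trait.

    The measurement model is held fixed at the CFA estimates; the per-SNP
    expansion and WLS solve are applied in vectorized form (identical, to
    numerical precision, to :func:`fit_snp_to_factors` SNP by SNP).
    Deterministic given its inputs.
    """
    if not fit.converged:
        raise FactorGWASError("multivariate_gwas requires a converged CFA fit")
    by_name = {t.trait_name: t for t in tables}
    missing = [r for r in spec.regions if r not in by_name]
    if missing:
        raise FactorGWASError(f"no summary statistics for indicator trait(s): {missing}")
    used = [by_name[r] for r in spec.regions]

    base = used[0].df[["snp_id", "chrom", "pos", "a1", "a2", "maf"]]
    merged = base
    for i, t in enumerate(used):
        cols = t.df[["snp_id", "beta", "se"]].rename(columns={"beta": f"b{i}", "se": f"s{i}"})
        merged = merged.merge(cols, on="snp_id", how="inner")
    if merged.empty:
        raise FactorGWASError("empty shared SNP set across indicator traits")
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    p = len(used)
    B = merged[[f"b{i}" for i in range(p)]].to_numpy(dtype=float)
    SE = merged[[f"s{i}" for i in range(p)]].to_numpy(dtype=float)
    ok = np.all(np.isfinite(B) & np.isfinite(SE) & (SE > 0), axis=1)
    merged, B, SE = merged.loc[ok].reset_index(drop=True), B[ok], SE[ok]

    if gs.standardized:
        trait_var = None
    else:
        sub = gs.subset(spec.regions)
        trait_var = np.diag(sub.S)
    lam = _factor_loadings_cov_metric(spec, fit, trait_var, spec.regions)
    k = lam.shape[1]
    live = np.abs(lam).sum(axis=0) > 0
    if not live.all():
        dead = [spec.factors[i] for i in np.flatnonzero(~live)]
        raise FactorGWASError(f"factor(s) with no nonzero loading: {dead}")

    W = 1.0 / SE**2  # n x p
    A = np.einsum("np,pk,pl->nkl", W, lam, lam)
    rhs = np.einsum("np,pk->nk", W * B, lam)
    gamma = np.linalg.solve(A, rhs[..., None])[..., 0]
    cov = np.linalg.inv(A)
    se_g = np.sqrt(np.einsum("nkk->nk", cov))
    z = gamma / se_g
    pval = 2.0 * _stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    frames = []
    for fi, fname in enumerate(spec.factors):
        fr = merged[["snp_id", "chrom", "pos", "a1", "a2", "maf"]].copy()
        fr["factor"] = fname
        fr["beta_f"] = gamma[:, fi]
        fr["se_f"] = se_g[:, fi]
        fr["z_f"] = z[:, fi]
        fr["pval_f"] = pval[:, fi]
        frames.append(fr)
    long = pd.concat(frames, ignore_index=True)
    lambdas = {f: genomic_inflation(pval[:, i]) for i, f in enumerate(spec.factors)}
    return FactorGWASTable(long, tuple(spec.factors), lambdas)


def factor_sumstats(
    gwas: FactorGWASTable, factor: str, n_eff_cap_quantile: float = 0.99
) -> SumStatsTable:
    """Export one factor's GWAS as a summary-statistics table for downstream
    cross-trait LDSC.  The per-SNP effective sample size is
    1 / (2 maf (1 - maf) se_f^2), capped at its 99th percentile."""
    fr = gwas.for_factor(factor)
    if fr.empty:
        raise FactorGWASError(f"unknown factor {factor!r}")
    var_g = 2.0 * fr["maf"] * (1.0 - fr["maf"])
    n_eff = 1.0 / (var_g * fr["se_f"] ** 2)
    n_eff = np.minimum(n_eff, n_eff.quantile(n_eff_cap_quantile))
    df = pd.DataFrame(
        {
            "snp_id": fr["snp_id"], "chrom": fr["chrom"], "pos": fr["pos"],
            "a1": fr["a1"], "a2": fr["a2"], "maf": fr["maf"],
            "beta": fr["beta_f"], "se": fr["se_f"], "z": fr["z_f"],
            "n": n_eff, "info": 1.0, "pval": fr["pval_f"],
        }
    )
    return SumStatsTable(factor, df, [f"factor GWAS export; N_eff capped at q{n_eff_cap_quantile}"])


def clump_loci(
    gwas: FactorGWASTable | pd.DataFrame,
    p_threshold: float = GWS_THRESHOLD,
    window: int = 250_000,
) -> pd.DataFrame:
    """Greedy distance-based clumping of genome-wide-significant SNPs.

    Pools the minimum p per SNP across factors, then repeatedly takes the
    most significant remaining SNP as a lead and absorbs every significant
    SNP within +/- ``window`` bp on the same chromosome; loci with
    overlapping spans are merged.  Returns one row per locus (lead snp_id,
    chrom, start, end, span, n_snps, min_p).
    """
    df = gwas.df if isinstance(gwas, FactorGWASTable) else gwas
    pcol = "pval_f" if "pval_f" in df.columns else "pval"
    snp = (
        df.groupby(["snp_id", "chrom", "pos"], as_index=False)[pcol].min()
        .rename(columns={pcol: "p"})
    )
    gws = snp.loc[snp["p"] < p_threshold].sort_values("p").reset_index(drop=True)
    loci: list[dict] = []
    remaining = gws
    while not remaining.empty:
        lead = remaining.iloc[0]
        members = remaining.loc[
            (remaining["chrom"] == lead["chrom"])
            & (np.abs(remaining["pos"] - lead["pos"]) <= window)
        ]
        loci.append(
            {
                "lead_snp": lead["snp_id"],
                "chrom": int(lead["chrom"]),
                "start": int(members["pos"].min()),
                "end": int(members["pos"].max()),
                "n_snps": int(len(members)),
                "min_p": float(lead["p"]),
            }
        )
        remaining = remaining.drop(members.index)

    # merge loci whose spans overlap
    loci.sort(key=lambda L: (L["chrom"], L["start"]))
    merged: list[dict] = []
    for L in loci:
        if merged and merged[-1]["chrom"] == L["chrom"] and L["start"] <= merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], L["end"])
            prev["n_snps"] += L["n_snps"]
            if L["min_p"] < prev["min_p"]:
                prev["min_p"] = L["min_p"]
                prev["lead_snp"] = L["lead_snp"]
        else:
            merged.append(dict(L))
    out = pd.DataFrame(
        merged, columns=["lead_snp", "chrom", "start", "end", "n_snps", "min_p"]
    )
    if not out.empty:
        out["span"] = out["end"] - out["start"]
    else:
        out["span"] = pd.Series(dtype=int)
    return out[["lead_snp", "chrom", "start", "end", "span", "n_snps", "min_p"]]
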