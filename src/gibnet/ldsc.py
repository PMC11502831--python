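"""LD score regression: heritabilities, genetic covariances, and the (S, V)
sampling structure by block jackknife.

Under polygenicity the expected association chi-square of SNP j rises
linearly in its LD score ell_j:

    E[chi2_j] = intercept + (N_j h2 / M) * ell_j

and for two traits

    E[Z1_j Z2_j] = cross_intercept + (sqrt(N1_j N2_j) gcov / M) * ell_j.

The slope recovers SNP heritability / genetic covariance on the
standardized-trait scale; the intercept absorbs confounding and sample
overlap.  Regressions are iteratively reweighted to a weight fixed point with
heteroskedasticity weights

    w_j = 1 / [ ell_j * (intercept + N h2 ell_j / M)^2 ]

(and the analogous product form for cross-trait regressions); chi-square
values above 80 are winsorized to guard against single-locus leverage.
Standard errors and the joint sampling covariance V of vech(S) come from a
delete-one-block jackknife over contiguous SNP blocks with the final weights
held fixed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .sumstats import LDScoreTable, SumStatsTable

__all__ = [
    "LDSCError", "LDSCFit", "CrossTraitFit", "GeneticCovarianceStructure",
    "univariate_ldsc", "bivariate_ldsc", "build_covariance_structure",
    "standardize_structure", "smooth_to_psd", "genomic_inflation",
    "vech", "vech_indices", "unvech",
]

MIN_SNPS = 200
CHI2_WINSOR = 80.0
_CHI2_1_MEDIAN = float(_stats.chi2.ppf(0.5, 1))  # 0.45494


class LDSCError(ValueError):
    """Fatal error in LD score regression."""


# ---------------------------------------------------------------------------
# half-vectorization helpers (column-major lower triangle)


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of vech in column-major lower-triangle order:
    (0,0), (1,0), ..., (p-1,0), (1,1), (2,1), ..."""
    rows, cols = [], []
    for j in range(p):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows), np.asarray(cols)


def vech(m: np.ndarray) -> np.ndarray:
    r, c = vech_indices(m.shape[0])
    return np.asarray(m)[r, c]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    r, c = vech_indices(p)
    out = np.zeros((p, p), dtype=float)
    out[r, c] = v
    out[c, r] = v
    return out


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class LDSCFit:
    """Univariate LDSC fit: SNP heritability and intercept with jackknife SEs."""

    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_snps_used: int


@dataclasses.dataclass
class CrossTraitFit:
    """Cross-trait LDSC fit: genetic covariance/correlation and overlap intercept."""

    gcov: float
    cross_intercept: float
    rg: float
    se_gcov: float
    se_rg: float
    rg_clamped: bool
    n_snps_used: int


@dataclasses.dataclass
class GeneticCovarianceStructure:
    """k-trait genetic covariance matrix S with the sampling covariance V of
    vech(S) (column-major lower-triangle order, q = k(k+1)/2) and the LDSC
    intercept matrix (diagonal: univariate intercepts; off-diagonal:
    sample-overlap intercepts)."""

    traits: tuple[str, ...]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        k = len(self.traits)
        q = k * (k + 1) // 2
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.S.shape != (k, k) or self.V.shape != (q, q):
            raise LDSCError(
                f"inconsistent dimensions: {k} traits, S {self.S.shape}, V {self.V.shape}"
            )
        self.S = (self.S + self.S.T) / 2.0
        self.V = (self.V + self.V.T) / 2.0

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def q(self) -> int:
        return self.k * (self.k + 1) // 2

    def subset(self, traits: tuple[str, ...]) -> "GeneticCovarianceStructure":
        """Restrict S, V and intercepts to a subset (and ordering) of traits."""
        idx = [self.traits.index(t) for t in traits]
        r_full, c_full = vech_indices(self.k)
        pos = {(r_full[e], c_full[e]): e for e in range(self.q)}
        r_sub, c_sub = vech_indices(len(idx))
        sel = []
        for i, j in zip(r_sub, c_sub):
            a, b = idx[i], idx[j]
            sel.append(pos[(max(a, b), min(a, b))])
        sel = np.asarray(sel)
        return GeneticCovarianceStructure(
            tuple(traits),
            self.S[np.ix_(idx, idx)],
            self.V[np.ix_(sel, sel)],
            self.intercepts[np.ix_(idx, idx)],
            self.standardized,
        )


# ---------------------------------------------------------------------------
# weighted block regression machinery


def _block_starts(n: int, n_blocks: int) -> np.ndarray:
    """Start index of each of n_blocks contiguous, near-equal SNP blocks."""
    sizes = np.full(n_blocks, n // n_blocks, dtype=int)
    sizes[: n % n_blocks] += 1
    return np.concatenate([[0], np.cumsum(sizes)[:-1]])


def _wls_normal_blocks(y, x, w, starts):
    """Per-block components of the weighted normal equations for y ~ 1 + x.

    Returns (A_blocks (B,2,2), b_blocks (B,2)); totals are their sums.
    """
    wy = w * y
    comps = np.stack([w, w * x, w * x * x, wy, wy * x], axis=0)  # (5, n)
    sums = np.add.reduceat(comps, starts, axis=1)  # (5, B)
    a11, a12, a22, b1, b2 = sums
    A = np.empty((sums.shape[1], 2, 2))
    A[:, 0, 0] = a11
    A[:, 0, 1] = A[:, 1, 0] = a12
    A[:, 1, 1] = a22
    b = np.stack([b1, b2], axis=1)
    return A, b


def _solve2(A, b):
    """Solve 2x2 systems (batched); A (...,2,2), b (...,2)."""
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    x0 = (A[..., 1, 1] * b[..., 0] - A[..., 0, 1] * b[..., 1]) / det
    x1 = (A[..., 0, 0] * b[..., 1] - A[..., 1, 0] * b[..., 0]) / det
    return np.stack([x0, x1], axis=-1)


def _jackknife(y, x, w, starts):
    """Full-sample and delete-one-block WLS estimates of (intercept, slope)."""
    A_b, b_b = _wls_normal_blocks(y, x, w, starts)
    A, b = A_b.sum(axis=0), b_b.sum(axis=0)
    theta = _solve2(A, b)
    theta_del = _solve2(A[None] - A_b, b[None] - b_b)
    return theta, theta_del


def _jackknife_se(theta_del: np.ndarray) -> np.ndarray:
    n = theta_del.shape[0]
    dev = theta_del - theta_del.mean(axis=0, keepdims=True)
    return np.sqrt((n - 1) / n * np.sum(dev**2, axis=0))


def _irls_weights_uni(ell, x, intercept, h2):
    a = np.clip(intercept + h2 * x, 0.05, None)
    return 1.0 / (np.clip(ell, 1.0, None) * a**2)


def _fit_univariate(chi2, ell, x, max_iter=50, tol=1e-12):
    """IRLS of chi2 on x = (N/M) ell, iterated to a weight fixed point
    (linear convergence; the tight tolerance makes the univariate and
    cross-trait paths agree exactly on duplicated traits)."""
    intercept, h2 = 1.0, 0.0
    w = _irls_weights_uni(ell, x, intercept, h2)
    for _ in range(max_iter):
        A_b, b_b = _wls_normal_blocks(chi2, x, w, np.array([0]))
        new = _solve2(A_b.sum(axis=0), b_b.sum(axis=0))
        delta = max(abs(new[0] - intercept), abs(new[1] - h2))
        intercept, h2 = new
        w = _irls_weights_uni(ell, x, intercept, h2)
        if delta < tol:
            break
    return intercept, h2, w


def _fit_cross(y, ell, x, a1, a2, max_iter=50, tol=1e-12):
    """IRLS of Z1*Z2 on x = sqrt(N1 N2)/M ell with product-form weights
    w = 1/[ell (a1 a2 + a12^2)]; a1, a2 are the per-SNP predicted chi2 from
    the univariate fits.  Iterated to a weight fixed point."""
    intercept, gcov = 0.0, 0.0
    w = 1.0 / (np.clip(ell, 1.0, None) * np.clip(a1 * a2, 0.05, None))
    for _ in range(max_iter):
        A_b, b_b = _wls_normal_blocks(y, x, w, np.array([0]))
        new = _solve2(A_b.sum(axis=0), b_b.sum(axis=0))
        delta = max(abs(new[0] - intercept), abs(new[1] - gcov))
        intercept, gcov = new
        axy = intercept + gcov * x
        w = 1.0 / (np.clip(ell, 1.0, None) * np.clip(a1 * a2 + axy**2, 0.05, None))
        if delta < tol:
            break
    return intercept, gcov, w


# ---------------------------------------------------------------------------
# merging


def _merge_arrays(tables, ld):
    """Inner-join tables with the LD scores on snp_id; returns (Z (n,p),
    N (n,p), ell (n,)) sorted by (chrom, pos)."""
    base = ld.df[["snp_id", "chrom", "pos", "ell"]]
    merged = base
    for i, t in enumerate(tables):
        sub = t.df[["snp_id", "z", "n"]].rename(columns={"z": f"z{i}", "n": f"n{i}"})
        merged = merged.merge(sub, on="snp_id", how="inner")
    if merged.empty:
        raise LDSCError("no SNPs shared between the summary statistics and LD scores")
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    p = len(tables)
    Z = merged[[f"z{i}" for i in range(p)]].to_numpy(dtype=float)
    N = merged[[f"n{i}" for i in range(p)]].to_numpy(dtype=float)
    ell = merged["ell"].to_numpy(dtype=float)
    ok = np.all(np.isfinite(Z), axis=1) & np.isfinite(ell)
    return Z[ok], N[ok], ell[ok]


def _effective_n(N, per_snp_n):
    return N if per_snp_n else np.full_like(N, N.mean())


# ---------------------------------------------------------------------------
# public operations


def univariate_ldsc(
    table: SumStatsTable,
    ld: LDScoreTable,
    n_blocks: int = 200,
    per_snp_n: bool = True,
) -> LDSCFit:
    """Estimate SNP heritability and the LDSC intercept for one trait.

    h2 is the unconstrained regression slope (may be <= 0); jackknife SEs use
    ``n_blocks`` contiguous SNP blocks.
    """
    Z, N, ell = _merge_arrays([table], ld)
    n = len(ell)
    if n < MIN_SNPS:
        raise LDSCError(f"too few SNPs for LDSC: {n} < {MIN_SNPS}")
    chi2 = np.minimum(Z[:, 0] ** 2, CHI2_WINSOR)
    x = _effective_n(N[:, 0], per_snp_n) / ld.m * ell
    _, _, w = _fit_univariate(chi2, ell, x)
    intercept, h2 = 0.0, 0.0
    n_blocks = int(min(n_blocks, n // 2))
    starts = _block_starts(n, n_blocks)
    (intercept, h2), theta_del = _jackknife(chi2, x, w, starts)
    se_int, se_h2 = _jackknife_se(theta_del)
    return LDSCFit(float(h2), float(intercept), float(se_h2), float(se_int), n)


def bivariate_ldsc(
    t1: SumStatsTable,
    t2: SumStatsTable,
    ld: LDScoreTable,
    n_blocks: int = 200,
    per_snp_n: bool = True,
) -> CrossTraitFit:
    """Cross-trait LDSC: genetic covariance, sample-overlap intercept, and
    genetic correlation rg = gcov / sqrt(h2_1 h2_2) (clamped to [-1, 1]).

    The rg jackknife SE propagates the three estimates jointly over the same
    delete-one-block replicates.  If either heritability estimate is <= 0,
    rg is reported as NaN (gcov is still returned).
    """
    Z, N, ell = _merge_arrays([t1, t2], ld)
    n = len(ell)
    if n < MIN_SNPS:
        raise LDSCError(f"too few shared SNPs for cross-trait LDSC: {n} < {MIN_SNPS}")
    n_blocks = int(min(n_blocks, n // 2))
    starts = _block_starts(n, n_blocks)
    Ne = _effective_n(N, per_snp_n)

    h2s, uni_del, preds = [], [], []
    for t in range(2):
        chi2 = np.minimum(Z[:, t] ** 2, CHI2_WINSOR)
        x = Ne[:, t] / ld.m * ell
        it, h2, w = _fit_univariate(chi2, ell, x)
        theta, theta_del = _jackknife(chi2, x, w, starts)
        h2s.append(theta[1])
        uni_del.append(theta_del[:, 1])
        preds.append(np.clip(it + h2 * x, 0.05, None))

    y = np.clip(Z[:, 0] * Z[:, 1], -CHI2_WINSOR, CHI2_WINSOR)
    x = np.sqrt(Ne[:, 0] * Ne[:, 1]) / ld.m * ell
    _, _, w = _fit_cross(y, ell, x, preds[0], preds[1])
    (cross_int, gcov), cross_del = _jackknife(y, x, w, starts)
    se_gcov = _jackknife_se(cross_del)[1]

    clamped = False
    if h2s[0] > 0 and h2s[1] > 0:
        rg = gcov / np.sqrt(h2s[0] * h2s[1])
        if abs(rg) > 1:
            rg, clamped = float(np.clip(rg, -1, 1)), True
        denom_del = uni_del[0] * uni_del[1]
        ok = denom_del > 0
        rg_del = np.where(ok, cross_del[:, 1] / np.sqrt(np.abs(denom_del)), rg)
        se_rg = float(_jackknife_se(rg_del[:, None])[0])
    else:
        rg, se_rg = float("nan"), float("nan")
    return CrossTraitFit(
        float(gcov), float(cross_int), float(rg), float(se_gcov), se_rg, clamped, n
    )


def build_covariance_structure(
    tables: list[SumStatsTable],
    ld: LDScoreTable,
    n_blocks: int = 200,
    per_snp_n: bool = True,
) -> GeneticCovarianceStructure:
    """Assemble the full genetic covariance matrix S and the joint sampling
    covariance V of vech(S) by a delete-one-block jackknife.

    All univariate (diagonal) and cross-trait (off-diagonal) LDSC slopes are
    re-estimated on every leave-one-block-out replicate with the final
    weights held fixed, so V captures the cross-element sampling covariance.
    """
    if n_blocks < 20:
        raise LDSCError(f"n_blocks must be >= 20, got {n_blocks}")
    p = len(tables)
    Z, N, ell = _merge_arrays(tables, ld)
    n = len(ell)
    if n < MIN_SNPS:
        raise LDSCError(f"too few shared SNPs: {n} < {MIN_SNPS}")
    n_blocks = int(min(n_blocks, n // 10))
    starts = _block_starts(n, n_blocks)
    Ne = _effective_n(N, per_snp_n)

    # univariate pass: predicted chi2 per trait for the cross-trait weights
    preds = np.empty((n, p))
    uni = []
    for t in range(p):
        chi2 = np.minimum(Z[:, t] ** 2, CHI2_WINSOR)
        x = Ne[:, t] / ld.m * ell
        it, h2, w = _fit_univariate(chi2, ell, x)
        preds[:, t] = np.clip(it + h2 * x, 0.05, None)
        uni.append((it, h2, w))

    rows, cols = vech_indices(p)
    q = len(rows)
    S = np.zeros((p, p))
    intercepts = np.zeros((p, p))
    slopes_del = np.empty((q, n_blocks))
    for e, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            y = np.minimum(Z[:, i] ** 2, CHI2_WINSOR)
            x = Ne[:, i] / ld.m * ell
            w = uni[i][2]
        else:
            y = np.clip(Z[:, i] * Z[:, j], -CHI2_WINSOR, CHI2_WINSOR)
            x = np.sqrt(Ne[:, i] * Ne[:, j]) / ld.m * ell
            _, _, w = _fit_cross(y, ell, x, preds[:, i], preds[:, j])
        theta, theta_del = _jackknife(y, x, w, starts)
        S[i, j] = S[j, i] = theta[1]
        intercepts[i, j] = intercepts[j, i] = theta[0]
        slopes_del[e] = theta_del[:, 1]

    dev = slopes_del - slopes_del.mean(axis=1, keepdims=True)
    V = (n_blocks - 1) / n_blocks * (dev @ dev.T)
    return GeneticCovarianceStructure(tuple(t.trait_name for t in tables), S, V, intercepts)


def standardize_structure(gs: GeneticCovarianceStructure) -> GeneticCovarianceStructure:
    """Rescale S to a genetic correlation matrix (unit diagonal) and transform
    V by the delta method for the rescaling map.

    For r_ij = s_ij / sqrt(s_ii s_jj) the Jacobian rows are
    dr/ds_ij = 1/sqrt(s_ii s_jj), dr/ds_ii = -r_ij/(2 s_ii),
    dr/ds_jj = -r_ij/(2 s_jj); diagonal elements map to the constant 1
    (zero rows in V).  Idempotent: an already-standardized structure is
    returned unchanged.
    """
    p = gs.k
    d = np.diag(gs.S).copy()
    if np.any(d <= 0):
        bad = [gs.traits[i] for i in np.flatnonzero(d <= 0)]
        raise LDSCError(f"non-positive genetic variance for trait(s): {bad}")
    rows, cols = vech_indices(p)
    diag_elems = np.flatnonzero(rows == cols)
    if gs.standardized or (
        np.allclose(d, 1.0, atol=1e-12)
        and np.allclose(gs.V[diag_elems], 0.0, atol=1e-15)
    ):
        out = GeneticCovarianceStructure(gs.traits, gs.S.copy(), gs.V.copy(), gs.intercepts.copy())
        out.standardized = True
        return out

    scale = np.sqrt(np.outer(d, d))
    R = gs.S / scale
    pos = {(int(r), int(c)): e for e, (r, c) in enumerate(zip(rows, cols))}
    J = np.zeros((gs.q, gs.q))
    for e, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            continue
        J[e, e] = 1.0 / scale[i, j]
        J[e, pos[(i, i)]] = -R[i, j] / (2.0 * d[i])
        J[e, pos[(j, j)]] = -R[i, j] / (2.0 * d[j])
    V_std = J @ gs.V @ J.T
    np.fill_diagonal(R, 1.0)
    out = GeneticCovarianceStructure(gs.traits, R, V_std, gs.intercepts.copy())
    out.standardized = True
    return out


def smooth_to_psd(S_std: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, float]:
    """Clip eigenvalues below ``eps`` and reconstitute; re-normalize to unit
    diagonal when the input had one.  Returns (matrix, max abs element change);
    an already-PSD input is returned unchanged (change 0.0).
    """
    S_std = np.asarray(S_std, dtype=float)
    if not np.allclose(S_std, S_std.T, atol=1e-10):
        raise LDSCError("smooth_to_psd requires a symmetric matrix")
    evals, evecs = np.linalg.eigh((S_std + S_std.T) / 2.0)
    if evals.min() >= eps:
        return S_std.copy(), 0.0
    out = (evecs * np.clip(evals, eps, None)) @ evecs.T
    if np.allclose(np.diag(S_std), 1.0, atol=1e-8):
        dd = np.sqrt(np.diag(out))
        out = out / np.outer(dd, dd)
        np.fill_diagonal(out, 1.0)
    return out, float(np.max(np.abs(out - S_std)))


def genomic_inflation(pvals) -> float:
    """Genomic inflation factor: the median association chi-square (1 df)
    divided by the null median 0.45494."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise LDSCError("genomic_inflation: empty p-value collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise LDSCError("genomic_inflation: p-values must lie in (0, 1]")
    chi2 = _stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)
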