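"""Latent factor models on genetic correlation matrices.

Exploratory factor analysis (maximum-likelihood extraction, promax rotation)
is run on the odd-chromosome genetic correlation matrix to discover candidate
loading patterns; thresholded patterns are carried forward as confirmatory
factor analysis (CFA) specifications and re-estimated on the even-chromosome
genetic covariance structure by diagonally weighted least squares (DWLS):

    F(theta) = (s - sigma(theta))' W^-1 (s - sigma(theta)),
    sigma(theta) = vech(Lambda Psi Lambda' + Theta),  W = diag(V),

with factors identified by unit variance, sandwich parameter covariance

    (D'W^-1 D)^-1 D'W^-1 V W^-1 D (D'W^-1 D)^-1,   D = d sigma / d theta,

model chi-square as the residual quadratic form against the residual
sampling covariance (I - H) V (I - H)' (calibrated for the DWLS estimator;
see :func:`_residual_chi2`) with df = q - (free parameters), AIC = chi2 +
2*(free parameters), CFI against the independence baseline, and SRMR as the
root-mean-square standardized residual.  Non-significant loadings
can be pruned greedily; candidate models are compared on AIC.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _stats

from .ldsc import GeneticCovarianceStructure, vech, vech_indices

__all__ = [
    "FactorModelError", "EFAResult", "FactorModelSpec", "CFAFit",
    "run_efa", "build_cfa_spec", "fit_cfa", "independence_fit",
    "fit_indices", "prune_loadings", "select_model",
]

RESIDUAL_FLOOR = 1e-6


class FactorModelError(ValueError):
    """Fatal error in factor model construction or fitting."""


# ---------------------------------------------------------------------------
# EFA: maximum-likelihood extraction + varimax/promax rotation


def _ml_extract(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML factor extraction on a correlation matrix.

    Profiles the likelihood over uniquenesses psi: given psi, the loadings
    come from the top-k eigenpairs of psi^-1/2 R psi^-1/2 and the profile
    discrepancy is sum_{i>k} (theta_i - log theta_i - 1).  Returns
    (loadings p x k, uniquenesses, heywood_flag).
    """
    p = R.shape[0]

    def eig_scaled(psi):
        s = 1.0 / np.sqrt(psi)
        evals, evecs = np.linalg.eigh(R * np.outer(s, s))
        return evals[::-1], evecs[:, ::-1]

    def objective(logpsi):
        evals, _ = eig_scaled(np.exp(logpsi))
        tail = np.clip(evals[k:], 1e-12, None)
        return float(np.sum(tail - np.log(tail) - 1.0))

    smc = 1.0 / np.clip(np.diag(np.linalg.inv(R)), 1.0, None)  # 1 - squared multiple corr
    x0 = np.log(np.clip(smc, 0.05, 0.95))
    lb, ub = np.log(1e-3), np.log(1.0)
    res = _opt.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(lb, ub)] * p, options={"maxiter": 500, "ftol": 1e-12},
    )
    psi = np.exp(res.x)
    heywood = bool(np.any(res.x <= lb + 1e-6))
    evals, evecs = eig_scaled(psi)
    lam = np.sqrt(psi)[:, None] * evecs[:, :k] * np.sqrt(np.clip(evals[:k] - 1.0, 0.0, None))
    return lam, psi, heywood


def _varimax_criterion(L: np.ndarray) -> float:
    sq = L**2
    return float(np.sum(sq**2) - np.sum(np.sum(sq, axis=0) ** 2) / L.shape[0])


def _varimax_from(L: np.ndarray, R0: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    p, k = L.shape
    R = R0
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ R


def _varimax(L: np.ndarray) -> np.ndarray:
    """Orthogonal varimax rotation.  The iteration is run from the identity
    and from a few fixed orthogonal starts (perfectly symmetric loading
    patterns make the identity a saddle point); the rotation with the
    largest varimax criterion wins.  Deterministic."""
    k = L.shape[1]
    starts = [np.eye(k)]
    rng = np.random.default_rng(12345)  # fixed: starts are part of the algorithm
    for _ in range(3):
        q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(q)
    candidates = [_varimax_from(L, R0) for R0 in starts]
    return max(candidates, key=_varimax_criterion)


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation: varimax followed by a least-squares fit to
    the element-wise |loading|^power target.  Returns (pattern, Phi)."""
    if L.shape[1] < 2:
        return L.copy(), np.ones((1, 1))
    V = _varimax(L)
    Q = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    Ui = np.linalg.inv(U)
    Phi = Ui @ Ui.T
    return pattern, Phi


@dataclasses.dataclass
class EFAResult:
    """Rotated exploratory factor solution on a genetic correlation matrix."""

    n_factors: int
    loadings: np.ndarray            # p x k pattern matrix, promax-rotated
    factor_correlations: np.ndarray  # k x k
    eigenvalues: np.ndarray          # of the input correlation matrix
    uniquenesses: np.ndarray
    converged: bool
    regions: tuple[str, ...]
    message: str = ""


def run_efa(S_std, n_factors: int, rotation_power: int = 4) -> EFAResult:
    """EFA with ML extraction and promax rotation on a standardized
    (smoothed, PSD) genetic correlation structure or plain matrix.

    Per-factor sign convention: each factor is flipped so the sum of its
    loadings is positive.  A Heywood case (communality above 1, uniqueness at
    the bound) is reported via ``converged = False``.
    """
    if isinstance(S_std, GeneticCovarianceStructure):
        R = S_std.S
        regions = S_std.traits
    else:
        R = np.asarray(S_std, dtype=float)
        regions = tuple(f"v{i+1}" for i in range(R.shape[0]))
    p = R.shape[0]
    if not (1 <= n_factors < p):
        raise FactorModelError(f"n_factors must be in [1, {p - 1}], got {n_factors}")
    evals_R = np.linalg.eigvalsh(R)[::-1]
    if evals_R.min() < -1e-6:
        raise FactorModelError("input matrix is not PSD; smooth it first")

    lam, psi, heywood = _ml_extract(R, n_factors)
    pattern, phi = _promax(lam, power=rotation_power)

    flip = np.where(pattern.sum(axis=0) < 0, -1.0, 1.0)
    pattern = pattern * flip
    phi = phi * np.outer(flip, flip)

    msg = "Heywood case: a communality reached 1" if heywood else ""
    return EFAResult(
        n_factors, pattern, phi, evals_R, psi, not heywood, tuple(regions), msg
    )


# ---------------------------------------------------------------------------
# CFA specification


@dataclasses.dataclass(frozen=True)
class FactorModelSpec:
    """Free/fixed loading pattern with factor correlations.

    ``free_loadings`` is the set of (region, factor) pairs estimated freely;
    everything else is fixed at zero.  Factors are identified by unit
    variance; residual variances are free per region.
    """

    regions: tuple[str, ...]
    factors: tuple[str, ...]
    free_loadings: tuple[tuple[str, str], ...]
    factor_correlations_free: bool = True
    residual_variances_free: bool = True
    start_loadings: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        known_r, known_f = set(self.regions), set(self.factors)
        for r, f in self.free_loadings:
            if r not in known_r or f not in known_f:
                raise FactorModelError(f"free loading ({r}, {f}) references unknown region/factor")
        for f in self.factors:
            if sum(1 for _, g in self.free_loadings if g == f) < 2:
                raise FactorModelError(f"factor {f} has fewer than 2 free loadings")

    @property
    def n_free(self) -> int:
        k = len(self.factors)
        n = len(self.free_loadings)
        if self.factor_correlations_free:
            n += k * (k - 1) // 2
        if self.residual_variances_free:
            n += len(self.regions)
        return n

    def loading_indicator(self) -> np.ndarray:
        out = np.zeros((len(self.regions), len(self.factors)), dtype=bool)
        for r, f in self.free_loadings:
            out[self.regions.index(r), self.factors.index(f)] = True
        return out


def build_cfa_spec(efa: EFAResult, cutoff: float) -> FactorModelSpec:
    """Threshold an EFA solution into a CFA specification.

    Positive rotated loadings strictly greater than ``cutoff`` are freed
    (cross-loadings allowed when both exceed the cutoff); factors left with
    fewer than 2 indicators are removed, as single regions do not constitute
    factors; regions with no surviving loading are excluded.
    """
    if not efa.converged:
        raise FactorModelError("refusing to build a CFA spec from a non-converged EFA")
    p, k = efa.loadings.shape
    keep = efa.loadings > cutoff
    surviving_factors = [f for f in range(k) if keep[:, f].sum() >= 2]
    if not surviving_factors:
        raise FactorModelError(f"no viable spec at cutoff {cutoff}")
    keep = keep[:, surviving_factors]
    surviving_regions = [r for r in range(p) if keep[r].any()]
    regions = tuple(efa.regions[r] for r in surviving_regions)
    factors = tuple(f"F{f + 1}" for f in surviving_factors)
    free, starts = [], []
    for ri, r in enumerate(surviving_regions):
        for fi, f in enumerate(surviving_factors):
            if keep[r][fi]:
                free.append((regions[ri], factors[fi]))
                starts.append((regions[ri], factors[fi], float(efa.loadings[r, f])))
    return FactorModelSpec(regions, factors, tuple(free), start_loadings=tuple(starts))


# ---------------------------------------------------------------------------
# CFA fitting (DWLS)


@dataclasses.dataclass
class CFAFit:
    """A fitted confirmatory factor model with sandwich standard errors and
    fit indices (chi2/df, AIC, CFI, SRMR)."""

    spec: FactorModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    chi2: float
    df: int
    aic: float
    cfi: float
    srmr: float
    converged: bool
    baseline_chi2: float = float("nan")
    baseline_df: int = 0
    message: str = ""
    removal_log: tuple[str, ...] = ()

    @property
    def n_free(self) -> int:
        return len(self.estimates)

    @property
    def n_factors(self) -> int:
        return len(self.spec.factors)

    def loading_matrix(self) -> np.ndarray:
        lam = np.zeros((len(self.spec.regions), len(self.spec.factors)))
        for (r, f) in self.spec.free_loadings:
            lam[self.spec.regions.index(r), self.spec.factors.index(f)] = self.estimates[
                f"lambda:{r}:{f}"
            ]
        return lam

    def factor_correlation_matrix(self) -> np.ndarray:
        k = len(self.spec.factors)
        psi = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                key = f"psi:{self.spec.factors[a]}:{self.spec.factors[b]}"
                if key in self.estimates:
                    psi[a, b] = psi[b, a] = self.estimates[key]
        return psi

    def residual_variances(self) -> np.ndarray:
        return np.array([self.estimates[f"theta:{r}"] for r in self.spec.regions])


def _param_names(spec: FactorModelSpec) -> list[str]:
    names = [f"lambda:{r}:{f}" for r, f in spec.free_loadings]
    if spec.factor_correlations_free:
        k = len(spec.factors)
        names += [
            f"psi:{spec.factors[a]}:{spec.factors[b]}"
            for a in range(k) for b in range(a + 1, k)
        ]
    names += [f"theta:{r}" for r in spec.regions]
    return names


def _unpack(spec: FactorModelSpec, x: np.ndarray):
    p, k = len(spec.regions), len(spec.factors)
    nl = len(spec.free_loadings)
    lam = np.zeros((p, k))
    for idx, (r, f) in enumerate(spec.free_loadings):
        lam[spec.regions.index(r), spec.factors.index(f)] = x[idx]
    psi = np.eye(k)
    off = nl
    if spec.factor_correlations_free:
        for a in range(k):
            for b in range(a + 1, k):
                psi[a, b] = psi[b, a] = x[off]
                off += 1
    theta = x[off : off + p]
    return lam, psi, theta


def _sigma_and_jac(spec: FactorModelSpec, x: np.ndarray):
    """Model-implied vech(Sigma) and its Jacobian wrt the free parameters."""
    p, k = len(spec.regions), len(spec.factors)
    lam, psi, theta = _unpack(spec, x)
    sigma_m = lam @ psi @ lam.T + np.diag(theta)
    rows, cols = vech_indices(p)
    s = sigma_m[rows, cols]

    t = len(x)
    J = np.zeros((len(s), t))
    lam_psi = lam @ psi  # p x k
    ridx = {r: i for i, r in enumerate(spec.regions)}
    fidx = {f: i for i, f in enumerate(spec.factors)}
    for idx, (r, f) in enumerate(spec.free_loadings):
        i, a = ridx[r], fidx[f]
        # dSigma/dlambda_ia = e_i (Lambda Psi)_a' + (Lambda Psi)_a e_i'
        col = lam_psi[:, a]
        dS = np.zeros((p, p))
        dS[i, :] += col
        dS[:, i] += col
        J[:, idx] = dS[rows, cols]
    off = len(spec.free_loadings)
    if spec.factor_correlations_free:
        for a in range(k):
            for b in range(a + 1, k):
                dS = np.outer(lam[:, a], lam[:, b])
                dS = dS + dS.T
                J[:, off] = dS[rows, cols]
                off += 1
    for i in range(p):
        J[rows == cols, off + i] = 0.0
        J[(rows == i) & (cols == i), off + i] = 1.0
    return s, J


def _weight_vector(gs: GeneticCovarianceStructure) -> np.ndarray:
    """DWLS weights: diag(V), with zero-variance elements (exactly fitted
    diagonal entries of a standardized structure) given the smallest positive
    weight so residual variances stay identified."""
    w = np.diag(gs.V).copy()
    pos = w[w > 1e-14 * max(w.max(), 1.0)]
    if pos.size == 0:
        raise LDSCErrorFromV()
    w[w <= 1e-14 * max(w.max(), 1.0)] = pos.min()
    return w


class LDSCErrorFromV(FactorModelError):
    """V has no invertible diagonal."""


def _starts_for(spec: FactorModelSpec) -> list[np.ndarray]:
    names = _param_names(spec)
    nl = len(spec.free_loadings)
    start_map = {(r, f): v for r, f, v in spec.start_loadings}
    base = np.concatenate([
        np.array([start_map.get(pair, 0.5) for pair in spec.free_loadings]),
        np.full(spec.n_free - nl - len(spec.regions), 0.3),
        np.full(len(spec.regions), 0.5),
    ])
    uniform = np.concatenate([
        np.full(nl, 0.5),
        np.full(spec.n_free - nl - len(spec.regions), 0.3),
        np.full(len(spec.regions), 0.5),
    ])
    perturb = uniform.copy()
    perturb[:nl] += 0.15 * np.where(np.arange(nl) % 2 == 0, 1.0, -1.0)
    assert len(base) == len(names)
    return [base, uniform, perturb]


def _srmr(s_obs: np.ndarray, s_mod: np.ndarray, p: int) -> float:
    """Root-mean-square residual of the standardized (correlation) matrices
    over the q unique elements."""
    So, Sm = unvech_local(s_obs, p), unvech_local(s_mod, p)
    do, dm = np.sqrt(np.diag(So)), np.sqrt(np.diag(Sm))
    Ro = So / np.outer(do, do)
    Rm = Sm / np.outer(dm, dm)
    rows, cols = vech_indices(p)
    resid = (Ro - Rm)[rows, cols]
    return float(np.sqrt(np.mean(resid**2)))


def unvech_local(v: np.ndarray, p: int) -> np.ndarray:
    rows, cols = vech_indices(p)
    out = np.zeros((p, p))
    out[rows, cols] = v
    out[cols, rows] = v
    return out


def _residual_chi2(r: np.ndarray, V: np.ndarray, J: np.ndarray, w: np.ndarray) -> float:
    """Model chi-square: quadratic form of the residuals against their own
    sampling covariance (I - H) V (I - H)' under the DWLS estimator, with
    H = J (J' W^-1 J)^-1 J' W^-1 the weighted projection onto the model
    tangent space.  Asymptotically chi-square with q - t degrees of freedom
    for data generated under the model (the plain V-pseudoinverse form is
    only calibrated for the efficient GLS estimator)."""
    q = len(r)
    if J.size:
        Jw = J / w[:, None]
        # pinv tolerates rank-deficient tangent spaces (collapsed loadings)
        H = J @ np.linalg.pinv(J.T @ Jw, rcond=1e-12) @ Jw.T
        P = np.eye(q) - H
    else:
        P = np.eye(q)
    U = P @ V @ P.T
    evals, evecs = np.linalg.eigh((U + U.T) / 2.0)
    keep = evals > 1e-8 * max(evals.max(), 1e-300)
    y = evecs[:, keep].T @ r
    return float(np.sum(y**2 / evals[keep]))


def independence_fit(gs: GeneticCovarianceStructure) -> CFAFit:
    """The independence baseline: no factors, free residual variances only.

    The diagonal is fitted exactly; the baseline chi-square is the residual
    quadratic form over the off-diagonal elements.
    """
    p = gs.k
    s = vech(gs.S)
    sigma = vech(np.diag(np.diag(gs.S)))
    r = s - sigma
    rows, cols = vech_indices(p)
    J = np.zeros((gs.q, p))
    for i in range(p):
        J[(rows == i) & (cols == i), i] = 1.0
    w = _weight_vector(gs)
    chi2 = _residual_chi2(r, gs.V, J, w)
    df = gs.q - p
    spec = FactorModelSpec(gs.traits, (), (), False, True)
    est = {f"theta:{t}": float(gs.S[i, i]) for i, t in enumerate(gs.traits)}
    return CFAFit(
        spec, est, {k: float("nan") for k in est}, chi2, df,
        chi2 + 2 * p, 1.0, _srmr(s, sigma, p), True, chi2, df,
    )


def fit_cfa(
    spec: FactorModelSpec,
    gs: GeneticCovarianceStructure,
    xtol: float = 1e-14,
) -> CFAFit:
    """Fit a CFA specification to a genetic covariance structure by DWLS.

    Runs three deterministic starts (EFA-derived, 0.5-uniform, perturbed) and
    keeps the best objective.  Residual variances are bounded below at 1e-6;
    a fit that lands on the bound (a Heywood case), an optimizer failure, or
    a rank-deficient sandwich bread matrix is reported with
    ``converged = False`` and undefined fit indices.
    """
    missing = set(spec.regions) - set(gs.traits)
    if missing:
        raise FactorModelError(f"spec regions absent from the structure: {sorted(missing)}")
    sub = gs.subset(spec.regions)
    p = sub.k
    s = vech(sub.S)
    w = _weight_vector(sub)
    sw = np.sqrt(w)

    names = _param_names(spec)
    nl = len(spec.free_loadings)
    npsi = spec.n_free - nl - p
    lb = np.concatenate([np.full(nl, -np.inf), np.full(npsi, -0.999), np.full(p, RESIDUAL_FLOOR)])
    ub = np.concatenate([np.full(nl, np.inf), np.full(npsi, 0.999), np.full(p, np.inf)])

    def residuals(x):
        sig, _ = _sigma_and_jac(spec, x)
        return (s - sig) / sw

    def jacobian(x):
        _, J = _sigma_and_jac(spec, x)
        return -J / sw[:, None]

    best = None
    for x0 in _starts_for(spec):
        x0 = np.clip(x0, lb + 1e-8, ub - 1e-8)
        try:
            res = _opt.least_squares(
                residuals, x0, jac=jacobian, bounds=(lb, ub), method="trf",
                xtol=xtol, ftol=1e-14, gtol=1e-12, max_nfev=3000,
            )
        except Exception as exc:  # singular steps etc. -> try next start
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return CFAFit(spec, {}, {}, float("nan"), sub.q - spec.n_free, float("nan"),
                      float("nan"), float("nan"), False, message="optimizer failed on all starts")

    x = best.x
    converged = bool(best.status > 0)
    message = ""
    theta_hat = x[nl + npsi:]
    if np.any(theta_hat <= RESIDUAL_FLOOR * (1 + 1e-6)):
        converged = False
        message = "Heywood case: residual variance at the lower bound"

    sig, J = _sigma_and_jac(spec, x)
    r = s - sig
    Delta_w = J / sw[:, None]
    B = Delta_w.T @ Delta_w  # Delta' W^-1 Delta
    cond = np.linalg.cond(B)
    se = {}
    if not np.isfinite(cond) or cond > 1e10:
        converged = False
        message = message or f"under-identified model (bread condition number {cond:.2e})"
        se = {nm: float("nan") for nm in names}
    else:
        Bi = np.linalg.inv(B)
        mid = (J / w[:, None]).T @ sub.V @ (J / w[:, None])
        cov = Bi @ mid @ Bi
        dse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = {nm: float(v) for nm, v in zip(names, dse)}

    chi2 = _residual_chi2(r, sub.V, J, w)
    df = sub.q - spec.n_free
    base = independence_fit(sub)
    aic = chi2 + 2 * spec.n_free
    num = max(chi2 - df, 0.0)
    den = max(base.chi2 - base.df, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    srmr = _srmr(s, sig, p)
    if not converged:
        chi2 = aic = cfi = srmr = float("nan")
    est = {nm: float(v) for nm, v in zip(names, x)}
    return CFAFit(spec, est, se, chi2, df, aic, cfi, srmr, converged,
                  base.chi2, base.df, message)


def fit_indices(fit: CFAFit, baseline: CFAFit) -> tuple[float, float, float]:
    """(AIC, CFI, SRMR) of a fitted model against the independence baseline
    on the same structure.  AIC = chi2 + 2*(free parameters); CFI compares
    the excess chi-square over df with the baseline's; a degenerate baseline
    yields CFI = 1 by convention."""
    aic = fit.chi2 + 2 * fit.n_free
    num = max(fit.chi2 - fit.df, 0.0)
    den = max(baseline.chi2 - baseline.df, fit.chi2 - fit.df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    return float(aic), float(cfi), float(fit.srmr)


def embed_spec(spec: FactorModelSpec, regions: tuple[str, ...]) -> FactorModelSpec:
    """Embed a specification in a larger region universe: added regions carry
    no loadings, only a free residual variance, so their correlations count
    as model misfit.  Makes chi-square and AIC comparable across candidate
    models that load different region subsets."""
    missing = set(spec.regions) - set(regions)
    if missing:
        raise FactorModelError(f"embedding universe lacks regions {sorted(missing)}")
    return FactorModelSpec(
        tuple(regions), spec.factors, spec.free_loadings,
        spec.factor_correlations_free, spec.residual_variances_free, spec.start_loadings,
    )


def _drop_loading(spec: FactorModelSpec, pair: tuple[str, str]) -> FactorModelSpec | None:
    """Remove one free loading; a factor reduced below 2 indicators is
    dropped with its correlations.  The region universe is preserved (the
    region keeps its free residual variance).  Returns None if no factor
    survives."""
    free = [fl for fl in spec.free_loadings if fl != pair]
    factors = [f for f in spec.factors if sum(1 for _, g in free if g == f) >= 2]
    free = [fl for fl in free if fl[1] in factors]
    if not factors:
        return None
    starts = tuple((r, f, v) for r, f, v in spec.start_loadings if (r, f) in set(free))
    return FactorModelSpec(
        spec.regions, tuple(factors), tuple(free),
        spec.factor_correlations_free, spec.residual_variances_free, starts,
    )


def prune_loadings(
    fit: CFAFit, gs: GeneticCovarianceStructure, alpha: float = 0.05
) -> CFAFit:
    """Successively remove the free loading with the largest non-significant
    two-sided Wald p-value (p >= alpha) and refit until all loadings are
    significant.  A factor reduced below 2 indicators is removed with its
    correlations.  Returns the final fit with a removal log."""
    if not fit.converged:
        raise FactorModelError("prune_loadings requires a converged fit")
    log: list[str] = list(fit.removal_log)
    current = fit
    while True:
        pvals = {}
        for r, f in current.spec.free_loadings:
            key = f"lambda:{r}:{f}"
            se = current.se.get(key, float("nan"))
            if not np.isfinite(se) or se <= 0:
                continue
            z = current.estimates[key] / se
            pvals[(r, f)] = 2.0 * _stats.norm.sf(abs(z))
        removable = {k: v for k, v in pvals.items() if v >= alpha}
        if not removable:
            break
        worst = max(removable, key=removable.get)
        new_spec = _drop_loading(current.spec, worst)
        if new_spec is None:
            raise FactorModelError(
                f"pruning emptied the model; log: {log + [str(worst)]}"
            )
        log.append(f"removed {worst[0]}~{worst[1]} (p={removable[worst]:.3g})")
        refit = fit_cfa(new_spec, gs)
        if not refit.converged:
            log.append("stopped: refit after removal did not converge")
            break
        current = refit
    return dataclasses.replace(current, removal_log=tuple(log))


def select_model(fits: Iterable[CFAFit]) -> CFAFit:
    """The converged fit with minimal AIC; ties (within 1e-9) broken by fewer
    free parameters, then fewer factors."""
    fits = list(fits)
    converged = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not converged:
        diag = [f"{len(f.spec.factors)} factors: {f.message or 'not converged'}" for f in fits]
        raise FactorModelError("no converged candidate model; diagnostics: " + "; ".join(diag))
    best_aic = min(f.aic for f in converged)
    tied = [f for f in converged if f.aic <= best_aic + 1e-9]
    return min(tied, key=lambda f: (f.n_free, f.n_factors))
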