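"""Synthetic GWAS summary statistics with a planted factor structure.

The generator instantiates the statistical model LD score regression assumes:
for SNP j with LD score ell_j the vector of per-trait Z-scores satisfies

    E[Z_t Z_u] = overlap_intercept[t,u] + sqrt(N_t N_u) * S_true[t,u] * ell_j / M

where S_true = sqrt(h2) (Lambda Psi Lambda' + Theta) sqrt(h2) is the planted
genetic covariance (Lambda, Psi, Theta on the genetic-correlation metric,
unit diagonal).  Two modes:

* ``covariance`` — Z drawn per SNP from the zero-mean multivariate normal
  above; fast, the default for covariance-structure and factor-recovery
  tests.
* ``causal`` — explicit per-SNP standardized factor effects (dense polygenic
  background plus listed large-effect causal SNPs acting through factors)
  mapped to trait effects, LD-smeared within equicorrelated sub-blocks, with
  LD-correlated noise; used for factor-GWAS power tests.

Both modes share a variant universe: LD sub-blocks are assigned to the 22
autosomes round-robin (so a block never straddles a chromosome and parity
splitting gets about half the SNPs on each side), LD scores are log-normal
(median about 10) and constant within sub-blocks, MAF is uniform(0.05, 0.5),
INFO is fixed at 1.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .overlap import RegionSet
from .sumstats import LDScoreTable, SumStatsTable

__all__ = [
    "SimulationError", "TruthParams", "SimulatedStudy",
    "simulate_ld", "simulate_sumstats", "make_region_fixtures",
    "default_truth",
]


class SimulationError(ValueError):
    """Inconsistent planted truth or generator misuse."""


def _default_lambda(p: int, k: int) -> np.ndarray:
    """Block loading pattern: equal-sized blocks, loadings 0.7 for the first
    factor's block, 0.6 for the second, alternating thereafter."""
    lam = np.zeros((p, k))
    blocks = np.array_split(np.arange(p), k)
    values = [0.7, 0.6]
    for f, idx in enumerate(blocks):
        lam[idx, f] = values[f % 2]
    return lam


@dataclasses.dataclass
class TruthParams:
    """Planted generative parameters.

    Lambda/Psi/Theta live on the genetic-correlation metric: the implied
    matrix Lambda Psi Lambda' + Theta has unit diagonal and Theta is derived
    as its complement.  ``h2`` scales it to the genetic covariance.
    ``causal`` lists (snp_index, factor_index, gamma) large-effect SNPs whose
    standardized effect acts through the named factor.
    """

    p: int = 8
    k: int = 2
    lambda_: np.ndarray | None = None
    psi: np.ndarray | None = None
    h2: float | np.ndarray = 0.25
    n: float | np.ndarray = 50_000.0
    m: int = 50_000
    n_ld_blocks: int = 2000
    overlap_intercepts: np.ndarray | None = None
    causal: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.lambda_ is None:
            self.lambda_ = _default_lambda(self.p, self.k)
        self.lambda_ = np.asarray(self.lambda_, dtype=float)
        if self.psi is None:
            self.psi = np.full((self.k, self.k), 0.7)
            np.fill_diagonal(self.psi, 1.0)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.lambda_.shape != (self.p, self.k) or self.psi.shape != (self.k, self.k):
            raise SimulationError("Lambda/Psi dimensions inconsistent with p, k")
        if not np.allclose(np.diag(self.psi), 1.0):
            raise SimulationError("Psi must have unit diagonal")
        comm = np.diag(self.lambda_ @ self.psi @ self.lambda_.T)
        if np.any(comm > 1.0 + 1e-12):
            raise SimulationError("planted communalities exceed 1")
        self.h2 = np.broadcast_to(np.asarray(self.h2, dtype=float), (self.p,)).copy()
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float), (self.p,)).copy()
        if self.overlap_intercepts is None:
            self.overlap_intercepts = np.eye(self.p)
        self.overlap_intercepts = np.asarray(self.overlap_intercepts, dtype=float)
        if self.m < self.n_ld_blocks:
            raise SimulationError("M must be at least the number of LD blocks")

    @property
    def theta(self) -> np.ndarray:
        """Residual genetic variances on the correlation metric."""
        return 1.0 - np.diag(self.lambda_ @ self.psi @ self.lambda_.T)

    @property
    def sigma_corr(self) -> np.ndarray:
        """Planted genetic correlation matrix Lambda Psi Lambda' + Theta."""
        return self.lambda_ @ self.psi @ self.lambda_.T + np.diag(self.theta)

    @property
    def s_true(self) -> np.ndarray:
        """Planted genetic covariance matrix on the standardized-trait scale."""
        d = np.sqrt(self.h2)
        return self.sigma_corr * np.outer(d, d)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(f"region{i + 1:02d}" for i in range(self.p))

    def manifest(self) -> dict:
        return {
            "p": self.p, "k": self.k,
            "lambda": self.lambda_.tolist(), "psi": self.psi.tolist(),
            "theta": self.theta.tolist(), "h2": self.h2.tolist(),
            "n": self.n.tolist(), "m": self.m, "n_ld_blocks": self.n_ld_blocks,
            "overlap_intercepts": self.overlap_intercepts.tolist(),
            "causal": [list(c) for c in self.causal], "seed": self.seed,
            "s_true": self.s_true.tolist(),
        }


def default_truth(**overrides) -> TruthParams:
    """The standard desk-scale fixture: 8 traits, 2 factors with loading
    blocks 0.7/0.6, inter-factor genetic correlation 0.7, h2 = 0.25,
    N = M = 50,000."""
    return TruthParams(**overrides)


@dataclasses.dataclass
class SimulatedStudy:
    """The generator's output: per-trait tables on a shared variant universe,
    LD scores, the planted truth, and a manifest of all planted values."""

    tables: list[SumStatsTable]
    ld: LDScoreTable
    truth: TruthParams
    block_ids: np.ndarray  # per-SNP LD sub-block id, aligned with ld.df order
    mode: str

    @property
    def manifest(self) -> dict:
        return {**self.truth.manifest(), "mode": self.mode}


def simulate_ld(m: int, n_blocks: int, seed: int) -> tuple[LDScoreTable, np.ndarray]:
    """Simulate a variant universe with block-constant LD scores.

    Sub-blocks are assigned to chromosomes 1-22 round-robin; LD scores are
    drawn log-normal (median 10, sigma 0.5) per block and clipped to
    [1, block size] so an equicorrelated within-block LD pattern with that
    score exists.  Returns (LDScoreTable, per-SNP block id).
    """
    if m < n_blocks or n_blocks < 1:
        raise SimulationError(f"need M >= n_blocks >= 1, got M={m}, n_blocks={n_blocks}")
    rng = np.random.default_rng(seed)
    block_of = np.array_split(np.arange(m), n_blocks)
    chrom_of_block = np.arange(n_blocks) % 22 + 1
    ell_of_block = np.exp(rng.normal(np.log(10.0), 0.5, size=n_blocks))
    sizes = np.array([len(b) for b in block_of])
    ell_of_block = np.clip(ell_of_block, 1.0, np.maximum(sizes.astype(float), 1.0))

    order = np.argsort(chrom_of_block, kind="stable")
    chrom = np.empty(m, dtype=int)
    ell = np.empty(m, dtype=float)
    block_id = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    cursor = 0
    next_pos: dict[int, int] = {}
    for b in order:
        size = sizes[b]
        c = int(chrom_of_block[b])
        start = next_pos.get(c, 0)
        sl = slice(cursor, cursor + size)
        chrom[sl] = c
        ell[sl] = ell_of_block[b]
        block_id[sl] = b
        pos[sl] = (start + np.arange(size) + 1) * 1000
        next_pos[c] = start + size
        cursor += size
    snp_id = np.array([f"rs{i + 1}" for i in range(m)])
    df = pd.DataFrame({"snp_id": snp_id, "chrom": chrom, "pos": pos, "ell": ell})
    ld = LDScoreTable(df, float(m))
    # LDScoreTable sorts by (chrom, pos) = the construction order
    return ld, block_id


def _tables_from_z(Z, truth: TruthParams, ld: LDScoreTable, maf: np.ndarray):
    tables = []
    base = ld.df[["snp_id", "chrom", "pos"]]
    for t, name in enumerate(truth.trait_names):
        se = 1.0 / np.sqrt(truth.n[t] * 2.0 * maf * (1.0 - maf))
        z = Z[:, t]
        df = base.copy()
        df["a1"] = "A"
        df["a2"] = "G"
        df["maf"] = maf
        df["beta"] = z * se
        df["se"] = se
        df["z"] = z
        df["n"] = truth.n[t]
        df["info"] = 1.0
        df["pval"] = np.clip(2.0 * _stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        tables.append(SumStatsTable(name, df, [f"simulated trait {name}"]))
    return tables


def simulate_sumstats(truth: TruthParams, mode: str = "covariance") -> SimulatedStudy:
    """Generate a full simulated study under the planted truth.

    covariance mode: per SNP j the p-vector of Z-scores is drawn from
    N(0, Sigma_j) with Sigma_j[t,u] = overlap_intercepts[t,u]
    + sqrt(N_t N_u) S_true[t,u] ell_j / M.

    causal mode: per-SNP standardized factor effects gamma_j ~ N(0, Psi/M)
    (plus the listed causal effects) and residual effects e_j ~ N(0, Theta/M)
    give trait effects b = sqrt(h2) * (Lambda gamma + e); Z-scores are
    sqrt(N) times the LD-smeared effects plus LD-correlated unit noise within
    each equicorrelated sub-block.
    """
    if mode not in ("covariance", "causal"):
        raise SimulationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(truth.seed)
    ld, block_id = simulate_ld(truth.m, truth.n_ld_blocks, truth.seed)
    ell = ld.df["ell"].to_numpy()
    m = truth.m
    p = truth.p
    maf = rng.uniform(*truth.maf_range, size=m)

    # sub-blocks are contiguous runs in (chrom, pos) order
    seg_starts = np.flatnonzero(np.r_[True, block_id[1:] != block_id[:-1]])
    seg_ends = np.r_[seg_starts[1:], m]

    if mode == "covariance":
        sqrtN = np.sqrt(np.outer(truth.n, truth.n))
        base_cov = truth.overlap_intercepts
        signal = sqrtN * truth.s_true / truth.m
        E = rng.standard_normal((m, p))
        Z = np.empty((m, p))
        for lo, hi in zip(seg_starts, seg_ends):
            sigma = base_cov + signal * ell[lo]
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                raise SimulationError(
                    f"non-PSD per-SNP covariance in block {block_id[lo]}: "
                    "planted truth is inconsistent"
                )
            Z[lo:hi] = E[lo:hi] @ L.T
    else:
        chol_psi = np.linalg.cholesky(truth.psi)
        gamma = (rng.standard_normal((m, truth.k)) @ chol_psi.T) / np.sqrt(m)
        # planted causal effects are per-allele SNP -> factor paths; convert to
        # the standardized-genotype scale of the polygenic background
        for snp_idx, f_idx, g in truth.causal:
            sg = np.sqrt(2.0 * maf[int(snp_idx)] * (1.0 - maf[int(snp_idx)]))
            gamma[int(snp_idx), int(f_idx)] += g * sg
        e = rng.standard_normal((m, p)) * np.sqrt(truth.theta / m)
        b_corr = gamma @ truth.lambda_.T + e
        b_trait = b_corr * np.sqrt(truth.h2)

        eps = rng.standard_normal((m, p))
        eps_block = rng.standard_normal((truth.n_ld_blocks, p))
        Z = np.empty((m, p))
        for lo, hi in zip(seg_starts, seg_ends):
            s = hi - lo
            r = 0.0 if s == 1 else np.sqrt(max(ell[lo] - 1.0, 0.0) / (s - 1))
            bsum = b_trait[lo:hi].sum(axis=0)
            smeared = (1.0 - r) * b_trait[lo:hi] + r * bsum[None, :]
            noise = np.sqrt(1.0 - r) * eps[lo:hi] + np.sqrt(r) * eps_block[block_id[lo]][None, :]
            Z[lo:hi] = np.sqrt(truth.n)[None, :] * smeared + noise

    tables = _tables_from_z(Z, truth, ld, maf)
    return SimulatedStudy(tables, ld, truth, block_id, mode)


def make_region_fixtures(
    universe_size: int,
    set_sizes: dict[str, int],
    seed: int = 0,
    planted: Sequence[tuple[str, str, int]] = (),
) -> tuple[tuple[str, ...], dict[str, RegionSet]]:
    """Reproducible named region sets over a synthetic region universe.

    ``planted`` lists (name_a, name_b, n_shared) pairs: set b is rebuilt to
    share exactly ``n_shared`` regions with set a (both must be in
    ``set_sizes``).  Stands in for an atlas universe with reference
    parcellations of known overlap.
    """
    rng = np.random.default_rng(seed)
    universe = tuple(f"region{i + 1:02d}" for i in range(universe_size))
    sets: dict[str, RegionSet] = {}
    for name, size in set_sizes.items():
        if size > universe_size:
            raise SimulationError(f"set {name} larger than the universe")
        members = frozenset(rng.choice(universe, size=size, replace=False).tolist())
        sets[name] = RegionSet(name, members, universe)
    for a, b, n_shared in planted:
        size_b = set_sizes[b]
        if n_shared > min(size_b, set_sizes[a]):
            raise SimulationError(f"cannot share {n_shared} regions between {a} and {b}")
        members_a = sorted(sets[a].members)
        shared = list(rng.choice(members_a, size=n_shared, replace=False))
        pool = [r for r in universe if r not in sets[a].members]
        rest = list(rng.choice(pool, size=size_b - n_shared, replace=False))
        sets[b] = RegionSet(b, frozenset(shared + rest), universe)
    return universe, sets
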