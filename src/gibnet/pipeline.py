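"""End-to-end orchestration: munge -> parity split -> (S, V) per parity ->
EFA grid -> thresholded CFA specs -> DWLS fits -> pruning -> AIC selection ->
factor GWAS -> locus clumping -> external genetic correlations -> overlap.

Configuration is a single YAML file; all defaults mirror the analysis
settings of the study design (factor counts 1-10, loading cutoffs 0.3 and
0.5, pruning alpha 0.05, genome-wide significance 5e-8, 250 kb clump window,
1000 permutation iterations).  Exploratory and confirmatory stages run on
complementary chromosome parities (EFA on odd, CFA on even by default; the
sensitivity swap reverses them).  All randomness flows from one root seed
recorded in the artifacts, and reruns with identical config and inputs are
bit-stable.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import factor_gwas as fg
from . import factor_models as fm
from . import ldsc as ldsc_mod
from . import overlap as ov
from . import simulate as sim
from .sumstats import (
    LDScoreTable, SumStatsTable, munge, read_ldscores, read_sumstats,
    select_chromosome_parity, write_ldscores, write_sumstats,
)

__all__ = ["PipelineConfig", "RunArtifacts", "run_pipeline", "factor_region_sets"]


class PipelineError(ValueError):
    """Invalid configuration or a failed pipeline stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for defaults)."""

    outdir: str = "gibnet_out"
    seed: int = 0
    # inputs: either a simulate block or real files
    simulate: dict | None = None
    traits: list[dict] = dataclasses.field(default_factory=list)
    ld_scores: str | list[str] | None = None
    reference: str | None = None  # allele/frequency reference for munging
    n_default: float | None = None
    # analysis settings
    efa_parity: str = "odd"
    factor_range: tuple[int, int] = (1, 10)
    cutoffs: tuple[float, ...] = (0.3, 0.5)
    prune_alpha: float = 0.05
    info_min: float = 0.6
    maf_min: float = 0.01
    n_blocks: int = 200
    per_snp_n: bool = True  # per-SNP sample sizes vs their mean in LDSC
    gws_threshold: float = 5e-8
    clump_window: int = 250_000
    n_perm: int = 1000
    external_traits: list[dict] = dataclasses.field(default_factory=list)
    reference_sets: str | None = None  # TSV: set_name <tab> region

    def __post_init__(self) -> None:
        if self.efa_parity not in ("odd", "even"):
            raise PipelineError(f"efa_parity must be odd or even, got {self.efa_parity!r}")
        lo, hi = self.factor_range
        if not (1 <= lo <= hi):
            raise PipelineError(f"invalid factor_range {self.factor_range}")
        self.factor_range = (int(lo), int(hi))
        self.cutoffs = tuple(float(c) for c in self.cutoffs)

    @property
    def cfa_parity(self) -> str:
        return "even" if self.efa_parity == "odd" else "odd"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "factor_range" in raw:
            raw["factor_range"] = tuple(raw["factor_range"])
        if "parities" in raw:
            raise PipelineError("set efa_parity; the CFA parity is always the complement")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["factor_range"] = list(self.factor_range)
        d["cutoffs"] = list(self.cutoffs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclasses.dataclass
class RunArtifacts:
    """Everything a pipeline run produces, in memory plus on disk under
    ``outdir`` (tab-delimited tables, a YAML summary, and a stage log)."""

    config: PipelineConfig
    tables: list[SumStatsTable]
    ld: LDScoreTable
    gs_efa: ldsc_mod.GeneticCovarianceStructure | None = None
    gs_cfa: ldsc_mod.GeneticCovarianceStructure | None = None
    gs_efa_std: ldsc_mod.GeneticCovarianceStructure | None = None
    gs_cfa_std: ldsc_mod.GeneticCovarianceStructure | None = None
    efa_results: dict[int, fm.EFAResult] = dataclasses.field(default_factory=dict)
    cfa_fits: list[fm.CFAFit] = dataclasses.field(default_factory=list)
    selected: fm.CFAFit | None = None
    gwas: fg.FactorGWASTable | None = None
    loci: pd.DataFrame | None = None
    rg_table: pd.DataFrame | None = None
    overlap_table: pd.DataFrame | None = None
    summary: dict = dataclasses.field(default_factory=dict)


def _setup_logger(outdir: str) -> logging.Logger:
    logger = logging.getLogger(f"gibnet.pipeline.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(os.path.join(outdir, "pipeline.log"), mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    logger.propagate = False
    return logger


def _load_inputs(config: PipelineConfig, log: logging.Logger):
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        mode = overrides.pop("mode", "covariance")
        for key in ("lambda_", "psi", "overlap_intercepts"):
            if key in overrides and overrides[key] is not None:
                overrides[key] = np.asarray(overrides[key], dtype=float)
        if "causal" in overrides:
            overrides["causal"] = tuple(tuple(c) for c in overrides["causal"])
        truth = sim.TruthParams(**overrides)
        study = sim.simulate_sumstats(truth, mode=mode)
        log.info("simulate: %d traits x %d SNPs (mode=%s)", truth.p, truth.m, study.mode)
        return study.tables, study.ld
    if not config.traits or config.ld_scores is None:
        raise PipelineError("config must provide either a simulate block or traits + ld_scores")
    tables = []
    for spec in config.traits:
        t = read_sumstats(
            spec["path"], spec.get("column_map"), spec.get("name"),
            spec.get("n_default", config.n_default),
        )
        tables.append(t)
        log.info("read %s: %d SNPs", t.trait_name, t.n_snps)
    ld = read_ldscores(config.ld_scores)
    log.info("ld scores: %d SNPs, M=%g", ld.n_snps, ld.m)
    if config.reference:
        ref = read_sumstats(config.reference, n_default=1.0)
        tables = [munge(t, ref, config.info_min, config.maf_min) for t in tables]
        for t in tables:
            log.info("munged %s: %d SNPs", t.trait_name, t.n_snps)
    return tables, ld


def factor_region_sets(fit: fm.CFAFit, universe) -> list[ov.RegionSet]:
    """One region set per factor: the regions carrying its free loadings."""
    sets = []
    for f in fit.spec.factors:
        members = frozenset(r for r, g in fit.spec.free_loadings if g == f)
        sets.append(ov.RegionSet(f, members, tuple(universe)))
    return sets


def _read_region_sets(path: str, universe) -> list[ov.RegionSet]:
    df = pd.read_csv(path, sep="\t")
    if not {"set_name", "region"} <= set(df.columns):
        raise PipelineError(f"region-set file {path} needs columns set_name, region")
    out = []
    for name, grp in df.groupby("set_name", sort=True):
        out.append(ov.RegionSet(str(name), frozenset(grp["region"]), tuple(universe)))
    return out


def run_pipeline(
    config: PipelineConfig,
    swap_parities: bool = False,
    stop_after: str | None = None,
) -> RunArtifacts:
    """Execute the full analysis (see module docstring).  ``swap_parities``
    runs the sensitivity analysis with EFA and CFA chromosome sets
    exchanged; ``stop_after`` ends the run after a named stage
    (inputs|ldsc|efa|cfa|gwas|rg|overlap)."""
    os.makedirs(config.outdir, exist_ok=True)
    log = _setup_logger(config.outdir)
    t0 = time.time()
    efa_parity = config.cfa_parity if swap_parities else config.efa_parity
    cfa_parity = "even" if efa_parity == "odd" else "odd"
    log.info("stage=start seed=%d efa_parity=%s cfa_parity=%s", config.seed, efa_parity, cfa_parity)

    tables, ld = _load_inputs(config, log)
    art = RunArtifacts(config, tables, ld)
    art.summary = {"seed": config.seed, "efa_parity": efa_parity}
    if stop_after == "inputs":
        return art

    # genetic covariance structures per parity
    split = {
        par: [select_chromosome_parity(t, par) for t in tables]
        for par in (efa_parity, cfa_parity)
    }
    gs = {}
    for par in (efa_parity, cfa_parity):
        gs[par] = ldsc_mod.build_covariance_structure(
            split[par], ld, n_blocks=config.n_blocks, per_snp_n=config.per_snp_n
        )
        log.info("stage=ldsc parity=%s snps=%d traits=%d", par,
                 split[par][0].n_snps, gs[par].k)
    art.gs_efa, art.gs_cfa = gs[efa_parity], gs[cfa_parity]

    def standardize_smooth(g):
        std = ldsc_mod.standardize_structure(g)
        S_psd, delta = ldsc_mod.smooth_to_psd(std.S)
        if delta > 0:
            log.info("stage=smooth max element change %.3g", delta)
        return ldsc_mod.GeneticCovarianceStructure(
            std.traits, S_psd, std.V, std.intercepts, standardized=True
        )

    art.gs_efa_std = standardize_smooth(art.gs_efa)
    art.gs_cfa_std = standardize_smooth(art.gs_cfa)
    _write_matrix(config.outdir, "S_efa_std.tsv", art.gs_efa_std.S, art.gs_efa_std.traits)
    _write_matrix(config.outdir, "S_cfa_std.tsv", art.gs_cfa_std.S, art.gs_cfa_std.traits)
    np.savetxt(os.path.join(config.outdir, "V_cfa.tsv"), art.gs_cfa_std.V, delimiter="\t")
    if stop_after == "ldsc":
        return art

    # EFA grid
    p = art.gs_efa_std.k
    lo, hi = config.factor_range
    hi = min(hi, p - 1)
    efa_rows = []
    for k in range(lo, hi + 1):
        res = fm.run_efa(art.gs_efa_std, k)
        art.efa_results[k] = res
        for ri, region in enumerate(res.regions):
            for fi in range(k):
                efa_rows.append(
                    {"n_factors": k, "region": region, "factor": f"F{fi + 1}",
                     "loading": res.loadings[ri, fi], "converged": res.converged}
                )
        log.info("stage=efa k=%d converged=%s", k, res.converged)
    pd.DataFrame(efa_rows).to_csv(
        os.path.join(config.outdir, "efa_loadings.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"eigenvalue": art.efa_results[lo].eigenvalues}
    ).to_csv(os.path.join(config.outdir, "scree.tsv"), sep="\t", index=False)
    if stop_after == "efa":
        return art

    # CFA grid over factor counts x cutoffs, then pruning and AIC selection
    fit_rows = []
    seen_specs = set()
    for k, res in art.efa_results.items():
        if not res.converged:
            continue
        for cutoff in config.cutoffs:
            try:
                spec = fm.build_cfa_spec(res, cutoff)
            except fm.FactorModelError as exc:
                log.info("stage=cfa k=%d cutoff=%g skipped (%s)", k, cutoff, exc)
                continue
            key = (spec.regions, spec.factors, spec.free_loadings)
            if key in seen_specs:
                continue
            seen_specs.add(key)
            spec = fm.embed_spec(spec, art.gs_cfa_std.traits)
            fit = fm.fit_cfa(spec, art.gs_cfa_std)
            if fit.converged:
                try:
                    fit = fm.prune_loadings(fit, art.gs_cfa_std, config.prune_alpha)
                except fm.FactorModelError as exc:
                    log.info("stage=prune k=%d cutoff=%g failed (%s)", k, cutoff, exc)
            art.cfa_fits.append(fit)
            fit_rows.append(
                {"efa_k": k, "cutoff": cutoff, "n_factors": fit.n_factors,
                 "n_free": fit.n_free, "chi2": fit.chi2, "df": fit.df,
                 "aic": fit.aic, "cfi": fit.cfi, "srmr": fit.srmr,
                 "converged": fit.converged, "message": fit.message}
            )
            log.info("stage=cfa k=%d cutoff=%g factors=%d aic=%s converged=%s",
                     k, cutoff, fit.n_factors, f"{fit.aic:.2f}" if np.isfinite(fit.aic) else "nan",
                     fit.converged)
    pd.DataFrame(fit_rows).to_csv(
        os.path.join(config.outdir, "cfa_fits.tsv"), sep="\t", index=False
    )
    art.selected = fm.select_model(art.cfa_fits)
    _write_selected(config.outdir, art.selected)
    art.summary.update(
        selected_factors=art.selected.n_factors,
        selected_aic=float(art.selected.aic),
        selected_cfi=float(art.selected.cfi),
        selected_srmr=float(art.selected.srmr),
    )
    log.info("stage=select factors=%d aic=%.2f cfi=%.3f srmr=%.4f",
             art.selected.n_factors, art.selected.aic, art.selected.cfi, art.selected.srmr)
    if stop_after == "cfa":
        _write_summary(config.outdir, art)
        return art

    # multivariate GWAS of the selected factors on all chromosomes
    art.gwas = fg.multivariate_gwas(tables, art.gs_cfa, art.selected.spec, art.selected)
    gpath = os.path.join(config.outdir, "factor_gwas.tsv")
    art.gwas.df.to_csv(gpath, sep="\t", index=False)
    art.loci = fg.clump_loci(art.gwas, config.gws_threshold, config.clump_window)
    art.loci.to_csv(os.path.join(config.outdir, "loci.tsv"), sep="\t", index=False)
    art.summary.update(
        lambda_gc={f: float(v) for f, v in art.gwas.lambdas.items()},
        n_gws=int((art.gwas.df["pval_f"] < config.gws_threshold).sum()),
        n_loci=int(len(art.loci)),
    )
    log.info("stage=gwas snps=%d gws=%d loci=%d lambdas=%s",
             art.gwas.df["snp_id"].nunique(), art.summary["n_gws"],
             art.summary["n_loci"], art.summary["lambda_gc"])
    if stop_after == "gwas":
        _write_summary(config.outdir, art)
        return art

    # genetic correlation of factors with external phenotypes
    if config.external_traits:
        ftabs = {f: fg.factor_sumstats(art.gwas, f) for f in art.gwas.factors}
        etabs = {}
        for spec_ in config.external_traits:
            etabs[spec_.get("name", spec_["path"])] = read_sumstats(
                spec_["path"], spec_.get("column_map"), spec_.get("name"),
                spec_.get("n_default", config.n_default),
            )
        art.rg_table = ov.factor_trait_rg(ftabs, etabs, ld, n_blocks=config.n_blocks)
        art.rg_table.to_csv(os.path.join(config.outdir, "factor_rg.tsv"), sep="\t", index=False)
        log.info("stage=rg pairs=%d", len(art.rg_table))
    if stop_after == "rg":
        _write_summary(config.outdir, art)
        return art

    # overlap of factor networks with reference parcellations
    if config.reference_sets:
        universe = [t.trait_name for t in tables]
        gibns = factor_region_sets(art.selected, universe)
        refs = _read_region_sets(config.reference_sets, universe)
        art.overlap_table = ov.overlap_grid(gibns, refs, n_iter=config.n_perm, seed=config.seed)
        art.overlap_table.to_csv(
            os.path.join(config.outdir, "overlap.tsv"), sep="\t", index=False
        )
        log.info("stage=overlap pairs=%d", len(art.overlap_table))

    _write_summary(config.outdir, art)
    log.info("stage=done wall=%.1fs", time.time() - t0)
    return art


def _write_matrix(outdir, fname, M, names):
    pd.DataFrame(M, index=list(names), columns=list(names)).to_csv(
        os.path.join(outdir, fname), sep="\t"
    )


def _write_selected(outdir: str, fit: fm.CFAFit) -> None:
    lines = []
    for f in fit.spec.factors:
        parts = [
            f"{r}({fit.estimates[f'lambda:{r}:{f}']:.3f})"
            for r, g in fit.spec.free_loadings if g == f
        ]
        lines.append(f"{f}: " + " ".join(parts))
    psi = fit.factor_correlation_matrix()
    for a in range(len(fit.spec.factors)):
        for b in range(a + 1, len(fit.spec.factors)):
            lines.append(
                f"rg({fit.spec.factors[a]},{fit.spec.factors[b]}) = {psi[a, b]:.3f}"
            )
    with open(os.path.join(outdir, "selected_model.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_summary(outdir: str, art: RunArtifacts) -> None:
    with open(os.path.join(outdir, "summary.yml"), "w") as fh:
        yaml.safe_dump(art.summary, fh, sort_keys=False)


def simulate_to_dir(truth: sim.TruthParams, outdir: str, mode: str = "covariance") -> None:
    """Write a full simulated study (sumstats, LD scores, manifest) to disk."""
    os.makedirs(outdir, exist_ok=True)
    study = sim.simulate_sumstats(truth, mode=mode)
    for t in study.tables:
        write_sumstats(t, os.path.join(outdir, f"{t.trait_name}.sumstats"))
    write_ldscores(study.ld, outdir)
    with open(os.path.join(outdir, "manifest.yml"), "w") as fh:
        yaml.safe_dump(study.manifest, fh, sort_keys=False)
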