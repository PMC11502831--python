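"""Shared fixtures: one small simulated study and its derived structures.

The session-scoped study (8 traits, planted 2-factor structure, 12,000 SNPs)
keeps unit tests fast; acceptance tests build their own full-size studies.
"""

import numpy as np
import pytest

from gibnet import (
    FactorModelSpec,
    GeneticCovarianceStructure,
    build_covariance_structure,
    fit_cfa,
    select_chromosome_parity,
    smooth_to_psd,
    standardize_structure,
)
from gibnet import simulate as sim


SMALL_M = 12_000
SMALL_BLOCKS = 480


def true_spec_for(truth: sim.TruthParams) -> FactorModelSpec:
    """The planted loading pattern as a CFA specification."""
    regions = truth.trait_names
    free = []
    for r in range(truth.p):
        for f in range(truth.k):
            if truth.lambda_[r, f] != 0:
                free.append((regions[r], f"F{f + 1}"))
    return FactorModelSpec(regions, tuple(f"F{f + 1}" for f in range(truth.k)), tuple(free))


def standardized(gs: GeneticCovarianceStructure) -> GeneticCovarianceStructure:
    std = standardize_structure(gs)
    S_psd, _ = smooth_to_psd(std.S)
    return GeneticCovarianceStructure(
        std.traits, S_psd, std.V, std.intercepts, standardized=True
    )


@pytest.fixture(scope="session")
def small_truth():
    return sim.default_truth(m=SMALL_M, n_ld_blocks=SMALL_BLOCKS, seed=11)


@pytest.fixture(scope="session")
def small_study(small_truth):
    return sim.simulate_sumstats(small_truth)


@pytest.fixture(scope="session")
def parity_structures(small_study):
    out = {}
    for par in ("odd", "even"):
        tabs = [select_chromosome_parity(t, par) for t in small_study.tables]
        gs = build_covariance_structure(tabs, small_study.ld, n_blocks=100)
        out[par] = gs
        out[par + "_std"] = standardized(gs)
    return out


@pytest.fixture(scope="session")
def true_spec(small_truth):
    return true_spec_for(small_truth)


@pytest.fixture(scope="session")
def cfa_fit(true_spec, parity_structures):
    fit = fit_cfa(true_spec, parity_structures["even_std"])
    assert fit.converged
    return fit
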