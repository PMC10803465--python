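"""Shared fixtures: small synthetic bundles and the two study-scale runs.

The study-scale runs (default planted scenario and the no-effect null, 5,000
pairs each) are expensive, so they are session-scoped and shared by every
test that scores recovery, type-I error or distribution shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import homoeobias as hb

ACCEPTANCE_SEED = 20240101  # fixed study-conditions seed for the suite


@pytest.fixture(scope="session")
def default_bundle() -> hb.SimBundle:
    """Default planted scenario at study scale (5,000 pairs)."""
    return hb.simulate(hb.SimConfig(n_pairs=5000, seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def default_result(default_bundle) -> hb.PipelineResult:
    return hb.run_analysis(
        default_bundle.counts,
        default_bundle.sheet,
        default_bundle.orthogroups,
        default_bundle.lengths,
        hb.PipelineConfig(),
    )


@pytest.fixture(scope="session")
def null_bundle() -> hb.SimBundle:
    """No planted effects: NC / NON_BIAS only, NB noise, 5,000 pairs."""
    return hb.simulate(hb.null_config(n_pairs=5000, seed=ACCEPTANCE_SEED + 1))


@pytest.fixture(scope="session")
def null_result(null_bundle) -> hb.PipelineResult:
    return hb.run_analysis(
        null_bundle.counts,
        null_bundle.sheet,
        null_bundle.orthogroups,
        null_bundle.lengths,
        hb.PipelineConfig(),
    )


@pytest.fixture()
def small_bundle() -> hb.SimBundle:
    """A fast 400-pair bundle for structural tests."""
    return hb.simulate(hb.SimConfig(n_pairs=400, seed=5))


def random_count_matrix(rng: np.random.Generator, n_genes=200, n_samples=4) -> hb.CountMatrix:
    """NB count matrix with log-normal gene means and uneven depths."""
    mu = rng.lognormal(3.0, 1.5, n_genes)
    depth = rng.uniform(0.5, 2.0, n_samples)
    mean = mu[:, None] * depth[None, :]
    x = rng.negative_binomial(10, 10 / (10 + mean))
    return hb.CountMatrix(
        pd.DataFrame(
            x,
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
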