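"""Shared fixtures: designed ladder sets and a deeply sequenced library.

The full 14-ladder design against a 1-Mb template and the deep low-error
library derived from it are expensive, so they are built once per session
and shared by the structural and acceptance tests.
"""

import numpy as np
import pytest

from cnladder import design, kmerquant, simulate


@pytest.fixture(scope="session")
def small_template():
    return design.random_template(150_000, seed=101, template_id="tpl_small")


@pytest.fixture(scope="session")
def ladder_set_small(small_template):
    cfg = design.DesignConfig(n_ladders=3)
    return design.design_ladder_set(small_template, cfg, seed=101)


@pytest.fixture(scope="session")
def catalog_small(ladder_set_small):
    return kmerquant.build_catalog(ladder_set_small)


@pytest.fixture(scope="session")
def full_template():
    return design.random_template(1_000_000, seed=11, template_id="tpl_1mb")


@pytest.fixture(scope="session")
def ladder_set_full(full_template):
    return design.design_ladder_set(full_template, design.DesignConfig(), seed=11)


@pytest.fixture(scope="session")
def catalog_full(ladder_set_full):
    return kmerquant.build_catalog(ladder_set_full)


@pytest.fixture(scope="session")
def deep_ladder_metrics(ladder_set_full, catalog_full):
    """Equimolar 14-ladder library at 100x per-copy depth, 0.5% error."""
    cfg = simulate.SimulationConfig(error_rate=0.005)
    batch = simulate.simulate_ladder_library(ladder_set_full, 100.0, cfg, seed=12)
    table = kmerquant.count_kmers(batch)
    profile = kmerquant.profile_cn(table, catalog_full)
    metrics = kmerquant.ladder_metrics(profile)
    return {"batch": batch, "table": table, "profile": profile, "metrics": metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
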