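"""Shared fixtures: one default control genome + annotation + catalog per
session, and a small genome for read-based tests."""

from __future__ import annotations

import numpy as np
import pytest

from subtel import build_reference_genome, build_extremity_map
from subtel.catalog import label_instances
from subtel.config import RunConfig
from subtel.simulate import CassetteSpec, SimConfig


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def cassette_specs() -> list[CassetteSpec]:
    return [
        CassetteSpec("bir1", "chrII-R", 4000, "chrVI-R", 6000, 1000, "arm"),
        CassetteSpec("bir2", "chrXIV-R", 3000, "chrXV-R", 5000, 700, "arm"),
        CassetteSpec("circ3", "chrIII-L", 10000, "chrIII-R", 12000, 1500, "original"),
    ]


@pytest.fixture(scope="session")
def control(cassette_specs):
    """Default control-like genome with its exact truth ledger."""
    genome, ledger = build_reference_genome(
        SimConfig(cassettes=cassette_specs), seed=1)
    return genome, ledger


@pytest.fixture(scope="session")
def x_library(control):
    _, ledger = control
    return [("X_ancestor", ledger.x_ancestor)]


@pytest.fixture(scope="session")
def control_maps(control, x_library, run_config):
    genome, ledger = control
    return build_extremity_map(genome, ledger.library, x_library, run_config)


@pytest.fixture(scope="session")
def control_catalog(control_maps):
    """(variants, matrix) over the control's Y' instances; labels written
    onto the instances in control_maps."""
    instances = [i for m in control_maps for i in m.yprime_instances]
    return label_instances(instances)


@pytest.fixture(scope="session")
def small_genome():
    """A reduced genome for read-simulation tests."""
    config = SimConfig(n_chromosomes=8, core_length=30000, core_length_jitter=3000,
                       n_yprime_ends=5, n_yprime_instances=8)
    genome, ledger = build_reference_genome(config, seed=2)
    return genome, ledger, config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
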