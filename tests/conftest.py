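"""Shared fixtures: a miniature self-contained study, generated at test time.

The expensive simulated trajectories are session-scoped and shared by the
tests that inspect them; everything is derived from fixed seeds so the
suite is fully reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import tdcsim as t

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_study")
    return t.generate_fixture_study(FIXTURE_SEED, out)


@pytest.fixture(scope="session")
def fixture_network(fixture_paths):
    return t.load_connectome(fixture_paths["connectome"])


@pytest.fixture(scope="session")
def fixture_montages(fixture_paths):
    return t.load_montages(fixture_paths["montages"])


@pytest.fixture(scope="session")
def fixture_config(fixture_paths):
    return t.SimulationConfig.from_yaml(fixture_paths["config"])


@pytest.fixture(scope="session")
def study_trajectories(fixture_config, fixture_network, fixture_montages):
    """Healthy, untreated-degeneration, anodal-posterior and its reversed
    montage, simulated over the full miniature protocol (10 runs, 20
    virtual timepoints).  This is the workhorse dataset of the suite."""
    results = {}
    for condition in ("healthy", "add", "add+PO7a-AF4c", "add+AF4a-PO7c"):
        cfg = replace(fixture_config, condition=condition)
        results[condition] = t.run_condition(
            cfg, network=fixture_network, montages=fixture_montages
        )
    return results


@pytest.fixture(scope="session")
def add_long_run(fixture_config, fixture_network):
    """Untreated degeneration over the full 40-timepoint protocol."""
    cfg = replace(fixture_config, condition="add", n_timepoints=40)
    return t.run_condition(cfg, network=fixture_network)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
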