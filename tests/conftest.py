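"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from oligosaxs.simulate import (
    build_scenario_model,
    monomer_dimer_scenario,
    simulate_batch,
)


@pytest.fixture(autouse=True)
def _quiet_shell_overflow():
    # second-shell overflow clamping is an expected regime during wide
    # parameter exploration; keep the signal in unit tests that ask for it
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="second-shell overflow")
        yield


@pytest.fixture(scope="session")
def md_scenario():
    """Default monomer-dimer synthetic study (seed 1)."""
    return monomer_dimer_scenario(seed=1, n_q=60)


@pytest.fixture(scope="session")
def md_batch(md_scenario):
    """Noisy batch + truth record for the default scenario."""
    return simulate_batch(md_scenario, seed=1)


@pytest.fixture(scope="session")
def md_model(md_scenario, md_batch):
    """Model built on the noisy batch with parameters set to the truth.

    Tests must not mutate the shared parameter set: pass explicit value
    mappings to ``chi2`` / ``model_intensity`` instead.
    """
    curves, truth = md_batch
    model = build_scenario_model(md_scenario, curves)
    model.params.set_values({k: v for k, v in truth.items() if k in model.params})
    return model


@pytest.fixture(scope="session")
def truth_values(md_batch):
    return md_batch[1]


@pytest.fixture(scope="session")
def grid_sphere():
    """Cubic-grid filling of a 20 Å sphere (continuum form-factor oracle)."""
    R, delta = 20.0, 1.5
    g = np.arange(-R, R + delta, delta)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    return R, pts[np.linalg.norm(pts, axis=1) <= R]
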