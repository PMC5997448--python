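"""Shared fixtures: miniature tubes so the physics tests run fast."""

import numpy as np
import pytest

import chiratube as ct


@pytest.fixture(scope="session")
def fixture_tube():
    """Miniature 63-cell tube with self-consistent relaxed-state targets."""
    return ct.make_fixture(seed=7)


@pytest.fixture(scope="session")
def paper_tube():
    """Full-scale 452-cell tube (geometry only; no dynamics)."""
    tess = ct.generate_initial_tessellation(seed=11)
    mesh = ct.wrap_to_cylinder(tess, 5.0)
    return {"tess": tess, "mesh": mesh}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def perturbed_fixture(fixture_tube, rng):
    """Fixture tube with a small random displacement (generic positions)."""
    mesh = fixture_tube["mesh"].copy()
    mesh.positions = mesh.positions + 0.01 * rng.normal(size=mesh.positions.shape)
    return {"mesh": mesh, "params": fixture_tube["params"],
            "diameter": fixture_tube["diameter"]}
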