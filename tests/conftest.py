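"""Shared fixtures: protocols and small phantoms generated at test time."""

import numpy as np
import pytest

import sminr


@pytest.fixture(scope="session")
def protocol():
    """The 154-measurement optimized multi-shell B-tensor protocol."""
    return sminr.optimized_protocol(seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """8^3 single-fiber phantom with full-grid mask (deterministic)."""
    return sminr.generate_phantom((8, 8, 8), lmax=2, seed=5, mask_type="full")


@pytest.fixture(scope="session")
def noiseless_signals(small_phantom, protocol):
    return sminr.simulate_signals(small_phantom, protocol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def mask_grid(phantom):
    return sminr.VolumeGrid(
        data=phantom.mask.astype(float), affine=phantom.grid.affine
    )
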