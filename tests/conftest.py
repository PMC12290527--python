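"""Shared fixtures: small phantoms and trajectories sized for fast tests."""

import numpy as np
import pytest

from spiralvaso import (PhantomConfig, SpiralParams, build_phantom,
                        design_vd_spiral, stack_spirals)


@pytest.fixture(scope="session")
def spiral_plane_small():
    """Single-plane spiral on a 16x16 grid (12 mm in-plane, FOV 192)."""
    return design_vd_spiral(SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.6,
                                         r_xy=1.5, dwell=4.0))


@pytest.fixture(scope="session")
def spiral_stack_small(spiral_plane_small):
    return stack_spirals(spiral_plane_small, 8, 24.0)


@pytest.fixture(scope="session")
def slow_spiral_plane():
    """Weak-gradient spiral: a 16x16 readout stretched to ~53 ms, so
    off-resonance phase accrual matches the full-scale acquisition."""
    return design_vd_spiral(SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.6,
                                         r_xy=1.0, g_max=0.36, sr_max=1.5,
                                         dwell=40.0))


@pytest.fixture(scope="session")
def phantom_small():
    """16x16x8 phantom, 3 coils, 3 layers, moderate smooth B0."""
    cfg = PhantomConfig(n_coils=3, n_layers=3, b0_amplitude=20.0, n_foci=0,
                        focus_amplitude=0.0)
    return build_phantom((16, 16, 8), seed=11, config=cfg)


@pytest.fixture(scope="session")
def phantom_default():
    """The default-run phantom geometry (32x32x8, 6 coils, 5 layers)."""
    return build_phantom((32, 32, 8), seed=5,
                         config=PhantomConfig(n_coils=6, n_layers=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
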