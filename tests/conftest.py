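"""Shared fixtures: analytic curves and simulated runs reused across modules."""

import math

import numpy as np
import pytest

from iecsaxs import ScatteringCurve, scan_shifts
from iecsaxs.simulate import (
    bsa_linear_config,
    bsa_step_config,
    simulate_run,
    sphere_form_factor,
)

SPHERE_RADIUS = 3.0  # nm
SPHERE_RG = math.sqrt(3.0 / 5.0) * SPHERE_RADIUS


@pytest.fixture(scope="session")
def default_grid():
    return np.linspace(0.032, 4.9, 1000)


@pytest.fixture(scope="session")
def sphere_curve(default_grid):
    """Noise-free ideal sphere, R = 3 nm, I(0) = 1000 a.u."""
    I = 1000.0 * sphere_form_factor(default_grid, SPHERE_RADIUS)
    return ScatteringCurve(default_grid, I, np.zeros_like(default_grid))


@pytest.fixture(scope="session")
def noiseless_linear_run():
    """BSA-like linear-gradient run without noise (true shift 130)."""
    return simulate_run(bsa_linear_config(noise_level=0.0))


@pytest.fixture(scope="session")
def noiseless_linear_scan(noiseless_linear_run):
    run = noiseless_linear_run
    return scan_shifts(run.sample, run.buffer)


@pytest.fixture(scope="session")
def noiseless_step_run():
    """BSA-like stepwise run without noise (N0 = 1289, N' = 17)."""
    return simulate_run(bsa_step_config(noise_level=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Factory for desk-scale runs: peak and gradient scaled to n_frames."""
    from iecsaxs.core import GradientProgram
    from iecsaxs.simulate import ElutionPeak, SimConfig

    def make(n_frames=40, n_q=60, **overrides):
        base = dict(
            n_frames=n_frames,
            n_q=n_q,
            peaks=(ElutionPeak(n_frames / 2.0, max(n_frames / 10.0, 2.0), 1.75, 0),),
            gradient=GradientProgram(
                25.0, 1000.0, "linear", (0, n_frames, 0.0, 0.5)
            ),
            true_shift=0,
        )
        base.update(overrides)
        return SimConfig(**base)

    return make
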