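"""Shared fixtures: a small world (coarse grids) and agents trained on it.

The small world keeps grid sizes and step counts low enough that the whole
unit suite runs in seconds while still exercising every code path; the
full-size desk configuration is only used by the acceptance tests.
"""

import warnings

import numpy as np
import pytest

import cosmo
from cosmo.learning import LearningSchedule, run_learning


@pytest.fixture(scope="session")
def forward():
    return cosmo.SurrogateForwardModel()


@pytest.fixture(scope="session")
def small_world(forward):
    """Coarse grids plus a calibrated master (9^3 motor, 25x31 sensory)."""
    motor_grid = cosmo.build_motor_grid(9)
    sensory_grid = cosmo.build_sensory_grid(forward, motor_grid, levels_f1=25, levels_f2=31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        master = cosmo.fit_master(motor_grid, forward, calibration_draws=5000)
    return motor_grid, sensory_grid, master


@pytest.fixture(scope="session")
def trained_agent(forward, small_world):
    """A communicatively trained learner on the small world (seed 11)."""
    motor_grid, sensory_grid, master = small_world
    agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
    rng = np.random.default_rng(11)
    schedule = LearningSchedule(6000, 6000, 6000, "communicative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_learning(agent, master, schedule, rng)
    return agent


@pytest.fixture(scope="session")
def ideal_world():
    """Ideal-learning conditions: affine forward map, analytic Gaussians.

    With a linear articulatory-to-acoustic map every vowel's sound
    distribution is exactly Gaussian, so the Gaussian sensory repertoire is a
    well-specified model of the environment — the premise under which
    auditory and motor decoding carry identical information.
    """
    forward = cosmo.LinearForwardModel()
    motor_grid = cosmo.build_motor_grid(21)
    sensory_grid = cosmo.build_sensory_grid(forward, motor_grid)
    master = cosmo.make_ideal_master(forward, cosmo.IDEAL_MOTOR_PROTOTYPES)
    return motor_grid, sensory_grid, master


@pytest.fixture(scope="session")
def perfect_agent(ideal_world):
    """A learner set analytically to the ideal master's generative truth."""
    motor_grid, sensory_grid, master = ideal_world
    return cosmo.make_perfect_learner(master, motor_grid, sensory_grid)


def on_support(master, sensory_grid, log_density_floor=-4.0):
    """Grid points the environment can plausibly produce.

    Off the support of the master's sound distributions both decoders only
    extrapolate tails, so the indistinguishability comparison is restricted
    to points where some vowel's sound density exceeds ``e**floor``.
    """
    logd = master.sensory_log_densities(sensory_grid.points).max(axis=1)
    return logd > log_density_floor
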