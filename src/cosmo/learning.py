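"""Three-phase developmental learning: sensory, sensorimotor, motor.

Phase 1 (sensory): the master utters labelled sounds; the learner updates its
per-vowel sound Gaussians.  Fully supervised.

Phase 2 (sensorimotor accommodation): the learner hears a master sound,
inverts its current internal model to draw a gesture, produces that gesture,
and hears its own (noiseless) output — updating the internal forward model
P(S | M) one motor cell at a time.

Phase 3 (motor): two variants.

* imitative — for each master pair (o, s) the learner draws a gesture from
  P(M | o, s) ∝ P(M | o) P(s | M) and records it unconditionally.
* communicative — the learner draws from P(M | o, C=1) ∝ P(M | o) A(m) where
  the plateau A(m) = Σ_S P(S | m) P(O_L = o | S) scores how likely a gesture
  is to be understood; the gesture is recorded only if the master actually
  categorizes the produced sound as o.

All categorical draws use log-space scores with max subtraction; if every
score underflows the draw falls back to uniform (an unexplored region).
The plateau maps are frozen at the start of phase 3: the sensory and
sensorimotor systems no longer change, so A is constant during the phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LearningSchedule",
    "sensory_step",
    "invert_motor",
    "sensorimotor_step",
    "plateau",
    "plateau_all",
    "motor_step_imitative",
    "motor_step_communicative",
    "run_learning",
]


@dataclass
class LearningSchedule:
    """Step counts per phase and the motor-learning variant."""

    steps_sensory: int = 300_000
    steps_sensorimotor: int = 300_000
    steps_motor: int = 300_000
    motor_variant: str = "communicative"
    log_every: int = 5000

    def __post_init__(self):
        for n in (self.steps_sensory, self.steps_sensorimotor, self.steps_motor):
            if n < 0:
                raise ValueError("step counts must be >= 0")
        if self.motor_variant not in ("imitative", "communicative"):
            raise ValueError(f"unknown motor variant: {self.motor_variant!r}")


def _normalize_log_weights(logw):
    """Exponentiate log scores into a probability vector; uniform on underflow."""
    logw = np.asarray(logw, dtype=float)
    m = np.max(logw)
    if not np.isfinite(m):
        return np.full(logw.size, 1.0 / logw.size)
    w = np.exp(logw - m)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full(logw.size, 1.0 / logw.size)
    return w / total


def _sample_categorical(rng, p):
    """Inverse-CDF draw from a normalized probability vector."""
    c = np.cumsum(p)
    u = rng.random() * c[-1]
    return int(np.searchsorted(c, u, side="right").clip(0, p.size - 1))


# ---------------------------------------------------------------------------
# Phase 1: sensory learning
# ---------------------------------------------------------------------------


def sensory_step(agent, master, rng):
    """One supervised sensory-learning step: hear (o, s), update P(S | o)."""
    o = int(rng.integers(master.n_vowels))
    _, s = master.produce(o, rng)
    agent.sensory.update(o, s)
    return o


# ---------------------------------------------------------------------------
# Phase 2: sensorimotor accommodation
# ---------------------------------------------------------------------------


def invert_motor(agent, s):
    """Posterior over motor cells for a heard sound: P(M | s) ∝ P(s | M).

    The cell prior is uniform, so the weights are the normalized internal-model
    densities at ``s``.  Returns a probability vector over motor cells; falls
    back to uniform if all densities underflow (unexplored sound region).
    """
    return _normalize_log_weights(agent.sensorimotor.logpdf_at(np.asarray(s, dtype=float)))


def sensorimotor_step(agent, master, rng):
    """One accommodation step.

    Hear a master sound, draw a cell from P(M | s), produce it, and update
    that cell's Gaussian with the self-heard sound f(m) — self-audition is
    treated as noiseless, so cell k only ever observes f(cell k).
    """
    o = int(rng.integers(master.n_vowels))
    _, s = master.produce(o, rng)
    w = invert_motor(agent, s)
    k = _sample_categorical(rng, w)
    agent.sensorimotor.update(k, agent.grid_image[k])
    return k


# ---------------------------------------------------------------------------
# Phase 3: motor learning
# ---------------------------------------------------------------------------


def plateau_all(agent, chunk=512):
    """Plateau maps A(m, o) = Σ_S P(S | m) P(O_L = o | S) for all vowels.

    P(S | m) is the internal-model density at each sensory grid cell times
    the cell area, renormalized over the grid (a proper categorical over
    sensory cells); P(O_L = o | S) is the Bayes inversion of the learned
    sensory repertoire under a uniform vowel prior.  Returns (n_cells, 7),
    each entry in [0, 1].
    """
    pts = agent.sensory_grid.points
    # P(o | S) on the whole grid from the learned sensory repertoire
    log_sens = agent.sensory.logpdf_points(pts)  # (7, n_sens)
    log_post = log_sens - logsumexp(log_sens, axis=0, keepdims=True)
    post = np.exp(log_post).T  # (n_sens, 7)

    n_cells = agent.motor_grid.n_cells
    A = np.empty((n_cells, agent.n_vowels))
    for start in range(0, n_cells, chunk):
        idx = np.arange(start, min(start + chunk, n_cells))
        logp = agent.sensorimotor.logpdf_points(pts, entries=idx)  # (chunk, n_sens)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)  # renormalize over the grid
        A[idx] = p @ post
    return A


def plateau(agent, o):
    """Plateau map for a single vowel index (see :func:`plateau_all`)."""
    return plateau_all(agent)[:, o]


def _motor_log_density_at_cells(agent, o):
    """Log-density of the vowel-o motor Gaussian at every motor cell."""
    bank = agent.motor
    coords = agent.motor_grid.coords
    mu = bank.means[o]
    ic = bank._invcov[o]
    dx = coords[:, 0] - mu[0]
    dy = coords[:, 1] - mu[1]
    dz = coords[:, 2] - mu[2]
    quad = (
        ic[0, 0] * dx * dx
        + ic[1, 1] * dy * dy
        + ic[2, 2] * dz * dz
        + 2.0 * (ic[0, 1] * dx * dy + ic[0, 2] * dx * dz + ic[1, 2] * dy * dz)
    )
    return -0.5 * (quad + bank._logdet[o] + 3 * np.log(2 * np.pi))


def motor_step_imitative(agent, master, rng):
    """One imitative step: reproduce the master's sound.

    Draw a cell from P(M | o, s) ∝ P(M | o) P(s | M) and record the gesture
    in the motor repertoire unconditionally.
    """
    o = int(rng.integers(master.n_vowels))
    _, s = master.produce(o, rng)
    logw = _motor_log_density_at_cells(agent, o) + agent.sensorimotor.logpdf_at(s)
    k = _sample_categorical(rng, _normalize_log_weights(logw))
    agent.motor.update(o, agent.motor_grid.coords[k])
    return o, k, True


def motor_step_communicative(agent, master, rng, plateaus):
    """One communicative step: produce a sound the master will understand.

    Draw a cell from P(M | o, C=1) ∝ P(M | o) A(m, o) with the frozen plateau
    maps, produce the sound with environmental noise, and record the gesture
    only if the master categorizes the sound as o.
    """
    o = int(rng.integers(master.n_vowels))
    with np.errstate(divide="ignore"):
        logw = _motor_log_density_at_cells(agent, o) + np.log(plateaus[:, o])
    k = _sample_categorical(rng, _normalize_log_weights(logw))
    s = agent.grid_image[k] + np.sqrt(master.sigma_env) * rng.standard_normal(2)
    accepted = master.categorize(s) == o
    if accepted:
        agent.motor.update(o, agent.motor_grid.coords[k])
    return o, k, bool(accepted)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_learning(agent, master, schedule, rng, progress=None):
    """Run the three phases in order; returns the trained agent.

    ``progress``, if given, is a list that accumulates dict records
    (phase, step, acceptance rate).  The same seed always yields a
    bit-identical trained agent: every random draw goes through ``rng`` in a
    fixed order (object, master gesture, environment noise, learner gesture).
    """
    log = progress if progress is not None else []
    if agent.grid_image is None:
        agent.attach_forward(master.forward)

    if schedule.steps_motor > 0 and schedule.steps_sensorimotor == 0:
        warnings.warn(
            "motor learning requested with no sensorimotor phase: "
            "acoustic-to-motor inversion will be prior-driven",
            stacklevel=2,
        )

    for step in range(schedule.steps_sensory):
        sensory_step(agent, master, rng)
        if (step + 1) % schedule.log_every == 0:
            log.append({"phase": "sensory", "step": step + 1, "acceptance": 1.0})

    for step in range(schedule.steps_sensorimotor):
        sensorimotor_step(agent, master, rng)
        if (step + 1) % schedule.log_every == 0:
            log.append({"phase": "sensorimotor", "step": step + 1, "acceptance": 1.0})

    if schedule.steps_motor > 0:
        plateaus = plateau_all(agent) if schedule.motor_variant == "communicative" else None
        accepted = 0
        window = 0
        for step in range(schedule.steps_motor):
            if schedule.motor_variant == "imitative":
                _, _, ok = motor_step_imitative(agent, master, rng)
            else:
                _, _, ok = motor_step_communicative(agent, master, rng, plateaus)
            accepted += ok
            window += 1
            if (step + 1) % schedule.log_every == 0:
                log.append(
                    {
                        "phase": f"motor_{schedule.motor_variant}",
                        "step": step + 1,
                        "acceptance": accepted / window,
                    }
                )
                accepted = 0
                window = 0
    return agent
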