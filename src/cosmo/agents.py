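"""Master and learner agents and the incremental Gaussian machinery they share.

Every learned "repertoire" entry — per-vowel sound statistics, per-motor-cell
sound statistics, per-vowel gesture statistics — is an incrementally updated
Gaussian: a (count, mean, scatter) triple whose covariance equals the batch
sample covariance of all observations pooled with a broad prior
pseudo-observation.  A small ridge (``variance_floor``) on the covariance
diagonal keeps every matrix positive definite even when all observations
coincide.

The master agent is the fixed generative model of the learning environment:
one 3-D motor Gaussian per vowel (diagonal covariance 0.1), a shared forward
map, and additive environmental noise of variance ``sigma_env`` (Bark^2) on
every emitted sound.  Its own categorizer is calibrated once, by pushing a
fixed-seed sample of each vowel's motor Gaussian through the forward map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spaces import MotorGrid, SensoryGrid, SurrogateForwardModel, build_motor_grid, build_sensory_grid, hz_to_bark

__all__ = [
    "VOWELS",
    "VOWEL_IPA",
    "DEFAULT_TARGETS_HZ",
    "GaussianStats",
    "GaussianBank",
    "gaussian_update",
    "MasterAgent",
    "fit_master",
    "LearnerAgent",
    "init_learner",
    "make_perfect_learner",
    "make_ideal_master",
    "IDEAL_MOTOR_PROTOTYPES",
]

# ASCII aliases used in every file output; IPA equivalents in VOWEL_IPA.
VOWELS = ("i", "u", "e", "o", "eps", "oo", "a")
VOWEL_IPA = {"i": "i", "u": "u", "e": "e", "o": "o", "eps": "ɛ", "oo": "ɔ", "a": "a"}

# Acoustic targets (F1, F2) in Hz approximating French oral vowels, projected
# into the reachable image of the default forward map (its logistic ranges
# compress the back-vowel corner relative to natural speech); any seven
# well-separated targets inside the forward image are acceptable.
DEFAULT_TARGETS_HZ = {
    "i": (280.0, 2250.0),
    "e": (390.0, 2050.0),
    "eps": (520.0, 1800.0),
    "a": (660.0, 1400.0),
    "oo": (560.0, 1050.0),
    "o": (450.0, 1180.0),
    "u": (420.0, 960.0),
}

_LOG2PI = float(np.log(2.0 * np.pi))


class GaussianBank:
    """A bank of ``n`` incrementally updated d-dimensional Gaussians.

    Stores counts (including the prior pseudo-count), means, and scatter
    matrices (Welford M2).  Covariance of entry ``i`` is
    ``m2[i] / count[i] + variance_floor * I``.  Inverse covariances and
    log-determinants are cached and refreshed per entry on update, so
    evaluating all entries' log-densities at one point is a vectorized O(n)
    operation — the workhorse of grid-based inference.
    """

    def __init__(self, n, dim, prior_mean, prior_cov, pseudo_count=1.0, variance_floor=1e-4):
        self.n = int(n)
        self.dim = int(dim)
        self.variance_floor = float(variance_floor)
        prior_mean = np.broadcast_to(np.asarray(prior_mean, dtype=float), (self.n, self.dim)).copy()
        prior_cov = np.broadcast_to(
            np.asarray(prior_cov, dtype=float), (self.n, self.dim, self.dim)
        ).copy()
        self.counts = np.full(self.n, float(pseudo_count))
        self.means = prior_mean
        # scatter = cov * count so that cov = m2 / count reproduces the prior
        self.m2 = prior_cov * np.maximum(self.counts, 1e-300)[:, None, None]
        if pseudo_count == 0.0:
            self.m2[:] = 0.0
        self._refresh_cache()

    # -- covariance handling -------------------------------------------------

    def cov(self, i=None):
        if i is not None:
            return self.m2[i] / max(self.counts[i], 1e-300) + self.variance_floor * np.eye(
                self.dim
            )
        counts = np.maximum(self.counts, 1e-300)
        return self.m2 / counts[:, None, None] + self.variance_floor * np.eye(self.dim)

    def _refresh_cache(self, idx=None):
        if idx is None:
            cov = self.cov()
            self._invcov = np.linalg.inv(cov)
            sign, logdet = np.linalg.slogdet(cov)
            self._logdet = logdet
        else:
            # closed-form small-matrix inverse: this is the per-step hot path
            cov = self.cov(idx)
            if self.dim == 2:
                a, b, d = cov[0, 0], cov[0, 1], cov[1, 1]
                det = a * d - b * b
                self._invcov[idx] = np.array([[d, -b], [-b, a]]) / det
                self._logdet[idx] = np.log(det)
            elif self.dim == 3:
                c00 = cov[1, 1] * cov[2, 2] - cov[1, 2] * cov[1, 2]
                c01 = cov[0, 2] * cov[1, 2] - cov[0, 1] * cov[2, 2]
                c02 = cov[0, 1] * cov[1, 2] - cov[0, 2] * cov[1, 1]
                det = cov[0, 0] * c00 + cov[0, 1] * c01 + cov[0, 2] * c02
                c11 = cov[0, 0] * cov[2, 2] - cov[0, 2] * cov[0, 2]
                c12 = cov[0, 1] * cov[0, 2] - cov[0, 0] * cov[1, 2]
                c22 = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[0, 1]
                self._invcov[idx] = (
                    np.array([[c00, c01, c02], [c01, c11, c12], [c02, c12, c22]]) / det
                )
                self._logdet[idx] = np.log(det)
            else:
                self._invcov[idx] = np.linalg.inv(cov)
                self._logdet[idx] = np.linalg.slogdet(cov)[1]

    # -- updates -------------------------------------------------------------

    def update(self, i, x):
        """Welford-style online update of entry ``i`` with observation ``x``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(f"observation has dimension {x.shape}, expected ({self.dim},)")
        self.counts[i] += 1.0
        delta = x - self.means[i]
        self.means[i] += delta / self.counts[i]
        delta2 = x - self.means[i]
        self.m2[i] += np.outer(delta, delta2)
        self._refresh_cache(i)

    # -- evaluation ----------------------------------------------------------

    def logpdf_at(self, s):
        """Log-density of every entry at a single point ``s`` -> (n,)."""
        s = np.asarray(s, dtype=float)
        if self.dim == 2:
            dx = s[0] - self.means[:, 0]
            dy = s[1] - self.means[:, 1]
            ic = self._invcov
            quad = ic[:, 0, 0] * dx * dx + 2.0 * ic[:, 0, 1] * dx * dy + ic[:, 1, 1] * dy * dy
        else:
            diff = s[None, :] - self.means
            quad = np.einsum("ni,nij,nj->n", diff, self._invcov, diff)
        return -0.5 * (quad + self._logdet + self.dim * _LOG2PI)

    def logpdf_points(self, pts, entries=None):
        """Log-density of entries at many points -> (n_entries, n_points)."""
        pts = np.asarray(pts, dtype=float)
        if entries is None:
            means, invcov, logdet = self.means, self._invcov, self._logdet
        else:
            means, invcov, logdet = (
                self.means[entries],
                self._invcov[entries],
                self._logdet[entries],
            )
        if self.dim == 2:
            dx = pts[None, :, 0] - means[:, None, 0]
            dy = pts[None, :, 1] - means[:, None, 1]
            quad = (
                invcov[:, None, 0, 0] * dx * dx
                + 2.0 * invcov[:, None, 0, 1] * dx * dy
                + invcov[:, None, 1, 1] * dy * dy
            )
        else:
            diff = pts[None, :, :] - means[:, None, :]
            quad = np.einsum("npi,nij,npj->np", diff, invcov, diff)
        return -0.5 * (quad + logdet[:, None] + self.dim * _LOG2PI)

    # -- serialization -------------------------------------------------------

    def to_dict(self):
        return {
            "n": self.n,
            "dim": self.dim,
            "variance_floor": self.variance_floor,
            "counts": self.counts.tolist(),
            "means": self.means.tolist(),
            "m2": self.m2.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        bank = cls.__new__(cls)
        bank.n = int(d["n"])
        bank.dim = int(d["dim"])
        bank.variance_floor = float(d["variance_floor"])
        bank.counts = np.asarray(d["counts"], dtype=float)
        bank.means = np.asarray(d["means"], dtype=float)
        bank.m2 = np.asarray(d["m2"], dtype=float)
        bank._refresh_cache()
        return bank

    def equals(self, other):
        return (
            self.n == other.n
            and self.dim == other.dim
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.m2, other.m2)
        )


@dataclass
class GaussianStats:
    """A single incrementally updated Gaussian (count, mean, scatter).

    ``count`` includes the prior pseudo-count; with ``count = 0`` the first
    observation becomes the mean exactly.  Covariance is the pooled scatter
    divided by the count, plus ``variance_floor`` on the diagonal.
    """

    dim: int
    count: float = 0.0
    mean: np.ndarray = None
    m2: np.ndarray = None
    variance_floor: float = 1e-4

    def __post_init__(self):
        if self.mean is None:
            self.mean = np.zeros(self.dim)
        if self.m2 is None:
            self.m2 = np.zeros((self.dim, self.dim))
        self.mean = np.asarray(self.mean, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)

    @classmethod
    def with_prior(cls, mean, cov, pseudo_count=1.0, variance_floor=1e-4):
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        return cls(
            dim=mean.size,
            count=float(pseudo_count),
            mean=mean.copy(),
            m2=cov * pseudo_count,
            variance_floor=variance_floor,
        )

    @property
    def covariance(self):
        if self.count <= 0:
            return self.variance_floor * np.eye(self.dim)
        return self.m2 / self.count + self.variance_floor * np.eye(self.dim)


def gaussian_update(stats, x):
    """Online mean/covariance update, equivalent to the batch estimate.

    After any sequence of updates the mean equals the (pseudo-count-weighted)
    sample mean of all observations pooled with the prior pseudo-observation,
    and the covariance equals the pooled sample scatter over the total count,
    ridge-floored on the diagonal.  Returns ``stats`` mutated in place.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (stats.dim,):
        raise ValueError(f"observation dimension {x.shape} does not match ({stats.dim},)")
    stats.count += 1.0
    delta = x - stats.mean
    stats.mean = stats.mean + delta / stats.count
    delta2 = x - stats.mean
    stats.m2 = stats.m2 + np.outer(delta, delta2)
    return stats


# ---------------------------------------------------------------------------
# Master agent
# ---------------------------------------------------------------------------


@dataclass
class MasterAgent:
    """Fixed generative model of the learning environment.

    One motor Gaussian per vowel (mean = best-fitting motor grid cell,
    covariance ``motor_variance * I``), a forward map shared with the
    learners, environmental noise variance ``sigma_env`` (Bark^2), and a
    calibrated sensory Gaussian per vowel used for categorizing sounds.
    """

    vowels: tuple
    motor_means: np.ndarray  # (7, 3)
    motor_variance: float
    sensory_means: np.ndarray  # (7, 2)
    sensory_covs: np.ndarray  # (7, 2, 2)
    forward: SurrogateForwardModel
    sigma_env: float
    motor_bounds: tuple

    def __post_init__(self):
        self._sens_invcov = np.linalg.inv(self.sensory_covs)
        self._sens_logdet = np.linalg.slogdet(self.sensory_covs)[1]
        self._lo = np.array([b[0] for b in self.motor_bounds])
        self._hi = np.array([b[1] for b in self.motor_bounds])
        self._motor_sd = np.sqrt(self.motor_variance)
        self._env_sd = np.sqrt(self.sigma_env)

    @property
    def n_vowels(self):
        return len(self.vowels)

    def produce(self, o, rng):
        """Draw a gesture for vowel index ``o`` and emit the noisy sound.

        The gesture is drawn from the vowel's motor Gaussian and clipped to
        the motor bounds; the sound is the forward image plus environmental
        noise in Barks.  Returns ``(m, s)``.
        """
        m = self.motor_means[o] + self._motor_sd * rng.standard_normal(3)
        np.clip(m, self._lo, self._hi, out=m)
        s = self.forward.point_bark(m) + self._env_sd * rng.standard_normal(2)
        return m, s

    def sensory_log_densities(self, s):
        """Log-densities of the calibrated sensory Gaussians -> (n_points, 7)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        dx = s[:, 0, None] - self.sensory_means[None, :, 0]
        dy = s[:, 1, None] - self.sensory_means[None, :, 1]
        ic = self._sens_invcov
        quad = (
            ic[None, :, 0, 0] * dx * dx
            + 2.0 * ic[None, :, 0, 1] * dx * dy
            + ic[None, :, 1, 1] * dy * dy
        )
        return -0.5 * (quad + self._sens_logdet[None, :] + 2 * _LOG2PI)

    def categorize(self, s):
        """Most probable vowel index for sound(s) ``s`` (uniform prior).

        Ties break to the lowest vowel index (argmax convention).
        """
        s = np.asarray(s, dtype=float)
        if s.ndim == 1:
            # scalar fast path used inside the communicative learning loop
            dx = s[0] - self.sensory_means[:, 0]
            dy = s[1] - self.sensory_means[:, 1]
            ic = self._sens_invcov
            quad = (
                ic[:, 0, 0] * dx * dx + 2.0 * ic[:, 0, 1] * dx * dy + ic[:, 1, 1] * dy * dy
            )
            return int(np.argmin(quad + self._sens_logdet))
        return np.argmax(self.sensory_log_densities(s), axis=1)

    def to_dict(self):
        return {
            "vowels": list(self.vowels),
            "motor_means": self.motor_means.tolist(),
            "motor_variance": self.motor_variance,
            "sensory_means": self.sensory_means.tolist(),
            "sensory_covs": self.sensory_covs.tolist(),
            "forward": self.forward.to_dict(),
            "sigma_env": self.sigma_env,
            "motor_bounds": [list(b) for b in self.motor_bounds],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            vowels=tuple(d["vowels"]),
            motor_means=np.asarray(d["motor_means"], dtype=float),
            motor_variance=float(d["motor_variance"]),
            sensory_means=np.asarray(d["sensory_means"], dtype=float),
            sensory_covs=np.asarray(d["sensory_covs"], dtype=float),
            forward=SurrogateForwardModel.from_dict(d["forward"]),
            sigma_env=float(d["sigma_env"]),
            motor_bounds=tuple(tuple(b) for b in d["motor_bounds"]),
        )


def fit_master(
    motor_grid,
    forward,
    targets_hz=None,
    vowels=VOWELS,
    motor_variance=0.1,
    sigma_env=0.01,
    calibration_draws=20_000,
    calibration_seed=7919,
    target_tolerance_bark=0.75,
):
    """Fit the master agent to acoustic vowel targets.

    Per vowel, the motor prototype is the motor grid cell whose forward image
    is closest (Euclidean, Barks) to the Bark-converted target.  The sensory
    Gaussian per vowel is then calibrated by pushing ``calibration_draws``
    clipped samples of the motor Gaussian through the forward map and adding
    environmental noise, with a fixed calibration seed so every experiment
    shares one identical master.

    Raises a configuration error if a target lies further than
    ``target_tolerance_bark`` from the reachable image, and warns if any two
    calibrated vowel centers are closer than three pooled standard deviations
    (the intended non-overlap of the master's vowel distributions).
    """
    if targets_hz is None:
        targets_hz = DEFAULT_TARGETS_HZ
    image = forward(motor_grid.coords)
    motor_means = np.empty((len(vowels), 3))
    for vi, v in enumerate(vowels):
        t = hz_to_bark(np.asarray(targets_hz[v], dtype=float))
        d = np.linalg.norm(image - t[None, :], axis=1)
        k = int(np.argmin(d))
        if d[k] > target_tolerance_bark:
            raise ValueError(
                f"target for /{v}/ is {d[k]:.2f} Bark from the forward image "
                f"(tolerance {target_tolerance_bark})"
            )
        motor_means[vi] = motor_grid.coords[k]

    rng = np.random.default_rng(calibration_seed)
    lo = np.array([b[0] for b in forward.bounds])
    hi = np.array([b[1] for b in forward.bounds])
    sensory_means = np.empty((len(vowels), 2))
    sensory_covs = np.empty((len(vowels), 2, 2))
    for vi in range(len(vowels)):
        draws = motor_means[vi] + np.sqrt(motor_variance) * rng.standard_normal(
            (calibration_draws, 3)
        )
        draws = np.clip(draws, lo, hi)
        sounds = forward(draws) + np.sqrt(sigma_env) * rng.standard_normal((calibration_draws, 2))
        sensory_means[vi] = sounds.mean(axis=0)
        sensory_covs[vi] = np.cov(sounds, rowvar=False)

    for a in range(len(vowels)):
        for b in range(a + 1, len(vowels)):
            gap = np.linalg.norm(sensory_means[a] - sensory_means[b])
            pooled_sd = np.sqrt(
                0.5 * (np.trace(sensory_covs[a]) + np.trace(sensory_covs[b])) / 2.0
            )
            if gap < 3.0 * pooled_sd:
                warnings.warn(
                    f"master vowels /{vowels[a]}/ and /{vowels[b]}/ are "
                    f"{gap:.2f} Bark apart (< 3 pooled sd = {3 * pooled_sd:.2f}); "
                    "their sound distributions overlap",
                    stacklevel=2,
                )

    return MasterAgent(
        vowels=tuple(vowels),
        motor_means=motor_means,
        motor_variance=float(motor_variance),
        sensory_means=sensory_means,
        sensory_covs=sensory_covs,
        forward=forward,
        sigma_env=float(sigma_env),
        motor_bounds=forward.bounds,
    )


# ---------------------------------------------------------------------------
# Learner agent
# ---------------------------------------------------------------------------


@dataclass
class LearnerAgent:
    """The three learned systems of one learning agent.

    * ``sensory``: per-vowel Gaussian over sounds — the sensory repertoire
      P(S | O_L), learned supervised from the master.
    * ``sensorimotor``: per-motor-cell Gaussian over sounds — the internal
      forward model P(S | M), learned by accommodation.
    * ``motor``: per-vowel Gaussian over gestures — the motor repertoire
      P(M | O_S), learned imitatively or communicatively.

    The object prior P(O_S) = P(O_L) is uniform over the seven vowels.
    """

    vowels: tuple
    motor_grid: MotorGrid
    sensory_grid: SensoryGrid
    sensory: GaussianBank
    sensorimotor: GaussianBank
    motor: GaussianBank
    grid_image: np.ndarray = None  # forward image of motor cells, (n_cells, 2)

    @property
    def n_vowels(self):
        return len(self.vowels)

    def attach_forward(self, forward):
        """Cache the forward image of the motor grid (used during learning)."""
        self.grid_image = forward(self.motor_grid.coords)
        return self

    def to_dict(self):
        return {
            "vowels": list(self.vowels),
            "motor_grid": {
                "levels_per_dim": self.motor_grid.levels_per_dim,
                "bounds": [list(b) for b in self.motor_grid.bounds],
            },
            "sensory_grid": {
                "levels_f1": self.sensory_grid.levels_f1,
                "levels_f2": self.sensory_grid.levels_f2,
                "f1_axis": self.sensory_grid.f1_axis.tolist(),
                "f2_axis": self.sensory_grid.f2_axis.tolist(),
            },
            "sensory": self.sensory.to_dict(),
            "sensorimotor": self.sensorimotor.to_dict(),
            "motor": self.motor.to_dict(),
        }

    def to_json(self):
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d):
        mg = build_motor_grid(
            d["motor_grid"]["levels_per_dim"],
            tuple(tuple(b) for b in d["motor_grid"]["bounds"]),
        )
        f1_axis = np.asarray(d["sensory_grid"]["f1_axis"], dtype=float)
        f2_axis = np.asarray(d["sensory_grid"]["f2_axis"], dtype=float)
        g1, g2 = np.meshgrid(f1_axis, f2_axis, indexing="ij")
        sg = SensoryGrid(
            levels_f1=int(d["sensory_grid"]["levels_f1"]),
            levels_f2=int(d["sensory_grid"]["levels_f2"]),
            f1_axis=f1_axis,
            f2_axis=f2_axis,
            points=np.stack([g1.ravel(), g2.ravel()], axis=-1),
        )
        return cls(
            vowels=tuple(d["vowels"]),
            motor_grid=mg,
            sensory_grid=sg,
            sensory=GaussianBank.from_dict(d["sensory"]),
            sensorimotor=GaussianBank.from_dict(d["sensorimotor"]),
            motor=GaussianBank.from_dict(d["motor"]),
        )

    @classmethod
    def from_json(cls, text):
        return cls.from_dict(json.loads(text))

    def equals(self, other):
        return (
            self.vowels == other.vowels
            and self.sensory.equals(other.sensory)
            and self.sensorimotor.equals(other.sensorimotor)
            and self.motor.equals(other.motor)
        )


def init_learner(
    motor_grid,
    sensory_grid,
    vowels=VOWELS,
    pseudo_count=1.0,
    sm_pseudo_count=0.02,
    variance_floor=1e-4,
):
    """Initialize a learner with broad, weakly informative priors.

    Sensory and sensorimotor priors are centered on the sensory grid with
    covariance ``diag(half_extent^2)``; the motor prior is centered on the
    motor box with covariance ``diag(half_extent^2)``.  Because all entries
    of a system share the same prior, inference before any learning is
    exactly uniform (exploratory), whatever the prior weight.

    The per-motor-cell internal model uses a much smaller pseudo-count than
    the per-vowel repertoires: a motor cell receives only tens of visits
    (steps / n_cells), and a unit-weight whole-space prior would keep its
    sound distribution blurred at the Bark scale for the entire run, which
    destroys the acoustic precision of imitation.  With a light prior the
    cell's covariance collapses to the observation scale within a few
    visits while unvisited cells keep the full-width prior.
    """
    s_center = sensory_grid.center
    s_cov = np.diag(sensory_grid.half_extent**2)
    m_lo = np.array([b[0] for b in motor_grid.bounds])
    m_hi = np.array([b[1] for b in motor_grid.bounds])
    m_center = (m_lo + m_hi) / 2.0
    m_cov = np.diag(((m_hi - m_lo) / 2.0) ** 2)
    return LearnerAgent(
        vowels=tuple(vowels),
        motor_grid=motor_grid,
        sensory_grid=sensory_grid,
        sensory=GaussianBank(
            len(vowels), 2, s_center, s_cov, pseudo_count=pseudo_count, variance_floor=variance_floor
        ),
        sensorimotor=GaussianBank(
            motor_grid.n_cells,
            2,
            s_center,
            s_cov,
            pseudo_count=sm_pseudo_count,
            variance_floor=variance_floor,
        ),
        motor=GaussianBank(
            len(vowels), 3, m_center, m_cov, pseudo_count=pseudo_count, variance_floor=variance_floor
        ),
    )


def _bank_from_gaussians(means, covs, variance_floor, count=1e6):
    """A GaussianBank whose entries equal given Gaussians exactly.

    The stored scatter is chosen so that ``m2 / count + floor * I`` equals the
    requested covariance, with a large count so further updates barely move it.
    """
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    n, dim = means.shape
    bank = GaussianBank(n, dim, means, covs, pseudo_count=count, variance_floor=variance_floor)
    bank.m2 = (covs - variance_floor * np.eye(dim)[None, :, :]) * count
    bank._refresh_cache()
    return bank


def make_perfect_learner(master, motor_grid, sensory_grid, variance_floor=1e-4):
    """A learner whose three systems are set analytically to the master's truth.

    This is the ideal-learning construction: the sensory repertoire equals the
    master's calibrated sensory Gaussians, the internal model of every motor
    cell equals the true forward image with the environmental noise variance,
    and the motor repertoire equals the master's motor Gaussians.  Under these
    conditions the auditory and motor decoders carry the same information and
    should be near-indistinguishable.
    """
    agent = LearnerAgent(
        vowels=master.vowels,
        motor_grid=motor_grid,
        sensory_grid=sensory_grid,
        sensory=_bank_from_gaussians(
            master.sensory_means, master.sensory_covs, variance_floor
        ),
        sensorimotor=_bank_from_gaussians(
            master.forward(motor_grid.coords),
            np.broadcast_to(
                master.sigma_env * np.eye(2), (motor_grid.n_cells, 2, 2)
            ),
            variance_floor,
        ),
        motor=_bank_from_gaussians(
            master.motor_means,
            np.broadcast_to(master.motor_variance * np.eye(3), (len(master.vowels), 3, 3)),
            variance_floor,
        ),
    )
    return agent.attach_forward(master.forward)


def make_ideal_master(
    linear_forward, motor_prototypes, motor_variance=0.02, sigma_env=0.01, vowels=VOWELS
):
    """A master whose per-vowel sound distributions are exactly Gaussian.

    Only valid for an affine forward map: the sensory Gaussians are computed
    in closed form (mean ``J mu + b``, covariance ``J Sigma J^T + sigma_env I``)
    instead of by sampling.  Paired with :func:`make_perfect_learner` this
    realizes the ideal-learning conditions in which the auditory and motor
    decoders carry identical information.
    """
    protos = np.asarray(motor_prototypes, dtype=float)
    J = linear_forward.J
    sens_means = protos @ J.T + linear_forward.b
    cov = J @ (motor_variance * np.eye(3)) @ J.T + sigma_env * np.eye(2)
    return MasterAgent(
        vowels=tuple(vowels),
        motor_means=protos,
        motor_variance=float(motor_variance),
        sensory_means=sens_means,
        sensory_covs=np.broadcast_to(cov, (len(vowels), 2, 2)).copy(),
        forward=linear_forward,
        sigma_env=float(sigma_env),
        motor_bounds=linear_forward.bounds,
    )


IDEAL_MOTOR_PROTOTYPES = np.array(
    [
        [0.5, -0.5, 0.5],
        [-0.5, 0.6, 0.5],
        [-0.2, -0.5, 0.3],
        [-0.5, 0.3, 0.4],
        [-0.6, -0.5, 0.1],
        [-0.5, 0.3, -0.1],
        [-0.5, -0.2, -0.5],
    ]
)
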