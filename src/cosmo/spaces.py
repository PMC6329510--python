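"""Discretized motor and sensory spaces and the articulatory-to-acoustic forward map.

The motor space is a 3-D box of normalized articulatory parameters
(lip height, tongue body, tongue dorsum), discretized on a regular grid.
The sensory space is the (F1, F2) formant plane expressed in Barks,
discretized on a regular rectangle that covers the image of the forward
map with a safety margin.

The forward map ``s = f(m)`` stands in for a full articulatory synthesizer:
it is a smooth, deterministic, many-to-one function from the 3-D motor box
to the formant plane, built from two logistic response surfaces whose output
ranges delimit a vocalic-triangle-like region (F1 roughly 250-700 Hz, F2
roughly 700-2500 Hz).  Any callable with the same contract (deterministic,
image strictly inside the sensory rectangle) can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "hz_to_bark",
    "bark_to_hz",
    "SurrogateForwardModel",
    "LinearForwardModel",
    "MotorGrid",
    "SensoryGrid",
    "build_motor_grid",
    "build_sensory_grid",
]


def hz_to_bark(frequency):
    """Convert frequency in Hz to the Bark auditory scale.

    Uses the asinh form ``F[Bark] = 7 * asinh(F[Hz] / 650)``, which is
    strictly increasing and maps 0 Hz to 0 Bark.

    Parameters
    ----------
    frequency : float or array-like
        Frequency in Hz, must be >= 0.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 7.0 * np.arcsinh(f / 650.0)
    return out if out.ndim else float(out)


def bark_to_hz(b):
    """Inverse of :func:`hz_to_bark`: ``F[Hz] = 650 * sinh(F[Bark] / 7)``."""
    z = np.asarray(b, dtype=float)
    if np.any(z < 0):
        raise ValueError("bark value must be non-negative")
    out = 650.0 * np.sinh(z / 7.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SurrogateForwardModel:
    """Default smooth many-to-one map from motor configurations to (F1, F2) Barks.

    With ``sigma`` the logistic function and ``x = (lip_height, tongue_body,
    tongue_dorsum)``::

        F1_Hz = f1_base + f1_scale * sigma(f1_weights . x)
        F2_Hz = f2_base + f2_scale * sigma(f2_weights . x)

    and the returned sound point is ``(hz_to_bark(F1_Hz), hz_to_bark(F2_Hz))``.
    Because two output coordinates are driven by three inputs, every sound in
    the image has a one-dimensional family of articulatory preimages: the map
    is many-to-one by construction.  The sign conventions of the default
    weights are arbitrary and only fix which corner of the motor box maps to
    which corner of the vowel space.
    """

    f1_base: float = 250.0
    f1_scale: float = 450.0
    f1_weights: tuple = (-1.2, 0.0, -1.8)
    f2_base: float = 700.0
    f2_scale: float = 1800.0
    f2_weights: tuple = (0.8, -1.6, 0.4)
    bounds: tuple = ((-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0))
    name: str = "surrogate"

    def formants_hz(self, m):
        m = np.asarray(m, dtype=float)
        squeeze = m.ndim == 1
        m2 = np.atleast_2d(m)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        if np.any(m2 < lo - 1e-9) or np.any(m2 > hi + 1e-9):
            raise ValueError("motor configuration outside the motor bounds")
        w1 = np.asarray(self.f1_weights)
        w2 = np.asarray(self.f2_weights)
        u1 = m2 @ w1
        u2 = m2 @ w2
        f1 = self.f1_base + self.f1_scale / (1.0 + np.exp(-u1))
        f2 = self.f2_base + self.f2_scale / (1.0 + np.exp(-u2))
        out = np.stack([f1, f2], axis=-1)
        return out[0] if squeeze else out

    def __call__(self, m):
        """Map motor configuration(s) to sound point(s) in Barks."""
        return hz_to_bark(self.formants_hz(m))

    def point_bark(self, m):
        """Fast single-point evaluation (no bounds check) for inner loops."""
        u1 = m[0] * self.f1_weights[0] + m[1] * self.f1_weights[1] + m[2] * self.f1_weights[2]
        u2 = m[0] * self.f2_weights[0] + m[1] * self.f2_weights[1] + m[2] * self.f2_weights[2]
        f1 = self.f1_base + self.f1_scale / (1.0 + np.exp(-u1))
        f2 = self.f2_base + self.f2_scale / (1.0 + np.exp(-u2))
        return np.array([7.0 * np.arcsinh(f1 / 650.0), 7.0 * np.arcsinh(f2 / 650.0)])

    def to_dict(self):
        return {
            "name": self.name,
            "f1_base": self.f1_base,
            "f1_scale": self.f1_scale,
            "f1_weights": list(self.f1_weights),
            "f2_base": self.f2_base,
            "f2_scale": self.f2_scale,
            "f2_weights": list(self.f2_weights),
            "bounds": [list(b) for b in self.bounds],
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d.pop("name", None)
        return cls(
            f1_base=d["f1_base"],
            f1_scale=d["f1_scale"],
            f1_weights=tuple(d["f1_weights"]),
            f2_base=d["f2_base"],
            f2_scale=d["f2_scale"],
            f2_weights=tuple(d["f2_weights"]),
            bounds=tuple(tuple(b) for b in d["bounds"]),
        )


@dataclass(frozen=True)
class MotorGrid:
    """Regular discretization of the 3-D motor box.

    Cells are enumerated row-major with the last coordinate (tongue dorsum)
    varying fastest, so linear indices are reproducible across runs.
    """

    levels_per_dim: int
    bounds: tuple
    coords: np.ndarray = field(repr=False)  # (n_cells, 3)

    @property
    def n_cells(self):
        return self.coords.shape[0]

    def index_to_coords(self, idx):
        return self.coords[idx]

    def coords_to_index(self, m):
        """Exact inverse of :meth:`index_to_coords` for grid cells."""
        axes = self.axes()
        sub = []
        m = np.atleast_2d(np.asarray(m, dtype=float))
        for d in range(3):
            sub.append(np.argmin(np.abs(axes[d][:, None] - m[:, d][None, :]), axis=0))
        flat = np.ravel_multi_index(tuple(sub), (self.levels_per_dim,) * 3)
        return int(flat[0]) if flat.size == 1 else flat

    def axes(self):
        return [_axis(self.levels_per_dim, lo, hi) for lo, hi in self.bounds]


def _axis(levels, lo, hi):
    if levels == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, levels)


def build_motor_grid(levels_per_dim=25, bounds=((-1.0, 1.0),) * 3):
    """Build the motor grid: ``levels_per_dim**3`` evenly spaced cells.

    Endpoints are included for ``levels_per_dim >= 2``; a single-level grid
    collapses to the box midpoint.
    """
    if levels_per_dim < 1:
        raise ValueError("levels_per_dim must be >= 1")
    bounds = tuple(tuple(b) for b in bounds)
    axes = [_axis(levels_per_dim, lo, hi) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in mesh], axis=-1)
    return MotorGrid(levels_per_dim=levels_per_dim, bounds=bounds, coords=coords)


@dataclass(frozen=True)
class SensoryGrid:
    """Regular discretization of the (F1, F2) Bark rectangle.

    Cells are enumerated row-major with F2 varying fastest.  ``cell_area`` is
    the Bark-plane area element used when grid sums approximate integrals.
    """

    levels_f1: int
    levels_f2: int
    f1_axis: np.ndarray = field(repr=False)
    f2_axis: np.ndarray = field(repr=False)
    points: np.ndarray = field(repr=False)  # (n_cells, 2)

    @property
    def n_cells(self):
        return self.points.shape[0]

    @property
    def bounds(self):
        return ((self.f1_axis[0], self.f1_axis[-1]), (self.f2_axis[0], self.f2_axis[-1]))

    @property
    def cell_area(self):
        df1 = self.f1_axis[1] - self.f1_axis[0] if self.levels_f1 > 1 else 1.0
        df2 = self.f2_axis[1] - self.f2_axis[0] if self.levels_f2 > 1 else 1.0
        return float(df1 * df2)

    @property
    def center(self):
        return np.array([self.f1_axis.mean(), self.f2_axis.mean()])

    @property
    def half_extent(self):
        return np.array(
            [
                (self.f1_axis[-1] - self.f1_axis[0]) / 2.0,
                (self.f2_axis[-1] - self.f2_axis[0]) / 2.0,
            ]
        )

    def contains(self, s):
        s = np.atleast_2d(np.asarray(s, dtype=float))
        (lo1, hi1), (lo2, hi2) = self.bounds
        ok = (s[:, 0] >= lo1) & (s[:, 0] <= hi1) & (s[:, 1] >= lo2) & (s[:, 1] <= hi2)
        return bool(ok[0]) if ok.size == 1 else ok


def build_sensory_grid(forward, motor_grid, levels_f1=59, levels_f2=73, margin_bark=0.5):
    """Build the sensory grid over the forward image's bounding box plus a margin.

    The rectangle is the bounding box of ``forward`` evaluated on all motor
    grid cells, expanded by ``margin_bark`` per side; the margin absorbs
    environmental noise so that every emitted sound stays on the grid.
    """
    if levels_f1 < 2 or levels_f2 < 2:
        raise ValueError("sensory grid needs at least 2 levels per dimension")
    image = forward(motor_grid.coords)
    lo = image.min(axis=0) - margin_bark
    hi = image.max(axis=0) + margin_bark
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate forward image: zero extent in a formant dimension")
    f1_axis = np.linspace(lo[0], hi[0], levels_f1)
    f2_axis = np.linspace(lo[1], hi[1], levels_f2)
    g1, g2 = np.meshgrid(f1_axis, f2_axis, indexing="ij")
    points = np.stack([g1.ravel(), g2.ravel()], axis=-1)
    return SensoryGrid(
        levels_f1=levels_f1,
        levels_f2=levels_f2,
        f1_axis=f1_axis,
        f2_axis=f2_axis,
        points=points,
    )


@dataclass(frozen=True)
class LinearForwardModel:
    """Affine articulatory-to-acoustic map, an alternative forward variant.

    ``s = J m + b`` with a 2x3 Jacobian.  Linearity makes every Gaussian
    gesture distribution push forward to an exactly Gaussian sound
    distribution, so the per-vowel Gaussian sensory repertoire is a
    well-specified model of the environment.  This is the regime in which
    auditory and motor decoding are provably equivalent under ideal
    learning; the logistic surrogate leaves that regime on purpose.
    """

    jacobian: tuple = ((0.8, 0.1, 1.0), (-0.5, 1.5, -0.3))
    offset: tuple = (4.5, 11.0)
    bounds: tuple = ((-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0))
    name: str = "linear"

    @property
    def J(self):
        return np.asarray(self.jacobian, dtype=float)

    @property
    def b(self):
        return np.asarray(self.offset, dtype=float)

    def __call__(self, m):
        m = np.asarray(m, dtype=float)
        lo = np.array([x[0] for x in self.bounds])
        hi = np.array([x[1] for x in self.bounds])
        if np.any(m < lo - 1e-9) or np.any(m > hi + 1e-9):
            raise ValueError("motor configuration outside the motor bounds")
        return m @ self.J.T + self.b

    def point_bark(self, m):
        return self.J @ np.asarray(m, dtype=float) + self.b
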