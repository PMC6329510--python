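"""Auditory, motor, and perceptuo-motor decoders over the sensory grid.

Given a sound s, each decoder returns a posterior over the seven vowels
(uniform vowel prior throughout):

* auditory — Bayes inversion of the learned sensory repertoire:
  P(o | s) ∝ P(s | O_L = o).
* motor — acoustic-to-articulatory inversion through the internal model and
  the motor repertoire: P(o | s) ∝ Σ_M P(M | o) P(s | M), with P(M | o)
  discretized as a categorical over motor grid cells.
* perceptuo-motor — fusion: the entrywise product of the two unnormalized
  scores, renormalized, i.e. conditioning on communication success.

All sums are accumulated in log space with max subtraction; a total
underflow yields a uniform posterior.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "auditory_posterior",
    "motor_posterior",
    "pm_posterior",
    "categorize_grid",
    "categorize_grid_all",
    "categorization_table",
    "DECODERS",
]

DECODERS = ("auditory", "motor", "pm")


def _as_points(s):
    s = np.asarray(s, dtype=float)
    return (np.atleast_2d(s), s.ndim == 1)


def _auditory_log_scores(agent, pts):
    """Unnormalized log scores of the auditory decoder -> (n_points, 7)."""
    return agent.sensory.logpdf_points(pts).T


def _motor_cell_weights(agent):
    """P(cell | o): the motor-repertoire density on the grid as a categorical."""
    bank = agent.motor
    cells = agent.motor_grid.coords
    diff = cells[None, :, :] - bank.means[:, None, :]
    quad = np.einsum("vni,vij,vnj->vn", diff, bank._invcov, diff)
    log_pcell = -0.5 * (quad + bank._logdet[:, None])  # (7, n_cells), unnormalized
    log_pcell -= logsumexp(log_pcell, axis=1, keepdims=True)
    return np.exp(log_pcell)


def _motor_log_scores(agent, pts, chunk=2048):
    """Unnormalized log scores of the motor decoder -> (n_points, 7).

    score(o, s) = Σ_cells P(cell | o) p(s | cell), with P(cell | o) the
    motor-repertoire density evaluated on the grid and normalized to a
    categorical, and p(s | cell) the internal-model density.  The cell sum
    is a max-shifted matrix product: exact in log space, and a single BLAS
    call per block of sensory points.
    """
    W = _motor_cell_weights(agent)  # (7, n_cells)
    n = pts.shape[0]
    out = np.empty((n, agent.n_vowels))
    with np.errstate(divide="ignore"):
        for start in range(0, n, chunk):
            block = pts[start : start + chunk]
            logd = agent.sensorimotor.logpdf_points(block)  # (n_cells, block)
            shift = logd.max(axis=0, keepdims=True)
            scores = W @ np.exp(logd - shift)  # (7, block)
            out[start : start + chunk] = (np.log(scores) + shift).T
    return out


def _log_scores(agent, pts, kind):
    if kind == "auditory":
        return _auditory_log_scores(agent, pts)
    if kind == "motor":
        return _motor_log_scores(agent, pts)
    if kind == "pm":
        return _auditory_log_scores(agent, pts) + _motor_log_scores(agent, pts)
    raise ValueError(f"unknown decoder kind: {kind!r}")


def _normalize(log_scores):
    m = np.max(log_scores, axis=1, keepdims=True)
    safe = np.where(np.isfinite(m), m, 0.0)
    w = np.exp(log_scores - safe)
    total = w.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(m[:, 0]) | (total[:, 0] <= 0)
    post = np.where(bad[:, None], 1.0 / log_scores.shape[1], w / np.where(total > 0, total, 1.0))
    return post


def auditory_posterior(agent, s):
    """Auditory decoder posterior over vowels at sound(s) ``s``."""
    pts, single = _as_points(s)
    post = _normalize(_log_scores(agent, pts, "auditory"))
    return post[0] if single else post


def motor_posterior(agent, s):
    """Motor decoder posterior over vowels at sound(s) ``s``."""
    pts, single = _as_points(s)
    post = _normalize(_log_scores(agent, pts, "motor"))
    return post[0] if single else post


def pm_posterior(agent, s):
    """Perceptuo-motor fusion posterior: product of the two scores, renormalized."""
    pts, single = _as_points(s)
    post = _normalize(_log_scores(agent, pts, "pm"))
    return post[0] if single else post


def categorize_grid(agent, kind):
    """Winning vowel index per sensory grid cell for one decoder -> (n_sens,).

    Ties break to the lowest vowel index (argmax convention); the map is a
    deterministic function of the agent state.
    """
    log_scores = _log_scores(agent, agent.sensory_grid.points, kind)
    return np.argmax(log_scores, axis=1)


def categorize_grid_all(agent):
    """Label maps for all three decoders, sharing the heavy motor-score pass.

    Returns a dict kind -> (n_sens,) label array, identical to calling
    :func:`categorize_grid` per kind.
    """
    pts = agent.sensory_grid.points
    aud = _auditory_log_scores(agent, pts)
    mot = _motor_log_scores(agent, pts)
    return {
        "auditory": np.argmax(aud, axis=1),
        "motor": np.argmax(mot, axis=1),
        "pm": np.argmax(aud + mot, axis=1),
    }


def categorization_table(agent):
    """Categorization maps as a tidy table ready for CSV export.

    One row per sensory grid cell: cell index, f1_bark, f2_bark, and the
    winning vowel alias under each decoder.
    """
    import pandas as pd

    maps = categorize_grid_all(agent)
    pts = agent.sensory_grid.points
    data = {
        "cell": np.arange(agent.sensory_grid.n_cells),
        "f1_bark": pts[:, 0],
        "f2_bark": pts[:, 1],
    }
    for kind in DECODERS:
        data[f"label_{kind}"] = [agent.vowels[i] for i in maps[kind]]
    return pd.DataFrame(data)
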