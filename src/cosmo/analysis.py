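"""Prototype extraction and idiosyncrasy statistics.

Production prototypes are the exact grid expectation of the forward image
under the motor repertoire (the deterministic limit of sampling gestures and
averaging their sounds).  Perceptual prototypes are the unweighted mean of
the sensory grid cells a decoder labels with a vowel — the whole grid, not
just the vocalic triangle.

Relative F1 rescales each agent's F1 axis so the high-vowel mean (/i u/)
maps to 0 and /a/ maps to 100; the four mid vowels /e ε o ɔ/ are then
compared across agents, per channel, with ordinary least squares of
perception on production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from scipy.special import logsumexp

__all__ = [
    "MID_VOWELS",
    "production_prototype",
    "perceptual_prototype",
    "decoder_prototypes",
    "relative_f1",
    "regress_production_perception",
    "distance_table",
    "RegressionResult",
]

MID_VOWELS = ("e", "eps", "o", "oo")


def production_prototype(agent, o):
    """Mean sound of vowel ``o``'s production distribution, in Barks.

    Expectation of the forward image over motor grid cells weighted by the
    normalized motor-repertoire density: deterministic, no sampling.
    """
    bank = agent.motor
    diff = agent.motor_grid.coords - bank.means[o][None, :]
    quad = np.einsum("ni,ij,nj->n", diff, bank._invcov[o], diff)
    logw = -0.5 * quad
    m = logw.max()
    if not np.isfinite(m):
        raise ValueError(f"degenerate motor-repertoire weights for vowel index {o}")
    w = np.exp(logw - m)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(f"degenerate motor-repertoire weights for vowel index {o}")
    if agent.grid_image is None:
        raise ValueError("agent has no cached forward image; call attach_forward first")
    return (w / total) @ agent.grid_image


def perceptual_prototype(labels, sensory_grid, o):
    """Unweighted mean of the grid cells a decoder labels as vowel ``o``.

    Returns None if the vowel owns no cell (flagged missing; excluded from
    downstream regressions).
    """
    mask = np.asarray(labels) == o
    if not np.any(mask):
        return None
    return sensory_grid.points[mask].mean(axis=0)


def decoder_prototypes(agent):
    """Per-vowel mean sound of each decoder's predictive distribution.

    For vowel o the three decoders carry sound distributions whose means are
    the agent's perceptual prototypes:

    * auditory — the sensory-repertoire Gaussian P(S | O_L = o): its mean.
    * motor — the internal-model mixture P(S | O_S = o) =
      Σ_cells P(cell | o) P(S | cell): the weighted mean of the per-cell sound
      means.
    * perceptuo-motor — the renormalized product of the auditory density and
      the motor mixture, evaluated over the sensory grid: its grid mean.

    Because the motor mixture runs through the learned internal model, its
    mean tracks the agent's own production prototype; the auditory mean
    tracks the learning environment instead.  Returns a dict
    kind -> (n_vowels, 2) array in Barks.

    The motor mean is conditioned on explored gestures: cells never visited
    during accommodation still carry the uninformative prior (centered on the
    grid), and including them in a mean would drag every prototype toward the
    grid center by exactly the unexplored mass — an artifact of the prior's
    arbitrary location, not a prediction of the model.  Cells with at least
    one observation enter with their repertoire weights renormalized.
    """
    from .perception import _auditory_log_scores, _motor_cell_weights, _motor_log_scores

    W = _motor_cell_weights(agent)  # (7, n_cells)
    explored = agent.sensorimotor.counts > agent.sensorimotor.counts.min()
    if explored.any():
        Wv = W[:, explored]
        Wv = Wv / Wv.sum(axis=1, keepdims=True)
        motor_means = Wv @ agent.sensorimotor.means[explored]
    else:
        motor_means = W @ agent.sensorimotor.means
    out = {
        "auditory": agent.sensory.means.copy(),
        "motor": motor_means,
    }
    pts = agent.sensory_grid.points
    log_w = _auditory_log_scores(agent, pts) + _motor_log_scores(agent, pts)  # (n_pts, 7)
    log_w -= log_w.max(axis=0, keepdims=True)
    w = np.exp(log_w)
    w /= w.sum(axis=0, keepdims=True)
    out["pm"] = w.T @ pts
    return out


def relative_f1(prototypes):
    """Relative F1 of the four mid vowels on a 0-100 scale.

    ``prototypes`` maps vowel alias -> (f1, f2) in Barks for one agent and
    one channel.  m_high is the mean /i u/ F1, m_low the /a/ F1; each mid
    vowel's F1 is mapped through 100 * (F1 - m_high) / (m_low - m_high), so
    a vowel at the high-vowel mean scores 0 and one at /a/ scores 100.
    """
    m_high = 0.5 * (prototypes["i"][0] + prototypes["u"][0])
    m_low = prototypes["a"][0]
    if m_low == m_high:
        raise ValueError("degenerate relative-F1 normalization: m_low equals m_high")
    return {
        v: 100.0 * (prototypes[v][0] - m_high) / (m_low - m_high) for v in MID_VOWELS
    }


@dataclass
class RegressionResult:
    """OLS of perceived relative F1 (y) on produced relative F1 (x)."""

    vowel: str
    channel: str
    slope: float
    intercept: float
    pearson_r: float
    n_agents: int
    degenerate: bool = False


def regress_production_perception(production, perception, vowel, channel):
    """Least squares of perception on production across agents for one vowel.

    ``production`` and ``perception`` are equal-length arrays of relative F1
    values (one entry per agent).  Requires at least 3 complete pairs; a
    zero-variance predictor is flagged degenerate with undefined slope.
    """
    x = np.asarray(production, dtype=float)
    y = np.asarray(perception, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 complete production/perception pairs")
    if np.var(x) == 0.0:
        return RegressionResult(vowel, channel, np.nan, np.nan, np.nan, x.size, degenerate=True)
    fit = sp_stats.linregress(x, y)
    return RegressionResult(
        vowel=vowel,
        channel=channel,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_agents=int(x.size),
    )


def distance_table(production_prototypes, master, vowels):
    """Per-vowel mean Euclidean Bark distance from agents to the master.

    ``production_prototypes`` is an array (n_agents, n_vowels, 2); the master
    prototype per vowel is the calibrated pushforward mean of its motor
    Gaussian.  Returns (per_vowel_mean: dict, over_vowel_mean: float).
    """
    protos = np.asarray(production_prototypes, dtype=float)
    d = np.linalg.norm(protos - master.sensory_means[None, :, :], axis=2)
    per_vowel = {v: float(d[:, i].mean()) for i, v in enumerate(vowels)}
    return per_vowel, float(np.mean(list(per_vowel.values())))
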