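"""Experiment orchestration: one fixed master, n independent learners per variant.

A run builds the world (forward map, grids, calibrated master) once, trains
``n_agents`` learners per requested motor-learning variant with per-agent
seeds ``base_seed + i``, applies the three decoders to every trained agent,
and derives the prototype, relative-F1, regression, and distance tables.
All outputs are plain CSV/JSON with a fixed dialect ('.' decimal separator,
UTF-8, header row) so that identical configurations and seeds produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, perception
from .agents import DEFAULT_TARGETS_HZ, VOWELS, LearnerAgent, MasterAgent, fit_master, init_learner
from .learning import LearningSchedule, run_learning
from .spaces import SurrogateForwardModel, build_motor_grid, build_sensory_grid

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "make_default_config",
    "run_experiment",
    "analyze_checkpoints",
]

# regression channels: production plus the three decoders' distribution-mean
# prototypes; *_map channels record the categorization-region means as well
CHANNELS = ("production", "auditory", "motor", "pm")
MAP_CHANNELS = ("auditory_map", "motor_map", "pm_map")
_CSV_FLOAT = "%.10g"


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    scale: str = "desk"
    n_agents: int = 12
    base_seed: int = 0
    variants: tuple = ("imitative", "communicative")
    motor_levels: int = 15
    motor_bounds: tuple = ((-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0))
    sensory_levels: tuple = (59, 73)
    sensory_margin_bark: float = 0.5
    forward_variant: str = "surrogate"
    forward_coefficients: dict = field(default_factory=dict)
    vowels: tuple = VOWELS
    targets_hz: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS_HZ))
    master_motor_variance: float = 0.1
    sigma_env: float = 0.01
    calibration_draws: int = 20_000
    calibration_seed: int = 7919
    variance_floor: float = 1e-4
    prior_pseudo_count: float = 1.0
    sm_prior_pseudo_count: float = 0.02
    steps_sensory: int = 30_000
    steps_sensorimotor: int = 30_000
    steps_motor: int = 30_000
    out_dir: str = None

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        self.variants = tuple(self.variants)
        unknown = set(self.variants) - {"imitative", "communicative"}
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        d["vowels"] = list(self.vowels)
        d["motor_bounds"] = [list(b) for b in self.motor_bounds]
        d["sensory_levels"] = list(self.sensory_levels)
        d["targets_hz"] = {k: list(v) for k, v in self.targets_hz.items()}
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "motor_bounds" in d:
            d["motor_bounds"] = tuple(tuple(b) for b in d["motor_bounds"])
        if "sensory_levels" in d:
            d["sensory_levels"] = tuple(d["sensory_levels"])
        if "vowels" in d:
            d["vowels"] = tuple(d["vowels"])
        if "targets_hz" in d:
            d["targets_hz"] = {k: tuple(v) for k, v in d["targets_hz"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"invalid config keys: {bad}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def make_default_config(scale="desk"):
    """Default configuration for a named scale preset.

    * ``full`` — 300,000 steps per phase on a 25^3 motor grid (the reference
      study conditions).
    * ``desk`` — 30,000 steps per phase on a 15^3 motor grid: a tenfold
      reduction that runs on a single CPU in minutes while preserving the
      qualitative regime (well-visited motor cells, converged sensory
      repertoires).
    """
    if scale == "full":
        return ExperimentConfig(
            scale="full",
            motor_levels=25,
            steps_sensory=300_000,
            steps_sensorimotor=300_000,
            steps_motor=300_000,
        )
    if scale == "desk":
        return ExperimentConfig(scale="desk")
    raise ValueError(f"unknown scale preset: {scale!r}")


@dataclass
class ExperimentResult:
    """All tables of one experiment, plus the config snapshot and logs."""

    config: ExperimentConfig
    master: MasterAgent
    agents: dict  # variant -> list of LearnerAgent
    prototypes: pd.DataFrame  # variant, agent, vowel, channel, f1_bark, f2_bark
    relative_f1: pd.DataFrame  # variant, agent, vowel, channel, relative_f1
    regressions: pd.DataFrame  # variant, vowel, channel, slope, intercept, pearson_r, n_agents
    distances: pd.DataFrame  # variant, vowel, mean_distance_bark (incl. 'mean' row)
    logs: dict
    warnings: list

    def regression(self, variant, vowel, channel, column="slope"):
        """Convenience lookup of one regression statistic."""
        df = self.regressions
        row = df[(df.variant == variant) & (df.vowel == vowel) & (df.channel == channel)]
        return float(row[column].iloc[0])

    def distance(self, variant, vowel):
        df = self.distances
        row = df[(df.variant == variant) & (df.vowel == vowel)]
        return float(row["mean_distance_bark"].iloc[0])


def _world(config):
    fwd_kwargs = dict(config.forward_coefficients)
    fwd_kwargs["bounds"] = config.motor_bounds
    forward = SurrogateForwardModel(**fwd_kwargs)
    motor_grid = build_motor_grid(config.motor_levels, config.motor_bounds)
    sensory_grid = build_sensory_grid(
        forward,
        motor_grid,
        levels_f1=config.sensory_levels[0],
        levels_f2=config.sensory_levels[1],
        margin_bark=config.sensory_margin_bark,
    )
    master = fit_master(
        motor_grid,
        forward,
        targets_hz=config.targets_hz,
        vowels=config.vowels,
        motor_variance=config.master_motor_variance,
        sigma_env=config.sigma_env,
        calibration_draws=config.calibration_draws,
        calibration_seed=config.calibration_seed,
    )
    return forward, motor_grid, sensory_grid, master


def _agent_prototypes(agent, vowels):
    """Prototypes per channel for one trained agent -> (dict, missing list).

    Decoder channels are the distribution-mean prototypes; the ``*_map``
    channels additionally record the categorization-region means, which may
    be missing when a vowel owns no grid cell.
    """
    protos = {
        "production": {v: analysis.production_prototype(agent, i) for i, v in enumerate(vowels)}
    }
    dec = analysis.decoder_prototypes(agent)
    for kind in perception.DECODERS:
        protos[kind] = {v: dec[kind][i] for i, v in enumerate(vowels)}
    missing = []
    label_maps = perception.categorize_grid_all(agent)
    for kind in perception.DECODERS:
        labels = label_maps[kind]
        chan = {}
        for i, v in enumerate(vowels):
            p = analysis.perceptual_prototype(labels, agent.sensory_grid, i)
            if p is None:
                missing.append((kind, v))
            else:
                chan[v] = p
        protos[f"{kind}_map"] = chan
    return protos, missing


def _derive_tables(config, master, agents, warns):
    """Build the four result tables from trained agents (no learning)."""
    vowels = config.vowels
    proto_rows, rel_rows, reg_rows, dist_rows = [], [], [], []

    for variant in config.variants:
        per_agent_protos = []
        prod_proto_array = np.empty((len(agents[variant]), len(vowels), 2))
        for i, agent in enumerate(agents[variant]):
            protos, missing = _agent_prototypes(agent, vowels)
            for kind, v in missing:
                warns.append(f"{variant} agent {i}: vowel /{v}/ owns no cell in {kind} map")
            per_agent_protos.append(protos)
            for vi, v in enumerate(vowels):
                prod_proto_array[i, vi] = protos["production"][v]
            for chan in CHANNELS + MAP_CHANNELS:
                for v in vowels:
                    if v in protos[chan]:
                        f1, f2 = protos[chan][v]
                        proto_rows.append(
                            dict(variant=variant, agent=i, vowel=v, channel=chan,
                                 f1_bark=f1, f2_bark=f2)
                        )

        needed = ("i", "u", "a") + analysis.MID_VOWELS
        rel = {chan: {v: {} for v in analysis.MID_VOWELS} for chan in CHANNELS}
        for i, protos in enumerate(per_agent_protos):
            for chan in CHANNELS:
                if not all(v in protos[chan] for v in needed):
                    warns.append(f"{variant} agent {i}: incomplete {chan} prototypes")
                    continue
                for v, val in analysis.relative_f1(protos[chan]).items():
                    rel[chan][v][i] = val
                    rel_rows.append(
                        dict(variant=variant, agent=i, vowel=v, channel=chan, relative_f1=val)
                    )

        for chan in ("auditory", "motor", "pm"):
            for v in analysis.MID_VOWELS:
                shared = sorted(set(rel["production"][v]) & set(rel[chan][v]))
                if len(shared) < 3:
                    warns.append(
                        f"{variant}: fewer than 3 complete pairs for /{v}/ {chan}; "
                        "regression skipped"
                    )
                    continue
                res = analysis.regress_production_perception(
                    [rel["production"][v][a] for a in shared],
                    [rel[chan][v][a] for a in shared],
                    v,
                    chan,
                )
                reg_rows.append(
                    dict(variant=variant, vowel=v, channel=chan, slope=res.slope,
                         intercept=res.intercept, pearson_r=res.pearson_r,
                         n_agents=res.n_agents)
                )

        per_vowel, over = analysis.distance_table(prod_proto_array, master, vowels)
        for v in vowels:
            dist_rows.append(dict(variant=variant, vowel=v, mean_distance_bark=per_vowel[v]))
        dist_rows.append(dict(variant=variant, vowel="mean", mean_distance_bark=over))

    return (
        pd.DataFrame(proto_rows),
        pd.DataFrame(rel_rows),
        pd.DataFrame(reg_rows),
        pd.DataFrame(dist_rows),
    )


def run_experiment(config):
    """Run the complete experiment described by ``config``.

    Returns an :class:`ExperimentResult`; if ``config.out_dir`` is set, also
    writes config.yaml, master.json, per-agent checkpoints, the four CSV
    tables, and the execution log there.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    forward, motor_grid, sensory_grid, master = _world(config)
    agents, logs, warns = {}, {}, []

    for variant in config.variants:
        schedule = LearningSchedule(
            steps_sensory=config.steps_sensory,
            steps_sensorimotor=config.steps_sensorimotor,
            steps_motor=config.steps_motor,
            motor_variant=variant,
        )
        agents[variant] = []
        logs[variant] = []
        for i in range(config.n_agents):
            rng = np.random.default_rng(config.base_seed + i)
            agent = init_learner(
                motor_grid,
                sensory_grid,
                vowels=config.vowels,
                pseudo_count=config.prior_pseudo_count,
                sm_pseudo_count=config.sm_prior_pseudo_count,
                variance_floor=config.variance_floor,
            ).attach_forward(forward)
            run_learning(agent, master, schedule, rng, progress=logs[variant])
            agents[variant].append(agent)
        if out_dir is not None:
            for i, agent in enumerate(agents[variant]):
                (out_dir / f"agent_{variant}_{i:02d}.json").write_text(
                    agent.to_json(), encoding="utf-8"
                )

    if config.n_agents < 3:
        warns.append("fewer than 3 agents: production/perception regressions are skipped")

    protos, rel, reg, dist = _derive_tables(config, master, agents, warns)
    result = ExperimentResult(
        config=config, master=master, agents=agents, prototypes=protos,
        relative_f1=rel, regressions=reg, distances=dist, logs=logs, warnings=warns,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result, out_dir):
    out_dir = Path(out_dir)
    result.config.to_yaml(out_dir / "config.yaml")
    (out_dir / "master.json").write_text(
        json.dumps(result.master.to_dict(), sort_keys=True), encoding="utf-8"
    )
    for name in ("prototypes", "relative_f1", "regressions", "distances"):
        getattr(result, name).to_csv(out_dir / f"{name}.csv", index=False, float_format=_CSV_FLOAT)
    (out_dir / "log.json").write_text(
        json.dumps({"logs": result.logs, "warnings": result.warnings}, sort_keys=True),
        encoding="utf-8",
    )


def analyze_checkpoints(checkpoint_dir, out_dir=None):
    """Recompute all tables from serialized agents without re-learning.

    Reads ``config.yaml``, ``master.json`` and ``agent_<variant>_<i>.json``
    from ``checkpoint_dir``; the tables are identical to those written by the
    original run.
    """
    checkpoint_dir = Path(checkpoint_dir)
    config = ExperimentConfig.from_yaml(checkpoint_dir / "config.yaml")
    master = MasterAgent.from_dict(
        json.loads((checkpoint_dir / "master.json").read_text(encoding="utf-8"))
    )
    agents, warns = {}, []
    for variant in config.variants:
        agents[variant] = []
        for i in range(config.n_agents):
            path = checkpoint_dir / f"agent_{variant}_{i:02d}.json"
            agent = LearnerAgent.from_json(path.read_text(encoding="utf-8"))
            agent.attach_forward(master.forward)
            agents[variant].append(agent)

    protos, rel, reg, dist = _derive_tables(config, master, agents, warns)
    result = ExperimentResult(
        config=config, master=master, agents=agents, prototypes=protos,
        relative_f1=rel, regressions=reg, distances=dist, logs={}, warnings=warns,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("prototypes", "relative_f1", "regressions", "distances"):
            getattr(result, name).to_csv(
                out_dir / f"{name}.csv", index=False, float_format=_CSV_FLOAT
            )
    return result
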