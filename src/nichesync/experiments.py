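"""Config-driven experiments: duet, precision-asymmetry learning, and
niche inheritance.

Each experiment writes a self-contained output directory: a config
snapshot, per-tick traces (delimited text), per-epoch metrics (JSON) and
a deterministic human-readable summary.  Everything is a pure function of
(config, seed).
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from ._rng import substreams
from .agent import AgentState, confidence_interval, make_agent
from .blanket_coupling import (AGENT_KEYS, EpochSchedule, MarkovBlanketSystem,
                               SimulationResult, couple, simulate_duet)
from .generative_model import HierarchicalModel, birdsong_model
from .synchrony_metrics import SynchronyReport, duet_synchrony_report, sonogram

EXPERIMENTS = ("duet", "precision_asymmetry", "niche_inheritance")


@dataclass(frozen=True)
class AgentConfig:
    theta_prior_mean: float = 24.0
    theta_prior_log_precision: float = 8.0
    learning_scale: float = 1.0


@dataclass(frozen=True)
class ModelConfig:
    """Overrides of the birdsong model defaults (see `birdsong_model`)."""

    rho_base_prior_mean: float = 24.0
    rho_top: float = 28.0
    tau_top: float = 2.0
    tau_bottom: float = 0.25
    gamma_w: float = 8.0
    gamma_z: float = 4.0
    gamma_v: float = 6.0
    gamma_v_prior: float = -6.0
    output_gain: float = 0.32
    smoothness: float = 1.0 / 128.0

    def build(self, *, gamma_z: float | None = None) -> HierarchicalModel:
        kw = asdict(self)
        if gamma_z is not None:
            kw["gamma_z"] = gamma_z
        return birdsong_model(**kw)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment run, fully resolvable to defaults."""

    experiment: str = "duet"
    mode: str = "coupled"
    n_epochs: int = 8
    epoch_seconds: float = 2.0
    dt: float = 1.0 / 256.0
    turn_order: str = "A"
    include_uncoupled: bool = True
    n_trials: int = 10
    trial_epochs: int = 4
    niche_learning_scale: float = 0.25
    niche_gamma_z: float | None = None
    eta_theta: float = 1.0
    kappa: float = 0.5
    refresh_every: int = 8
    write_sonograms: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)
    agent_A: AgentConfig = field(default_factory=AgentConfig)
    agent_B: AgentConfig = field(default_factory=AgentConfig)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")
        if self.experiment == "niche_inheritance" and self.n_trials < 3:
            raise ValueError("niche inheritance needs at least 3 trials")


def default_config(experiment: str) -> ExperimentConfig:
    """The study conditions each experiment ships with.

    The duet uses freely drifting causes (what level-2 synchrony needs);
    the learning and inheritance experiments anchor the cause prior
    (gamma_v_prior = 2), the precision context under which the trait —
    rather than the fast states — carries the information exchanged.
    """
    if experiment == "duet":
        return ExperimentConfig(experiment="duet")
    if experiment == "precision_asymmetry":
        return ExperimentConfig(
            experiment="precision_asymmetry",
            model=ModelConfig(gamma_v_prior=2.0),
            agent_A=AgentConfig(theta_prior_mean=30.0, theta_prior_log_precision=0.0),
            agent_B=AgentConfig(theta_prior_mean=24.0, theta_prior_log_precision=8.0))
    if experiment == "niche_inheritance":
        return ExperimentConfig(
            experiment="niche_inheritance",
            model=ModelConfig(gamma_v_prior=2.0),
            agent_A=AgentConfig(theta_prior_mean=28.0, theta_prior_log_precision=8.0),
            agent_B=AgentConfig(theta_prior_mean=32.0, theta_prior_log_precision=2.0))
    raise ValueError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# Config I/O (fail-fast on unknown keys)
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: Mapping[str, Any], context: str):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    experiment = raw.get("experiment", "duet")
    base = default_config(experiment)
    nested = {"model": ModelConfig, "agent_A": AgentConfig, "agent_B": AgentConfig}
    kwargs: dict[str, Any] = {}
    _from_mapping(ExperimentConfig, raw, "experiment config")
    for key, value in raw.items():
        if key in nested:
            sub = _from_mapping(nested[key], value, key)
            kwargs[key] = replace(getattr(base, key), **sub)
        else:
            kwargs[key] = value
    return replace(base, **kwargs)


def config_snapshot(config: ExperimentConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=True)


def config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(config_snapshot(config).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _build_system(config: ExperimentConfig, mode: str,
                  model_A: HierarchicalModel | None = None,
                  model_B: HierarchicalModel | None = None,
                  agent_B_override: AgentState | None = None) -> MarkovBlanketSystem:
    model_A = model_A or config.model.build()
    model_B = model_B or model_A
    sched = EpochSchedule(epoch_seconds=config.epoch_seconds, n_epochs=config.n_epochs,
                          turn_order=config.turn_order, dt=config.dt)
    a_cfg, b_cfg = config.agent_A, config.agent_B
    agent_A = make_agent(model_A, theta_prior_mean=a_cfg.theta_prior_mean,
                         theta_prior_log_precision=a_cfg.theta_prior_log_precision,
                         dt=config.dt)
    agent_B = agent_B_override or make_agent(
        model_B, theta_prior_mean=b_cfg.theta_prior_mean,
        theta_prior_log_precision=b_cfg.theta_prior_log_precision, dt=config.dt)
    return couple(agent_A, agent_B, mode, sched, model_A, model_B,
                  learning_scales={"A": a_cfg.learning_scale,
                                   "B": b_cfg.learning_scale})


def _run(config: ExperimentConfig, mode: str, seed: int,
         **kwargs) -> SimulationResult:
    system = _build_system(config, mode, **kwargs)
    return simulate_duet(system, seed, kappa=config.kappa,
                         refresh_every=config.refresh_every,
                         eta_theta=config.eta_theta)


def write_traces(result: SimulationResult, path: Path) -> None:
    """Per-tick trace table: time axis, roles, free energies, expectations."""
    import pandas as pd

    cols: dict[str, np.ndarray] = {
        "tick": np.arange(result.times.size),
        "time_s": result.times,
        "epoch": result.epoch_index,
        "singer": np.where(result.singer == 0, "A", "B"),
        "emit_amplitude": result.emissions[:, 0],
        "emit_frequency_hz": result.emissions[:, 1],
    }
    for a, key in enumerate(AGENT_KEYS):
        cols[f"F_{key}"] = result.F[:, a]
        for lvl, name in (("bottom", "hvc"), ("top", "areax")):
            traj = result.level_trajectory(key, level=lvl)
            for i in range(3):
                cols[f"{name}{i + 1}_{key}"] = traj[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_outputs(out: Path, config: ExperimentConfig, seed: int,
                   metrics: dict, traces: dict[str, SimulationResult]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_snapshot.yaml").write_text(config_snapshot(config))
    metrics = dict(metrics, seed=seed, config_hash=config_hash(config))
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True, default=_json_default) + "\n")
    for name, result in traces.items():
        write_traces(result, out / f"traces_{name}.tsv")
    (out / "summary.md").write_text(render_report(out))


def _sync_metrics(report: SynchronyReport) -> dict:
    return {"generalized_r2": report.generalized_r2,
            "identical_deviation": report.identical_deviation,
            "per_epoch_r2": report.per_epoch_r2,
            "per_epoch_identical": report.per_epoch_identical,
            "per_epoch_complementarity": report.per_epoch_complementarity,
            "final_fraction": report.final_fraction}


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_duet(config: ExperimentConfig, seed: int, out: str | Path) -> dict:
    """Two birds with the same generative model and different initial
    expectations; coupled and (optionally) matched uncoupled runs."""
    out = Path(out)
    traces: dict[str, SimulationResult] = {}
    metrics: dict[str, Any] = {"experiment": "duet"}
    modes = ["coupled"] + (["uncoupled"] if config.include_uncoupled else [])
    for mode in modes:
        result = _run(config, mode, seed)
        traces[mode] = result
        report = duet_synchrony_report(result)
        metrics[mode] = _sync_metrics(report)
        if config.write_sonograms:
            # the sonogram heard by the first bird, over the whole run
            sono = sonogram(result.heard_samples[:, 0, 0],
                            result.heard_samples[:, 0, 1], config.dt)
            np.savetxt(_ensure(out, f"sonogram_{mode}.tsv"), sono.power,
                       delimiter="\t",
                       header=f"window_s={sono.window_seconds} "
                              f"hop_s={sono.hop_seconds} "
                              f"f0={sono.freqs[0]} df={sono.freqs[1] - sono.freqs[0]}")
    if config.include_uncoupled:
        A = traces["uncoupled"].level_trajectory("A")
        B = traces["uncoupled"].level_trajectory("B")
        dist = [float(np.sqrt(np.mean((A[sl] - B[sl]) ** 2)))
                for sl in traces["uncoupled"].epoch_slices()]
        metrics["uncoupled"]["per_epoch_distance"] = dist
        metrics["contrast"] = {
            "r2_coupled_minus_uncoupled": metrics["coupled"]["generalized_r2"]
            - metrics["uncoupled"]["generalized_r2"],
            "divergence_slope": float(np.polyfit(np.arange(len(dist)), dist, 1)[0]),
        }
    _write_outputs(out, config, seed, metrics, traces)
    return metrics


def _ensure(out: Path, name: str) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def run_precision_asymmetry(config: ExperimentConfig, seed: int,
                            out: str | Path) -> dict:
    """Teacher-learner duet: the agent with more precise beliefs about its
    order parameter teaches the other; records per-epoch theta with 90%
    credible intervals, plus the uncoupled control."""
    out = Path(out)
    traces: dict[str, SimulationResult] = {}
    metrics: dict[str, Any] = {"experiment": "precision_asymmetry"}
    modes = ["coupled"] + (["uncoupled"] if config.include_uncoupled else [])
    for mode in modes:
        result = _run(config, mode, seed)
        traces[mode] = result
        theta = result.theta
        lp = result.theta_log_precision
        z90 = 1.6448536269514722
        width = z90 * np.exp(-lp / 2.0)
        disp = np.abs(np.diff(theta, axis=0)).sum(axis=0)
        metrics[mode] = {
            "theta": theta, "theta_log_precision": lp,
            "ci90_low": theta - width, "ci90_high": theta + width,
            "displacement_A": float(disp[0]), "displacement_B": float(disp[1]),
            "initial_gap": float(abs(theta[0, 0] - theta[0, 1])),
            "final_gap": float(abs(theta[-1, 0] - theta[-1, 1])),
        }
    _write_outputs(out, config, seed, metrics, traces)
    return metrics


def run_niche_inheritance(config: ExperimentConfig, seed: int,
                          out: str | Path) -> dict:
    """Ecological inheritance: agent B is the niche.

    Its learned order parameter and posterior precision persist across
    trials as the next trial's prior (the constructed niche is what a new
    organism inherits), while agent A is re-initialized each trial.  The
    niche learns slowly (learning scale < 1).  Records trial-mean joint
    free energy (complementarity).
    """
    out = Path(out)
    model_A = config.model.build()
    model_B = config.model.build(gamma_z=config.niche_gamma_z)
    sched = EpochSchedule(epoch_seconds=config.epoch_seconds,
                          n_epochs=config.trial_epochs,
                          turn_order=config.turn_order, dt=config.dt)
    trial_seeds = substreams(seed)["trials"].integers(0, 2**31 - 1,
                                                      config.n_trials)
    prior_theta = config.agent_B.theta_prior_mean
    prior_lp = config.agent_B.theta_prior_log_precision
    rows = []
    last_result: SimulationResult | None = None
    for k in range(config.n_trials):
        agent_A = make_agent(model_A,
                             theta_prior_mean=config.agent_A.theta_prior_mean,
                             theta_prior_log_precision=config.agent_A.theta_prior_log_precision,
                             dt=config.dt)
        niche = make_agent(model_B, theta_prior_mean=prior_theta,
                           theta_prior_log_precision=prior_lp, dt=config.dt)
        system = couple(agent_A, niche, "coupled", sched, model_A, model_B,
                        learning_scales={"A": config.agent_A.learning_scale,
                                         "B": config.niche_learning_scale})
        result = simulate_duet(system, int(trial_seeds[k]), kappa=config.kappa,
                               refresh_every=config.refresh_every,
                               eta_theta=config.eta_theta)
        last_result = result
        if config.niche_learning_scale > 0:
            prior_theta = float(result.theta[-1, 1])
            prior_lp = float(result.theta_log_precision[-1, 1])
        joint, _ = result.F[:, 0] + result.F[:, 1], None
        rows.append({"trial": k, "joint_F_mean": float(np.mean(joint)),
                     "F_A_mean": float(np.mean(result.F[:, 0])),
                     "F_B_mean": float(np.mean(result.F[:, 1])),
                     "niche_theta": prior_theta,
                     "niche_log_precision": prior_lp})
    joints = np.array([r["joint_F_mean"] for r in rows])
    metrics = {"experiment": "niche_inheritance", "trials": rows,
               "joint_F_by_trial": joints,
               "n_increases": int(np.sum(np.diff(joints) > 0)),
               "total_decline": float(joints[0] - joints[-1]),
               "niche_learning_scale": config.niche_learning_scale}
    _write_outputs(Path(out), config, seed, metrics,
                   {"last_trial": last_result} if last_result else {})
    return metrics


def run_experiment(config: ExperimentConfig, seed: int, out: str | Path) -> dict:
    runner = {"duet": run_duet,
              "precision_asymmetry": run_precision_asymmetry,
              "niche_inheritance": run_niche_inheritance}[config.experiment]
    return runner(config, seed, out)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def render_report(results_dir: str | Path) -> str:
    """One-page structured summary of an experiment directory.

    Deterministic given the directory contents; numbers are re-read from
    the metric files, never recomputed.
    """
    results_dir = Path(results_dir)
    metrics_path = results_dir / "metrics.json"
    config_path = results_dir / "config_snapshot.yaml"
    missing = [p.name for p in (metrics_path, config_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete results in {results_dir}: "
                                f"missing {missing}")
    metrics = json.loads(metrics_path.read_text())
    lines = [f"# {metrics.get('experiment', 'experiment')} summary", ""]
    lines.append(f"- seed: {metrics.get('seed')}")
    lines.append(f"- config hash: {metrics.get('config_hash')}")
    for mode in ("coupled", "uncoupled"):
        if mode in metrics:
            m = metrics[mode]
            lines.append(f"\n## {mode}")
            for key in ("generalized_r2", "identical_deviation", "displacement_A",
                        "displacement_B", "initial_gap", "final_gap"):
                if key in m:
                    lines.append(f"- {key}: {_fmt(m[key])}")
    if "contrast" in metrics:
        lines.append("\n## contrast")
        for key, value in metrics["contrast"].items():
            lines.append(f"- {key}: {_fmt(value)}")
    if "joint_F_by_trial" in metrics:
        lines.append("\n## trials")
        lines.append("| trial | joint F (nats/tick) | niche theta |")
        lines.append("|---|---|---|")
        for row in metrics["trials"]:
            lines.append(f"| {row['trial']} | {row['joint_F_mean']:.4f} | "
                         f"{row['niche_theta']:.4f} |")
        lines.append(f"\n- increases across trials: {metrics['n_increases']}")
        lines.append(f"- total decline: {_fmt(metrics['total_decline'])} nats/tick")
    inventory = sorted(p.name for p in results_dir.iterdir()
                       if p.name != "summary.md")
    lines.append("\n## files")
    lines.extend(f"- {name}" for name in inventory)
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, (int, float)) else str(x)
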