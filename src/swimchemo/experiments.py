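"""Config-driven scenario registry and command-line interface.

Every navigation scenario studied with this package has a named
configuration (field, controller, navigator choice, evaluation protocol)
so that results can be reproduced bit-for-bit from a master seed.  The
``swimchemo`` CLI exposes thin wrappers over the library: train-gait,
train-nav, evaluate, simulate, classify and report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import click
import numpy as np
import yaml

from .analysis import Trajectory, classify_modes, mode_fractions, write_modes_csv
from .chem_fields import get_field
from .gait_control import OracleGaitController, PPOGaitController, train_gait_predictor
from .hydrodynamics import HydroParams
from .navigation import (
    NavConfig,
    PointNavEnv,
    evaluate_policy,
    greedy_source_stub,
    train_mapbased_baseline,
    train_navigator,
    write_aggregate_json,
    write_trials_csv,
)
from .rl_core import PPOConfig, SACAgent

__all__ = ["ScenarioConfig", "SCENARIOS", "get_scenario", "run_scenario", "cli"]


@dataclass
class ScenarioConfig:
    """One reproducible evaluation scenario."""

    name: str
    field: str
    controller: str = "oracle"  # "oracle" or "ppo:<checkpoint>"
    navigator: str = "mapless"  # "mapless", "mapbased" or "stub"
    checkpoint: str | None = None
    n_trials: int = 200
    seed: int = 0
    nav: NavConfig = dc_field(default_factory=NavConfig)
    hydro: HydroParams = dc_field(default_factory=HydroParams)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# Start-azimuth window for the shifted-source comparison: bearings within
# +-60 degrees of the displacement direction (45 deg) are excluded, because
# from those starts any trajectory bound for the original source transits
# the displaced source's success disc regardless of sensing ability.
SHIFTED_AZIMUTH_WINDOW = (math.radians(105.0), math.radians(345.0))


def _scenarios() -> dict[str, ScenarioConfig]:
    names = ["training", "gaussian_s2", "gaussian_s4", "gaussian_s6",
             "gaussian_s8", "gaussian_s10", "skewed", "multimodal", "fluctuating"]
    out = {n: ScenarioConfig(name=n, field=n) for n in names}
    shifted_nav = NavConfig(init_azimuth=SHIFTED_AZIMUTH_WINDOW)
    out["shifted"] = ScenarioConfig(name="shifted", field="shifted", nav=shifted_nav)
    out["mapbased-on-shifted"] = ScenarioConfig(
        name="mapbased-on-shifted", field="shifted", navigator="mapbased",
        nav=shifted_nav,
    )
    return out


SCENARIOS = _scenarios()


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}") from None


def _make_controller(spec: str):
    if spec == "oracle":
        return OracleGaitController()
    if spec.startswith("ppo:"):
        return PPOGaitController.from_checkpoint(spec[len("ppo:"):])
    raise ValueError(f"unknown controller spec {spec!r}")


def _make_policy(cfg: ScenarioConfig):
    if cfg.navigator == "stub":
        return greedy_source_stub
    if cfg.checkpoint is None:
        raise FileNotFoundError(
            f"scenario {cfg.name!r} needs a trained checkpoint (navigator={cfg.navigator})"
        )
    if not Path(cfg.checkpoint).exists():
        raise FileNotFoundError(f"checkpoint not found: {cfg.checkpoint}")
    return SACAgent.load(cfg.checkpoint)


def run_scenario(cfg: ScenarioConfig, out_dir, keep_trajectories: bool = False) -> dict:
    """Evaluate one scenario; writes config snapshot, per-trial CSV and metrics JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field = get_field(cfg.field)
    policy = _make_policy(cfg)
    observation = "mapbased" if cfg.navigator == "mapbased" else "mapless"
    result = evaluate_policy(
        policy, field, cfg.n_trials, cfg.nav, seed=cfg.seed,
        controller_factory=lambda: _make_controller(cfg.controller),
        params=cfg.hydro,
        observation=observation, keep_trajectories=keep_trajectories,
    )
    snapshot = asdict(cfg)
    snapshot["config_hash"] = cfg.config_hash()
    from . import __version__
    snapshot["swimchemo_version"] = __version__
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh)
    write_trials_csv(out / "trials.csv", result, cfg.seed)
    write_aggregate_json(out / "metrics.json", result, cfg.nav,
                         extra={"scenario": cfg.name, "config_hash": cfg.config_hash()})
    return {"success_rate": result.success_rate, "mean_t_reach": result.mean_t_reach,
            "sem_t_reach": result.sem_t_reach, "n_trials": result.n_trials}


def _load_scenario_file(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    nav = NavConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.pop("nav", {}).items()})
    hydro = HydroParams(**raw.pop("hydro", {}))
    raw.pop("config_hash", None)
    raw.pop("swimchemo_version", None)
    return ScenarioConfig(nav=nav, hydro=hydro, **raw)


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


@click.group()
def cli():
    """Mapless chemotactic navigation of a three-sphere microswimmer."""


@cli.command("train-gait")
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--updates", type=int, default=60, show_default=True)
@click.option("--rollout-steps", type=int, default=2048, show_default=True)
def cli_train_gait(seed, out, updates, rollout_steps):
    """Train the PPO locomotory-gait predictor."""
    cfg = PPOConfig(seed=seed, rollout_steps=rollout_steps)
    agent, history = train_gait_predictor(cfg, seed=seed, n_updates=updates, progress=True)
    agent.save(out, extra_meta={"task": "gait"})
    click.echo(f"saved gait checkpoint to {out} ({len(history)} episodes)")


@cli.command("train-nav")
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--field", "field_name", default="training", show_default=True)
@click.option("--episodes", type=int, default=None,
              help="Training episodes (defaults to the per-task library default).")
@click.option("--mapbased", is_flag=True, help="Train the map-based baseline instead.")
@click.option("--controller", default="oracle", show_default=True)
@click.option("--surrogate", is_flag=True, help="Train on the kinematic point surrogate.")
@click.option("--batch-size", type=int, default=128, show_default=True)
@click.option("--max-event-steps", type=int, default=None)
@click.option("--curve-out", type=click.Path(), default=None,
              help="CSV of per-episode training rewards.")
def cli_train_nav(seed, out, field_name, episodes, mapbased, controller, surrogate,
                  batch_size, max_event_steps, curve_out):
    """Train the SAC chemotactic navigator (or the map-based baseline)."""
    from .navigation import navigation_sac_defaults, train_mapless_navigator

    field = get_field(field_name)
    sac = navigation_sac_defaults(seed, batch_size=batch_size)
    if surrogate:
        env = PointNavEnv(field, NavConfig(), seed=seed)
        agent, curve = train_navigator(env, sac, episodes or 200, max_event_steps,
                                       progress=True)
    elif mapbased:
        kw = {"n_episodes": episodes} if episodes else {}
        agent, curve = train_mapbased_baseline(
            field, lambda: _make_controller(controller), sac, seed=seed,
            progress=True, **kw)
    else:
        kw = {"n_episodes": episodes} if episodes else {}
        agent, curve = train_mapless_navigator(
            field, lambda: _make_controller(controller), sac, seed=seed,
            progress=True, **kw)
    agent.save(out, extra_meta={"task": "mapbased" if mapbased else "mapless",
                                "field": field_name})
    if curve_out:
        np.savetxt(curve_out, np.column_stack([np.arange(len(curve)), curve]),
                   delimiter=",", header="episode,reward", comments="")
    click.echo(f"saved navigator checkpoint to {out}")


@cli.command("evaluate")
@click.option("--scenario", "scenario_name", default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--checkpoint", type=click.Path(), default=None)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--n-trials", type=int, default=None)
@click.option("--fast", is_flag=True, help="Evaluate 20 trials instead of 200.")
def cli_evaluate(scenario_name, config_path, checkpoint, seed, out, n_trials, fast):
    """Evaluate a navigator on a named scenario or a scenario config file."""
    if (scenario_name is None) == (config_path is None):
        raise click.UsageError("give exactly one of --scenario or --config")
    cfg = get_scenario(scenario_name) if scenario_name else _load_scenario_file(config_path)
    if checkpoint:
        cfg.checkpoint = checkpoint
    cfg.seed = seed
    if fast:
        cfg.n_trials = 20
    if n_trials:
        cfg.n_trials = n_trials
    metrics = run_scenario(cfg, out)
    click.echo(json.dumps(metrics, indent=2))


@cli.command("simulate")
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--steps", type=int, default=500, show_default=True)
@click.option("--theta-t", type=float, default=0.0, show_default=True)
def cli_simulate(seed, out, steps, theta_t):
    """Integrate the oracle gait controller at fixed theta_T; write trajectory CSV."""
    from .hydrodynamics import SwimmerState, step, write_trajectory

    rng = np.random.default_rng(seed)
    st = SwimmerState.from_centroid(np.zeros(2), rng.uniform(-math.pi, math.pi))
    ctrl = OracleGaitController()
    params = HydroParams()
    states = [st]
    for _ in range(steps):
        st = step(st, ctrl(st, theta_t), params)
        states.append(st)
    write_trajectory(out, np.arange(len(states)) * params.dt, states)
    click.echo(f"wrote {len(states)} states to {out}")


@cli.command("classify")
@click.option("--scenario", "scenario_name", required=True)
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--n-trials", type=int, default=5, show_default=True)
def cli_classify(scenario_name, checkpoint, seed, out, n_trials):
    """Run evaluation episodes and export run/tumble/wander labels."""
    cfg = get_scenario(scenario_name)
    cfg.checkpoint = checkpoint
    cfg.seed = seed
    field = get_field(cfg.field)
    policy = _make_policy(cfg)
    result = evaluate_policy(
        policy, field, n_trials, cfg.nav, seed=seed,
        controller_factory=lambda: _make_controller(cfg.controller),
        keep_trajectories=True,
    )
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for i, rec in enumerate(result.trajectories):
        traj = Trajectory.from_record(rec)
        labels = classify_modes(traj)
        write_modes_csv(out / f"modes_trial{i}.csv",
                        traj.t[: len(labels) * 5 : 5], labels)
        summary.append(mode_fractions(labels))
    with open(out / "mode_fractions.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    click.echo(f"classified {n_trials} trials into {out}")


@cli.command("report")
@click.option("--results-dir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="-")
def cli_report(results_dir, out):
    """Aggregate a directory of evaluation metrics.json files into one table."""
    import pandas as pd

    rows = []
    for p in sorted(Path(results_dir).rglob("metrics.json")):
        with open(p) as fh:
            m = json.load(fh)
        rows.append({
            "scenario": m.get("scenario", p.parent.name),
            "n_trials": m["n_trials"],
            "success_rate": m["success_rate"],
            "mean_t_reach": m["mean_t_reach"],
            "sem_t_reach": m["sem_t_reach"],
        })
    if not rows:
        raise click.ClickException("no metrics.json files found")
    df = pd.DataFrame(rows)
    if out == "-":
        click.echo(df.to_string(index=False))
    else:
        df.to_csv(out, index=False)
        click.echo(f"wrote {out}")


if __name__ == "__main__":
    cli()
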