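"""Scenario configuration, validation and experiment dispatch.

A scenario file (YAML or JSON) declares a circuit variant, dimensionless
parameters, an engine and an experiment with options; :func:`run` executes
it and writes CSV/JSON artifacts plus the resolved configuration and a
structured log, so every output directory is reproducible from what it
contains.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import DimensionlessParams, build_network
from . import circuits, markov, ode, ssa

__all__ = ["ScenarioConfig", "load_config", "save_config", "run",
           "list_scenarios", "scenario_path"]

_ENGINES = ("ode", "ssa", "cme", "reduced")
_EXPERIMENTS = ("simulate", "equilibria", "bifurcation", "chart", "hysteresis",
                "stationary", "first_passage", "reactivation", "events",
                "robustness", "scaling")
_VARIANTS = ("full", "histone_only", "autoregulated", "mutual_repression")
_PARAM_FIELDS = set(DimensionlessParams.__dataclass_fields__)
_TOP_KEYS = {"variant", "params", "engine", "experiment", "options", "seed",
             "note", "circuit"}


@dataclass
class ScenarioConfig:
    variant: str
    params: DimensionlessParams
    engine: str
    experiment: str
    options: dict = field(default_factory=dict)
    circuit: dict = field(default_factory=dict)   # coupling options (p_x, ...)
    seed: int | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {"variant": self.variant, "params": asdict(self.params),
                "engine": self.engine, "experiment": self.experiment,
                "options": self.options, "circuit": self.circuit,
                "seed": self.seed, "note": self.note}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _validate(payload: dict, source: str) -> ScenarioConfig:
    if not isinstance(payload, dict):
        raise ValueError(f"{source}: scenario must be a mapping")
    unknown = set(payload) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    for key in ("variant", "engine", "experiment"):
        if key not in payload:
            raise ValueError(f"{source}: missing required key '{key}'")
    if payload["variant"] not in _VARIANTS:
        raise ValueError(f"{source}: variant must be one of {_VARIANTS}")
    if payload["engine"] not in _ENGINES:
        raise ValueError(f"{source}: engine must be one of {_ENGINES}")
    if payload["experiment"] not in _EXPERIMENTS:
        raise ValueError(f"{source}: experiment must be one of {_EXPERIMENTS}")
    raw_params = payload.get("params", {})
    unknown = set(raw_params) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"{source}: unknown parameters {sorted(unknown)}")
    try:
        params = DimensionlessParams(**raw_params)
    except ValueError as exc:
        raise ValueError(f"{source}: {exc}") from exc
    seed = payload.get("seed")
    if payload["engine"] == "ssa" and seed is None:
        raise ValueError(f"{source}: stochastic engines require a seed")
    options = payload.get("options", {}) or {}
    circuit = payload.get("circuit", {}) or {}
    if not isinstance(options, dict) or not isinstance(circuit, dict):
        raise ValueError(f"{source}: options/circuit must be mappings")
    return ScenarioConfig(payload["variant"], params, payload["engine"],
                          payload["experiment"], options, circuit,
                          seed, payload.get("note", ""))


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file."""
    path = Path(path)
    text = path.read_text()
    payload = (json.loads(text) if path.suffix == ".json"
               else yaml.safe_load(text))
    return _validate(payload, str(path))


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_SCENARIO_DIR = Path(__file__).parent / "scenarios"


def list_scenarios() -> list[str]:
    return sorted(p.stem for p in _SCENARIO_DIR.glob("*.yaml"))


def scenario_path(name: str) -> Path:
    p = _SCENARIO_DIR / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no scenario preset named {name!r}")
    return p


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def _build(config: ScenarioConfig, qss: bool):
    c = config.circuit
    if config.variant == "autoregulated":
        gc = circuits.make_autoregulated(
            config.params, p_x=c.get("p_x", config.params.p_x),
            u_tilde_A=c.get("u_tilde_A", 1.0),
            gamma_x_bar=c.get("gamma_x_bar", 1.0),
            coupling=c.get("coupling", "linear"),
            hill=tuple(c["hill"]) if "hill" in c else None,
            variant=c.get("base_variant", "full"))
        return gc.qss_network if qss else gc.network
    if config.variant == "mutual_repression":
        gc = circuits.make_mutual_repression(
            config.params, p_x=c.get("p_x", 1.0), p_z=c.get("p_z"),
            u_tilde_A=c.get("u_tilde_A", 1.0),
            u_tilde_1R=c.get("u_tilde_1R", 1.0),
            gamma_bar=c.get("gamma_bar", 1.0),
            variant=c.get("base_variant", "full"))
        return gc.qss_network if qss else gc.network
    return build_network(config.params, config.variant)


def _init_state(config: ScenarioConfig, network, fractions: bool):
    init = config.options.get("init")
    if init is None:
        if fractions:
            return {"D1R": 0.0, "D2R": 0.0, "D12R": 1.0}
        return {"D12R": network.D_tot}
    if fractions:
        return {k: float(v) for k, v in init.items()}
    return {k: int(v) for k, v in init.items()}


def run(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Execute a scenario and write its artifacts under ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    opts = config.options
    summary: dict = {"engine": config.engine, "experiment": config.experiment}

    key = (config.engine, config.experiment)
    if key == ("ode", "simulate"):
        net = _build(config, qss=True)
        traj = ode.simulate_ode(net, _init_state(config, net, True),
                                opts.get("duration", 100.0),
                                t_eval=np.linspace(0, opts.get("duration", 100.0),
                                                   opts.get("n_samples", 201)))
        traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
        summary["final"] = dict(zip(net.species, traj.final().tolist()))
    elif key == ("ode", "equilibria"):
        net = _build(config, qss=True)
        eqset = ode.find_equilibria(net, n_starts=opts.get("n_starts", 200),
                                    seed=config.seed or 0)
        eqset.to_frame().to_csv(outdir / "equilibria.csv", index=False)
        summary["classification"] = eqset.classification
        summary["n_stable"] = len(eqset.stable)
    elif key == ("ode", "bifurcation"):
        scan = ode.bifurcation_scan(
            config.params, opts["scan_param"], opts["grid"],
            variant=config.variant if config.variant in ("full", "histone_only")
            else "full", n_starts=opts.get("n_starts", 60),
            seed=config.seed or 0)
        scan.to_frame().to_csv(outdir / "branches.csv", index=False)
        summary["saddle_nodes"] = scan.saddle_nodes
    elif key == ("ode", "chart"):
        chart = ode.stability_chart(
            config.params, opts.get("x_param", "eps"), opts["x_grid"],
            opts.get("y_param", "mu_prime"), opts["y_grid"],
            variant=config.variant, n_starts=opts.get("n_starts", 40),
            seed=config.seed or 0)
        chart.to_csv(outdir / "chart.csv", index=False)
        summary["n_bistable_cells"] = int((chart["n_stable"] >= 2).sum())
    elif key == ("ode", "hysteresis"):
        sweep = ode.hysteresis_sweep(
            config.params, opts.get("input", "uA"), opts["grid"],
            init=_init_state(config, _build(config, qss=True), True),
            variant=config.variant)
        sweep.summary().to_csv(outdir / "sweep.csv", index=False)
        summary["hysteretic"] = sweep.is_hysteretic(
            "DA", tol=opts.get("tol", 0.1))
    elif key == ("ode", "robustness"):
        df, crit = circuits.robustness_scan(
            config.params, opts["uR_grid"], opts["p_x_grid"],
            u_tilde_A=config.circuit.get("u_tilde_A", 1.0))
        df.to_csv(outdir / "robustness.csv", index=False)
        summary["critical_uR"] = {str(k): v for k, v in crit.items()}
    elif key == ("ssa", "stationary"):
        net = _build(config, qss=False)
        dist = ssa.stationary_histogram(
            net, _init_state(config, net, False), opts.get("horizon", 500.0),
            opts.get("reps", 50), config.seed,
            samples_per_rep=opts.get("samples_per_rep", 200))
        dist.to_frame().to_csv(outdir / "histogram.csv", index=False)
        if "DA" in net.species:
            m = dist.marginal_nA_nR(net.D_tot)
            pd.DataFrame(m).to_csv(outdir / "histogram_nA_nR.csv")
        summary["support"] = int(len(dist.states))
    elif key == ("ssa", "first_passage"):
        net = _build(config, qss=False)
        target = ssa.StopCondition.on(opts.get("target", "nR"),
                                      opts.get("op", "le"),
                                      opts.get("threshold", 6))
        fps = ssa.first_passage_sample(
            net, _init_state(config, net, False), target,
            opts.get("reps", 200), opts.get("max_time", 1e4), config.seed)
        pd.DataFrame({"time": fps.times, "censored": fps.censored}
                     ).to_csv(outdir / "first_passage.csv", index=False)
        summary.update(fps.summary())
    elif key == ("ssa", "reactivation"):
        net = _build(config, qss=False)
        fps, trajs = ssa.reactivation_experiment(
            net, _init_state(config, net, False), opts.get("reps", 100),
            config.seed, opts.get("max_time", 1e3),
            margin=opts.get("margin", 6), n_traj=opts.get("n_traj", 0))
        pd.DataFrame({"latency": fps.times, "censored": fps.censored}
                     ).to_csv(outdir / "latency.csv", index=False)
        summary.update(fps.summary())
    elif key == ("ssa", "events"):
        net = _build(config, qss=False)
        events = [circuits.PerturbationEvent(**e) for e in opts.get("events", [])]
        horizon = opts.get("horizon", 200.0)
        run_ = circuits.apply_events_ssa(
            net, _init_state(config, net, False), horizon, config.seed,
            events, sample_times=np.linspace(0, horizon,
                                             opts.get("n_samples", 200)))
        run_.trajectory().to_csv(outdir / "trajectory.csv", index=False)
        summary["final"] = dict(zip(net.species,
                                    run_.state_end.astype(int).tolist()))
    elif key == ("cme", "stationary"):
        net = _build(config, qss=True)
        space = markov.StateSpace(net)
        dist = markov.exact_stationary(markov.build_generator(net, space), space)
        dist.to_frame().to_csv(outdir / "stationary.csv", index=False)
        summary["support"] = int(len(dist.states))
    elif key == ("cme", "first_passage"):
        net = _build(config, qss=True)
        space = markov.StateSpace(net)
        Q = markov.build_generator(net, space)
        target_idx = [space.find(**{opts.get("target_species", "DA"):
                                    net.D_tot})]
        res = markov.exact_mfpt(Q, target_idx)
        start = space.find(**_init_state(config, net, False))
        summary["mfpt"] = float(res.mfpt[start])
    elif key == ("reduced", "stationary"):
        net = _build(config, qss=True)
        chain = markov.reduce_to_1d(net)
        chain.to_frame().assign(pi=chain.stationary()).to_csv(
            outdir / "reduced_chain.csv", index=False)
        pi = chain.stationary()
        summary["pi_active"] = float(pi[0])
        summary["pi_repressed"] = float(pi[-1])
    elif key == ("reduced", "scaling") or key == ("cme", "scaling"):
        res = markov.mfpt_scaling_check(
            config.params, opts.get("eps_grid", [0.02, 0.05, 0.1, 0.2]),
            variant=config.variant)
        pd.DataFrame({"eps": res.eps_grid, "tau_repressed": res.tau_repressed,
                      "tau_active": res.tau_active}
                     ).to_csv(outdir / "scaling.csv", index=False)
        summary["slope_repressed"] = res.slope_repressed
        summary["slope_active"] = res.slope_active
    else:
        raise ValueError(f"experiment {config.experiment!r} is not available "
                         f"on engine {config.engine!r}")

    save_config(config, outdir / "resolved_config.yaml")
    log = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
           "config_hash": config.digest(), "seed": config.seed,
           "chromem": __version__, "numpy": np.__version__,
           "runtime_s": round(time.time() - t_start, 3)}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    return summary
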