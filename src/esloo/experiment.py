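"""Reproducible experiment runner.

Executes the full protocol around the sequential loop: several
independent maximin-LHD starting designs, per-iteration accuracy metrics
against a replicated test set, checkpointed histories, and a summary
(mean and max-min range across starts) per iteration.  Four independent
seed streams (design / fit / acquisition / simulator) let ablations
change one component at a time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmarks import get_simulator
from .design import ReplicatedDesign, make_maximin_lhd
from .domain import InputDomain
from .hetgp import FitSettings, fit_hetgp
from .metrics import TestSet, make_test_set, nrmse, score
from .selection import SelectionPolicy, _derive_seed, run_sequential


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    simulator: str = "toy"
    simulator_params: dict = field(default_factory=dict)
    domain: dict | None = None          # optional physical bounds for CSV output
    initial_points: int = 6
    initial_reps: int = 4
    lhd_restarts: int = 50
    n_starts: int = 10                  # number of independent starting designs
    n_iterations: int = 50
    policy: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    test_points: int = 100
    test_reps: int = 50
    seed_design: int = 1
    seed_fit: int = 2
    seed_acquisition: int = 3
    seed_simulator: int = 4
    output_dir: str = "esloo_output"

    def __post_init__(self) -> None:
        for name in ("initial_points", "initial_reps", "n_starts",
                     "n_iterations", "test_points", "test_reps"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"field '{name}' must be a positive integer, got {v!r}")
        try:
            self.make_policy(0)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"field 'policy' is invalid: {exc}") from exc
        try:
            self.make_fit_settings(0)
        except TypeError as exc:
            raise ConfigError(f"field 'fit' is invalid: {exc}") from exc

    def make_policy(self, seed: int) -> SelectionPolicy:
        return SelectionPolicy(**{**self.policy, "seed": seed})

    def make_fit_settings(self, seed: int) -> FitSettings:
        return FitSettings(**{**self.fit, "seed": seed})

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        known = cls.__dataclass_fields__
        bad = [k for k in data if k not in known]
        if bad:
            raise ConfigError(f"unknown config field(s): {bad}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _metric_fn(test: TestSet):
    def fn(model, design):
        pred = model.predict(test.points)
        return {
            "nrmse_m": nrmse(pred, test, "mean"),
            "nrmse_tau": nrmse(pred, test, "variance"),
            "score": score(pred, test),
            "n_unique": design.n,
            "N": design.N,
        }
    return fn


def _initial_design(cfg: ExperimentConfig, sim, start: int) -> ReplicatedDesign:
    X0 = make_maximin_lhd(cfg.initial_points, sim.domain.p,
                          seed=_derive_seed(cfg.seed_design, start),
                          n_restarts=cfg.lhd_restarts)
    rng = np.random.default_rng(_derive_seed(cfg.seed_simulator, start, 999))
    design = ReplicatedDesign(p=sim.domain.p)
    for x in X0:
        for _ in range(cfg.initial_reps):
            design.add_run(x, sim.sample(x, rng))
    return design


def run_experiment(cfg: ExperimentConfig, resume: bool = False) -> dict:
    """Run all starts, write histories, manifest and summary; returns paths."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = get_simulator(cfg.simulator, **cfg.simulator_params)
    test = make_test_set(sim, cfg.test_points, cfg.test_reps,
                         seed=_derive_seed(cfg.seed_simulator, 777))
    test.to_csv(out / "test_set.csv")
    metric = _metric_fn(test)
    domain = InputDomain.from_dict(cfg.domain) if cfg.domain else None

    manifest = {
        "config": asdict(cfg),
        "version": __version__,
        "completed": {},
    }
    man_path = out / "manifest.json"
    if resume and man_path.exists():
        manifest = json.loads(man_path.read_text())

    history_paths = []
    for s in range(cfg.n_starts):
        hist_path = out / f"history_start{s}.csv"
        des_path = out / f"design_start{s}.csv"
        done = int(manifest["completed"].get(str(s), 0))
        if resume and done > 0 and des_path.exists():
            design = ReplicatedDesign.from_csv(des_path, domain=domain)
            rows = pd.read_csv(hist_path).to_dict("records") if hist_path.exists() else []
            rows = [r for r in rows if r["iteration"] < done]
        else:
            design = _initial_design(cfg, sim, s)
            rows, done = [], 0

        policy = cfg.make_policy(_derive_seed(cfg.seed_acquisition, s))
        fit_settings = cfg.make_fit_settings(_derive_seed(cfg.seed_fit, s))
        for it in range(done, cfg.n_iterations):
            hist = run_sequential(
                sim.sample, design, policy, n_iterations=1,
                fit_settings=fit_settings, metric_fn=metric,
                sim_seed=_derive_seed(cfg.seed_simulator, s),
                start_iteration=it,
            )
            df = hist.to_frame()
            df["start"] = s
            rows.extend(df.to_dict("records"))
            # checkpoint
            design.to_csv(des_path, domain=domain)
            pd.DataFrame(rows).to_csv(hist_path, index=False)
            manifest["completed"][str(s)] = it + 1
            man_path.write_text(json.dumps(manifest, indent=1))
        # final metrics row from a fresh fit of the finished design
        final_model = fit_hetgp(design, cfg.make_fit_settings(
            _derive_seed(cfg.seed_fit, s, cfg.n_iterations, 1)))
        final = {"iteration": cfg.n_iterations, "start": s,
                 **metric(final_model, design)}
        all_rows = rows + [final]
        pd.DataFrame(all_rows).to_csv(hist_path, index=False)
        design.to_csv(des_path, domain=domain)
        history_paths.append(hist_path)

    summary = summarize(out, cfg.n_starts)
    summary.to_csv(out / "summary.csv", index=False)
    man_path.write_text(json.dumps(manifest, indent=1))
    return {"output_dir": str(out), "histories": [str(p) for p in history_paths],
            "summary": str(out / "summary.csv"), "manifest": str(man_path)}


def summarize(out_dir, n_starts: int) -> pd.DataFrame:
    """Mean and max-min range of each metric across starts, per iteration."""
    frames = []
    for s in range(n_starts):
        df = pd.read_csv(Path(out_dir) / f"history_start{s}.csv")
        df["start"] = s
        frames.append(df)
    alld = pd.concat(frames, ignore_index=True)
    cols = [c for c in ("nrmse_m", "nrmse_tau", "score") if c in alld.columns]
    grp = alld.groupby("iteration")[cols]
    mean = grp.mean().add_suffix("_mean")
    rng = (grp.max() - grp.min()).add_suffix("_range")
    return pd.concat([mean, rng], axis=1).reset_index()


def report(out_dir) -> dict[str, pd.DataFrame]:
    """Summary tables from a finished experiment directory.

    Returns NRMSE/score trajectories (one row per iteration per start)
    and the final replicate-count table per start.
    """
    out = Path(out_dir)
    man = json.loads((out / "manifest.json").read_text())
    n_starts = man["config"]["n_starts"]
    frames = []
    for s in range(n_starts):
        path = out / f"history_start{s}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing history file {path}")
        df = pd.read_csv(path)
        if "iteration" not in df.columns:
            raise ValueError(f"{path} lacks an 'iteration' column")
        df["start"] = s
        frames.append(df)
    traj = pd.concat(frames, ignore_index=True)
    keep = [c for c in ("start", "iteration", "is_replicate", "g_new", "g_rep",
                        "nrmse_m", "nrmse_tau", "score", "n_unique", "N")
            if c in traj.columns]
    traj = traj[keep]

    reps = []
    for s in range(n_starts):
        design = ReplicatedDesign.from_csv(out / f"design_start{s}.csv")
        df = pd.DataFrame(design.unique_points,
                          columns=[f"x{j + 1}" for j in range(design.p)])
        df["r"] = design.rep_counts
        df["start"] = s
        reps.append(df)
    rep_table = pd.concat(reps, ignore_index=True)
    traj.to_csv(out / "trajectories.csv", index=False)
    rep_table.to_csv(out / "replicate_counts.csv", index=False)
    return {"trajectories": traj, "replicate_counts": rep_table}
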