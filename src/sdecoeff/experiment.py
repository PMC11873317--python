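"""End-to-end experiment orchestration.

`run_experiment` composes the full pipeline on one benchmark problem:

    generate -> split -> scale -> (pre-train) -> train -> unscale -> evaluate

All randomness derives from one master seed via named child streams, so a
configuration reproduces its results exactly.  `generate_fixture` writes
small deterministic ensembles (200 paths x 50 points by default) for tests
and quick experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .evaluation import (EvalReport, coefficient_mse, resampling_mse,
                         signature_mmd)
from .io import problem_from_config, write_ensemble
from .losses import LossConfig
from .network import (NetworkSpec, build_network, fit_scaler,
                      pretrain_initialize, save_network, unscale_coefficients)
from .sde import (BrownianDraws, PathEnsemble, SDEProblem,
                  euler_maruyama_simulate, split_train_test)
from .training import TrainConfig, TrainReport, train

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("ou_tiny", "cir_tiny", "sin1_tiny", "sin2_tiny")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one training-and-evaluation run."""

    problem: dict                      # name / params / grid / initial
    n_paths: int = 5000
    test_fraction: float = 0.2
    network: NetworkSpec = field(default_factory=NetworkSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    pretrain_steps: int = 100
    eval_points: int = 10_000
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"]["hidden_layers"] = list(self.network.hidden_layers)
        d["loss"]["terms"] = list(self.loss.terms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["network"] = NetworkSpec(**{**d.get("network", {}),
                                      "hidden_layers": tuple(
                                          d.get("network", {}).get(
                                              "hidden_layers", (16, 64, 64, 16)))})
        d["loss"] = LossConfig(**{**d.get("loss", {}),
                                  "terms": tuple(d.get("loss", {}).get(
                                      "terms", ("wasserstein", "lt", "autocorr")))})
        d["training"] = TrainConfig(**d.get("training", {}))
        return cls(**d)


@dataclass
class ExperimentResult:
    report: EvalReport
    train_report: TrainReport
    network: object
    scaler: object
    test: PathEnsemble


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def run_experiment(
    config: ExperimentConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> ExperimentResult:
    """Run the full pipeline for one configuration.

    Stages fail loudly with the stage name.  If `out_dir` is given, the
    checkpoint, train trace and evaluation report are written there along
    with the config itself.
    """
    seeds = _child_seeds(config.master_seed, 6)
    s_data, s_split, s_net, s_pre, s_train, s_eval = seeds

    stage = "generate"
    try:
        problem = problem_from_config(config.problem)
        data = euler_maruyama_simulate(problem, config.n_paths, noise=s_data)

        stage = "split"
        train_set, test_set = split_train_test(data, config.test_fraction, s_split)

        stage = "scale"
        scaler = fit_scaler(train_set)
        scaled_train = scaler.transform_ensemble(train_set)

        stage = "build"
        net = build_network(config.network, seed=s_net)

        if config.loss.simulation_terms and config.pretrain_steps > 0:
            stage = "pretrain"
            t = problem.grid.times
            net = pretrain_initialize(
                net, steps=config.pretrain_steps,
                probe_region=((float(t[0]), float(t[-1])), (-1.5, 1.5)),
                seed=s_pre)

        stage = "train"
        tc = TrainConfig(**{**asdict(config.training), "master_seed": s_train})
        net, train_report = train(net, scaled_train, config.loss, tc)

        stage = "evaluate"
        estimate = unscale_coefficients(net, scaler)
        truth = problem.coefficients
        drift_mse, diffusion_mse = coefficient_mse(
            estimate, truth, test_set, n_points=config.eval_points, seed=s_eval)
        eval_rng = np.random.default_rng(s_eval)
        initials = problem.initial_sampler.sample(test_set.n_paths, eval_rng)
        noise = BrownianDraws.sample(test_set.n_paths, problem.grid, eval_rng)
        res_mse = resampling_mse(estimate, truth, initials, noise, problem.grid)
        regen = euler_maruyama_simulate(
            SDEProblem(coefficients=estimate, initial_sampler=None,
                       grid=problem.grid),
            test_set.n_paths, noise=noise, initial_values=initials)
        mmd = signature_mmd(test_set, regen)
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    report = EvalReport(
        drift_mse=drift_mse,
        diffusion_mse=diffusion_mse,
        resampling_mse=res_mse,
        signature_mmd=mmd,
        config={
            "problem": config.problem["name"],
            "terms": "+".join(config.loss.terms),
            "n_paths": config.n_paths,
            "n_times": problem.grid.n_times,
            "eval_points": config.eval_points,
            "master_seed": config.master_seed,
            "final_epoch": train_report.final_epoch,
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_network(net, scaler, out / "checkpoint")
        train_report.to_frame().to_csv(out / "train_trace.csv", index=False)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))

    return ExperimentResult(report=report, train_report=train_report,
                            network=net, scaler=scaler, test=test_set)


def generate_fixture(kind: str, seed: int,
                     path: Optional[Union[str, Path]] = None,
                     n_paths: int = 200, n_times: int = 50) -> PathEnsemble:
    """Deterministic miniature dataset for one of the benchmark problems.

    Same coefficient formulas and parameters as the full-scale benchmarks,
    on a reduced path count and grid.  If `path` is given the ensemble is
    written there (format by extension).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    name = kind.split("_")[0].upper()
    from .sde import TimeGrid, make_benchmark_problem

    t0, t1 = {"OU": (0.0, 5.0), "CIR": (0.0, 2.0),
              "SIN1": (0.0, 2.0), "SIN2": (0.0, 2.0)}[name]
    problem = make_benchmark_problem(name, grid=TimeGrid.regular(t0, t1, n_times))
    ens = euler_maruyama_simulate(problem, n_paths, noise=seed)
    if path is not None:
        write_ensemble(ens, path)
    return ens


def reports_to_table(reports: list[EvalReport]):
    """Merge evaluation reports into a tidy frame (one row per report)."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports])
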