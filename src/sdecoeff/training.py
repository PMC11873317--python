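"""Training loop: Adam, minibatched transitions, plateau LR schedule.

The protocol is deliberately fixed across problems ("common"
hyperparameters): Adam with initial learning rate 1e-3; batches of 2^14
transitions for pseudo-likelihood terms; m = 200 freshly simulated paths
per optimizer step for simulation terms; learning-rate decay by a factor of
0.1 whenever the epoch-mean training loss has not improved by delta = 0.2
(absolute) within a patience of 10 epochs; training stops after `epochs`
epochs or when the learning rate falls below `min_lr`.

One epoch is ceil(N*(T-1) / batch_size) optimizer steps, also for losses
without a pseudo-likelihood term (which have no natural batch partition).
Randomness is organized as named child streams of a single master seed, so
identical configurations reproduce identical loss traces bit for bit.
"""

from __future__ import annotations

import time
from contextlib import nullcontext
from dataclasses import dataclass
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .losses import (LossConfig, TransitionBatch, _acf_loss_against,
                     _w1_profile, em_neg2_log_pseudolik, ensemble_acf,
                     lt_neg2_log_pseudolik, moment_loss)
from .network import CoefficientNetwork
from .optim import Adam
from .sde import BrownianDraws, PathEnsemble, SDEProblem, euler_maruyama_simulate

__all__ = ["TrainConfig", "TrainReport", "train", "closed_form_ou_mle"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.1
    plateau_delta: float = 0.2
    plateau_patience: int = 10
    epochs: int = 500
    min_lr: float = 1e-6
    master_seed: int = 0
    precision: str = "float32"   # training dtype; evaluation is float64

    def __post_init__(self):
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.learning_rate <= 0 or self.plateau_patience < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")


@dataclass
class TrainReport:
    loss_trace: np.ndarray            # epoch-mean total loss
    term_traces: dict                 # term name -> epoch-mean value
    lr_trace: np.ndarray              # learning rate per epoch (nonincreasing)
    wall_time: float
    final_epoch: int
    master_seed: int

    def to_frame(self):
        import pandas as pd

        data = {"epoch": np.arange(len(self.loss_trace)),
                "total": self.loss_trace, "lr": self.lr_trace}
        for k, v in self.term_traces.items():
            data[k] = v
        return pd.DataFrame(data)


def _seed_streams(master_seed: int, names: tuple) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def train(
    net: CoefficientNetwork,
    data: PathEnsemble,
    loss_config: LossConfig,
    train_config: TrainConfig,
) -> tuple[CoefficientNetwork, TrainReport]:
    """Optimize the coefficient network on a (scaled) training ensemble.

    `data` should already be scaled to roughly [-1, 1] (see
    `network.fit_scaler`), and the network pre-initialized with
    `pretrain_initialize` when any simulation term is configured.
    Returns the trained network (modified in place) and the full report.

    By default the loop runs in float32 (the convention of the deep-learning
    frameworks this training protocol comes from); parameters are cast back
    to float64 on return, and all evaluation is float64.
    """
    use32 = train_config.precision == "float32" and train_config.epochs > 0
    with (ad.use_dtype(np.float32) if use32 else nullcontext()):
        if use32:
            for p in net.parameters:
                p.data = p.data.astype(np.float32)
        try:
            return _train_loop(net, data, loss_config, train_config)
        finally:
            if use32:
                for p in net.parameters:
                    p.data = p.data.astype(np.float64)


def _train_loop(net, data, loss_config, train_config):
    t_start = time.time()
    n_paths, T = data.array.shape
    n_transitions = n_paths * (T - 1)
    steps_per_epoch = max(1, int(np.ceil(n_transitions / loss_config.batch_size)))
    rngs = _seed_streams(train_config.master_seed,
                         ("shuffle", "sim_noise", "sim_init"))

    scheme = loss_config.pseudolik_scheme
    sim_terms = loss_config.simulation_terms
    transitions = TransitionBatch.from_ensemble(data) if scheme else None
    pl_fn = {"em": em_neg2_log_pseudolik, "lt": lt_neg2_log_pseudolik}.get(scheme)

    # observed-side statistics are constant: compute once
    obs_sorted = np.sort(data.array, axis=0) if "wasserstein" in sim_terms else None
    rho_obs = (ensemble_acf(data.array, loss_config.K)
               if "autocorr" in sim_terms else None)
    first_col = data.array[:, 0]
    sim_problem = SDEProblem(coefficients=net, initial_sampler=None, grid=data.grid)

    opt = Adam(net.parameters, lr=train_config.learning_rate)
    lr = train_config.learning_rate
    best = np.inf
    wait = 0
    loss_trace, lr_trace = [], []
    term_traces: dict = {t: [] for t in loss_config.terms}

    epoch = 0
    for epoch in range(train_config.epochs):
        perm = (rngs["shuffle"].permutation(n_transitions)
                if scheme else None)
        epoch_total = 0.0
        epoch_terms = {t: 0.0 for t in loss_config.terms}
        for step in range(steps_per_epoch):
            total = Tensor(0.0)
            if sim_terms:
                initials = rngs["sim_init"].choice(
                    first_col, size=loss_config.m, replace=True)
                noise = BrownianDraws.sample(
                    loss_config.m, data.grid, rngs["sim_noise"])
                sim = euler_maruyama_simulate(
                    sim_problem, loss_config.m, noise=noise,
                    initial_values=initials)
                if "moment" in sim_terms:
                    v = as_tensor(moment_loss(data, sim))
                    epoch_terms["moment"] += v.item()
                    total = total + v
                if "wasserstein" in sim_terms:
                    w1 = _w1_profile(obs_sorted, sim.values)
                    v = w1.mean() + w1.max()
                    epoch_terms["wasserstein"] += v.item()
                    total = total + v
                if "autocorr" in sim_terms:
                    v = _acf_loss_against(rho_obs, sim.values, loss_config.K)
                    epoch_terms["autocorr"] += v.item()
                    total = total + v
            if scheme:
                lo = step * loss_config.batch_size
                idx = perm[lo : lo + loss_config.batch_size]
                batch = transitions.subset(idx)
                v = as_tensor(pl_fn(batch, net)).mean()
                epoch_terms[scheme] += v.item()
                total = total + loss_config.eta * v
            value = total.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_total += value

        epoch_mean = epoch_total / steps_per_epoch
        loss_trace.append(epoch_mean)
        lr_trace.append(lr)
        for t in loss_config.terms:
            term_traces[t].append(epoch_terms[t] / steps_per_epoch)

        # plateau schedule on the epoch-mean total loss (absolute threshold)
        if epoch_mean < best - train_config.plateau_delta:
            best = epoch_mean
            wait = 0
        else:
            best = min(best, epoch_mean)
            wait += 1
            if wait > train_config.plateau_patience:
                lr *= train_config.lr_decay_factor
                opt.lr = lr
                wait = 0
        if lr < train_config.min_lr:
            break

    report = TrainReport(
        loss_trace=np.asarray(loss_trace),
        term_traces={k: np.asarray(v) for k, v in term_traces.items()},
        lr_trace=np.asarray(lr_trace),
        wall_time=time.time() - t_start,
        final_epoch=epoch,
        master_seed=train_config.master_seed,
    )
    return net, report


def closed_form_ou_mle(data: PathEnsemble) -> tuple[float, float]:
    """Exact maximizer of the Euler-Maruyama pseudo-likelihood for the
    parametric Ornstein-Uhlenbeck family dX = -lambda X dt + sigma dB.

    Least squares of the increment rates dX/dt on the state gives
    lambda_hat = -slope; sigma_hat^2 is the mean of (dX - a_hat dt)^2 / dt.
    Used as an oracle in parameter-recovery tests.
    """
    vals = data.array
    dt = data.grid.dt
    x = vals[:, :-1].ravel()
    dx = np.diff(vals, axis=1).ravel()
    sxx = float(np.dot(x, x))
    if sxx == 0.0 or vals.shape[0] * (vals.shape[1] - 1) < 2 or np.ptp(x) == 0.0:
        raise ValueError("degenerate data for OU regression")
    slope = float(np.dot(x, dx / dt)) / sxx       # regression through origin
    lam_hat = -slope
    resid = dx - slope * x * dt
    sigma2_hat = float(np.mean(resid * resid / dt))
    return lam_hat, float(np.sqrt(sigma2_hat))
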