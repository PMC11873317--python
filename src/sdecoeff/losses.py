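"""Loss formulations for fitting coefficient networks to path ensembles.

Two families are implemented, plus their weighted hybrids:

* simulation-based penalties, comparing the observed ensemble against m
  paths simulated from the candidate coefficients — timepoint-wise moment
  matching, a timepoint-wise Wasserstein-1 penalty (mean plus max over
  timepoints), and ensemble-mean lag-autocorrelation matching;
* Gaussian transition pseudo-likelihoods induced by the Euler-Maruyama and
  Lie-Trotter discretization schemes, averaged over observed consecutive
  transitions as -2 log likelihood.

The headline hybrid objective is  L^W + eta * L^LT + L^AC.

Every loss is differentiable with respect to the coefficient-network
parameters: the Wasserstein term through the sorting permutation (exact 1-D
optimal transport is a quantile coupling), the autocorrelation term through
the Pearson formula, and the Lie-Trotter term through an exact forward-mode
derivative of the drift head.  Functions return a plain float when no input
tracks gradients, and an autodiff tensor otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .autodiff import Tensor, as_tensor, no_value
from .sde import (BrownianDraws, PathEnsemble, SDEProblem,
                  euler_maruyama_simulate)

__all__ = [
    "TransitionBatch",
    "LossConfig",
    "SummaryStatistics",
    "moment_loss",
    "wasserstein1_empirical",
    "wasserstein_loss",
    "lag_autocorrelation",
    "autocorrelation_loss",
    "ensemble_acf",
    "em_neg2_log_pseudolik",
    "lt_neg2_log_pseudolik",
    "pseudolik_loss",
    "hybrid_loss",
    "summary_statistics",
]

_B2_FLOOR = 1e-8  # floor on b^2 inside pseudo-likelihoods (Softplus underflow)

SIMULATION_TERMS = ("moment", "wasserstein", "autocorr")
PSEUDOLIK_TERMS = ("em", "lt")
ALL_TERMS = SIMULATION_TERMS + PSEUDOLIK_TERMS


@dataclass
class TransitionBatch:
    """Flattened consecutive observations (t, X_t, dt, X_{t+dt})."""

    t: np.ndarray
    x: np.ndarray
    dt: np.ndarray
    x_next: np.ndarray

    def __post_init__(self):
        for name in ("t", "x", "dt", "x_next"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.t.size
        if not (self.x.size == self.dt.size == self.x_next.size == n):
            raise ValueError("transition batch fields must have equal length")
        if np.any(self.dt <= 0):
            raise ValueError("time steps must be positive")

    @classmethod
    def from_ensemble(cls, ensemble: PathEnsemble) -> "TransitionBatch":
        """All N*(T-1) consecutive transitions; column k pairs with k+1."""
        vals = ensemble.array
        times = ensemble.grid.times
        n, T = vals.shape
        t = np.broadcast_to(times[:-1], (n, T - 1)).ravel()
        dt = np.broadcast_to(np.diff(times), (n, T - 1)).ravel()
        return cls(t=t, x=vals[:, :-1].ravel(), dt=dt, x_next=vals[:, 1:].ravel())

    def subset(self, idx: np.ndarray) -> "TransitionBatch":
        return TransitionBatch(self.t[idx], self.x[idx], self.dt[idx], self.x_next[idx])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class LossConfig:
    """Which loss terms to combine, and their shared hyperparameters.

    eta scales the pseudo-likelihood term only; m is the number of simulated
    paths per loss evaluation; K the autocorrelation lag cut-off; batch_size
    the transition minibatch size for pseudo-likelihood terms.
    """

    terms: tuple = ("wasserstein", "lt", "autocorr")
    eta: float = 10.0
    m: int = 200
    K: int = 10
    batch_size: int = 2 ** 14

    def __post_init__(self):
        self.terms = tuple(self.terms)
        unknown = set(self.terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown loss terms {sorted(unknown)}")
        if not self.terms:
            raise ValueError("at least one loss term must be selected")
        if "em" in self.terms and "lt" in self.terms:
            raise ValueError("select at most one pseudo-likelihood scheme")
        if self.eta < 0 or self.m < 1 or self.K < 1 or self.batch_size < 1:
            raise ValueError("invalid loss hyperparameters")

    @property
    def simulation_terms(self) -> tuple:
        return tuple(t for t in self.terms if t in SIMULATION_TERMS)

    @property
    def pseudolik_scheme(self) -> Optional[str]:
        for t in self.terms:
            if t in PSEUDOLIK_TERMS:
                return t
        return None


@dataclass
class SummaryStatistics:
    """Timepoint-wise summary statistics of one (or a pair of) ensembles."""

    mean_per_timepoint: np.ndarray
    var_per_timepoint: np.ndarray
    w1_per_timepoint: Optional[np.ndarray] = None
    acf_profile: Optional[np.ndarray] = None


def _check_grids(a: PathEnsemble, b: PathEnsemble) -> None:
    if a.grid.n_times != b.grid.n_times or not np.allclose(
        a.grid.times, b.grid.times, rtol=0, atol=1e-12
    ):
        raise ValueError("ensembles are on different time grids")


def _finish(value: Tensor) -> Union[float, Tensor]:
    return value if value.requires_grad else float(value.data)


# ------------------------------------------------------------------ moments

def moment_loss(observed: PathEnsemble, simulated: PathEnsemble):
    """Squared timepoint-wise mean and (unbiased) variance discrepancies."""
    _check_grids(observed, simulated)
    obs = as_tensor(observed.values)
    sim = as_tensor(simulated.values)
    dm = obs.mean(axis=0) - sim.mean(axis=0)
    dv = obs.var(axis=0, ddof=1) - sim.var(axis=0, ddof=1)
    return _finish((dm * dm).sum() + (dv * dv).sum())


# -------------------------------------------------------------- Wasserstein

def _quantile_coupling(n: int, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interval weights and order-statistic indices for exact 1-D W1.

    The empirical quantile functions are step functions with breakpoints at
    i/n and j/m; on the merged grid each interval maps to one order statistic
    of each sample.  Depends only on the sample sizes.
    """
    edges = np.union1d(np.arange(1, n + 1) / n, np.arange(1, m + 1) / m)
    lower = np.concatenate(([0.0], edges[:-1]))
    w = edges - lower
    mid = 0.5 * (edges + lower)
    iu = np.minimum((mid * n).astype(int), n - 1)
    iv = np.minimum((mid * m).astype(int), m - 1)
    return w, iu, iv


def wasserstein1_empirical(u, v):
    """Exact W1 between two empirical measures on the real line.

    Equal sizes reduce to the mean absolute difference of sorted samples;
    unequal sizes integrate |F_u^{-1} - F_v^{-1}| over the merged grid of
    order-statistic levels.  Differentiable in the sample values via the
    sorting permutation.
    """
    ut, vt = as_tensor(u), as_tensor(v)
    if ut.size == 0 or vt.size == 0:
        raise ValueError("empty sample in Wasserstein distance")
    us, vs = ut.sort(axis=0), vt.sort(axis=0)
    n, m = ut.size, vt.size
    if n == m:
        return _finish((us - vs).abs().mean())
    w, iu, iv = _quantile_coupling(n, m)
    return _finish(((us[iu] - vs[iv]).abs() * Tensor(w)).sum())


def _w1_profile(obs_sorted: np.ndarray, sim) -> Tensor:
    """Per-timepoint W1 against pre-sorted observed columns (constant side)."""
    sim = as_tensor(sim)
    ss_ = sim.sort(axis=0)
    n, m = obs_sorted.shape[0], sim.shape[0]
    if n == m:
        return (Tensor(obs_sorted) - ss_).abs().mean(axis=0)
    w, iu, iv = _quantile_coupling(n, m)
    diff = (Tensor(obs_sorted[iu, :]) - ss_[iv, :]).abs()
    return (diff * Tensor(w[:, None])).sum(axis=0)


def wasserstein_loss(observed: PathEnsemble, simulated: PathEnsemble):
    """Mean plus max over timepoints of the per-timepoint W1 distance."""
    _check_grids(observed, simulated)
    obs_sorted = np.sort(observed.array, axis=0)
    w1 = _w1_profile(obs_sorted, simulated.values)
    return _finish(w1.mean() + w1.max())


# ---------------------------------------------------------- autocorrelation

def lag_autocorrelation(path, k: int) -> float:
    """Pearson correlation of the pairs (x_j, x_{j+k}) for 1 <= j < T-k.

    Note the pairing range excludes the final observation (the upper limit
    is strict), matching the estimator used by the autocorrelation loss.
    """
    x = np.asarray(path, dtype=np.float64)
    T = x.size
    if k < 1 or T - k < 3:
        raise ValueError("need T - k >= 3 for a lag-k autocorrelation")
    a = x[: T - k - 1]
    b = x[k : T - 1]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("constant path over the pairing range")
    return float(np.corrcoef(a, b)[0, 1])


def _ensemble_acf_tensor(values, K: int, context: str = "") -> list:
    """Per-lag ensemble-mean autocorrelations, differentiable.

    Zero-variance paths are excluded from the mean at the affected lag; a
    lag with no valid path contributes a detached zero (warned).
    """
    vals = as_tensor(values)
    arr = vals.data
    _, T = arr.shape
    out = []
    for k in range(1, K + 1):
        a = vals[:, : T - k - 1]
        b = vals[:, k : T - 1]
        ca = a - a.mean(axis=1, keepdims=True)
        cb = b - b.mean(axis=1, keepdims=True)
        va = (ca * ca).sum(axis=1)
        vb = (cb * cb).sum(axis=1)
        valid = np.flatnonzero((va.data > 0) & (vb.data > 0))
        if valid.size == 0:
            warnings.warn(
                f"all paths constant at lag {k}{context}; lag excluded from loss"
            )
            out.append(Tensor(0.0))
            continue
        if valid.size < arr.shape[0]:
            ca, cb = ca[valid, :], cb[valid, :]
            va, vb = va[valid], vb[valid]
        r = (ca * cb).sum(axis=1) / (va.sqrt() * vb.sqrt())
        out.append(r.mean())
    return out


def ensemble_acf(arr: np.ndarray, K: int) -> np.ndarray:
    """Ensemble-mean lag-1..K autocorrelations of an ndarray ensemble.

    Fast numpy counterpart of the differentiable estimator; zero-variance
    paths are excluded per lag, an all-constant lag yields 0 with a warning.
    """
    arr = np.asarray(arr, dtype=np.float64)
    _, T = arr.shape
    out = np.empty(K)
    for k in range(1, K + 1):
        a = arr[:, : T - k - 1]
        b = arr[:, k : T - 1]
        ca = a - a.mean(axis=1, keepdims=True)
        cb = b - b.mean(axis=1, keepdims=True)
        va = (ca * ca).sum(axis=1)
        vb = (cb * cb).sum(axis=1)
        valid = (va > 0) & (vb > 0)
        if not valid.any():
            warnings.warn(f"all paths constant at lag {k}; lag excluded from loss")
            out[k - 1] = 0.0
            continue
        r = (ca[valid] * cb[valid]).sum(axis=1) / np.sqrt(va[valid] * vb[valid])
        out[k - 1] = r.mean()
    return out


def _acf_loss_against(rho_obs: np.ndarray, sim, K: int):
    rho_sim = _ensemble_acf_tensor(sim, K, " in simulated ensemble")
    total = Tensor(0.0)
    for ro, rs in zip(rho_obs, rho_sim):
        d = rs - float(ro)
        total = total + d * d
    return total


def autocorrelation_loss(observed: PathEnsemble, simulated: PathEnsemble, K: int):
    """Sum over lags 1..K of squared differences of ensemble-mean lag
    autocorrelations between the observed and simulated ensembles."""
    _check_grids(observed, simulated)
    T = observed.n_times
    if K >= T - 2:
        raise ValueError(f"lag cut-off K={K} too large for T={T}")
    rho_obs = ensemble_acf(observed.array, K)
    return _finish(_acf_loss_against(rho_obs, simulated.values, K))


# --------------------------------------------------------- pseudo-likelihoods

def _floored_b2(b) -> Tensor:
    b = as_tensor(b)
    b2 = (b * b).maximum(_B2_FLOOR)
    if np.any(no_value(b2) <= 0):
        bad = np.flatnonzero(no_value(b2) <= 0)
        raise FloatingPointError(f"nonpositive diffusion variance at indices {bad[:10]}")
    return b2


def em_neg2_log_pseudolik(batch: TransitionBatch, coeffs):
    """-2 log of the Euler-Maruyama Gaussian transition pseudo-likelihood:

        log(2 pi b^2 dt) + (x' - x - a dt)^2 / (b^2 dt)
    """
    a = as_tensor(coeffs.drift(batch.t, batch.x))
    b2 = _floored_b2(coeffs.diffusion(batch.t, batch.x))
    dt = Tensor(batch.dt)
    scale = b2 * dt
    resid = Tensor(batch.x_next) - Tensor(batch.x) - a * dt
    out = (scale * (2.0 * np.pi)).log() + (resid * resid) / scale
    return out if out.requires_grad else out.data


def lt_neg2_log_pseudolik(batch: TransitionBatch, coeffs):
    """-2 log of the Lie-Trotter splitting pseudo-likelihood:

        log(b^2 dt) + (x' - x - a dt - (dt^2/2) a d_x a)^2 / (b^2 dt)

    The scheme refines the drift part of the transition mean with a
    second-order term; its normalizing constant, as used here, drops the
    2 pi that the Euler-Maruyama expression carries, so with a state-constant
    drift the two differ by exactly -log(2 pi).
    """
    if hasattr(coeffs, "full_evaluation"):
        a, b, da = coeffs.full_evaluation(batch.t, batch.x)
    else:
        a = coeffs.drift(batch.t, batch.x)
        b = coeffs.diffusion(batch.t, batch.x)
        da = coeffs.drift_x_derivative(batch.t, batch.x)
    a, da = as_tensor(a), as_tensor(da)
    b2 = _floored_b2(b)
    dt = Tensor(batch.dt)
    scale = b2 * dt
    resid = (Tensor(batch.x_next) - Tensor(batch.x) - a * dt
             - (dt * dt) * 0.5 * (a * da))
    out = scale.log() + (resid * resid) / scale
    return out if out.requires_grad else out.data


def pseudolik_loss(data: PathEnsemble, coeffs, scheme: str,
                   batch: Optional[np.ndarray] = None):
    """Average -2 log pseudo-likelihood over (a subset of) all transitions."""
    if scheme not in PSEUDOLIK_TERMS:
        raise ValueError("scheme must be 'em' or 'lt'")
    transitions = TransitionBatch.from_ensemble(data)
    if batch is not None:
        transitions = transitions.subset(np.asarray(batch))
    fn = em_neg2_log_pseudolik if scheme == "em" else lt_neg2_log_pseudolik
    vals = fn(transitions, coeffs)
    return _finish(as_tensor(vals).mean())


# ------------------------------------------------------------------ hybrids

def simulate_for_loss(
    data: PathEnsemble,
    coeffs,
    m: int,
    noise: BrownianDraws,
    initial_values: Optional[np.ndarray] = None,
    initial_seed: int = 0,
) -> PathEnsemble:
    """One m-path simulation from the candidate field on the data grid.

    Initial values are bootstrap-resampled (with replacement) from the
    observed first column unless given explicitly.
    """
    if initial_values is None:
        rng = np.random.default_rng(initial_seed)
        first = data.array[:, 0]
        initial_values = rng.choice(first, size=m, replace=True)
    problem = SDEProblem(
        coefficients=coeffs,
        initial_sampler=None,  # unused: initials are explicit
        grid=data.grid,
    )
    return euler_maruyama_simulate(problem, m, noise=noise,
                                   initial_values=initial_values)


def hybrid_loss(
    data: PathEnsemble,
    coeffs,
    config: LossConfig,
    simulator_noise: Optional[BrownianDraws] = None,
    initial_values: Optional[np.ndarray] = None,
    batch: Optional[np.ndarray] = None,
    initial_seed: int = 0,
):
    """Weighted sum of the configured loss terms.

    All simulation-based terms share a single m-path simulation; the
    pseudo-likelihood term is multiplied by eta.  With the default
    configuration this is the hybrid Lie-Trotter objective
    L^W + eta L^LT + L^AC.
    """
    total = Tensor(0.0)
    if config.simulation_terms:
        if simulator_noise is None:
            raise ValueError("simulation terms need Brownian draws")
        sim = simulate_for_loss(data, coeffs, config.m, simulator_noise,
                                initial_values, initial_seed)
        if "moment" in config.terms:
            total = total + as_tensor(moment_loss(data, sim))
        if "wasserstein" in config.terms:
            total = total + as_tensor(wasserstein_loss(data, sim))
        if "autocorr" in config.terms:
            total = total + as_tensor(autocorrelation_loss(data, sim, config.K))
    scheme = config.pseudolik_scheme
    if scheme is not None:
        total = total + config.eta * as_tensor(
            pseudolik_loss(data, coeffs, scheme, batch)
        )
    return _finish(total)


# ------------------------------------------------------------------ summary

def summary_statistics(
    observed: PathEnsemble,
    simulated: Optional[PathEnsemble] = None,
    K: Optional[int] = None,
) -> SummaryStatistics:
    """Plain-numpy summary of an ensemble (optionally versus a second one)."""
    arr = observed.array
    w1 = None
    if simulated is not None:
        _check_grids(observed, simulated)
        w1 = np.array([
            wasserstein1_empirical(arr[:, k], simulated.array[:, k])
            for k in range(arr.shape[1])
        ])
    acf = None
    if K is not None:
        acf = np.array([no_value(r) for r in _ensemble_acf_tensor(arr, K)])
    return SummaryStatistics(
        mean_per_timepoint=arr.mean(axis=0),
        var_per_timepoint=arr.var(axis=0, ddof=1),
        w1_per_timepoint=w1,
        acf_profile=acf,
    )
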