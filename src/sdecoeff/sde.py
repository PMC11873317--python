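"""Core SDE data types, the Euler-Maruyama simulator and benchmark problems.

The package works with scalar Itô equations

    dX_t = a(t, X_t) dt + b(t, X_t) dB_t

observed as ensembles of N independent trajectories on a shared equidistant
time grid.  Four benchmark processes with known coefficients are provided:
Ornstein-Uhlenbeck (OU), Cox-Ingersoll-Ross (CIR), an unstable-sine problem
(SIN1) with state-dependent diffusion, and a multi-modal sine problem (SIN2)
with time-dependent wells of attraction and constant diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor, no_value

__all__ = [
    "TimeGrid",
    "PathEnsemble",
    "CoefficientField",
    "BrownianDraws",
    "InitialDistribution",
    "SDEProblem",
    "SimulationDivergedError",
    "euler_maruyama_simulate",
    "make_benchmark_problem",
    "sample_initial",
    "split_train_test",
    "BENCHMARK_NAMES",
]

_EQUIDISTANCE_RTOL = 1e-9


class SimulationDivergedError(RuntimeError):
    """Raised when an Euler-Maruyama step produces a non-finite state."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"simulation diverged at step {step}")


@dataclass(frozen=True)
class TimeGrid:
    """Equidistant observation times t_0 < t_1 < ... < t_{T-1}."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least two points")
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            raise ValueError("time grid must be strictly increasing")
        dt = (t[-1] - t[0]) / (t.size - 1)
        if np.max(np.abs(diffs - dt)) > _EQUIDISTANCE_RTOL * dt:
            raise ValueError("time grid is not equidistant")

    @classmethod
    def regular(cls, t0: float, t1: float, n: int) -> "TimeGrid":
        return cls(np.linspace(t0, t1, n))

    @property
    def dt(self) -> float:
        return float((self.times[-1] - self.times[0]) / (self.times.size - 1))

    @property
    def n_times(self) -> int:
        return self.times.size

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PathEnsemble:
    """N trajectories observed at the grid's T timepoints (values: N x T).

    `values` is normally a float64 ndarray; when an ensemble is produced by a
    differentiable simulation it is an autodiff Tensor instead, and `array`
    exposes the underlying numbers either way.
    """

    values: Union[np.ndarray, Tensor]
    grid: TimeGrid

    def __post_init__(self):
        arr = no_value(self.values)
        if not isinstance(self.values, Tensor):
            self.values = np.asarray(self.values, dtype=np.float64)
            arr = self.values
        if arr.ndim != 2:
            raise ValueError("ensemble values must be an N x T matrix")
        if arr.shape[1] != self.grid.n_times:
            raise ValueError(
                f"ensemble has {arr.shape[1]} columns but grid has "
                f"{self.grid.n_times} timepoints"
            )
        if arr.shape[0] < 1:
            raise ValueError("ensemble needs at least one path")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ensemble contains non-finite values")

    @property
    def array(self) -> np.ndarray:
        return no_value(self.values)

    @property
    def n_paths(self) -> int:
        return self.array.shape[0]

    @property
    def n_times(self) -> int:
        return self.array.shape[1]


@dataclass
class CoefficientField:
    """A drift/diffusion pair (t, x) -> real; diffusion is nonnegative.

    Both callables must accept numpy inputs with broadcasting; trainable
    fields (see `network.CoefficientNetwork`) also accept autodiff tensors.
    """

    drift: Callable
    diffusion: Callable

    def drift_x_derivative(self, t, x):
        """d/dx of the drift; central finite difference by default.

        Trainable fields override this with an exact forward-mode derivative.
        """
        h = 1e-5 * (1.0 + np.abs(np.asarray(x, dtype=np.float64)))
        return (no_value(self.drift(t, x + h)) - no_value(self.drift(t, x - h))) / (2 * h)


@dataclass(frozen=True)
class BrownianDraws:
    """Pre-drawn Brownian increments, one row per path, entries ~ N(0, dt).

    Pre-drawing lets the identical noise be replayed under different
    coefficient fields, which the shared-noise resampling metric requires.
    """

    increments: np.ndarray

    @classmethod
    def sample(cls, n_paths: int, grid: TimeGrid, seed_or_rng) -> "BrownianDraws":
        rng = np.random.default_rng(seed_or_rng)
        inc = rng.normal(0.0, np.sqrt(grid.dt), size=(n_paths, grid.n_times - 1))
        return cls(increments=inc)

    @property
    def n_paths(self) -> int:
        return self.increments.shape[0]


@dataclass(frozen=True)
class InitialDistribution:
    """Initial-value law: normal(mean, sd), exponential(rate) or point(value)."""

    kind: str
    params: tuple

    @classmethod
    def normal(cls, mean: float, sd: float) -> "InitialDistribution":
        if sd <= 0:
            raise ValueError("sd must be positive")
        return cls("normal", (float(mean), float(sd)))

    @classmethod
    def exponential(cls, rate: float) -> "InitialDistribution":
        if rate <= 0:
            raise ValueError("rate must be positive")
        return cls("exponential", (float(rate),))

    @classmethod
    def point(cls, value: float) -> "InitialDistribution":
        return cls("point", (float(value),))

    def sample(self, n: int, seed_or_rng) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed_or_rng)
        if self.kind == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size=n)
        if self.kind == "exponential":
            (rate,) = self.params
            return rng.exponential(1.0 / rate, size=n)
        if self.kind == "point":
            (value,) = self.params
            return np.full(n, value, dtype=np.float64)
        raise ValueError(f"unknown initial distribution kind {self.kind!r}")


def sample_initial(spec: InitialDistribution, n: int, seed) -> np.ndarray:
    """Draw n independent initial values from the given distribution spec."""
    return spec.sample(n, seed)


@dataclass
class SDEProblem:
    """Coefficients + initial law + time grid defining one benchmark."""

    coefficients: CoefficientField
    initial_sampler: InitialDistribution
    grid: TimeGrid
    params: dict = field(default_factory=dict)
    name: str = ""


def euler_maruyama_simulate(
    problem: SDEProblem,
    n_paths: int,
    noise: Union[BrownianDraws, int, np.random.Generator, None] = None,
    initial_values: Optional[np.ndarray] = None,
) -> PathEnsemble:
    """Simulate n_paths trajectories with the Euler-Maruyama scheme.

    The forward recursion is

        X_{k+1} = X_k + a(t_k, X_k) dt + b(t_k, X_k) (B_{k+1} - B_k)

    applied columnwise to the whole ensemble.  When the coefficient field is
    a trainable network the recursion is built from autodiff tensors, so loss
    gradients flow back through the entire unrolled simulation.  `noise` may
    be pre-drawn `BrownianDraws` (replayable across coefficient fields) or a
    seed / generator from which increments are drawn.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    grid = problem.grid
    if isinstance(noise, BrownianDraws):
        draws = noise
        rng = None
    else:
        rng = np.random.default_rng(noise)
        draws = BrownianDraws.sample(n_paths, grid, rng)
    if draws.increments.shape != (n_paths, grid.n_times - 1):
        raise ValueError(
            f"noise shape {draws.increments.shape} does not match "
            f"({n_paths}, {grid.n_times - 1})"
        )
    if initial_values is None:
        if rng is None:
            raise ValueError(
                "initial_values is required when noise is pre-drawn; pass them "
                "explicitly or give a seed/generator as noise"
            )
        x = problem.initial_sampler.sample(n_paths, rng)
    else:
        x = np.asarray(initial_values, dtype=np.float64)
        if x.shape != (n_paths,):
            raise ValueError("initial_values must have length n_paths")

    coeffs = problem.coefficients
    fused = getattr(coeffs, "drift_and_diffusion", None)
    times = grid.times
    dt = grid.dt
    columns = [x]
    for k in range(grid.n_times - 1):
        if fused is not None:
            a, b = fused(times[k], x)
        else:
            a = coeffs.drift(times[k], x)
            b = coeffs.diffusion(times[k], x)
        x = x + a * dt + b * draws.increments[:, k]
        if not np.all(np.isfinite(no_value(x))):
            raise SimulationDivergedError(k + 1)
        columns.append(x)

    if any(isinstance(c, Tensor) for c in columns):
        from .autodiff import stack

        values = stack(columns, axis=1)
    else:
        values = np.stack(columns, axis=1)
    return PathEnsemble(values=values, grid=grid)


# --------------------------------------------------------------- benchmarks

BENCHMARK_NAMES = ("OU", "CIR", "SIN1", "SIN2")

_DEFAULT_PARAMS = {
    "OU": {"lambda": 2.0, "sigma": 2.0},
    "CIR": {"alpha": 2.0, "mu": 4.0, "sigma": 2.0},
    "SIN1": {"alpha": 15.0, "beta": 1.0 / (2 * np.pi), "gamma": 2.0, "sigma": 1.0},
    "SIN2": {"alpha": 15.0, "beta": 1.0 / (2 * np.pi), "gamma": 2.0, "sigma": 1.0},
}

_DEFAULT_INITIALS = {
    "OU": InitialDistribution.normal(0.0, 3.0),
    "CIR": InitialDistribution.exponential(0.5),
    "SIN1": InitialDistribution.normal(0.0, 3.0),
    "SIN2": InitialDistribution.normal(0.0, 3.0),
}

_DEFAULT_SPANS = {"OU": (0.0, 5.0), "CIR": (0.0, 2.0), "SIN1": (0.0, 2.0), "SIN2": (0.0, 2.0)}


def _require(params: dict, name: str, keys: Sequence[str]) -> dict:
    got = set(params)
    want = set(keys)
    if got != want:
        raise ValueError(f"{name} requires parameters {sorted(want)}, got {sorted(got)}")
    for k in keys:
        if params[k] <= 0:
            raise ValueError(f"{name} parameter {k} must be positive")
    return {k: float(params[k]) for k in keys}


def make_benchmark_problem(
    name: str,
    params: Optional[dict] = None,
    grid: Optional[TimeGrid] = None,
    initial: Optional[InitialDistribution] = None,
) -> SDEProblem:
    """Construct one of the named benchmark SDE problems.

    OU:   dX = -lambda X dt + sigma dB
    CIR:  dX = -alpha (X - mu) dt + sigma sqrt(X) dB
    SIN1: dX = (alpha sin(beta X) - gamma X) dt + sigma (1 + |X|) dB
    SIN2: dX = (-alpha sin(X) + beta sin(t) - gamma X) dt + sigma dB

    Under Euler-Maruyama the CIR state can make small negative excursions
    (discretization artifacts; the true process is nonnegative), so its
    diffusion is evaluated as sigma * sqrt(max(x, 0)).
    """
    if name not in BENCHMARK_NAMES:
        raise ValueError(f"unknown benchmark {name!r}; expected one of {BENCHMARK_NAMES}")
    p = dict(_DEFAULT_PARAMS[name] if params is None else params)

    if name == "OU":
        p = _require(p, name, ["lambda", "sigma"])
        lam, sig = p["lambda"], p["sigma"]
        coeffs = CoefficientField(
            drift=lambda t, x, lam=lam: -lam * x,
            diffusion=lambda t, x, sig=sig: sig * np.ones_like(np.asarray(x, dtype=np.float64)),
        )
    elif name == "CIR":
        p = _require(p, name, ["alpha", "mu", "sigma"])
        al, mu, sig = p["alpha"], p["mu"], p["sigma"]
        coeffs = CoefficientField(
            drift=lambda t, x, al=al, mu=mu: -al * (x - mu),
            diffusion=lambda t, x, sig=sig: sig * np.sqrt(np.maximum(x, 0.0)),
        )
    elif name == "SIN1":
        p = _require(p, name, ["alpha", "beta", "gamma", "sigma"])
        al, be, ga, sig = p["alpha"], p["beta"], p["gamma"], p["sigma"]
        coeffs = CoefficientField(
            drift=lambda t, x, al=al, be=be, ga=ga: al * np.sin(be * x) - ga * x,
            diffusion=lambda t, x, sig=sig: sig * (1.0 + np.abs(x)),
        )
    else:  # SIN2
        p = _require(p, name, ["alpha", "beta", "gamma", "sigma"])
        al, be, ga, sig = p["alpha"], p["beta"], p["gamma"], p["sigma"]
        coeffs = CoefficientField(
            drift=lambda t, x, al=al, be=be, ga=ga: (
                -al * np.sin(x) + be * np.sin(t) - ga * x
            ),
            diffusion=lambda t, x, sig=sig: sig * np.ones_like(np.asarray(x, dtype=np.float64)),
        )

    if grid is None:
        t0, t1 = _DEFAULT_SPANS[name]
        grid = TimeGrid.regular(t0, t1, 400)
    if initial is None:
        initial = _DEFAULT_INITIALS[name]
    return SDEProblem(coefficients=coeffs, initial_sampler=initial, grid=grid,
                      params=p, name=name)


def split_train_test(
    ensemble: PathEnsemble, test_fraction: float, seed
) -> tuple[PathEnsemble, PathEnsemble]:
    """Split whole paths into disjoint train/test ensembles.

    The split is over path indices only — a path is never cut in time — and
    the partition is a deterministic function of the seed.
    """
    n = ensemble.n_paths
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n_test >= n:
        raise ValueError("split leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    arr = ensemble.array
    return (
        PathEnsemble(values=arr[train_idx], grid=ensemble.grid),
        PathEnsemble(values=arr[test_idx], grid=ensemble.grid),
    )
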