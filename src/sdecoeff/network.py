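"""The trainable coefficient field: a small fully-connected network.

One network represents both unknown coefficient functions.  It maps a
phase-space point, fed as an (x, t) pair, through four hidden layers of
16, 64, 64 and 16 Swish units to two output heads: a linear head for the
drift a(t, x) and a Softplus head for the diffusion b(t, x) > 0.

Training happens on state values scaled to [-1, 1] by the maximal absolute
value of the training data; `unscale_coefficients` converts a network fitted
in scaled space back to original units via the Itô change of variables
Y = sX, under which

    a_orig(t, x) = s * a_net(t, x / s),   b_orig(t, x) = s * b_net(t, x / s).

Time is not rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_value
from .optim import Adam
from .sde import CoefficientField, PathEnsemble

__all__ = [
    "NetworkSpec",
    "DataScaler",
    "CoefficientNetwork",
    "build_network",
    "fit_scaler",
    "unscale_coefficients",
    "pretrain_initialize",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkSpec:
    hidden_layers: tuple = (16, 64, 64, 16)
    activation: str = "swish"
    drift_head_activation: str = "linear"
    diffusion_head_activation: str = "softplus"
    input_dim: int = 2

    def __post_init__(self):
        if len(self.hidden_layers) < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden_layers must be positive ints")
        if self.activation != "swish":
            raise ValueError("only swish hidden activation is supported")
        if self.drift_head_activation != "linear":
            raise ValueError("drift head must be linear")
        if self.diffusion_head_activation != "softplus":
            raise ValueError("diffusion head must be softplus")
        if self.input_dim != 2:
            raise ValueError("input dimension is (x, t), i.e. 2")
        object.__setattr__(self, "hidden_layers", tuple(int(h) for h in self.hidden_layers))


@dataclass(frozen=True)
class DataScaler:
    """State scaling by maximal absolute value of the training data."""

    scale: float
    time_range: tuple = (0.0, 1.0)

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("scale must be a positive finite real")

    def transform(self, x):
        return np.asarray(x, dtype=np.float64) / self.scale

    def inverse(self, x):
        return np.asarray(x, dtype=np.float64) * self.scale

    def transform_ensemble(self, ensemble: PathEnsemble) -> PathEnsemble:
        return PathEnsemble(values=ensemble.array / self.scale, grid=ensemble.grid)


def fit_scaler(train: PathEnsemble) -> DataScaler:
    """Fit max-abs scaling on the training ensemble only.

    Test data transformed with this scaler may exceed [-1, 1]; that is
    intended (no clamping).
    """
    s = float(np.max(np.abs(train.array)))
    if s == 0.0:
        raise ValueError("cannot fit a scaler on all-zero data")
    t = train.grid.times
    return DataScaler(scale=s, time_range=(float(t[0]), float(t[-1])))


class CoefficientNetwork:
    """Trainable drift/diffusion field with shared hidden layers.

    Satisfies the CoefficientField protocol (`drift`, `diffusion`,
    `drift_x_derivative`) and additionally exposes fused evaluations used in
    the training losses.  All methods accept numpy arrays or autodiff
    tensors for the state; outputs are tensors tracking the parameters.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = [spec.input_dim, *spec.hidden_layers]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights.append(Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True))
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))
        last = sizes[-1]
        self.w_drift = Tensor(_glorot(rng, last, 1), requires_grad=True)
        self.b_drift = Tensor(np.zeros(1), requires_grad=True)
        self.w_diff = Tensor(_glorot(rng, last, 1), requires_grad=True)
        self.b_diff = Tensor(np.zeros(1), requires_grad=True)

    # ------------------------------------------------------------ parameters
    @property
    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases,
                self.w_drift, self.b_drift, self.w_diff, self.b_diff]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    # --------------------------------------------------------------- forward
    def _input(self, t, x):
        """Assemble the (n, 2) input matrix in (x, t) order."""
        if isinstance(x, Tensor):
            n = x.data.shape[0]
            t_col = np.broadcast_to(np.asarray(t, dtype=np.float64), (n,))
            return ad.stack([x, Tensor(t_col)], axis=1)
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        t_col = np.broadcast_to(np.asarray(t, dtype=np.float64), x.shape)
        return Tensor(np.stack([x, t_col], axis=1))

    def _hidden(self, inp: Tensor) -> Tensor:
        h = inp
        for w, b in zip(self.weights, self.biases):
            h = ad.linear(h, w, b).swish()
        return h

    def _hidden_with_tangent(self, inp: Tensor) -> tuple[Tensor, Tensor]:
        """Forward pass plus the forward-mode tangent d(hidden)/dx.

        The tangent starts as the unit direction along the state input and is
        propagated layerwise with the exact swish derivative; every node has
        a closed-form backward, so reverse mode through the tangent (needed
        to train the Lie-Trotter drift-derivative term) is exact.
        """
        h = inp
        n = inp.data.shape[0]
        u = Tensor(np.stack([np.ones(n), np.zeros(n)], axis=1))  # d(x,t)/dx
        for w, b in zip(self.weights, self.biases):
            z = ad.linear(h, w, b)
            h = z.swish()
            u = (u @ w) * z.swish_prime()
        return h, u

    def drift_and_diffusion(self, t, x) -> tuple[Tensor, Tensor]:
        out = self._fused_pair(t, x)
        return out[:, 0], out[:, 1]

    def _fused_pair(self, t, x) -> Tensor:
        """Whole forward pass as one tape node returning (n, 2) = [a, b].

        Hand-written backward (standard MLP backpropagation with the closed
        form swish derivative); equivalent to composing the primitive ops
        but with far less tape overhead, which matters inside the unrolled
        Euler-Maruyama simulation.  Verified against the composed
        implementation in the test suite.
        """
        from scipy.special import expit

        x_tensor = x if isinstance(x, Tensor) else None
        xd = x.data if x_tensor is not None else np.atleast_1d(
            np.asarray(x, dtype=np.float64))
        t_col = np.broadcast_to(np.asarray(t, dtype=np.float64), xd.shape)
        inp = np.stack([xd, t_col], axis=1).astype(
            self.weights[0].data.dtype, copy=False)
        hs = [inp]
        zs, sigs = [], []
        h = inp
        for w, b in zip(self.weights, self.biases):
            z = h @ w.data + b.data
            s = expit(z)
            h = z * s
            zs.append(z); sigs.append(s); hs.append(h)
        a = h @ self.w_drift.data + self.b_drift.data
        zb = h @ self.w_diff.data + self.b_diff.data
        out_data = np.concatenate([a, np.logaddexp(0.0, zb)], axis=1)
        parents = tuple(self.parameters) + (
            (x_tensor,) if x_tensor is not None else ())
        out = Tensor(out_data, _parents=parents)
        if out.requires_grad:
            def _bw(g, self=self, hs=hs, zs=zs, sigs=sigs, zb=zb,
                    x_tensor=x_tensor):
                ga = g[:, :1]
                gb = g[:, 1:] * expit(zb)
                self.w_drift._accumulate(hs[-1].T @ ga)
                self.b_drift._accumulate(ga.sum(axis=0))
                self.w_diff._accumulate(hs[-1].T @ gb)
                self.b_diff._accumulate(gb.sum(axis=0))
                gh = ga @ self.w_drift.data.T + gb @ self.w_diff.data.T
                for i in reversed(range(len(self.weights))):
                    z, s = zs[i], sigs[i]
                    gz = gh * (s * (1.0 + z * (1.0 - s)))
                    self.weights[i]._accumulate(hs[i].T @ gz)
                    self.biases[i]._accumulate(gz.sum(axis=0))
                    gh = gz @ self.weights[i].data.T
                if x_tensor is not None:
                    x_tensor._accumulate(gh[:, 0])
            out._backward = _bw
        return out

    def drift(self, t, x) -> Tensor:
        return self.drift_and_diffusion(t, x)[0]

    def diffusion(self, t, x) -> Tensor:
        return self.drift_and_diffusion(t, x)[1]

    def drift_x_derivative(self, t, x) -> Tensor:
        return self.full_evaluation(t, x)[2]

    def full_evaluation(self, t, x) -> tuple[Tensor, Tensor, Tensor]:
        """(drift, diffusion, d drift/dx) in one shared forward pass.

        Fused single-node version of the tangent-propagation pass; its
        backward carries both the activation and the tangent adjoints, with
        the closed-form swish second derivative where the tangent multiplier
        is differentiated.  Verified against `composed_full_evaluation`.
        """
        from scipy.special import expit

        xd = np.atleast_1d(np.asarray(x, dtype=np.float64))
        t_col = np.broadcast_to(np.asarray(t, dtype=np.float64), xd.shape)
        dt_ = self.weights[0].data.dtype
        inp = np.stack([xd, t_col], axis=1).astype(dt_, copy=False)
        n = inp.shape[0]
        hs = [inp]
        us = [np.stack([np.ones(n, dtype=dt_), np.zeros(n, dtype=dt_)], axis=1)]
        zs, sigs, ps, ms = [], [], [], []
        h, u = hs[0], us[0]
        for w, b in zip(self.weights, self.biases):
            z = h @ w.data + b.data
            s = expit(z)
            p = s * (1.0 + z * (1.0 - s))        # swish'
            m = u @ w.data
            h = z * s
            u = m * p
            zs.append(z); sigs.append(s); ps.append(p); ms.append(m)
            hs.append(h); us.append(u)
        a = h @ self.w_drift.data + self.b_drift.data
        zb = h @ self.w_diff.data + self.b_diff.data
        da = u @ self.w_drift.data
        out_data = np.concatenate([a, np.logaddexp(0.0, zb), da], axis=1)
        out = Tensor(out_data, _parents=tuple(self.parameters))
        if out.requires_grad:
            def _bw(g, self=self, hs=hs, us=us, zs=zs, sigs=sigs, ps=ps,
                    ms=ms, zb=zb):
                ga, gbo, gda = g[:, :1], g[:, 1:2], g[:, 2:]
                gb = gbo * expit(zb)
                self.w_drift._accumulate(hs[-1].T @ ga + us[-1].T @ gda)
                self.b_drift._accumulate(ga.sum(axis=0))
                self.w_diff._accumulate(hs[-1].T @ gb)
                self.b_diff._accumulate(gb.sum(axis=0))
                gh = ga @ self.w_drift.data.T + gb @ self.w_diff.data.T
                gu = gda @ self.w_drift.data.T
                for i in reversed(range(len(self.weights))):
                    z, s, p, m = zs[i], sigs[i], ps[i], ms[i]
                    gm = gu * p
                    # swish'' = s(1-s)(2 + z(1-2s))
                    gz = gh * p + (gu * m) * (
                        s * (1.0 - s) * (2.0 + z * (1.0 - 2.0 * s)))
                    w = self.weights[i]
                    w._accumulate(hs[i].T @ gz + us[i].T @ gm)
                    self.biases[i]._accumulate(gz.sum(axis=0))
                    gh = gz @ w.data.T
                    gu = gm @ w.data.T
            out._backward = _bw
        return out[:, 0], out[:, 1], out[:, 2]

    def composed_full_evaluation(self, t, x) -> tuple[Tensor, Tensor, Tensor]:
        """(drift, diffusion, d drift/dx) built from primitive tape ops.

        Reference implementation used to validate the fused node."""
        h, u = self._hidden_with_tangent(self._input(t, x))
        a = ad.linear(h, self.w_drift, self.b_drift).reshape(-1)
        b = ad.linear(h, self.w_diff, self.b_diff).softplus().reshape(-1)
        da = (u @ self.w_drift).reshape(-1)
        return a, b, da

    # ------------------------------------------------------------ numpy view
    def as_numpy_field(self) -> CoefficientField:
        """A tape-free CoefficientField view for evaluation and plotting."""
        Ws = [w.data for w in self.weights]
        bs = [b.data for b in self.biases]
        wa, ba = self.w_drift.data, self.b_drift.data
        wb, bb = self.w_diff.data, self.b_diff.data

        from scipy.special import expit

        def hidden(t, x):
            x = np.atleast_1d(np.asarray(x, dtype=np.float64))
            t_col = np.broadcast_to(np.asarray(t, dtype=np.float64), x.shape)
            h = np.stack([x, t_col], axis=1)
            for w, b in zip(Ws, bs):
                z = h @ w + b
                h = z * expit(z)
            return h

        return CoefficientField(
            drift=lambda t, x: (hidden(t, x) @ wa + ba).reshape(-1),
            diffusion=lambda t, x: np.logaddexp(0.0, hidden(t, x) @ wb + bb).reshape(-1),
        )

    def state_dict(self) -> dict:
        names = self._param_names()
        return {k: p.data.copy() for k, p in zip(names, self.parameters)}

    def load_state_dict(self, state: dict) -> None:
        names = self._param_names()
        for k, p in zip(names, self.parameters):
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            p.data = arr.copy()

    def _param_names(self) -> list[str]:
        n_hidden = len(self.weights)
        return (
            [f"w{i}" for i in range(n_hidden)]
            + [f"b{i}" for i in range(n_hidden)]
            + ["w_drift", "b_drift", "w_diff", "b_diff"]
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_network(spec: Optional[NetworkSpec] = None, seed: int = 0) -> CoefficientNetwork:
    """Build a freshly initialized coefficient network (reproducible by seed)."""
    return CoefficientNetwork(spec or NetworkSpec(), seed)


def unscale_coefficients(
    net: Union[CoefficientNetwork, CoefficientField], scaler: DataScaler
) -> CoefficientField:
    """Map a field fitted on max-abs-scaled states back to original units.

    If Y = sX and X solves dX = a(t, X)dt + b(t, X)dB, then Y solves
    dY = s a(t, Y/s)dt + s b(t, Y/s)dB; both coefficients are multiplied by
    the scale and the state input divided by it.  Time is untouched.
    """
    fld = net.as_numpy_field() if isinstance(net, CoefficientNetwork) else net
    s = scaler.scale
    return CoefficientField(
        drift=lambda t, x: s * no_value(fld.drift(t, np.asarray(x, dtype=np.float64) / s)),
        diffusion=lambda t, x: s * no_value(fld.diffusion(t, np.asarray(x, dtype=np.float64) / s)),
    )


def pretrain_initialize(
    net: CoefficientNetwork,
    steps: int = 100,
    probe_region: tuple = ((0.0, 1.0), (-1.5, 1.5)),
    seed: int = 0,
    n_probe: int = 4096,
    lr: float = 1e-3,
) -> CoefficientNetwork:
    """Regress the fresh network to drift (t, x) -> -x and diffusion 1.

    Run for the stated number of Adam steps on uniform probe points over the
    (t, x) box, resampled each step.  This initialization keeps early
    simulated paths from overflowing when simulator-based losses are used.
    """
    if steps == 0:
        return net
    (t0, t1), (x0, x1) = probe_region
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters, lr=lr)
    first_loss = None
    for _ in range(steps):
        t = rng.uniform(t0, t1, size=n_probe)
        x = rng.uniform(x0, x1, size=n_probe)
        a, b = net.drift_and_diffusion(t, x)
        loss = ((a - Tensor(-x)) ** 2).mean() + ((b - 1.0) ** 2).mean()
        if first_loss is None:
            first_loss = loss.item()
        elif loss.item() > 10.0 * first_loss:
            raise RuntimeError("pre-training diverged (loss grew 10x)")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return net


# ------------------------------------------------------------- persistence

def save_network(net: CoefficientNetwork, scaler: Optional[DataScaler],
                 path: Union[str, Path]) -> None:
    """Save weights (.npz) plus a JSON sidecar describing spec/scaler/seed."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_dict())
    sidecar = {
        "spec": {
            "hidden_layers": list(net.spec.hidden_layers),
            "activation": net.spec.activation,
            "drift_head_activation": net.spec.drift_head_activation,
            "diffusion_head_activation": net.spec.diffusion_head_activation,
            "input_dim": net.spec.input_dim,
        },
        "seed": net.seed,
        "scaler": None if scaler is None else {
            "scale": scaler.scale, "time_range": list(scaler.time_range)
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: Union[str, Path]) -> tuple[CoefficientNetwork, Optional[DataScaler]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(
        hidden_layers=tuple(sidecar["spec"]["hidden_layers"]),
        activation=sidecar["spec"]["activation"],
        drift_head_activation=sidecar["spec"]["drift_head_activation"],
        diffusion_head_activation=sidecar["spec"]["diffusion_head_activation"],
        input_dim=sidecar["spec"]["input_dim"],
    )
    net = CoefficientNetwork(spec, seed=sidecar["seed"])
    with np.load(path.with_suffix(".npz")) as state:
        net.load_state_dict({k: state[k] for k in state.files})
    sc = sidecar.get("scaler")
    scaler = None if sc is None else DataScaler(scale=sc["scale"],
                                               time_range=tuple(sc["time_range"]))
    return net, scaler
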