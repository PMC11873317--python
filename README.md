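# sdecoeff

Assumption-free inference of the coefficient functions of a scalar
stochastic differential equation from an ensemble of observed trajectories.

Many biological processes — gene expression, mRNA translation, population
dynamics — are naturally modelled as Itô equations

```
dX_t = a(t, X_t) dt + b(t, X_t) dB_t
```

with drift `a` describing the deterministic dynamics and diffusion `b` the
noise amplitude. When the analytical form of `a` and `b` is unknown,
`sdecoeff` represents both by a small fully-connected neural network mapping
phase-space points `(t, x)` to scalar drift and (positive) diffusion values,
and fits it to `N` trajectories observed at `T` shared equidistant
timepoints.

The fitting objective combines two complementary families of losses:

* **simulation-based penalties** — simulate `m` paths from the candidate
  coefficients with Euler–Maruyama and penalize disagreement with the data:
  timepoint-wise moment matching, a timepoint-wise Wasserstein-1 penalty
  `L^W = mean_t Ŵ₁ + max_t Ŵ₁`, and ensemble-mean lag-autocorrelation
  matching `L^AC = Σ_{k≤K} (ρ_k(X) − ρ_k(Ξ_m))²`;
* **Gaussian transition pseudo-likelihoods** — score every observed
  transition `(t, X_t) → (t+Δt, X_{t+Δt})` under the one-step density of a
  discretization scheme: Euler–Maruyama, or the Lie–Trotter splitting which
  adds the second-order drift correction `(Δt²/2)·a·∂ₓa`.

The headline objective is the **hybrid Lie–Trotter loss**

```
L^HLT = L^W + η·L^LT + L^AC        (η = 10)
```

whose simulation terms control the population statistics while the
pseudo-likelihood term pins down individual increments.

Everything differentiable — the network, both pseudo-likelihoods (including
the exact forward-mode `∂ₓa`), the unrolled Euler–Maruyama simulation, the
sorting-based Wasserstein coupling and the autocorrelation estimator — runs
on a small vectorized reverse-mode autodiff engine over numpy arrays that
ships with the package (`sdecoeff.autodiff`).

## Worked example

```python
import numpy as np
from sdecoeff import (ExperimentConfig, LossConfig, TrainConfig,
                      run_experiment)

config = ExperimentConfig(
    problem={"name": "OU", "grid": {"t0": 0.0, "t1": 5.0, "n": 200}},
    n_paths=1000,                       # 80/20 train/test split
    loss=LossConfig(terms=("wasserstein", "lt", "autocorr")),  # hybrid LT
    training=TrainConfig(epochs=25, plateau_delta=0.02),
    master_seed=41,
)
result = run_experiment(config)
print(result.report.to_dict())
```

Output (a few minutes on one CPU):

```
{'drift_mse': 0.03010687446135471, 'diffusion_mse': 0.008458086833943232,
 'resampling_mse': 0.00821825014825155, 'signature_mmd': 555.3381398167353,
 'config_problem': 'OU', 'config_terms': 'wasserstein+lt+autocorr',
 'config_n_paths': 1000, 'config_n_times': 200, 'config_eval_points': 10000,
 'config_master_seed': 41, 'config_final_epoch': 24}
```

The run generates 1000 Ornstein–Uhlenbeck paths (`dX = −2X dt + 2 dB`,
initial values from N(0, 3), 200 points on [0, 5]), trains the network with
the hybrid Lie–Trotter loss under the common hyperparameters, and evaluates:

* `drift_mse` / `diffusion_mse` — mean squared error between learned and
  true coefficients on 10⁴ phase-space points drawn from test data (here the
  learned drift is within ~0.17 RMS of the true `−2x` where the data live);
* `resampling_mse` — mean squared gap between paths simulated from the
  learned and the true dynamics with identical initial values and identical
  Brownian increments;
* `signature_mmd` — maximum mean discrepancy between test paths and freshly
  generated paths after the depth-5 signature transform (scale-dependent;
  useful for comparing methods under one convention, not across settings).

The same pipeline is scriptable from the shell:

```bash
sdecoeff train experiment.yaml --out runs/ou_hybrid
sdecoeff evaluate runs/ou_hybrid/checkpoint --problem ou.yaml
sdecoeff fixture ou_tiny --out ou_tiny.csv
```

## Benchmarks

Four synthetic processes with known coefficients are built in
(`make_benchmark_problem`): Ornstein–Uhlenbeck (`OU`), Cox–Ingersoll–Ross
(`CIR`, square-root diffusion, guarded as `σ√max(x,0)` under
discretization), an unstable-sine problem (`SIN1`, state-dependent
diffusion) and a multi-modal sine problem (`SIN2`, time-dependent wells of
attraction). Real datasets enter through the generic ensemble reader
(HDF5 or CSV; see `sdecoeff.io`).

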