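# aftfuse

Integrative estimation of heterogeneous treatment effects (HTE) for censored
survival outcomes, fusing a randomized controlled trial (RCT) with real-world
data (RWD) that may carry unmeasured confounding.

## The problem and the model

A small trial identifies the treatment effect but estimates it noisily; a
large observational cohort is precise but possibly confounded. `aftfuse`
implements a doubly penalized, Kaplan–Meier-weighted least-squares estimator
that uses both sources at once, *learns which covariates drive the treatment
effect*, and *detects whether the observational source is confounded*.

For observed time `T = min(T~, C)`, event indicator `δ`, treatment `A`,
source `S` (1 = RCT, 0 = RWD) and covariates `X`, the accelerated failure
time model after a Robinson-type residualization reads

    log T~ = μ(X,S) + (A − e(X,S)) · [ τ(X) + (1−S)·uc(X) ] + ε,

where `e(X,S) = E[A|X,S]` is the propensity, `μ(X,S) = E[log T~|X,S]`, the
HTE is `τ(X) = Xᵀα`, and `uc(X) = Xᵀβ` is the confounding function — the gap
between the RWD arm contrast and the causal effect, which is zero in the
randomized source. The estimator minimizes the Stute-weighted loss

    Σᵢ wᵢ ( log T₍ᵢ₎ − μ̂(Z₍ᵢ₎) − (A₍ᵢ₎ − ê(Z₍ᵢ₎)) U₍ᵢ₎ᵀθ )²
      + Σⱼ ρ(|αⱼ|; λ₁) + Σⱼ ρ(|βⱼ|; λ₂),

with `U = (X, (1−S)X)`, `θ = (α, β)`, Kaplan–Meier jump weights `wᵢ`
attached to the time-ordered observations (censored subjects get weight 0),
and a folded-concave penalty `ρ` (MCP by default; SCAD and adaptive lasso
available). Nuisances `(ê, μ̂)` are cross-fitted; `(λ₁, λ₂)` are tuned by
cross-validation or BIC. Unmeasured confounding is declared present exactly
when some penalized `β̂ⱼ` survives the tuning.

The package also provides the trial-only and naive (confounding-ignoring)
variants, oracle fits on known supports, five pseudo-response comparator
estimators (outcome-adjusted/AIPW, arm-mean based, their meta-combination),
a 0.632 subsampling bootstrap for standard errors, a synthetic-data generator
with known ground truth, and a replicate-level benchmark driver computing
RMSE, false-discovery and confounding-identification rates, bias, SD and
coverage.

## Worked example

```python
import numpy as np
from aftfuse import (SimulationConfig, generate, cross_fit, FitOptions,
                     fit_integrative, bootstrap_632, predict_hte)

config = SimulationConfig(n=2500, p=20, signal=2.0, confounded=True,
                          censor_rate=0.20, seed=7)
data, truth = generate(config)

nuisance = cross_fit(data, seed=7)
est = fit_integrative(data, FitOptions(seed=7), nuisance)
print("confounding detected:", est.confounding_detected)
print("selected HTE covariates:", est.support_alpha)
print("alpha (first 8):", np.round(est.alpha[1:9], 2))

boot = bootstrap_632(data, nuisance, est, n_boot=200, seed=7)
print("SE (first 8):", np.round(boot.se[1:9], 2))
```

Output:

```
confounding detected: True
selected HTE covariates: [0 1 2 3 4 5 6 7]
alpha (first 8): [-1.68 -2.07 -2.04 -1.83  1.84  1.93  1.91  1.83]
SE (first 8): [0.43 0.17 0.15 0.13 0.08 0.07 0.07 0.08]
```

The generator's true coefficients are ±2 on the first eight covariates; the
fit recovers exactly that support and flags the (truly present) confounding.
The first four covariates also drive the confounding function, so separating
their treatment effect from the RWD bias costs precision — their bootstrap
SEs are several times those of the cleanly identified coefficients 5–8.

A thin CLI mirrors the library: `aftfuse simulate | fit | bootstrap |
benchmark` (see `--help` on each).

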