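# plastidyn

Population dynamics of epithelial–mesenchymal phenotypic plasticity in
tumors, for modelers studying how plastic phenotype transitions shape tumor
heterogeneity, metastasis formation, and treatment response.

## The model

A tumor cell population is discretized into *N* phenotypes along the
epithelial–mesenchymal axis: compartment 1 is the most epithelial
(proliferative, non-motile), compartment *N* the most mesenchymal
(slow-growing, invasive), with hybrid phenotypes in between.  Abundances
*x₁ … x_N* obey a competitive logistic system with biased nearest-neighbour
transitions and treatment mortality:

```
dxᵢ/dt = rᵢ xᵢ (1 − X/K)                                  (logistic growth)
       + c r₁ [(1+λ) xᵢ₋₁ + (1−λ) xᵢ₊₁ − 2 xᵢ]            (transitions)
       − (m_D rᵢ + m_I) xᵢ                                 (treatment)
```

with boundary compartments losing cells in one direction only,
`X = Σⱼ xⱼ`, and a linearly decreasing growth ladder
`rᵢ = r₁ − (r₁ − r_N)(i−1)/(N−1)`.  The transition speed *c* scales
plasticity relative to the epithelial growth rate; the transition bias
λ ∈ [−1, 1] favours mesenchymal-ward (λ > 0) or epithelial-ward (λ < 0)
switching.  Growth-dependent treatment (chemotherapy-like) kills at
`m_D rᵢ`; growth-independent treatment (immunotherapy-like) kills at `m_I`.

Untreated, the system has an unstable extinction equilibrium and a stable
coexistence equilibrium with total abundance *K* and a geometric phenotype
profile set by the bias alone:

```
xᵢ* = K (1−λ)^(N−i) (1+λ)^(i−1) / Σⱼ (1−λ)^(N−j) (1+λ)^(j−1)
```

The package provides this closed form, trait-distribution moments, linear
stability via the analytic Jacobian, piecewise integration over treatment
schedules (single-block, alternating, and adaptive block sequences), the
endpoint calibration of `m_I`, the treatment decision boundary λ̃, and
burden-reduction sweeps over the (λ, c) plane, plus a `plastidyn` CLI.

## Worked example

```python
import numpy as np
from plastidyn import (
    ModelParams, calibrate_mI, decision_boundary,
    coexistence_equilibrium, simulate, build_schedule, burden_reduction,
)

params = ModelParams()           # N=3, r=(1, 0.6, 0.2), K=1, c=1, lambda=0
mi = calibrate_mI(params)        # match both treatment types' endpoints
params = params.replace(mI=mi)
print(f"mI = {mi:.4f}")
print(f"lambda_tilde = {decision_boundary(params):.4f}")

x0 = coexistence_equilibrium(params)
print("equilibrium:", np.round(x0, 4))

traj = simulate(params, x0, build_schedule("single_GD", 1, 10.0), horizon=10.0)
print(f"burden reduction = {burden_reduction(traj, params, 10.0):.4f}")
```

prints

```
mI = 0.6475
lambda_tilde = -0.0893
equilibrium: [0.3333 0.3333 0.3333]
burden reduction = 0.8499
```

The calibrated growth-independent intensity is 0.6475: a uniform death rate
of that size removes exactly as much tumor over a duration-10 block as
chemotherapy-like mortality with `m_D = 1`, starting from the unbiased
equilibrium.  The decision boundary λ̃ ≈ −0.089 means that for tumors with
a transition bias above −0.089 (including the unbiased case) the
growth-independent treatment exerts the higher instantaneous mortality, and
an adaptive scheme picks it; below, the growth-dependent treatment wins.
Either single-block treatment reduces the unbiased tumor's burden by 85% of
the carrying capacity by the end of treatment.

The same computations from the shell:

```sh
plastidyn boundary --config config.yaml --out results/
plastidyn sweep --config sweep.yaml --out results/
```

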