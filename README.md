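# hexpov

Health-expenditure poverty measurement and regional inference: who is pushed
below the poverty line by out-of-pocket health spending, whether that burden
clusters in space, and which regional health-service-equity indicators
predict it.

`hexpov` is aimed at health economists and regional epidemiologists working
with household survey microdata (income, health spending, reimbursement)
paired with regional health-system aggregates. Because such microdata are
usually restricted, the package ships a synthetic-data generator with known
ground truth that emulates the survey/yearbook input pair, so every stage of
the analysis is testable offline.

## The statistics

**Impoverishment rule.** A household with pre-expenditure income
`y ≥ z` (the poverty line, RMB/year) is *health-expenditure impoverished*
when `y − OOP < z`, where `OOP = total health expenditure − reimbursed −
expected-to-be-reimbursed` (clamped at 0). Households already below `z` are
counted in the population but never in the impoverished count.

**HFGT index family.** Per region (and pooled),

    HFGT_α = (1/n) Σ_{i impoverished} ((z − y_i)/z)^α ,   α ∈ {0, 1, 2}

with `y_i` the post-expenditure income floored at 0. `α = 0` is the
headcount ratio (*breadth*), `α = 1` the poverty gap (*depth*), `α = 2` the
squared poverty gap (*strength*). The family is decomposable: the
population-share-weighted regional indices equal the pooled index exactly.

**Spatial autocorrelation.** Global Moran's I with row-standardized
contiguity weights `w_ij`,

    I = (n/S0) · Σ_ij w_ij z_i z_j / Σ_i z_i² ,   z_i = x_i − x̄ ,

with analytic (normality-assumption) and permutation inference, plus
Anselin's local Moran's I with conditional permutation and HH/LL/LH/HL
cluster typing.

**Variable selection.** Tolerance/VIF multicollinearity screening, then an
elastic net

    min_{β0,β} (1/2N) Σ_i (y_i − β0 − x_iᵀβ)² + λ[(1−α)·½‖β‖₂² + α‖β‖₁]

fit by cyclic coordinate descent, with the penalty λ selected by k-fold
cross-validation (the MSE-minimizing λ is the headline; the sparser
one-standard-error λ is also reported).

## Worked example

```python
import numpy as np
from hexpov import (PovertyLine, cross_validate, global_morans_i,
                    regional_profiles, row_standardize, standardize)
from hexpov.synth import (SyntheticScenario, generate_households,
                          generate_lattice_weights, generate_regional_indicators)

scen = SyntheticScenario(n_regions=100, lattice_dims=(10, 10),
                         households_per_region=400, seed=42)
W = generate_lattice_weights(10, 10, "queen")
indicators = generate_regional_indicators(scen)
households, truth = generate_households(scen, indicators, W)

profiles = regional_profiles(households, PovertyLine(2300.0, "baseline"))
print(profiles.head(3).to_string(index=False))

res = global_morans_i(profiles["breadth"].to_numpy(), row_standardize(W),
                      n_perm=999, seed=42)
print(f"Moran's I = {res.I:.3f}, E[I] = {res.expected_I:.3f}, "
      f"z = {res.z_normal:.2f}, pseudo p = {res.p_perm:.3f}")

xcols = [f"X{j+1}" for j in range(20)]
D = standardize(indicators[xcols].to_numpy(),
                profiles["breadth"].to_numpy(), xcols)
fit = cross_validate(D, alpha=0.5, k=10, seed=42)
print(f"lambda_min = {fit.lambda_min:.5f}")
print("selected:", ", ".join(fit.selected_support))
print("1-SE rule:", ", ".join(fit.support_1se))
print("true support:", ", ".join(truth.support))
```

prints

```
region_id   n   q  breadth    depth  strength
    R0000 400 239   0.5975 0.302504  0.202142
    R0001 400  13   0.0325 0.021684  0.016320
    R0002 400  46   0.1150 0.059997  0.041121
Moran's I = 0.122, E[I] = -0.010, z = 2.47, pseudo p = 0.017
lambda_min = 0.02234
selected: X1, X2, X4, X5, X6, X7, X8, X10, X13, X15, X16, X17, X18
1-SE rule: X2, X5, X7, X10, X13, X15, X16, X17
true support: X2, X5, X7, X10, X13, X16, X17
```

Regional breadth varies widely (here from 3% to 60% of households), the
generator's spatially autoregressive disturbance shows up as a significantly
positive Moran's I, and the cross-validated elastic net recovers every
truly active indicator — with several spurious extras at the
MSE-minimizing penalty, and almost none under the one-standard-error rule.

The same analysis is available from the shell:

```sh
hexpov simulate --seed 42 --n-regions 100 --out data/
hexpov poverty --households data/households.csv --z 2300 --out profiles.csv
hexpov moran --values profiles.csv --weights data/weights.gal
hexpov lisa  --values profiles.csv --weights data/weights.gal --out lisa.csv
hexpov fit   --indicators data/indicators.csv --response profiles.csv --out fit.json
hexpov run   --config config.yaml --out study/      # the full pipeline
```

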