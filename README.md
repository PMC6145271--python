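# labferm

Kinetic modelling of lactic-acid-bacteria (LAB) growth in Thai fermented
sausage, with Monte-Carlo parameter estimation, chi-squared model
validation, a synthetic-data generator matching the study design, and a
preparation-plus-transportation cost model for the finished product.

The package is aimed at predictive-microbiology and fermentation-process
modellers who want a tested, reproducible implementation of an
unstructured six-state fermentation model and of the statistical
machinery needed to fit and validate it against sparse, replicated
time-series assays.

## The model

Six coupled ODEs on a per-100-g-sausage basis, over 0–60 hr:

* **Biomass** `y1` (g dry cells/100 g): Monod growth in the limiting
  substrate (total protein) with a logistic ceiling and an exponential
  lag factor, minus first-order lysis:

  `dy1/dt = (1 − e^(−k3 t)) · k1 y2/(k2 + y2) · y1 (1 − y1/y1max) − k12 y1`

* **Total protein nitrogen** `y2` (g N/100 g): depleted by incorporation
  into biomass and nonprotein nitrogen (fixed elemental stoichiometry,
  dimensionless corrections `cor_bio`, `cor_NPN`) plus a first-order
  proteolytic loss `cor_X·y2`; the protein and NPN balances are
  mutually implicit and solved in closed form.
* **Nonprotein nitrogen** `y3` (g N/100 g): Luedeking–Piret,
  `dy3/dt = −k4 dy2/dt + k5 y2`.
* **Lactic acid** `y4`, **formic acid** `y5` (g/100 g): Luedeking–Piret
  with product-saturation brackets, e.g.
  `dy4/dt = k6 dy1/dt + k7 (1 − y4/y4max)`.
* **Glucose** `y6` (g/100 g): consumed for growth and lactate synthesis,
  `dy6/dt = −k10 dy1/dt − k11 (1 − y4/y4max)`.

Trajectories are integrated by **orthogonal collocation on finite
elements** (Gauss–Legendre nodes; the default 20 elements × order 4
agrees with an independent adaptive Runge–Kutta oracle to ~1e-9
relative). Parameters are estimated by weighted least squares followed
by **Metropolis-within-Gibbs** sampling in log-parameter space
(≥ 10,000 trials, log-uniform box priors), and fits are validated per
state with a variance-weighted Pearson chi-squared test at the 95%
level. The cost model prices a truckload of sausage shipped
refrigerated (pre-fermented) or nonrefrigerated (fermenting in transit)
as `TC = C0 + (C1 + C2)·t_dr + C3(t_dr)` with overtime doubling after
the 540-minute driver duty period.

## Worked example

```python
import numpy as np
from labferm import (control_parameters, default_initial_conditions,
                     simulate, GeneratorConfig, generate, gibbs_fit,
                     compare_scenarios)

# simulate the spontaneous-fermentation (control) batch
p = control_parameters()
traj = simulate(p, None, default_initial_conditions("control"))
print(traj.to_frame().round(4).to_string(index=False))
```

```
 time_hr  y1_gdcw_per100g  y2_gN_per100g  y3_gN_per100g  y4_g_per100g  y5_g_per100g  y6_g_per100g
     0.0           0.0040         0.5630         0.1090        0.0000        0.0000        1.0000
    12.0           0.0220         0.4150         0.1091        0.6076        0.0170        0.0527
    24.0           0.1440         0.2937         0.1092        1.0059        0.0338       -0.4974
    36.0           0.1954         0.2123         0.1092        1.2190        0.0484       -0.8006
    48.0           0.1984         0.1570         0.1092        1.3325        0.0611       -0.9777
    60.0           0.1985         0.1163         0.1093        1.3996        0.0728       -1.0836
```

Biomass shows the long lag (12-hr value ≈ 11% of the plateau) before
rising to its logistic ceiling of 0.2 g/100 g (10⁹ CFU/g); protein falls
while NPN creeps up; lactate saturates towards its 1.5 g/100 g ceiling.
Glucose runs negative after ~20 hr — a documented artefact of the
published uptake constants (glucose feeds back on nothing in this
model).

```python
# fit synthetic triplicate data and validate
cfg = GeneratorConfig(batch="control", noise_frac_of_range=0.01, seed=1)
obs = generate(cfg)
fit = gibbs_fit(obs, n_draws=10_000, seed=1, p0=p, y0=cfg.resolved_y0())
print(fit.point_estimate.k7, {s: c.passed for s, c in fit.chi2.items()})

# transport economics
print(compare_scenarios([0, 240, 480]).round(2))
```

```
   distance_km  refrigerated_usd  nonrefrigerated_usd  gap_usd
0            0          13170.15             13042.15    128.0
1          240          13228.83             13071.63    157.2
2          480          13287.51             13101.91    185.6
```

The nonrefrigerated truck is cheaper at every distance (lower labour
cost and less fuel per minute) and the gap widens with distance.

The same stages are scriptable from the shell:

```
labferm synth --batch control --seed 1 --out-dir runs/synth
labferm fit --observations runs/synth/observations.csv --batch control \
        --seed 1 --out-dir runs/fit
labferm compare --out-dir runs/cost
```

Every run writes a manifest with SHA-256 checksums and the seed, so
deterministic stages are byte-reproducible.

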