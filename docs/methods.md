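# Methods notes

## Model structure and assumptions

The fermentation is described by an unstructured (no intracellular
structure, no pH dynamics) six-state model. Growth is protein-limited —
the sausage matrix is protein-rich and carbon-supplemented — so the
Monod term uses total protein nitrogen `y2` as the limiting substrate.
The lag phase is a multiplicative factor `1 − exp(−k3·t)`: at
inoculation (t = 0) the growth term vanishes exactly and only lysis
acts, which the suite asserts. Product formation (NPN, lactate,
formate) follows Luedeking–Piret kinetics: a growth-associated term
proportional to `dy1/dt` plus a non-growth term; the two acids carry
saturation brackets `(1 − y/ymax)` in their own concentration. Glucose
is a pure sink (uptake for growth and for lactate synthesis) and feeds
back on no other state.

Working units: hours; all states per 100 g sausage; protein and NPN as
grams of *nitrogen* so the elemental bookkeeping of the protein balance
is dimensionally coherent. Rate constants are per hour.

### The protein/NPN coupling

The protein balance contains `dy3/dt` and the NPN balance contains
`dy2/dt`; substituting one into the other gives the closed form used by
`protein_npn_rates` (no iteration; residuals of both balances vanish to
1e-12, asserted). The sign layout is fixed by physics: protein must
decrease when biomass and NPN are being formed. The coupling
denominator `1 − b·k4` (with `b` the NPN nitrogen fraction times
`cor_NPN`) is far from zero for all realistic values; a configuration
error names the offending parameters if it vanishes.

### The protein loss term

The extra proteolytic loss controlled by `cor_X` supports two forms:

* `first_order` (default): rate `cor_X·y2`, `cor_X` in 1/hr. With the
  published values (0.025 control, 0.046 *P. acidilactici*) protein
  decays smoothly and stays positive over the full 60-hr window, and
  protein/NPN remain monotone (asserted).
* `constant`: rate `cor_X` in g N/100 g/hr. With the same values a
  constant loss of 0.025 g N/100 g/hr exhausts the 0.563 g N/100 g
  initial pool before 25 hr, then drives `y2` into the Monod pole at
  `y2 = −k2` — a finite-time singularity inside the study window. The
  option is retained for sensitivity studies only and is not used by
  any default.

### Saturation maxima and stoichiometry

No fitted values exist for `y1max`, `y4max`, `y5max`; the defaults are
`y1max` equivalent to 10⁹ CFU/g (2e-12 g/CFU for the mixed natural
flora, 3e-12 for the doublet/tetrad *P. acidilactici* morphology),
`y4max` = 1.5 and `y5max` = 0.2 g/100 g, chosen to reproduce the
observed plateau levels of the acids. They are held fixed during
fitting (freeing them collapses identifiability further); all are
config-overridable. Biomass stoichiometry uses the generic microbial
formula CH₁.₈O₀.₅N₀.₂ (nitrogen mass fraction 0.114) and NPN an average
free amino acid (MW 120, one N, fraction 0.117); both are overridable
and held at their defaults in generation *and* fitting, so they cancel
out of recovery studies.

### Known artefact: negative glucose

With the published constants the zero-order lactate-linked uptake
(`k11` = 0.101 control, 1.280 *P. acidilactici*) consumes more glucose
than the 1.0 g/100 g default initial supply (which is itself an
assumption — no initial glucose was reported). Because glucose feeds
back on nothing, the state simply runs negative (to −1.08 control,
−18.8 *P. acidilactici* at 60 hr). We deliberately do not clamp it:
clamping would introduce a non-smooth vector field (bad for
collocation) and would hide a real property of the published rate
constants. Consequently the nonnegativity guarantee covers `y1..y5`
only.

## Numerics

* **Collocation**: 20 finite elements × order-4 Gauss–Legendre nodes
  over 60 hr (equivalent to the Gauss implicit RK method; order-8
  superconvergence at element ends). Each element solves a 24-unknown
  Newton system with finite-difference Jacobians to residual < 1e-9.
  Measured agreement with the RK oracle is ~1e-9 relative; the spec of
  12×3 was tried first and only reaches ~1e-4, short of the 1e-6
  equivalence requirement, hence the larger default. Dense output
  evaluates the per-element Lagrange polynomial, so sampling times are
  unconstrained.
* **RK oracle**: `scipy.integrate.solve_ivp` (LSODA) at rtol 1e-10.
  Wherever the two methods disagree the RK result is treated as the
  referee. Cross-method deviation is measured per state, normalised by
  the state's peak magnitude (glucose crosses zero, so a pure relative
  metric would be ill-defined).
* **Fitting solver**: RK at rtol 1e-7 (~1 ms/solve); its error is
  orders of magnitude below any measurement noise. The collocation
  route is the default for simulation and generation.
* Overshoot (`y > ymax` from noise or solver error) is handled by
  letting the bracket go negative (self-correcting) rather than
  clamping, preserving smoothness.

## Estimation

* **Likelihood**: independent Gaussians per replicate observation,
  `−½((obs−pred)/σ)² − log σ`, with σ from the observation file's `sd`
  column. A floor of 5% of the state's observed range substitutes for
  *missing or zero* SDs only; reported positive SDs are used as-is (a
  floor that overrides every reported SD would distort the posterior
  scale rather than protect against singularities).
* **Least squares**: `scipy.optimize.least_squares` (TRF) on replicate
  means weighted by `sd/√n`, in log-parameter space with ±2-decade box
  bounds. On noiseless data it recovers every generating parameter to a
  fraction of a percent (asserted at 0.5%) from ±20%-perturbed starts —
  except `cor_NPN`, whose contribution is below solver precision (a
  structurally null direction).
* **Sampler**: component-wise Metropolis-within-Gibbs in log space,
  log-uniform box priors (default ±2 decades around the initialiser —
  the constants span five orders of magnitude). One *trial* = one
  component update; accepted runs perform ≥ 10,000 trials. Proposal
  scales adapt towards 44% acceptance during the first 20% of trials
  (burn-in) and are frozen afterwards, keeping the post-burn-in chain
  Markovian; the vector is recorded once per sweep. Convergence is
  monitored by split-chain R-hat (warn > 1.1, via `arviz`); acceptance
  rates outside [0.05, 0.7] also warn. Point estimate: component-wise
  posterior median.
* **Chi-squared validation**: per state,
  `Σ_t ((mean − pred)/(sd/√n))²` against `χ²₀.₉₅(dof)`,
  `dof = n_times − n_params(state)` with no allocation by default
  (correct for predictions not fitted to the data; callers may allocate
  fitted parameters per state, and `dof ≤ 0` raises with advice to pool
  states). The weighting is the variance-weighted Pearson form.

## Synthetic data

The generator emulates the study design: sampling at 0, 12, 24, 36, 48,
60 hr, triplicate assays, homoscedastic per-state Gaussian noise.
Default SDs use the reported 0-hr replicate spreads for protein (0.023 /
0.017 g N/100 g) and NPN (0.006 / 0.004), and plausible assay
repeatabilities for the rest (biomass 0.005, lactate 0.05, formate
0.01, glucose 0.05 g/100 g — plate counts, HPLC organic acids and the
enzymatic glucose kit on the same basis). A `noise_frac_of_range`
option sets SDs as a fraction of each state's noiseless trajectory
range instead (the recovery studies use 1%). The `sd` column of a
generated set carries the *nominal* noise SD, so the chi-squared
statistic is exactly χ²(6) per state under the null — the calibration
test observes the 5% nominal rejection rate directly.

Noise is not clipped at zero by default: the generating trajectory
itself is negative for glucose, so clipping would censor every
negative-glucose observation and make the data impossible under the
generating model, inflating the weighted misfit at the truth by orders
of magnitude. `clip_negative=True` restores
detector-style censoring for realism studies, and a test documents the
bias it introduces at zero-valued states. A plate-count view of the
biomass channel (log₁₀ CFU/g with 0.1-log lognormal noise) is available
for realism.

What passing tests do **not** show about real data: the generator
shares the fitted model's structure, so recovery results say nothing
about structural misfit (the study itself noted protein over-prediction
and suggested acid-induction terms); real assay noise is neither
Gaussian nor homoscedastic; and duplicate-batch (biological) variation
is not simulated — only assay replication is.

## Identifiability of the recovery study

`labferm.recovery.cramer_rao_bounds` computes the Cramér–Rao lower
bounds at the truth (weights = the 1%-of-range design, six timepoints,
triplicates, all 12 rate constants + 3 corrections free; the test suite
asserts the structure below). Relative sds:

| batch | k6 | k10 | cor_bio | k4 | k7 | k9 | k11 | cor_X |
|---|---|---|---|---|---|---|---|---|
| control | 27% | 1690% | 31% | 510% | 2.0% | 1.9% | 1.6% | 2.2% |
| *P. acidilactici* | 6500% | 14600% | 20% | 30% | 1.4% | 2.3% | 1.1% | 1.5% |

Two mechanisms dominate. First, at six timepoints the growth increment
`Δy1(t)` is nearly collinear with the saturation integrals of the
non-growth terms, so growth-associated yields trade against their
non-growth partners (`k6` has a 25% floor even with only `k6, k7`
free). Second, some contributions are simply buried: `k10`'s entire
effect on glucose is `k10·Δy1 ≈ 0.002` g/100 g against a noise SD of
0.021 — unidentifiable even in isolation. `cor_NPN` is a null
direction at any noise. Observed recovery errors (e.g. seed 1: k6
+8.8%, k10 −60%, cor_bio −16%, k4 +3.3%) sit well inside these floors:
the pipeline extracts essentially all the information the design
contains. Tight recovery of every coefficient is only possible in the
noiseless limit, which the suite verifies separately.

## Cost model

All primitives are exposed: C1 = diesel price / consumption (0.72/3.6 =
0.20 and 0.72/9.0 = 0.08 USD/min), annual depreciation = 20% × 14,285.71
= 2,857.14 USD/yr, C2 = that over 8 hr × 330 day × 60 min = 0.01804
USD/min, wage rate = 14.29/540 min. The printed table rounds C2 to
0.009 and the wage rates to 0.027/0.054, which are not exactly
consistent with their own primitives; both variants ship as presets
(`derived` default, `paper_exact`), neither silently preferred.
Sleeper-berth minutes are inside the 540-min duty period, which is paid
as a lump `wage_per_period`; trips beyond one duty period stay at the
doubled rate. The labour saving of the ferment-in-transit product is
carried as a literal (708.57 vs 836.57 USD/load; the printed figure is
not exactly 20% lower, and the literal wins). Total cost is piecewise
linear and nondecreasing in distance with a slope break exactly at the
overtime point; with default constants the nonrefrigerated curve
dominates everywhere and the gap is nondecreasing — all asserted.

## Problem sizes

Defaults were chosen so a full run is laptop-scale: one collocation
solve ~25 ms, one fitting solve ~1 ms, a 10,000-trial recovery fit
~45 s, the whole suite ~2 min, the recovery script ~2 min. The GOF
calibration uses 200 replicates (binomial sd on the pooled rate
~0.6%).

## Known limitations

* Single-strain, unstructured kinetics: no pH feedback, no acetic
  acid/ethanol, no hetero-fermentative switching dynamics.
* Glucose balance unphysical at the published constants (see above).
* Posterior medians from one chain of 10,000 component updates; for
  publication-grade intervals run longer chains (the API takes
  `n_draws`) and check R-hat.
* Cost model: single truck, no route optimisation, no spoilage risk for
  the unrefrigerated option.
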