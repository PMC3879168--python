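# Methods

## Model

`mitoswitch` implements a six-variable mass-action ODE model of the
mammalian G2/M transition.  The dynamic variables are

| variable | meaning | bounds |
|---|---|---|
| `MPF` | active (Tyr15-dephosphorylated) Cdk1/CycB | `[0, CycT]` |
| `Cdc25` | phosphorylated, active Cdc25 | `[0, Cdc25T]` |
| `Wee1` | unphosphorylated, active Wee1 | `[0, Wee1T]` |
| `Gwl` | phosphorylated, active Greatwall kinase | `[0, GwlT]` |
| `ENSAPt` | total phospho-ENSA/ARPP19 (free + PP2A-bound) | `[0, ENSAT]` |
| `PP2` | free, active PP2A/B55 | `[0, PP2T]` |

with the right-hand sides

```
MPF'    = k25*(CycT - MPF) - kwee*MPF
Cdc25'  = Va25*MPFa*(Cdc25T - Cdc25) - Vi25*PP2a*Cdc25
Wee1'   = Vawee*PP2a*(Wee1T - Wee1) - Viwee*MPFa*Wee1
Gwl'    = kagwl*MPFa*(GwlT - Gwl)
          - (kigwl' + kigwl''*PP2T/(1+OA) + kigwl*PP2a)*Gwl
ENSAPt' = kaensa*Gwl*(ENSAT - ENSAPt) - kiensa*ENSAPt
PP2'    = -kas*(ENSAPt - (PP2T - PP2))*PP2 + (kdis + kiensa)*(PP2T - PP2)
```

where `k25 = k25'*(Cdc25T - Cdc25) + k25''*Cdc25` and
`kwee = kwee'*(Wee1T - Wee1) + kwee''*Wee1` are the effective Tyr15
modification rates (linear in the regulator because each enzyme form
carries a constant specific activity), and

```
MPFa = MPF/(1+RO)        PP2a = PP2/(1+OA)
```

are the drug-corrected active fractions.  `RO` (a Cdk1 inhibitor of the
RO-3306 type) and `OA` (okadaic acid, a PP2A inhibitor) are effective
dimensionless dose parameters of an instantaneously equilibrating
reversible binding reaction; no attempt is made to map them to molar
drug concentrations.  All concentrations are dimensionless (totals 1
except `PP2T = 0.5`, kept below its stoichiometric inhibitor ENSA), and
time is in dimensionless model units — the experimental comparisons are
therefore orderings and relative delays, never absolute times.

Assumptions inherited from the network formulation: all Cyclin B is
Cdk1-bound (Cdk1 in excess), every reaction is mass action, and
phospho-ENSA binds free PP2A/B55 as a stoichiometric unfair-competition
inhibitor whose bound substrate is released upon dephosphorylation
(hence the `kdis + kiensa` release term).

### Gwl-phosphatase variants

The phosphatase that inactivates Gwl is unknown, so three variants are
provided as parameter presets over the same default set:

* `pp2a_b55` (default): `kigwl = 2`, `kigwl' = 0.02`, `kigwl'' = 0` —
  Gwl is dephosphorylated by PP2A/B55 itself, adding a second
  double-negative feedback loop (Gwl —| PP2A/B55 —| Gwl);
* `oa_insensitive`: `kigwl' = 2`, `kigwl = 0` — a constant,
  okadaic-acid-insensitive activity;
* `oa_sensitive`: `kigwl'' = 2`, `kigwl = 0` — an OA-sensitive activity
  that is not B55-dependent, hence not subject to ENSA inhibition; its
  term uses the total pool `PP2T/(1+OA)` exactly as the model defines
  it, i.e. this pool is implicitly treated as constitutively active.
  The equations are transcribed as printed without reinterpreting that
  choice.

A deliberate documentation point: the published metaphase initial
condition `(MPF, Cdc25, Wee1, Gwl, ENSAPt, PP2) = (0.96, 0.97, 0.03,
0.9, 0.75, 0.027)` is, at its printed precision, the mitotic steady
state of the **OA-sensitive** variant (computed: 0.9632, 0.9725,
0.0275, 0.9042, 0.7509, 0.0272).  The default PP2A/B55 variant's
mitotic state differs in the Gwl and ENSAPt coordinates (0.9926 and
0.7679).  Reproduction of the printed coordinates therefore uses the
OA-sensitive variant; all exit simulations start from the printed
metaphase values regardless of variant, as specified.

## Simulation and protocols

Integration uses `scipy.integrate.solve_ivp` with LSODA at
`rtol = 1e-8`, `atol = 1e-10` — tight enough that output is insensitive
to further tightening; the original model's fixed output step of 0.5
time units is treated as a sampling grid and refined to 0.05 for smooth
event-time estimates.  Three protocols reproduce the chemical-biology
perturbations:

* `entry_release`: pre-equilibrate from the G2 state under `RO = 25`
  (to right-hand-side max-norm < 1e-9, at most 500 time units — the
  reproducible stand-in for an unspecified inhibitor-arrest duration),
  then set `RO = 0`;
* `entry_oa`: same pre-equilibration, then keep `RO = 25` and add
  `OA = 100`;
* `exit`: start from the printed metaphase state and set `RO = 100`.

Default horizon is 30 time units (the published figure window).  Note
that the OA-driven entry transition is only ~10% complete by t = 30 and
finishes around t ≈ 80; analyses that need the completed transition
(readout-based event-time recovery, the readout demo) therefore use a
100-unit window, while figure-level comparisons keep the 30-unit one.

Event times are "t50" values: the first linearly interpolated crossing
of half the excursion between the value at perturbation time and the
value at the final time (robust to partial transitions).  A flat series
(excursion < 1e-6) or a direction mismatch yields a not-found result.

## Equilibria and bifurcation analysis

Steady states are found by Newton root-finding (`scipy.optimize.root`,
hybr, finite-difference Jacobian with central step 1e-7, validated once
against a symbolic Jacobian) to residual max-norm < 1e-10, restricted
to the state box.  Stability is classified from the Jacobian
eigenvalues with threshold ±1e-9 on real parts; anything inside the
threshold is labelled `marginal`, never silently classified.
Duplicates are merged at 1e-6 in state max-norm.

**Localization.**  Newton from box-corner starts can converge across
basin boundaries and silently lose a coexisting state.  The package
therefore localizes equilibria semi-analytically first: at steady state
the ENSA balance gives `ENSAPt(Gwl)`, the complex balance gives free
`PP2(ENSAPt)` (positive root of a quadratic), the Cdc25/Wee1 balances
give both regulators in terms of `MPFa` and `PP2a`, and the Gwl balance
yields `MPFa(Gwl)`; every equilibrium of the 6-D system is then a root
of the single remaining Tyr15-balance residual, scanned on a dense Gwl
grid (~8400 points, log-refined near 0).  Root brackets seed the 6-D
Newton polish.  Corner and neighbour seeds are retained on top, and
segment starts between two stable states guard the separating saddle.
Long-time integration from both basins serves as an independent oracle
in the tests (never as the implementation).

Balance curves (equilibrium branches over total Cyclin B) use parameter
stepping with neighbour seeding rather than pseudo-arclength
continuation — the system is six-dimensional and well conditioned at
this scale.  Saddle-node folds are located by bisection on the interval
where the equilibrium count changes, to 1e-4 in the parameter.
Two-parameter bistability maps classify each cell by scanning CycT in
[0, 1] (101 points, probed in bit-reversal order with early exit);
solver failures mark a cell `unknown`, never silently monostable.

Computed structure worth knowing: with the default parameter set the
bistable window is CycT ≈ (0.05, 0.20); at CycT = 1 only the mitotic
state is stable, which is exactly why integrating the G2 initial
condition at full Cyclin B commits to mitosis.  The PP2A/B55 variant's
window is wider than the OA-insensitive variant's (extra double-negative
loop).  With `kiensa = 0` the model is provably monostable for every
CycT: each steady state then has `ENSAPt = ENSAT`, free PP2 is fixed by
a quadratic, and the reduction above becomes a one-root scalar
equation.  More broadly, the published bistability ranges
(`kagwl > 1`, `kigwl' ∈ [0,10]`, `kaensa > 1`, `kiensa ∈ [0,2.5]`) hold
as one-at-a-time variations around the default set (except the
`kiensa = 0` boundary) but not over the full four-parameter product
grid: the `bistability_ranges` experiment writes the exact per-point
table, and the corresponding acceptance test records the discrepancy
rather than papering over it.

## Synthetic readouts

`generate_readout` emulates quantified immunoblot band intensities:
channel value = trajectory value (linear interpolation) × LogNormal(0,
sigma) + background, divided by a normalization constant (the
loading-control analogue, fixed at 1 by default and exposed for
sensitivity analysis).  Multiplicative log-normal noise with additive
background was chosen because blot intensities are positive and
heteroscedastic; default `sigma = 0.1`.  Channels map model variables
to the epitopes they stand for: pTyr15 ↦ preMPF, pThr194 ↦ Gwl,
pSer67 ↦ ENSAPt, phospho-SP ↦ MPFa.  All randomness flows from one
seeded `numpy` generator; no global state.

**t50 estimation.**  The sampled series is smoothed in log space —
where the multiplicative noise is homoscedastic with known standard
deviation sigma — by a smoothing spline whose penalty is set by the
discrepancy principle (RMS log-residual matched to sigma, bisection
over the penalty; replicate-averaged series use sigma/√n).  The t50 is
the half-excursion crossing of the fit on a 20×-refined grid.  Smoothing
before crossing matters: a raw noisy series first-crosses early wherever
it hovers near the threshold, a one-sided bias that sampling density
does not remove.  Uncertainty comes from a residual-resampling
bootstrap around the fit, re-using the chosen penalty; `ordering_test`
bootstraps two channels independently and reports the fraction of
replicates in which one t50 precedes the other, counting ties and
non-crossings as 1/2 (so identical channels score ≈ 0.5 and swapping
channels maps f → 1 − f).  At least 4 sampling times are required; the
recovery guarantees quoted in the tests use grids dense enough to
resolve the transition in question (0.5-unit spacing over the exit and
release transitions).

What the generator does **not** emulate: saturation/nonlinearity of
band quantification, gel-to-gel normalization error (the loading
control is noiseless), channel cross-talk, and timing jitter of sample
collection.  Passing recovery tests therefore show that the inference
machinery is correct under the stated noise model, not that real blot
quantifications would achieve the same precision.

## Experiments layer

Each experiment id (`fig1_entry_release`, `fig1_entry_oa`, `fig1_exit`,
`figS1_balance`, `bistability_ranges`, `readout_demo`) is a one-command
run writing tidy CSV, an optional plot layer, a `summary.json` of
scalar results and a `manifest.json` with the spec, package version and
SHA-256 of every CSV.  Plots are a convenience over the CSVs; nothing
downstream reads them.  Reruns with the same config and seed are
byte-identical (plots excluded).  YAML configs are validated with the
offending key named before any computation starts.

## Numerical choices, in one place

| choice | value | why |
|---|---|---|
| solver | LSODA, rtol 1e-8, atol 1e-10 | stiff (kas = 100); output tolerance-insensitive |
| output step | 0.05 | smooth t50 interpolation |
| pre-equilibration | rhs max-norm < 1e-9, ≤ 500 t.u. | reproducible inhibited state |
| Newton residual | < 1e-10 max-norm | steady-state contract |
| stability threshold | ±1e-9 eigenvalue real part | below = marginal, flagged |
| duplicate merge | 1e-6 state max-norm | well above residual, below state scale |
| fold bisection | 1e-4 in parameter | matches branch-grid resolution |
| Gwl-scan density | ~8400 points, log-refined near 0 | resolves roots near both Gwl bounds |
| readout sigma default | 0.1 | typical blot quantification spread |
| smoothing penalty | discrepancy principle at known sigma | unbiased noise level is available by construction |

## Known limitations

* No Fcp1/Cdk1-regulated ENSA dephosphorylation terms (that extension
  of the network has no published equations), no stochastic variant, no
  spatial compartments, no Hopf/limit-cycle continuation (only
  saddle-node structure is present in the analysed ranges).
* Model time is not calibrated to minutes; only orderings and relative
  delays are comparable to experiments.
* The OA-sensitive non-B55 route uses the total PP2A pool as printed;
  whether that pool should itself be ENSA-inhibitable is a modelling
  question the package intentionally does not answer.
* `balance_curve` assumes fold (count-change) structure; a window
  narrower than the CycT grid spacing would be missed at the default
  101-point grid (the probe grid, not the localization, is the limit).
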