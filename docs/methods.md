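# Methods

`lipidpbtk` implements a lipid-based physiologically based toxicokinetic
(PBTK) model for a mixture of six PCB congeners (118, 138, 153, 170, 180,
187) in rats, an enzyme-induction submodel linking internal exposure to
metabolic clearance, a synthetic-study generator, and a hierarchical
Bayesian population calibration by blockwise random-walk Metropolis MCMC.
This note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic-data pipeline does and does not
demonstrate.

## Disposition model

PCBs are highly lipophilic; the model assumes they reside only in the
neutral-lipid equivalent (NLE) space of blood and tissues — all neutral
lipids plus 30% of phospholipids — so no tissue/blood partition
coefficients are needed. State variables are chemical masses in compartment
NLE (μg); flows are NLE flows (mL NLE/h). Five compartments: blood, fat,
liver, rapidly perfused, poorly (slowly) perfused.

For each congener and non-metabolizing tissue t,

    dA_t/dt = Q_t (C_a − C_t),      C_t = A_t / V_t,

with `Q_t` the tissue NLE flow and `C_a` the arterial (blood pool) NLE
concentration. The liver adds a first-order metabolic sink

    dA_L/dt = Q_L (C_a − C_L) − v_cl · C_L,

and the well-mixed blood pool closes the loop: venous return is the
flow-weighted sum of tissue outflow concentrations, arterial outflow is
cardiac output times the pool concentration. Measurable quantities are
concentrations in *total* lipid, obtained per tissue as
`C_tl = C_nl × (V_nl/V_tl)`; plasma lipid is assumed to carry the same
NLE-basis concentration as blood lipid and is converted with the plasma
NLE/total-lipid fraction (0.748).

Conventional physiology of a 225 g reference rat (flows: fat 448, liver
1245, rapid 2540, slow 747 mL blood/h; cardiac output 4980 mL/h; volumes:
blood 20, fat 17.5, liver 10, rapid 12.5, slow 167.5 mL) is converted to
the lipid basis with per-tissue NLE ratios (blood 0.0019, plasma 0.0009,
fat 0.8536, liver/rapid 0.0425, slow 0.0120). Volumes scale with the
tissue's own ratio, all flows with the *blood* ratio. The printed blood
ratio 0.0019 is kept as the default even though the tabulated lipid-basis
cardiac output (9.45 mL lipid/h) back-computes to ≈0.0018976; flow
reproduction is therefore exact only to two decimals, and the
back-calculated ratio can be supplied through the physiology config if a
user prefers it. We do not silently invent precision the source tables do
not print.

Growth: each rat carries an initial and final body weight; weight is
interpolated linearly over the study and held constant outside it. Volumes
scale linearly with body weight and flows with BW^0.75 (standard
allometry, consistent with the BW^0.75 clearance scaling below). When a
measured liver-weight ratio is available the liver NLE volume is
overridden with `ratio × BW × 0.0425` (liver density 1 g/mL).

## Induction model

Hepatic CYP1A and CYP2B amounts follow a zero-order-synthesis /
first-order-degradation balance with a linear stimulation term:

    dA/dt = k0 − ke·A + k0 · F · C_IND,

with one set of turnover constants shared by both enzymes
(A0 = 0.1 nmol/g protein, ke = 0.04 h⁻¹, k0 = ke·A0 = 0.004 nmol/h/g
protein; the steady-state closure k0 = ke·A0 is enforced). Clearance
depends on the enzymes only through the ratio A/A0, so the absolute
baselines are not identifiable and separate per-enzyme constants would
change results only through ke; the package keeps the single shared set.
`C_IND` is the inducer concentration in liver NLE: PCB 118 alone for CYP1A,
the sum of all six congeners (equal weights) for CYP2B. Hill-type
saturation, Ah-receptor occupancy, stimulation time lags, competitive P450
inhibition and Phase-II induction are deliberately out of scope: the linear
slope F absorbs the lumped dose-response, which is adequate at μg/kg doses
where the response stays far from saturation.

Clearance couples back to disposition as

    v_cl = v0 · BW_kg^0.75 · A/A0,

where `v0` (mL/h/kg^0.75) is the congener's basal clearance. PCB 118
(mono-ortho) clears through CYP1A; 138/153/170/180/187 (multi-ortho)
through CYP2B.

With constant exposure the enzyme ratio tends to `A/A0 = 1 + F·C_IND`;
combining with the quasi-steady liver concentration gives
`r(r−1) = F·C⁰`, where `C⁰` is the liver concentration the chemical would
reach without induction. At the default (calibrated-median) slopes this
yields terminal ratios ≈4.6 (CYP1A) and ≈3.2 (CYP2B) for daily
500 μg/kg dosing over 90 days — and, unavoidably for a linear model, a
~10% CYP1A ratio at the 5 μg/kg daily/90-day cell, i.e. the model predicts
a small but not strictly negligible low-dose induction of CYP1A. This is a
structural property of the linear stimulation with the calibrated slope,
not a numerical artifact; shorter or sparser low-dose protocols stay below
~7%.

## Dosing and absorption

Dose levels are per-administration μg of *each* congener per kg body
weight; protocols: daily, weekly, daily-through-day-13, and a nonperiodic
protocol of 13 irregular doses. The irregular times are not published; the
package default is days {0, 1, 2, 5, 8, 9, 15, 22, 29, 43, 57, 71, 85},
fully overridable. Doses are applied as instantaneous boluses into the
liver NLE pool with 100% oral bioavailability — PCBs are nearly completely
absorbed, and routing through the liver preserves first-pass exposure of
the induction sensor. A gut compartment with first-order `ka` is available
as an option. By default the administered mass is recomputed from the body
weight at each dosing time (configurable), since a fixed μg/kg protocol on
a growing animal implies growing doses.

## Observation model and hierarchy

Measurements are tissue total-lipid concentrations in plasma, liver and
(for 90-day sacrifices) adipose tissue. The likelihood is lognormal:

    log y_i = log Y_i + Normal(0, σ_tissue),

with separate σ for plasma, liver and fat. Inter-rat variation is carried
entirely by basal clearance: per rat and congener,
`log v0 ~ Normal(mu_v0, sigma_v0)`. Reported population values are the
geometric means `exp(mu_v0)`. Priors: uniform on `mu_v0` between clearance
bounds 0.001–1.0 mL/h/kg^0.75 (set wide around the physically plausible
decade; also applied as truncation to individual clearances), inverse-gamma
(shape 1, scale 0.8) on `sigma_v0` — placed on the log-SD itself, the scale
matching the initial assumption on the lognormal Σ; a switch moves it to
the variance — uniform [0, 10] on each induction slope, and uniform
[0.01, 2] on each error σ. Induction slopes carry no inter-individual
variation: two slopes serve the whole population, which avoids per-rat
slope parameters that the data cannot identify.

## Two-step calibration

Basal and induced clearance are confounded, so the fit is decomposed:

1. **Step 1** uses only the lowest dose level with induction off (F = 0)
   and samples {mu_v0, sigma_v0, per-rat v0, σ_err}.
2. **Step 2** uses the two higher dose levels and samples
   {F_1A, F_2B, per-rat v0, σ_err}, with per-rat clearances tied to the
   step-1 posterior medians of (mu_v0, sigma_v0) as fixed informative
   priors — the population mean and variance are not updated in step 2.
   If more than 5% of step-2 clearance samples pile up at the prior
   bounds, a warning advises re-optimizing the population parameters.

Error σs are sampled in both steps; letting them float improves mixing.

Sampling is blockwise random-walk Metropolis on log-transformed positive
parameters (Jacobians included): per-congener population blocks
(mu, log sigma), one error block, one per-rat block of six log-clearances,
and in step 2 a two-parameter induction block. Caching follows the block
structure — population and error blocks touch no ODE solution, a rat block
re-simulates only that rat, the induction block re-simulates all rats.
Proposal scales adapt toward a 10% acceptance rate (a Robbins–Monro
multiplicative rule, damped over burn-in) during the first 40% of
iterations only and are frozen afterwards, preserving detailed balance for
every retained sample. Three chains with over-dispersed initial values are
run per step; initials are drawn from documented ranges (population
geometric mean uniform on log[0.005, 0.2], population SD uniform on
[0.15, 1.2], error SDs uniform on log[0.08, 0.8], slopes log-uniform over
about two decades below their plausible maxima), spanning far more than the
posterior spread. Convergence is judged by the classic Gelman–Rubin
between/within-chain statistic on every population-level parameter; chains
are persisted with their seeds and replay bit-identically.

## Numerical solvers

Two forward solvers share one model definition:

* **Reference path** (`kinetics.simulate`): LSODA with analytic Jacobian,
  rtol 1e-8, atol 1e-10 μg, integration restarted at every dose event so
  no discontinuity is stepped across. Used for data generation, reported
  simulations, and all acceptance quantities. Mass balance (absorbed =
  in-body + gut + cumulatively metabolized) holds to ~1e-14 relative.
* **Fast path** (`fastsolve.FastRatContext`): used only inside the MCMC
  likelihood, where ~10⁶ single-rat solves are needed. It treats the blood
  pool as quasi-steady (its NLE volume, 0.038 mL, equilibrates within
  seconds), freezes coefficients over each 24 h interval (clearance from
  the CYP amount at interval start, physiology at the interval-midpoint
  body weight), and propagates each congener's four-tissue subsystem with
  a 5×5 matrix exponential (Padé-13 with scaling and squaring; the fifth
  state accumulates the liver-amount integral). Each day is split into a
  2 h post-dose segment and the remainder so the absorption spike is
  integrated at the right weight; the CYP balance is advanced with its
  exact linear-ODE solution driven by the segment-average liver
  concentration. Propagators are rebuilt only when clearance drifts by
  >3% or body weight by >2% since the last build. Endpoint agreement with
  the reference path is 0.1–1% across the design cells (asserted at 3% in
  the tests); this discrepancy enters the calibration as a model error far
  below the smallest measurement σ (0.19).

Degenerate inputs: zero population or error SDs are accepted by the
generator (producing identical rats / noise-free observations) but never
arise in inference, which works on log scales; nonpositive observations or
predictions raise errors naming the record; `-inf` is a legitimate prior
value outside support, not an error.

## Synthetic-data generator

No real dataset ships with the package, so the generator emulates the
study frame: 3 dose levels (5/50/500 μg/kg) × 4 protocols × 2 sacrifice
days (41/90) × 6 rats per cell = 144 rats (the real study's uneven cells
totalled 142; per-cell overrides can reproduce any total). Per rat it
draws clearances from the population lognormal, covariates from documented
defaults — initial weight Normal(225 g, 15 g) truncated positive, growth
to Normal(1.6, 0.1) × initial by day 90 (interpolated for 41-day rats),
liver-weight ratio Normal(0.04, 0.004) truncated positive — simulates the
rat through its design cell with the reference solver, and multiplies the
sacrifice-time concentrations by `exp(Normal(0, σ_tissue))`. Generating
parameters are stored with each record.

What the generator does *not* emulate: assay detection limits and
censoring, congener cross-contamination, dropout, inter-rat physiological
variation beyond body/liver weight, and any model misspecification — the
data generator and the fitted model share the same structure (up to the
solver difference above). Passing recovery tests therefore demonstrate
that the pipeline is self-consistent and well-calibrated at realistic
noise levels and study sizes, not that the model is correct for real rats.

## Problem sizes used in the tests

The shipped recovery experiment generates the full 144-rat frame with the
calibrated posterior medians as truth, then calibrates with step 1 on all
48 low-dose rats and step 2 on one rat per higher-dose design cell
(16 rats), 3 chains × 10,000 iterations, 40% burn-in — sizes chosen to
exercise the full pipeline at a single-workstation scale. Recovered
population geometric-mean clearances land within 25% of truth, induction
slopes within 50%, error SDs within 25%, with Gelman–Rubin R < 1.2 on
population parameters.

## Known limitations

* The lipid basis cannot produce tissue-specific congener orderings: at
  steady state the multi-ortho concentration ranking is identical in every
  compartment (asserted in the tests as a structural property). Real data
  show mild tissue dependence in that ordering.
* The linear stimulation has no saturation; extrapolation far above
  500 μg/kg would predict unbounded induction.
* A single set of CYP turnover constants serves both enzymes; only the
  ratio A/A0 matters for clearance, so the absolute baselines are not
  identifiable and are taken from the literature values above.
* Basal clearance estimated at the lowest dose absorbs any residual
  low-dose induction (the model itself predicts ~10% for CYP1A at the
  daily low-dose cell), slightly inflating "basal" rates for PCB 118.
* The step-1→step-2 hand-off passes marginal posterior medians only;
  clearance correlations are not propagated.
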