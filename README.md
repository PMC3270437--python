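# lipidpbtk

Lipid-based physiologically based toxicokinetic (PBTK) modelling of a
six-congener PCB mixture in rats, with CYP1A/CYP2B induction and
hierarchical Bayesian population calibration by Metropolis MCMC.

The package is aimed at toxicokinetic modellers who need a fully testable
population-PBTK calibration pipeline for highly lipophilic chemicals:
forward simulation of tissue-lipid concentrations under arbitrary oral
dosing schedules, a synthetic-study generator with realistic inter-animal
variability, a two-step MCMC calibration of population clearances and
induction slopes, and posterior-predictive population evaluation.

## The model

PCBs are assumed to distribute only in the neutral-lipid equivalent (NLE)
space of blood and tissues, which removes tissue/blood partition
coefficients entirely. For each congener and compartment *t* (fat, liver,
rapidly and slowly perfused, around a well-mixed blood pool):

$$\frac{dA_{nlt}}{dt} = Q_{nlt}\,(C_{nla} - C_{nlt}), \qquad
C_{tlt} = C_{nlt}\,\frac{V_{nlt}}{V_{tlt}},$$

with the liver carrying a first-order metabolic sink
$-\,v_0\,(A^{CYP}\!/A_0^{CYP})\,C_{nlL}$. Hepatic enzyme amounts obey a
turnover-and-induction balance with linear stimulation,

$$\frac{dA^{CYP}}{dt} = k_0 - k_e A^{CYP} + k_0 F\, C_{IND},$$

where $C_{IND}$ is the liver-NLE concentration of PCB 118 for CYP1A and
the summed concentration of all six congeners for CYP2B, and metabolic
clearance scales as $v_{cl} = v_0\,\mathrm{BW}^{0.75}\,A^{CYP}/A_0^{CYP}$.
PCB 118 (mono-ortho) is metabolized via CYP1A; congeners 138, 153, 170,
180 and 187 (multi-ortho) via CYP2B.

Inter-rat variability enters through basal clearance,
$\log v_0^{(i)} \sim \mathrm{Normal}(\mu_{v_0}, \Sigma_{v_0})$ per
congener, and measurements are lognormal around model predictions with a
separate error SD per tissue (plasma, liver, fat). Calibration is
decomposed into two Metropolis MCMC steps — basal clearances from the
lowest dose with induction off, then induction slopes from the two higher
doses under the step-1 population posteriors as fixed informative priors —
with three over-dispersed chains and Gelman–Rubin convergence checks.
See `docs/methods.md` for assumptions, priors, solver details and
limitations.

## Worked example

```python
import lipidpbtk as lp

# a small synthetic study: 3 dose levels x 2 protocols x 2 sacrifice days
design = lp.StudyDesign(
    dose_levels=(5.0, 50.0, 500.0), protocols=("daily", "weekly"),
    sacrifice_days=(41, 90), rats_per_cell=2, seed=42,
)
truth = lp.HierarchicalParams.reference()
records = lp.generate_population(design, truth, seed=42)

model = lp.PBTKPopulationModel(records)
results = model.fit(n_iter=4000, n_chains=2, seed=1)
print(results.summary())

report = results.induction_ratios(dose_level=500.0, protocol="daily")
print(report.terminal)
```

Output (abridged):

```
   parameter  step   median     cv  r_hat
      v0_118     1  0.02939 0.2567  1.012
sigma_v0_118     1   0.4399 0.5647  1.026
      v0_138     1  0.02762 0.2576  1.021
      ...
        F_2B     2 0.001854 0.2293  1.001
        F_1A     2  0.07558 0.2546  1.005
sigma_plasma     1    0.198 0.1418  1.007
 sigma_liver     1   0.3051 0.1245   1.02
   sigma_fat     1   0.3253  0.179      1
terminal clearance increase: CYP1A 6.58x, CYP2B 2.90x
```

Each `summary()` row is one population parameter: `v0_<PCB>` is the
posterior median of the population geometric-mean basal clearance
(mL/h/kg^0.75), `sigma_v0_<PCB>` the lognormal population SD, `F_1A`/`F_2B`
the induction slopes, and `sigma_<tissue>` the lognormal measurement-error
SD, with the chain coefficient of variation and the Gelman–Rubin R per
parameter. At this toy size (24 rats, 8 of them low-dose) the clearances
land near the generating values (e.g. `v0_138` 0.0276 vs 0.026 generated)
while loosely informed parameters such as `F_1A` remain noisy — the full
144-rat recovery experiment in `tests/test_acceptance.py` recovers all
population clearances within 25%. The induction report says that under
daily 500 μg/kg dosing this fit predicts a ~6.6-fold increase in PCB 118
(CYP1A) clearance and ~2.9-fold for the multi-ortho congeners by day 90;
at the calibrated reference medians those factors are 4.64 and 3.24.

A thin CLI wraps the same functions:

```sh
lipidpbtk generate --seed 1 --design-out design.csv --obs-out obs.csv
lipidpbtk calibrate --design design.csv --obs obs.csv --n-iter 10000
lipidpbtk evaluate --dose 500 --protocol daily
```

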