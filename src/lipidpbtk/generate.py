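"""Synthetic rat studies with the statistical structure the analysis assumes.

The generator emulates the mixture study frame — 3 dose levels x 4 dose
protocols x 2 sacrifice days, ~6 rats per cell — with lognormal inter-rat
variation in basal clearance and tissue-specific lognormal measurement
error.  Body-weight trajectories and liver-weight ratios are drawn from
documented default distributions (the study reports measuring them but not
their spread): initial BW ~ Normal(225 g, 15 g) truncated positive, growth
to Normal(1.6, 0.1) x initial by day 90, liver-weight ratio ~
Normal(0.04, 0.004) truncated positive.

Each rat is simulated through its design cell with the reference ODE path
and observed at sacrifice in plasma and liver total lipids (plus adipose
for rats sacrificed at 90 days); observations are the noise-free
concentrations times exp(Normal(0, sigma_tissue)).  The generating per-rat
clearances are stored alongside the records.
"""

from __future__ import annotations

import numpy as np

from .dosing import build_schedule
from .induction import DEFAULT_CONGENERS, CongenerSpec, InductionParams
from .kinetics import simulate
from .physiology import NLEPhysiology, RatCovariates, default_nle_physiology
from .priors import HierarchicalParams
from .study import Observation, StudyDesign, StudyRecord

__all__ = ["sample_individual_clearances", "sample_covariates", "generate_population"]

# Documented default covariate distributions.
BW0_MEAN, BW0_SD = 225.0, 15.0
GROWTH_MEAN, GROWTH_SD = 1.6, 0.1
LWR_MEAN, LWR_SD = 0.04, 0.004
GROWTH_HORIZON_DAYS = 90.0


def _truncated_normal(rng: np.random.Generator, mean, sd, lo=0.0, hi=np.inf):
    """Draw one Normal(mean, sd) variate truncated to (lo, hi) by rejection."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def sample_individual_clearances(
    pop: HierarchicalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-rat basal clearances, shape (n, n_congeners).

    log v0 ~ Normal(mu_v0, sigma_v0) per congener (natural log), so the
    geometric mean of the draws converges to exp(mu_v0) and the SD of their
    logs to sigma_v0.
    """
    mu = np.array([pop.mu_v0[c] for c in pop.congeners])
    sig = np.array([pop.sigma_v0[c] for c in pop.congeners])
    return np.exp(rng.normal(mu, sig, size=(n, len(mu))))


def sample_covariates(
    rng: np.random.Generator, sacrifice_day: float
) -> RatCovariates:
    """Body-weight trajectory and liver-weight ratio for one rat."""
    bw0 = _truncated_normal(rng, BW0_MEAN, BW0_SD)
    growth = _truncated_normal(rng, GROWTH_MEAN, GROWTH_SD, lo=1.0)
    bw_final = bw0 * (1.0 + (growth - 1.0) * sacrifice_day / GROWTH_HORIZON_DAYS)
    lwr = _truncated_normal(rng, LWR_MEAN, LWR_SD, lo=1e-6, hi=0.0999)
    return RatCovariates(
        initial_body_weight=bw0,
        final_body_weight=bw_final,
        sacrifice_day=sacrifice_day,
        liver_weight_ratio=lwr,
    )


def generate_population(
    design: StudyDesign,
    pop: HierarchicalParams,
    seed: int | None = None,
    phys: NLEPhysiology | None = None,
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    induction_constants: InductionParams | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    vary_covariates: bool = True,
) -> list[StudyRecord]:
    """Generate a synthetic study: one record per rat of the design.

    ``pop`` supplies the generating population (mu_v0/sigma_v0 per congener,
    induction slopes, per-tissue error SDs).  With ``vary_covariates=False``
    every rat uses the mean covariates, so ``sigma_v0 = 0`` and
    ``sigma_err = 0`` make all same-cell rats identical and observations
    equal the model predictions exactly.  A fixed ``seed`` makes the output
    reproducible draw-for-draw.
    """
    phys = default_nle_physiology() if phys is None else phys
    base = InductionParams() if induction_constants is None else induction_constants
    induction = InductionParams(
        A0=base.A0, ke=base.ke, k0=base.k0, F_1A=pop.F_1A, F_2B=pop.F_2B
    )
    names = [c.name for c in congeners]
    if set(names) != set(pop.congeners):
        raise ValueError("population parameters and congener set do not match")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    records: list[StudyRecord] = []
    rat_no = 0
    for dose, protocol, day in design.cells():
        schedule = build_schedule(protocol, dose, day)
        for _ in range(design.rats_in(dose, protocol, day)):
            rat_no += 1
            if vary_covariates:
                cov = sample_covariates(rng, float(day))
            else:
                cov = RatCovariates(
                    initial_body_weight=BW0_MEAN,
                    final_body_weight=BW0_MEAN
                    * (1.0 + (GROWTH_MEAN - 1.0) * day / GROWTH_HORIZON_DAYS),
                    sacrifice_day=float(day),
                    liver_weight_ratio=LWR_MEAN,
                )
            v0 = sample_individual_clearances(pop, 1, rng)[0]
            specs = tuple(
                CongenerSpec(c.name, c.ortho_class, c.metabolizing_enzyme, v)
                for c, v in zip(congeners, v0)
            )
            res = simulate(
                phys=phys,
                congeners=specs,
                induction=induction,
                schedule=schedule,
                covariates=cov,
                t_grid=np.array([0.0, day * 24.0]),
                rtol=rtol,
                atol=atol,
            )
            tissues = ["plasma", "liver"] + (["fat"] if day >= 90 else [])
            observations = []
            for tissue in tissues:
                sigma = pop.sigma_err[tissue]
                for name in names:
                    y = res.final(name, tissue) * np.exp(rng.normal(0.0, sigma))
                    observations.append(Observation(name, tissue, y))
            records.append(
                StudyRecord(
                    rat_id=f"r{rat_no:03d}",
                    dose_level=float(dose),
                    protocol=protocol,
                    sacrifice_day=int(day),
                    covariates=cov,
                    observations=observations,
                    true_v0={n: float(v) for n, v in zip(names, v0)},
                )
            )
    return records
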