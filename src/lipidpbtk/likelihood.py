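"""Lognormal likelihood and hierarchical prior of the population model.

The likelihood assumes log measurements scatter normally around log model
predictions with a tissue-specific SD:

    log y_i = log Y_i + Normal(0, sigma_tissue),

with separate sigma for plasma, liver and fat.  The prior combines wide
uniforms on the population mean log-clearances (bounds on the clearance
scale), an inverse-gamma on each population log-SD, uniforms on the
induction slopes and error SDs, and the hierarchical lognormal terms tying
each rat's clearances to the population.

These functions are the plain, direct implementations used by tests and
small problems; the MCMC engine in :mod:`lipidpbtk.calibrate` evaluates the
same quantities incrementally through cached per-rat simulations.
"""

from __future__ import annotations

import math

import numpy as np

from .fastsolve import FastRatContext
from .induction import DEFAULT_CONGENERS, CongenerSpec, InductionParams
from .physiology import NLEPhysiology, default_nle_physiology
from .priors import HierarchicalParams, PriorSpec
from .study import StudyRecord

__all__ = ["build_contexts", "log_likelihood", "log_prior"]

_LOG_2PI = math.log(2.0 * math.pi)


def build_contexts(
    records: list[StudyRecord],
    phys: NLEPhysiology | None = None,
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    **fast_opts,
) -> dict[str, FastRatContext]:
    """One fast-solver context per rat, keyed by rat_id."""
    from .dosing import build_schedule

    phys = default_nle_physiology() if phys is None else phys
    out = {}
    for r in records:
        schedule = build_schedule(r.protocol, r.dose_level, r.sacrifice_day)
        out[r.rat_id] = FastRatContext(
            phys, congeners, schedule, r.covariates, **fast_opts
        )
    return out


def log_likelihood(
    params: HierarchicalParams,
    records: list[StudyRecord],
    contexts: dict[str, FastRatContext],
    induction_constants: InductionParams | None = None,
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
) -> float:
    """Sum of lognormal observation log-densities over all records.

    ``params.v0_individual`` must carry every rat's clearances.  Raises a
    ``ValueError`` naming the record for a nonpositive observation or
    prediction.
    """
    base = InductionParams() if induction_constants is None else induction_constants
    induction = InductionParams(
        A0=base.A0, ke=base.ke, k0=base.k0, F_1A=params.F_1A, F_2B=params.F_2B
    )
    names = [c.name for c in congeners]
    if params.v0_individual is None:
        raise ValueError("params.v0_individual is required for the likelihood")
    total = 0.0
    for r in records:
        v0 = np.array([params.v0_individual[r.rat_id][n] for n in names])
        pred = contexts[r.rat_id].predict(v0, induction)
        for o in r.observations:
            y_hat = float(pred[o.tissue][names.index(o.congener)])
            if o.concentration <= 0 or y_hat <= 0:
                raise ValueError(
                    f"nonpositive observation or prediction for rat {r.rat_id}, "
                    f"PCB {o.congener}, {o.tissue}"
                )
            sigma = params.sigma_err[o.tissue]
            resid = math.log(o.concentration) - math.log(y_hat)
            total += -math.log(sigma) - 0.5 * _LOG_2PI - 0.5 * (resid / sigma) ** 2
    return total


def log_prior(params: HierarchicalParams, priors: PriorSpec) -> float:
    """Log prior density of population and individual parameters.

    Returns ``-inf`` outside the support (never raises).  Individual
    clearances carry lognormal(mu_v0, sigma_v0) terms and are truncated to
    the same clearance bounds as the population mean.
    """
    lo, hi = priors.log_v0_bounds
    total = 0.0
    for k in params.congeners:
        mu = params.mu_v0[k]
        if not lo <= mu <= hi:
            return -np.inf
        total += -math.log(hi - lo)
        total += priors.log_ig_pdf(params.sigma_v0[k])
    if not np.isfinite(total):
        return -np.inf

    f_lo, f_hi = priors.f_bounds
    for f in (params.F_1A, params.F_2B):
        if not f_lo <= f <= f_hi:
            return -np.inf
        total += -math.log(f_hi - f_lo)

    s_lo, s_hi = priors.sigma_err_bounds
    for sigma in params.sigma_err.values():
        if not s_lo <= sigma <= s_hi:
            return -np.inf
        total += -math.log(s_hi - s_lo)

    if params.v0_individual is not None:
        for rat, v0s in params.v0_individual.items():
            for k, v in v0s.items():
                if v <= 0:
                    return -np.inf
                lv = math.log(v)
                if not lo <= lv <= hi:
                    return -np.inf
                sig = params.sigma_v0[k]
                total += (
                    -lv
                    - math.log(sig)
                    - 0.5 * _LOG_2PI
                    - 0.5 * ((lv - params.mu_v0[k]) / sig) ** 2
                )
    return total
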