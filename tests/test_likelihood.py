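"""Lognormal likelihood and hierarchical prior against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from lipidpbtk import (
    HierarchicalParams,
    PriorSpec,
    StudyDesign,
    build_contexts,
    generate_population,
    log_likelihood,
    log_prior,
)
from lipidpbtk.induction import DEFAULT_CONGENERS, InductionParams
from lipidpbtk.study import Observation


@pytest.fixture(scope="module")
def one_rat_study():
    design = StudyDesign(
        dose_levels=(5.0,), protocols=("daily",), sacrifice_days=(41,),
        rats_per_cell=1, seed=2,
    )
    recs = generate_population(design, HierarchicalParams.reference(), seed=2)
    return recs


def _params_with_individual(records, sigma_err):
    pop = HierarchicalParams.reference()
    return HierarchicalParams(
        mu_v0=dict(pop.mu_v0),
        sigma_v0=dict(pop.sigma_v0),
        F_1A=0.0,
        F_2B=0.0,
        sigma_err=dict(sigma_err),
        v0_individual={r.rat_id: dict(r.true_v0) for r in records},
    )


class TestLogLikelihood:
    def test_zero_residuals_closed_form(self, one_rat_study):
        """If y_i = Y_i for all i the log-likelihood is -N log(s sqrt(2 pi))."""
        recs = one_rat_study
        ctx = build_contexts(recs)
        params = _params_with_individual(recs, {"plasma": 0.5, "liver": 0.5, "fat": 0.5})
        # replace observations with the model's own predictions
        names = [c.name for c in DEFAULT_CONGENERS]
        ind = InductionParams(F_1A=0.0, F_2B=0.0)
        recs_copy = []
        for src in recs:
            v0 = np.array([src.true_v0[n] for n in names])
            pred = ctx[src.rat_id].predict(v0, ind)
            obs = [
                Observation(
                    o.congener, o.tissue, float(pred[o.tissue][names.index(o.congener)])
                )
                for o in src.observations
            ]
            recs_copy.append(
                type(src)(
                    rat_id=src.rat_id,
                    dose_level=src.dose_level,
                    protocol=src.protocol,
                    sacrifice_day=src.sacrifice_day,
                    covariates=src.covariates,
                    observations=obs,
                    true_v0=src.true_v0,
                )
            )
        n = sum(len(r.observations) for r in recs_copy)
        ll = log_likelihood(params, recs_copy, ctx)
        assert ll == pytest.approx(-n * math.log(0.5 * math.sqrt(2 * math.pi)), rel=1e-9)

    def test_hand_summed_density_oracle(self, one_rat_study):
        """A small case must match scipy's normal density summed by hand."""
        recs = one_rat_study
        r = recs[0]
        r3 = type(r)(
            rat_id=r.rat_id,
            dose_level=r.dose_level,
            protocol=r.protocol,
            sacrifice_day=r.sacrifice_day,
            covariates=r.covariates,
            observations=r.observations[:3],
            true_v0=r.true_v0,
        )
        sigma_err = {"plasma": 0.2, "liver": 0.4, "fat": 0.3}
        params = _params_with_individual([r3], sigma_err)
        ctx = build_contexts([r3])
        names = [c.name for c in DEFAULT_CONGENERS]
        pred = ctx[r3.rat_id].predict(
            np.array([r3.true_v0[n] for n in names]), InductionParams(F_1A=0.0, F_2B=0.0)
        )
        expected = 0.0
        for o in r3.observations:
            y_hat = pred[o.tissue][names.index(o.congener)]
            expected += stats.norm.logpdf(
                math.log(o.concentration), loc=math.log(y_hat), scale=sigma_err[o.tissue]
            )
        assert log_likelihood(params, [r3], ctx) == pytest.approx(expected, rel=1e-10)

    def test_sigma_scaling_identity(self, one_rat_study):
        """Doubling sigma changes each term by -log2 + (r^2/2)(1/s^2 - 1/4s^2)."""
        recs = one_rat_study
        ctx = build_contexts(recs)
        s = 0.25
        p1 = _params_with_individual(recs, {"plasma": s, "liver": s, "fat": s})
        p2 = _params_with_individual(recs, {"plasma": 2 * s, "liver": 2 * s, "fat": 2 * s})
        ll1, ll2 = log_likelihood(p1, recs, ctx), log_likelihood(p2, recs, ctx)
        # recompute residuals to apply the algebraic identity
        names = [c.name for c in DEFAULT_CONGENERS]
        ind = InductionParams(F_1A=0.0, F_2B=0.0)
        rsq = 0.0
        n = 0
        for r in recs:
            pred = ctx[r.rat_id].predict(np.array([r.true_v0[k] for k in names]), ind)
            for o in r.observations:
                y_hat = pred[o.tissue][names.index(o.congener)]
                rsq += (math.log(o.concentration) - math.log(y_hat)) ** 2
                n += 1
        delta = -n * math.log(2.0) + rsq / 2.0 * (1.0 / s**2 - 1.0 / (2 * s) ** 2)
        assert ll2 - ll1 == pytest.approx(delta, rel=1e-9)

    def test_missing_individual_clearances_rejected(self, one_rat_study):
        pop = HierarchicalParams.reference()
        ctx = build_contexts(one_rat_study)
        with pytest.raises(ValueError, match="v0_individual"):
            log_likelihood(pop, one_rat_study, ctx)


class TestLogPrior:
    def test_outside_uniform_bounds_is_minus_inf(self):
        priors = PriorSpec()
        pop = HierarchicalParams.reference()
        bad = HierarchicalParams(
            mu_v0={**pop.mu_v0, "118": math.log(5.0)},  # above 1.0 mL/h/kg^0.75
            sigma_v0=dict(pop.sigma_v0),
            sigma_err=dict(pop.sigma_err),
        )
        assert log_prior(bad, priors) == -np.inf
        bad_f = HierarchicalParams(
            mu_v0=dict(pop.mu_v0),
            sigma_v0=dict(pop.sigma_v0),
            F_1A=25.0,
            sigma_err=dict(pop.sigma_err),
        )
        assert log_prior(bad_f, priors) == -np.inf

    def test_hierarchical_term_matches_lognormal_density(self):
        """A rat at exactly exp(mu) contributes the lognormal density there."""
        priors = PriorSpec()
        pop = HierarchicalParams.reference()
        base = HierarchicalParams(
            mu_v0=dict(pop.mu_v0), sigma_v0=dict(pop.sigma_v0),
            sigma_err=dict(pop.sigma_err),
        )
        with_rat = HierarchicalParams(
            mu_v0=dict(pop.mu_v0), sigma_v0=dict(pop.sigma_v0),
            sigma_err=dict(pop.sigma_err),
            v0_individual={"r1": {"118": math.exp(pop.mu_v0["118"])}},
        )
        delta = log_prior(with_rat, priors) - log_prior(base, priors)
        expected = stats.lognorm.logpdf(
            math.exp(pop.mu_v0["118"]),
            s=pop.sigma_v0["118"],
            scale=math.exp(pop.mu_v0["118"]),
        )
        assert delta == pytest.approx(expected, rel=1e-10)

    def test_inverse_gamma_peaks_at_mode(self):
        """IG(shape 1, scale 0.8) has its mode at scale/(shape+1) = 0.4."""
        priors = PriorSpec()
        grid = np.linspace(0.05, 2.0, 391)
        vals = [priors.log_ig_pdf(s) for s in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.4, abs=0.01)
        # and matches scipy's parameterization everywhere
        expected = stats.invgamma.logpdf(grid, a=1.0, scale=0.8)
        np.testing.assert_allclose(vals, expected, rtol=1e-10)

    def test_variance_parameterization_switch(self):
        priors = PriorSpec(ig_on_variance=True)
        sigma = 0.6
        expected = stats.invgamma.logpdf(sigma**2, a=1.0, scale=0.8) + math.log(2 * sigma)
        assert priors.log_ig_pdf(sigma) == pytest.approx(expected, rel=1e-10)
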