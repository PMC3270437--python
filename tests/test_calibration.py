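"""Calibration machinery on small problems: grid oracle, determinism, variants."""

import math

import numpy as np
import pytest

from lipidpbtk import (
    DEFAULT_CONGENERS,
    HierarchicalParams,
    InductionParams,
    PBTKPopulationModel,
    StudyDesign,
    build_contexts,
    generate_population,
    metropolis_run,
    run_step,
)
from lipidpbtk.induction import CongenerSpec

SINGLE_118 = (CongenerSpec("118", "mono-ortho", "CYP1A", 0.038),)


def _single_congener_study(seed=4, n_rats=1):
    """One low-dose rat observed for PCB 118 only."""
    design = StudyDesign(
        dose_levels=(5.0,), protocols=("daily",), sacrifice_days=(41,),
        rats_per_cell=n_rats, seed=seed,
    )
    pop = HierarchicalParams(
        mu_v0={"118": math.log(0.038)},
        sigma_v0={"118": 0.24},
        sigma_err={"plasma": 0.19, "liver": 0.40, "fat": 0.30},
    )
    return generate_population(design, pop, seed=seed, congeners=SINGLE_118), pop


@pytest.fixture(scope="module")
def slice_posterior():
    recs, pop = _single_congener_study()
    rec = recs[0]
    ctx = build_contexts(recs, congeners=SINGLE_118)[rec.rat_id]
    ind = InductionParams(F_1A=0.0, F_2B=0.0)
    sigma_pop = 0.24
    sig = {"plasma": 0.19, "liver": 0.40, "fat": 0.30}
    obs = [(o.tissue, math.log(o.concentration)) for o in rec.observations]
    mu_lo, mu_hi = math.log(0.005), math.log(0.3)

    def loglik(lv0):
        pred = ctx.predict(np.array([math.exp(lv0)]), ind)
        total = 0.0
        for tissue, ly in obs:
            total += -0.5 * ((ly - math.log(pred[tissue][0])) / sig[tissue]) ** 2
        return total

    def logpost(x):
        mu, lv0 = x
        if not mu_lo <= mu <= mu_hi:
            return -np.inf
        return loglik(lv0) - 0.5 * ((lv0 - mu) / sigma_pop) ** 2

    return loglik, logpost, (mu_lo, mu_hi), sigma_pop


@pytest.fixture(scope="module")
def tiny_low_dose():
    design = StudyDesign(
        dose_levels=(5.0,), protocols=("daily", "weekly"), sacrifice_days=(41,),
        rats_per_cell=1, seed=6,
    )
    return generate_population(design, HierarchicalParams.reference(), seed=6)


class TestGridOracle:
    """MCMC vs dense-grid integration on a 2-parameter slice.

    One rat, one congener, sigma_v0 and sigma_err fixed: the joint posterior
    of (mu, log v0) is evaluated on a dense grid by quadrature and compared
    with the Metropolis samples — two independent routes to the same density.
    """

    def test_mcmc_matches_grid_quadrature(self, slice_posterior):
        loglik, logpost, (mu_lo, mu_hi), sigma_pop = slice_posterior
        mus = np.linspace(mu_lo, mu_hi, 121)
        lvs = np.linspace(math.log(0.005), math.log(0.3), 121)
        ll = np.array([loglik(lv) for lv in lvs])  # likelihood: lv0 only
        grid = ll[None, :] - 0.5 * ((lvs[None, :] - mus[:, None]) / sigma_pop) ** 2
        w = np.exp(grid - grid.max())
        w /= w.sum()
        mu_mean = float((w.sum(axis=1) * mus).sum())
        lv_mean = float((w.sum(axis=0) * lvs).sum())
        lv_sd = float(np.sqrt((w.sum(axis=0) * (lvs - lv_mean) ** 2).sum()))

        chain = metropolis_run(
            logpost,
            np.array([math.log(0.02), math.log(0.02)]),
            40_000,
            blocks=[np.array([0]), np.array([1])],
            scales=0.3,
            target_acceptance=0.3,
            seed=9,
        )
        kept = chain.burned(0.25)
        assert kept[:, 0].mean() == pytest.approx(mu_mean, abs=0.05)
        assert kept[:, 1].mean() == pytest.approx(lv_mean, abs=0.05)
        assert kept[:, 1].std() == pytest.approx(lv_sd, rel=0.2)

    def test_duplicated_data_sharpens_toward_likelihood_peak(self, slice_posterior):
        """Doubling the data pulls the posterior toward the likelihood mode."""
        loglik, _, _, sigma_pop = slice_posterior
        lvs = np.linspace(math.log(0.005), math.log(0.3), 241)
        ll = np.array([loglik(lv) for lv in lvs])
        mu0 = math.log(0.038)
        prior = -0.5 * ((lvs - mu0) / sigma_pop) ** 2
        mle = lvs[np.argmax(ll)]

        def post_mean(mult):
            g = mult * ll + prior
            w = np.exp(g - g.max())
            w /= w.sum()
            return float((w * lvs).sum())

        assert abs(post_mean(2) - mle) <= abs(post_mean(1) - mle) + 1e-9


class TestRunStep:
    def test_seeded_chains_replay_bit_identically(self, tiny_low_dose):
        a = run_step(tiny_low_dose, n_iter=200, n_chains=2, seed=13)
        b = run_step(tiny_low_dose, n_iter=200, n_chains=2, seed=13)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.samples, cb.samples)
            np.testing.assert_array_equal(ca.log_posterior, cb.log_posterior)

    def test_near_noise_free_posterior_concentrates_at_truth(self):
        """With sigma_err -> 0.01 the per-rat clearances pin to the generator truth."""
        design = StudyDesign(
            dose_levels=(5.0,), protocols=("daily",), sacrifice_days=(41, 90),
            rats_per_cell=2, seed=8,
        )
        pop = HierarchicalParams.reference()
        tight = HierarchicalParams(
            mu_v0=dict(pop.mu_v0),
            sigma_v0=dict(pop.sigma_v0),
            sigma_err={t: 0.01 for t in pop.sigma_err},
        )
        recs = generate_population(design, tight, seed=8)
        res = run_step(recs, n_iter=3000, n_chains=2, seed=1)
        fitted = res.per_rat_v0_medians()
        rel_errs = []
        for r in recs:
            for name, truth in r.true_v0.items():
                rel_errs.append(abs(fitted[r.rat_id][name] / truth - 1.0))
        # fast-solver vs reference-generator discrepancy bounds the floor (~1%)
        assert float(np.median(rel_errs)) < 0.05
        assert float(np.max(rel_errs)) < 0.25


class TestIntervalCoverage:
    def test_credible_intervals_cover_generating_values(self):
        """95% CIs for the population clearances cover truth in >= 80% of runs.

        Five seeded replications of a small low-dose study; coverage is
        counted across congener x replication.
        """
        truth = HierarchicalParams.reference()
        covered = total = 0
        for rep in range(5):
            design = StudyDesign(
                dose_levels=(5.0,), protocols=("daily", "weekly"),
                sacrifice_days=(41,), rats_per_cell=1, seed=100 + rep,
            )
            recs = generate_population(design, truth, seed=100 + rep)
            res = run_step(recs, n_iter=1500, n_chains=2, seed=rep)
            for c in DEFAULT_CONGENERS:
                t = res.trace(f"mu_v0_{c.name}").ravel()
                lo, hi = np.percentile(t, [2.5, 97.5])
                total += 1
                covered += int(lo <= math.exp(truth.mu_v0[c.name]) <= hi)
        assert covered / total >= 0.8


class TestPooledVariant:
    def test_pooled_posterior_consistent_with_separate_fits(self):
        """With exchangeable congeners the pooled fit agrees with per-PCB fits."""
        design = StudyDesign(
            dose_levels=(5.0,), protocols=("daily", "weekly"), sacrifice_days=(41,),
            rats_per_cell=2, seed=10,
        )
        shared = HierarchicalParams(
            mu_v0={c.name: math.log(0.027) for c in DEFAULT_CONGENERS},
            sigma_v0={c.name: 0.43 for c in DEFAULT_CONGENERS},
            sigma_err={"plasma": 0.19, "liver": 0.40, "fat": 0.30},
        )
        recs = generate_population(design, shared, seed=10)
        model = PBTKPopulationModel(recs)
        pooled = model.fit_pooled(n_iter=2500, n_chains=2, seed=3)
        separate = run_step(recs, n_iter=2500, n_chains=2, seed=3)
        pooled_v0 = pooled.median("mu_v0_all")
        sep_v0 = [separate.median(f"mu_v0_{c.name}") for c in DEFAULT_CONGENERS]
        assert min(sep_v0) * 0.9 <= pooled_v0 <= max(sep_v0) * 1.1
        # and the pooled estimate is near the shared generating value
        assert pooled_v0 == pytest.approx(0.027, rel=0.35)

    def test_single_rat_input_is_prior_dominated(self):
        recs, _ = _single_congener_study(seed=12)
        res = run_step(
            recs, congeners=SINGLE_118, n_iter=1500, n_chains=2, seed=2, pooled=True
        )
        sigma = res.median("log_sigma_v0_all")
        # one rat cannot inform the population SD: it stays in the broad
        # region favoured by the IG(1, 0.8) prior rather than collapsing
        assert 0.1 < sigma < 3.0
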