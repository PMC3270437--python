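"""Population Monte-Carlo bands, induction ratios, predicted vs observed."""

import math

import numpy as np
import pytest

from lipidpbtk import (
    HierarchicalParams,
    StudyDesign,
    generate_population,
    induction_ratio_report,
    monte_carlo_population,
    predicted_vs_observed,
)
from lipidpbtk.fastsolve import FastRatContext
from lipidpbtk.induction import DEFAULT_CONGENERS, InductionParams
from lipidpbtk.dosing import build_schedule
from lipidpbtk.population import median_rat_covariates


def _pop(sigma_v0=None, sigma_err=None, f_1a=None, f_2b=None):
    ref = HierarchicalParams.reference()
    return HierarchicalParams(
        mu_v0=dict(ref.mu_v0),
        sigma_v0={k: (sigma_v0 if sigma_v0 is not None else v) for k, v in ref.sigma_v0.items()},
        F_1A=ref.F_1A if f_1a is None else f_1a,
        F_2B=ref.F_2B if f_2b is None else f_2b,
        sigma_err={k: (sigma_err if sigma_err is not None else v) for k, v in ref.sigma_err.items()},
    )


class TestMonteCarloPopulation:
    def test_zero_population_sd_gives_zero_width_bands(self):
        run = monte_carlo_population(_pop(sigma_v0=0.0), 5.0, "daily", 41, n_draws=20, seed=1)
        b = run.bands
        np.testing.assert_allclose(b["lower"], b["upper"], rtol=1e-12)
        np.testing.assert_allclose(b["lower"], b["median"], rtol=1e-12)

    def test_bands_are_nested_and_seeded(self, reference_pop):
        a = monte_carlo_population(reference_pop, 50.0, "weekly", 41, n_draws=60, seed=4)
        b = monte_carlo_population(reference_pop, 50.0, "weekly", 41, n_draws=60, seed=4)
        np.testing.assert_array_equal(a.conc, b.conc)
        bands = a.bands
        assert np.all(bands["lower"] <= bands["median"] + 1e-15)
        assert np.all(bands["median"] <= bands["upper"] + 1e-15)

    def test_sampled_clearances_span_a_factor_of_two(self, reference_pop):
        """At 1000 draws the clearance spread matches the lognormal quantiles.

        A population log-SD around 0.24-0.55 means individuals deviate from
        the geometric mean by up to a factor ~2 at the 97.5th percentile.
        """
        run = monte_carlo_population(reference_pop, 5.0, "daily", 90, n_draws=1000, seed=0)
        names = run.congener_names
        for j, name in enumerate(names):
            sig = reference_pop.sigma_v0[name]
            lo, med, hi = np.percentile(run.v0_draws[:, j], [2.5, 50, 97.5])
            assert hi / med == pytest.approx(math.exp(1.96 * sig), rel=0.12)
            assert med / lo == pytest.approx(math.exp(1.96 * sig), rel=0.12)
        spread = np.exp(1.96 * np.array([reference_pop.sigma_v0[n] for n in names]))
        assert spread.min() > 1.5 and spread.max() < 3.2  # "factor of ~2"

    def test_median_parameter_run_lies_inside_band(self, reference_pop, phys):
        run = monte_carlo_population(reference_pop, 500.0, "daily", 90, n_draws=200, seed=2)
        ctx = FastRatContext(
            phys, DEFAULT_CONGENERS, build_schedule("daily", 500.0, 90),
            median_rat_covariates(90),
        )
        ind = InductionParams(F_1A=reference_pop.F_1A, F_2B=reference_pop.F_2B)
        med = ctx.predict(np.exp([reference_pop.mu_v0[n] for n in run.congener_names]), ind)
        b = run.bands
        for iu, tissue in enumerate(run.tissues):
            assert np.all(med[tissue] >= b["lower"][0, :, iu])
            assert np.all(med[tissue] <= b["upper"][0, :, iu])

    def test_rejects_degenerate_draw_count(self, reference_pop):
        with pytest.raises(ValueError):
            monte_carlo_population(reference_pop, 5.0, "daily", 41, n_draws=1)


class TestInductionRatios:
    def test_zero_slopes_pin_ratio_to_one(self):
        rep = induction_ratio_report(_pop(f_1a=0.0, f_2b=0.0), 500.0, "daily", 90)
        assert np.allclose(rep.trajectory["ratio_CYP1A"], 1.0, atol=1e-9)
        assert np.allclose(rep.trajectory["ratio_CYP2B"], 1.0, atol=1e-9)

    def test_ratio_monotone_in_dose(self, reference_pop):
        ratios = [
            induction_ratio_report(reference_pop, d, "daily", 41).terminal["CYP2B"]
            for d in (5.0, 50.0, 500.0)
        ]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_concentrated_dosing_induces_at_least_as_much_as_sporadic(
        self, reference_pop
    ):
        """13 daily doses beat the same 13 doses spread over 85 days."""
        burst = induction_ratio_report(reference_pop, 500.0, "daily-to-day-13", 90)
        spread = induction_ratio_report(reference_pop, 500.0, "nonperiodic", 90)
        for enzyme in ("CYP1A", "CYP2B"):
            assert burst.maximum[enzyme] >= spread.maximum[enzyme]


@pytest.fixture(scope="module")
def noisy_study():
    design = StudyDesign(
        dose_levels=(50.0,), protocols=("daily", "weekly"), sacrifice_days=(41, 90),
        rats_per_cell=2, seed=21,
    )
    pop = _pop(sigma_err=0.3)
    return generate_population(design, pop, seed=21), pop


class TestPredictedVsObserved:
    def test_noise_free_records_sit_on_identity_line(self):
        design = StudyDesign(
            dose_levels=(50.0,), protocols=("daily",), sacrifice_days=(41,),
            rats_per_cell=2, seed=22,
        )
        pop = _pop(sigma_err=0.0)
        recs = generate_population(design, pop, seed=22)
        fitted = HierarchicalParams(
            mu_v0=dict(pop.mu_v0),
            sigma_v0=dict(pop.sigma_v0),
            F_1A=pop.F_1A,
            F_2B=pop.F_2B,
            sigma_err={"plasma": 0.01, "liver": 0.01, "fat": 0.01},
            v0_individual={r.rat_id: dict(r.true_v0) for r in recs},
        )
        table, stats = predicted_vs_observed(recs, fitted)
        # identical parameters; only the fast-vs-reference solver gap remains
        assert np.abs(table["log_residual"]).max() < 0.03

    def test_noise_sd_recovered_per_tissue(self, noisy_study):
        recs, pop = noisy_study
        fitted = HierarchicalParams(
            mu_v0=dict(pop.mu_v0),
            sigma_v0=dict(pop.sigma_v0),
            F_1A=pop.F_1A,
            F_2B=pop.F_2B,
            sigma_err=dict(pop.sigma_err),
            v0_individual={r.rat_id: dict(r.true_v0) for r in recs},
        )
        table, stats = predicted_vs_observed(recs, fitted)
        for tissue in ("plasma", "liver", "fat"):
            sd = table.loc[table.tissue == tissue, "log_residual"].std()
            assert sd == pytest.approx(0.3, rel=0.45)

    def test_empty_records_give_empty_table(self, reference_pop):
        table, stats = predicted_vs_observed([], reference_pop)
        assert table.empty and stats.empty

    def test_unmatched_record_named(self, noisy_study, reference_pop):
        recs, _ = noisy_study
        with pytest.raises(KeyError, match=recs[0].rat_id):
            predicted_vs_observed(recs, reference_pop)
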