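"""Model / results facade for the population PBTK calibration.

``PBTKPopulationModel`` bundles a study (records), the congener set,
physiology, CYP constants and priors; ``fit()`` runs the two-step Metropolis
calibration and returns a ``TwoStepResults`` carrying posterior medians,
chain CVs and Gelman-Rubin diagnostics, with population evaluation
(Monte-Carlo bands, induction ratios, predicted-vs-observed) hanging off
the results object:

    >>> model = PBTKPopulationModel.from_tables("design.csv", "observations.csv")
    >>> results = model.fit(n_iter=10_000, n_chains=3, seed=1)
    >>> print(results.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import StepResult, calibrate_two_step, pooled_v0_variant
from .induction import DEFAULT_CONGENERS, CongenerSpec, InductionParams
from .kinetics import SimulationResult, simulate
from .dosing import build_schedule
from .physiology import NLEPhysiology, default_nle_physiology
from .priors import OBS_TISSUES, HierarchicalParams, PriorSpec
from .study import StudyRecord, read_study
from . import population as _population

__all__ = ["PBTKPopulationModel", "TwoStepResults"]


class PBTKPopulationModel:
    """Hierarchical population PBTK model for a PCB-mixture rat study."""

    def __init__(
        self,
        records: list[StudyRecord],
        congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
        phys: NLEPhysiology | None = None,
        priors: PriorSpec | None = None,
        induction_constants: InductionParams | None = None,
    ):
        if not records:
            raise ValueError("a model needs at least one record")
        self.records = list(records)
        self.congeners = tuple(congeners)
        self.phys = default_nle_physiology() if phys is None else phys
        self.priors = PriorSpec() if priors is None else priors
        self.induction_constants = (
            InductionParams() if induction_constants is None else induction_constants
        )

    @classmethod
    def from_tables(cls, design_path, observations_path, **kwargs):
        """Build the model from design + observation CSV tables."""
        return cls(read_study(design_path, observations_path), **kwargs)

    def fit(
        self,
        n_iter: int = 10_000,
        n_chains: int = 3,
        seed: int | None = 0,
        target_acceptance: float = 0.10,
        burn_frac: float = 0.4,
        fast_opts: dict | None = None,
    ) -> "TwoStepResults":
        """Two-step MCMC calibration (see :mod:`lipidpbtk.calibrate`)."""
        step1, step2 = calibrate_two_step(
            self.records,
            self.congeners,
            self.phys,
            self.priors,
            self.induction_constants,
            n_iter=n_iter,
            n_chains=n_chains,
            seed=seed,
            target_acceptance=target_acceptance,
            burn_frac=burn_frac,
            fast_opts=fast_opts,
        )
        return TwoStepResults(model=self, step1=step1, step2=step2)

    def fit_pooled(
        self,
        n_iter: int = 10_000,
        n_chains: int = 3,
        seed: int | None = 0,
        **kw,
    ) -> StepResult:
        """Low-dose fit with one shared clearance population for all PCBs."""
        return pooled_v0_variant(
            self.records,
            self.congeners,
            self.phys,
            self.priors,
            self.induction_constants,
            n_iter=n_iter,
            n_chains=n_chains,
            seed=seed,
            **kw,
        )

    def simulate_rat(
        self, record: StudyRecord, v0: dict[str, float] | None = None, **kw
    ) -> SimulationResult:
        """Reference simulation of one record (optionally with given v0)."""
        specs = self.congeners
        if v0 is not None:
            specs = tuple(
                CongenerSpec(c.name, c.ortho_class, c.metabolizing_enzyme, v0[c.name])
                for c in self.congeners
            )
        return simulate(
            phys=self.phys,
            congeners=specs,
            induction=self.induction_constants,
            schedule=build_schedule(record.protocol, record.dose_level, record.sacrifice_day),
            covariates=record.covariates,
            **kw,
        )


@dataclass
class TwoStepResults:
    """Posterior summaries and evaluation tools of a two-step calibration."""

    model: PBTKPopulationModel
    step1: StepResult
    step2: StepResult | None

    # -- parameter access ---------------------------------------------
    def params(self) -> HierarchicalParams:
        """Posterior-median population parameters and per-rat clearances."""
        names = [c.name for c in self.model.congeners]
        mu = {n: math.log(self.step1.median(f"mu_v0_{n}")) for n in names}
        sigma = {n: self.step1.median(f"log_sigma_v0_{n}") for n in names}
        if self.step2 is not None:
            f_1a = self.step2.median("log_F_1A")
            f_2b = self.step2.median("log_F_2B")
            sigma_err = {t: self.step2.median(f"log_sigma_{t}") for t in OBS_TISSUES}
        else:
            f_1a = f_2b = 0.0
            sigma_err = {t: self.step1.median(f"log_sigma_{t}") for t in OBS_TISSUES}
        v0_ind = self.step1.per_rat_v0_medians()
        if self.step2 is not None:
            v0_ind.update(self.step2.per_rat_v0_medians())
        return HierarchicalParams(
            mu_v0=mu,
            sigma_v0=sigma,
            F_1A=f_1a,
            F_2B=f_2b,
            sigma_err=sigma_err,
            v0_individual=v0_ind,
        )

    def summary(self) -> pd.DataFrame:
        """Tidy population posterior table: parameter, step, median, CV, R."""
        rows = []
        names = [c.name for c in self.model.congeners]
        for n in names:
            rows.append(
                {
                    "parameter": f"v0_{n}",
                    "step": 1,
                    "median": self.step1.median(f"mu_v0_{n}"),
                    "cv": self.step1.cv(f"mu_v0_{n}"),
                    "r_hat": self.step1.r_hat(f"mu_v0_{n}"),
                }
            )
            rows.append(
                {
                    "parameter": f"sigma_v0_{n}",
                    "step": 1,
                    "median": self.step1.median(f"log_sigma_v0_{n}"),
                    "cv": self.step1.cv(f"log_sigma_v0_{n}"),
                    "r_hat": self.step1.r_hat(f"log_sigma_v0_{n}"),
                }
            )
        if self.step2 is not None:
            for p in ("F_2B", "F_1A"):
                rows.append(
                    {
                        "parameter": p,
                        "step": 2,
                        "median": self.step2.median(f"log_{p}"),
                        "cv": self.step2.cv(f"log_{p}"),
                        "r_hat": self.step2.r_hat(f"log_{p}"),
                    }
                )
        for t in OBS_TISSUES:
            rows.append(
                {
                    "parameter": f"sigma_{t}",
                    "step": 1,
                    "median": self.step1.median(f"log_sigma_{t}"),
                    "cv": self.step1.cv(f"log_sigma_{t}"),
                    "r_hat": self.step1.r_hat(f"log_sigma_{t}"),
                }
            )
            if self.step2 is not None:
                rows.append(
                    {
                        "parameter": f"sigma_{t}",
                        "step": 2,
                        "median": self.step2.median(f"log_sigma_{t}"),
                        "cv": self.step2.cv(f"log_sigma_{t}"),
                        "r_hat": self.step2.r_hat(f"log_sigma_{t}"),
                    }
                )
        return pd.DataFrame(rows)

    def gelman_rubin(self) -> dict[str, float]:
        """R per population-level parameter (both steps)."""
        out = {}
        for step, tag in ((self.step1, "step1"), (self.step2, "step2")):
            if step is None:
                continue
            for internal in step.population_names:
                out[f"{tag}:{internal}"] = step.r_hat(internal)
        return out

    # -- evaluation ----------------------------------------------------
    def monte_carlo_population(
        self, dose_level, protocol, sacrifice_day, n_draws=1000, seed=0, **kw
    ) -> _population.PopulationRun:
        return _population.monte_carlo_population(
            self.params(),
            dose_level,
            protocol,
            sacrifice_day,
            n_draws=n_draws,
            seed=seed,
            phys=self.model.phys,
            congeners=self.model.congeners,
            induction_constants=self.model.induction_constants,
            **kw,
        )

    def induction_ratios(
        self, dose_level, protocol="daily", horizon_days=90.0
    ) -> _population.InductionRatioReport:
        return _population.induction_ratio_report(
            self.params(),
            dose_level,
            protocol,
            horizon_days,
            phys=self.model.phys,
            congeners=self.model.congeners,
            induction_constants=self.model.induction_constants,
        )

    def predicted_vs_observed(self):
        return _population.predicted_vs_observed(
            self.model.records,
            self.params(),
            phys=self.model.phys,
            congeners=self.model.congeners,
            induction_constants=self.model.induction_constants,
        )

    def save_chains(self, directory) -> None:
        """Persist chains as CSV (one table per step and chain)."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for step, tag in ((self.step1, "step1"), (self.step2, "step2")):
            if step is None:
                continue
            for ci, chain in enumerate(step.chains):
                df = pd.DataFrame(chain.samples, columns=step.internal_names)
                df.insert(0, "iteration", np.arange(len(df)))
                df["log_posterior"] = chain.log_posterior
                df.to_csv(d / f"{tag}_chain{ci}.csv", index=False)
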