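"""Two-step hierarchical MCMC calibration of the PBTK/induction model.

Basal and induced clearances are inherently confounded, so calibration is
decomposed: step 1 fits the population of basal clearances (induction off)
to the lowest-dose records; step 2 fits the induction slopes to the two
higher dose levels, with the step-1 population posteriors acting as fixed
informative priors on the per-rat clearances (population mean and variance
are not updated in step 2).  The measurement-error SDs are sampled in both
steps.  Inter-individual variation of the induction slopes is neglected —
two slopes (CYP1A, CYP2B) serve the whole population.

Blocks and caching: population and error blocks touch no ODE solution;
each rat's clearance block re-simulates only that rat; the induction-slope
block re-simulates every rat.  Three independent chains with over-dispersed
initial values are run per step and convergence is judged by the
Gelman-Rubin statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .induction import DEFAULT_CONGENERS, CongenerSpec, InductionParams
from .likelihood import build_contexts
from .physiology import NLEPhysiology, default_nle_physiology
from .priors import OBS_TISSUES, PriorSpec
from .sampler import ChainState, gelman_rubin, metropolis_run
from .study import StudyRecord

__all__ = ["StepResult", "run_step", "calibrate_two_step", "pooled_v0_variant"]

_LOG_2PI = math.log(2.0 * math.pi)
_TISSUE_INDEX = {t: i for i, t in enumerate(OBS_TISSUES)}


class _StepPosterior:
    """Stateful block posterior for one calibration step.

    Parameter vector layout (everything positive on the log scale):

    * step 1: ``mu_k`` (one per population group), ``log sigma_k``,
      ``log sigma_err`` (plasma, liver, fat), ``log v0`` per rat and
      congener;
    * step 2: ``log F_1A``, ``log F_2B``, ``log sigma_err``, ``log v0``
      (population mean/SD fixed at the step-1 posterior medians).
    """

    def __init__(
        self,
        records: list[StudyRecord],
        contexts,
        congeners: tuple[CongenerSpec, ...],
        priors: PriorSpec,
        induction_constants: InductionParams,
        estimate_F: bool = False,
        fixed_pop: tuple[np.ndarray, np.ndarray] | None = None,
        pooled: bool = False,
    ):
        self.records = list(records)
        self.contexts = contexts
        self.congeners = tuple(congeners)
        self.names = [c.name for c in congeners]
        self.priors = priors
        self.base = induction_constants
        self.estimate_F = estimate_F
        self.pooled = pooled
        nr, nc = len(self.records), len(self.names)
        self.nr, self.nc = nr, nc
        self.n_tissues = len(OBS_TISSUES)

        if estimate_F:
            if fixed_pop is None:
                raise ValueError("step 2 requires the fixed population from step 1")
            self.mu_fixed = np.asarray(fixed_pop[0], dtype=float)
            self.sigma_fixed = np.asarray(fixed_pop[1], dtype=float)
            self.npop = 0
            self.i_f = np.array([0, 1])
            self.i_serr = 2 + np.arange(self.n_tissues)
            self.i_v0 = 2 + self.n_tissues
        else:
            self.npop = 1 if pooled else nc
            self.i_mu = np.arange(self.npop)
            self.i_sig = self.npop + np.arange(self.npop)
            self.i_serr = 2 * self.npop + np.arange(self.n_tissues)
            self.i_v0 = 2 * self.npop + self.n_tissues
        self.n_params = self.i_v0 + nr * nc
        #: population-group index of each congener
        self.group = np.zeros(nc, dtype=int) if pooled else np.arange(nc)

        # observation bookkeeping: per rat, tissue/congener indices and log y
        self.obs_t = []
        self.obs_flat = []  # flat index into the (3, nc) prediction matrix
        self.log_y = []
        self.n_obs = np.zeros((nr, self.n_tissues))
        for i, r in enumerate(self.records):
            ts = np.array([_TISSUE_INDEX[o.tissue] for o in r.observations])
            cs = np.array([self.names.index(o.congener) for o in r.observations])
            self.obs_t.append(ts)
            self.obs_flat.append(ts * nc + cs)
            self.log_y.append(np.log([o.concentration for o in r.observations]))
            for t in ts:
                self.n_obs[i, t] += 1
        self.n_obs_total = self.n_obs.sum(axis=0)

        # blocks
        self.blocks: list[np.ndarray] = []
        if estimate_F:
            self.blocks.append(self.i_f)
        else:
            for k in range(self.npop):
                self.blocks.append(np.array([self.i_mu[k], self.i_sig[k]]))
        self.blocks.append(self.i_serr)
        for i in range(nr):
            self.blocks.append(self.i_v0 + i * nc + np.arange(nc))
        self._n_fixed_blocks = len(self.blocks) - nr

        self._pending = None

    # -- decoding -----------------------------------------------------
    def _lv0(self, x, i):
        return x[self.i_v0 + i * self.nc : self.i_v0 + (i + 1) * self.nc]

    def _pop(self, x):
        if self.estimate_F:
            return self.mu_fixed, self.sigma_fixed
        mu = x[self.i_mu][self.group]
        sigma = np.exp(x[self.i_sig])[self.group]
        return mu, sigma

    def _slopes(self, x) -> tuple[float, float]:
        if self.estimate_F:
            return float(np.exp(x[0])), float(np.exp(x[1]))
        return 0.0, 0.0

    # -- pieces -------------------------------------------------------
    def _rat_ssq(self, i, x, f_1a, f_2b):
        """Per-tissue residual sum of squares for rat i (or None if invalid)."""
        v0 = np.exp(self._lv0(x, i))
        mat = self.contexts[self.records[i].rat_id].predict_obs(
            v0, f_1a, f_2b, self.base.A0, self.base.ke, self.base.k0
        )
        vals = mat.ravel()[self.obs_flat[i]]
        if np.any(vals <= 0.0) or not np.all(np.isfinite(vals)):
            return None
        resid = self.log_y[i] - np.log(vals)
        ssq = np.zeros(self.n_tissues)
        np.add.at(ssq, self.obs_t[i], resid**2)
        return ssq

    def _loglik_from_agg(self, agg_ssq, log_serr):
        serr2 = np.exp(2.0 * log_serr)
        return float(
            np.sum(
                -self.n_obs_total * (log_serr + 0.5 * _LOG_2PI)
                - agg_ssq / (2.0 * serr2)
            )
        )

    def _hier_terms(self, x, i):
        """Hierarchical Normal terms of rat i's log-clearances."""
        mu, sigma = self._pop(x)
        lv = self._lv0(x, i)
        lo, hi = self.priors.log_v0_bounds
        if np.any(lv < lo) or np.any(lv > hi):
            return -np.inf
        return float(
            np.sum(-np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * ((lv - mu) / sigma) ** 2)
        )

    def _hier_all(self, x):
        """Vectorized hierarchical terms for every rat at once, (nr,)."""
        mu, sigma = self._pop(x)
        lv = x[self.i_v0 :].reshape(self.nr, self.nc)
        out = np.sum(
            -np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * ((lv - mu) / sigma) ** 2, axis=1
        )
        lo, hi = self.priors.log_v0_bounds
        bad = np.any((lv < lo) | (lv > hi), axis=1)
        if bad.any():
            out = out.copy()
            out[bad] = -np.inf
        return out

    def _pop_prior(self, x):
        """Uniform(mu) + inverse-gamma(sigma) terms (step 1 only)."""
        if self.estimate_F:
            return 0.0
        lo, hi = self.priors.log_v0_bounds
        mu = x[self.i_mu]
        if np.any(mu < lo) or np.any(mu > hi):
            return -np.inf
        total = -self.npop * math.log(hi - lo)
        for ls in x[self.i_sig]:
            sigma = math.exp(ls)
            total += self.priors.log_ig_pdf(sigma) + ls  # + Jacobian
        return total

    def _err_prior(self, x):
        s_lo, s_hi = self.priors.sigma_err_bounds
        total = 0.0
        for ls in x[self.i_serr]:
            sigma = math.exp(ls)
            if not s_lo <= sigma <= s_hi:
                return -np.inf
            total += -math.log(s_hi - s_lo) + ls
        return total

    def _f_prior(self, x):
        if not self.estimate_F:
            return 0.0
        f_lo, f_hi = self.priors.f_bounds
        total = 0.0
        for lf in x[self.i_f]:
            f = math.exp(lf)
            if not f_lo <= f <= f_hi:
                return -np.inf
            total += -math.log(f_hi - f_lo) + lf
        return total

    # -- stateful protocol --------------------------------------------
    def full(self, x):
        x = np.asarray(x, dtype=float)
        f_1a, f_2b = self._slopes(x)
        ssq = np.empty((self.nr, self.n_tissues))
        for i in range(self.nr):
            s = self._rat_ssq(i, x, f_1a, f_2b)
            if s is None:
                return -np.inf
            ssq[i] = s
        hier = self._hier_all(x)
        if not np.all(np.isfinite(hier)):
            return -np.inf
        parts = (
            self._pop_prior(x),
            self._err_prior(x),
            self._f_prior(x),
        )
        if not all(np.isfinite(p) for p in parts):
            return -np.inf
        self._x = x.copy()
        self._ssq = ssq
        self._agg = ssq.sum(axis=0)
        self._hier = hier
        self._pop_p, self._err_p, self._f_p = parts
        self._loglik = self._loglik_from_agg(self._agg, x[self.i_serr])
        self._lp = self._loglik + hier.sum() + sum(parts)
        self._pending = None
        return self._lp

    def propose(self, x_new, block):
        x_new = np.asarray(x_new, dtype=float)
        if block < self._n_fixed_blocks and self.estimate_F and block == 0:
            # induction-slope block: every rat re-simulated
            f_p = self._f_prior(x_new)
            if not np.isfinite(f_p):
                self._pending = None
                return -np.inf
            f_1a, f_2b = self._slopes(x_new)
            ssq = np.empty_like(self._ssq)
            for i in range(self.nr):
                s = self._rat_ssq(i, x_new, f_1a, f_2b)
                if s is None:
                    self._pending = None
                    return -np.inf
                ssq[i] = s
            agg = ssq.sum(axis=0)
            loglik = self._loglik_from_agg(agg, x_new[self.i_serr])
            lp = loglik + self._hier.sum() + self._pop_p + self._err_p + f_p
            self._pending = dict(
                x=x_new, ssq=ssq, agg=agg, loglik=loglik, f_p=f_p, lp=lp
            )
            return lp
        if block < self._n_fixed_blocks and not self.estimate_F and block < self.npop:
            # population block k: no simulation, hierarchy + IG/uniform only
            pop_p = self._pop_prior(x_new)
            if not np.isfinite(pop_p):
                self._pending = None
                return -np.inf
            hier = self._hier_all(x_new)
            if not np.all(np.isfinite(hier)):
                self._pending = None
                return -np.inf
            lp = self._loglik + hier.sum() + pop_p + self._err_p + self._f_p
            self._pending = dict(x=x_new, hier=hier, pop_p=pop_p, lp=lp)
            return lp
        if block == self._n_fixed_blocks - 1:
            # error block: likelihood re-weighted from cached residuals
            err_p = self._err_prior(x_new)
            if not np.isfinite(err_p):
                self._pending = None
                return -np.inf
            loglik = self._loglik_from_agg(self._agg, x_new[self.i_serr])
            lp = loglik + self._hier.sum() + self._pop_p + err_p + self._f_p
            self._pending = dict(x=x_new, loglik=loglik, err_p=err_p, lp=lp)
            return lp
        # rat block
        i = block - self._n_fixed_blocks
        hier_i = self._hier_terms(x_new, i)
        if not np.isfinite(hier_i):
            self._pending = None
            return -np.inf
        f_1a, f_2b = self._slopes(x_new)
        s = self._rat_ssq(i, x_new, f_1a, f_2b)
        if s is None:
            self._pending = None
            return -np.inf
        agg = self._agg - self._ssq[i] + s
        loglik = self._loglik_from_agg(agg, x_new[self.i_serr])
        lp = (
            loglik
            + self._hier.sum()
            - self._hier[i]
            + hier_i
            + self._pop_p
            + self._err_p
            + self._f_p
        )
        self._pending = dict(x=x_new, rat=i, ssq_i=s, agg=agg, loglik=loglik, hier_i=hier_i, lp=lp)
        return lp

    def accept(self):
        p = self._pending
        if p is None:
            raise RuntimeError("accept() without a finite pending proposal")
        self._x = p["x"].copy()
        self._lp = p["lp"]
        if "rat" in p:
            self._agg = p["agg"]
            self._ssq[p["rat"]] = p["ssq_i"]
            self._loglik = p["loglik"]
            self._hier[p["rat"]] = p["hier_i"]
        else:
            if "ssq" in p:
                self._ssq = p["ssq"]
                self._agg = p["agg"]
            if "loglik" in p:
                self._loglik = p["loglik"]
            if "hier" in p:
                self._hier = p["hier"]
            if "pop_p" in p:
                self._pop_p = p["pop_p"]
            if "err_p" in p:
                self._err_p = p["err_p"]
            if "f_p" in p:
                self._f_p = p["f_p"]
        self._pending = None

    def reject(self):
        self._pending = None

    # -- naming -------------------------------------------------------
    def param_names(self) -> list[str]:
        names = []
        if self.estimate_F:
            names += ["log_F_1A", "log_F_2B"]
        else:
            groups = ["all"] if self.pooled else self.names
            names += [f"mu_v0_{g}" for g in groups]
            names += [f"log_sigma_v0_{g}" for g in groups]
        names += [f"log_sigma_{t}" for t in OBS_TISSUES]
        for r in self.records:
            names += [f"log_v0_{r.rat_id}_{n}" for n in self.names]
        return names


def _natural(name: str, samples: np.ndarray) -> tuple[str, np.ndarray]:
    """Map an internal (possibly log-scale) trace to its reporting scale."""
    if name.startswith("log_"):
        return name[4:], np.exp(samples)
    if name.startswith("mu_v0_"):
        # report the geometric-mean clearance exp(mu) in v0 units
        return "v0_" + name[len("mu_v0_") :], np.exp(samples)
    return name, samples


@dataclass
class StepResult:
    """Chains and summaries of one calibration step."""

    chains: list[ChainState]
    internal_names: list[str]
    burn_frac: float
    records: list[StudyRecord]
    congener_names: list[str]

    def _index(self, internal: str) -> int:
        return self.internal_names.index(internal)

    def trace(self, internal: str, natural: bool = True) -> np.ndarray:
        """(n_chains, n_kept) post-burn-in samples of one parameter."""
        j = self._index(internal)
        rows = [c.burned(self.burn_frac)[:, j] for c in self.chains]
        arr = np.stack(rows)
        if natural:
            _, arr = _natural(internal, arr)
        return arr

    def median(self, internal: str) -> float:
        return float(np.median(self.trace(internal)))

    def cv(self, internal: str) -> float:
        t = self.trace(internal).ravel()
        return float(np.std(t) / np.mean(t))

    def r_hat(self, internal: str) -> float:
        return gelman_rubin(self.trace(internal, natural=False))

    @property
    def population_names(self) -> list[str]:
        return [n for n in self.internal_names if not n.startswith("log_v0_r")]

    def summary(self) -> pd.DataFrame:
        rows = []
        for internal in self.population_names:
            name, _ = _natural(internal, np.zeros(1))
            rows.append(
                {
                    "parameter": name,
                    "median": self.median(internal),
                    "cv": self.cv(internal),
                    "r_hat": self.r_hat(internal),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def per_rat_v0_medians(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for r in self.records:
            out[r.rat_id] = {
                n: self.median(f"log_v0_{r.rat_id}_{n}") for n in self.congener_names
            }
        return out

    def bound_pileup_fraction(self, priors: PriorSpec, tol: float = 0.02) -> float:
        """Fraction of per-rat clearance samples within ``tol`` (log) of bounds."""
        lo, hi = priors.log_v0_bounds
        total = near = 0
        for internal in self.internal_names:
            if not internal.startswith("log_v0_r"):
                continue
            t = self.trace(internal, natural=False).ravel()
            total += t.size
            near += int(np.sum((t < lo + tol) | (t > hi - tol)))
        return near / total if total else 0.0


def _initial_state(post: _StepPosterior, rng: np.random.Generator) -> np.ndarray:
    """Over-dispersed initial values (documented package defaults)."""
    x = np.empty(post.n_params)
    if post.estimate_F:
        x[0] = np.log(10 ** rng.uniform(-3, np.log10(0.5)))  # F_1A
        x[1] = np.log(10 ** rng.uniform(-4, np.log10(0.05)))  # F_2B
        mu, sigma = post.mu_fixed, post.sigma_fixed
    else:
        x[post.i_mu] = rng.uniform(math.log(0.005), math.log(0.2), size=post.npop)
        x[post.i_sig] = np.log(rng.uniform(0.15, 1.2, size=post.npop))
        mu = x[post.i_mu][post.group]
        sigma = np.exp(x[post.i_sig])[post.group]
    x[post.i_serr] = np.log(rng.uniform(0.08, 0.8, size=post.n_tissues))
    lo, hi = post.priors.log_v0_bounds
    for i in range(post.nr):
        lv = rng.normal(mu, sigma)
        x[post.i_v0 + i * post.nc : post.i_v0 + (i + 1) * post.nc] = np.clip(
            lv, lo + 0.05, hi - 0.05
        )
    return x


def run_step(
    records: list[StudyRecord],
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    phys: NLEPhysiology | None = None,
    priors: PriorSpec | None = None,
    induction_constants: InductionParams | None = None,
    estimate_F: bool = False,
    fixed_pop: tuple[np.ndarray, np.ndarray] | None = None,
    pooled: bool = False,
    n_iter: int = 10_000,
    n_chains: int = 3,
    seed: int | None = 0,
    target_acceptance: float = 0.10,
    burn_frac: float = 0.4,
    contexts=None,
    fast_opts: dict | None = None,
) -> StepResult:
    """Run one calibration step (3 over-dispersed chains by default)."""
    if not records:
        raise ValueError("no records supplied")
    phys = default_nle_physiology() if phys is None else phys
    priors = PriorSpec() if priors is None else priors
    base = InductionParams() if induction_constants is None else induction_constants
    if contexts is None:
        contexts = build_contexts(records, phys, congeners, **(fast_opts or {}))

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    chains = []
    names = None
    for cs in chain_seeds:
        post = _StepPosterior(
            records,
            contexts,
            congeners,
            priors,
            base,
            estimate_F=estimate_F,
            fixed_pop=fixed_pop,
            pooled=pooled,
        )
        init_rng = np.random.default_rng(cs.spawn(1)[0])
        x0 = _initial_state(post, init_rng)
        scales = np.full(len(post.blocks), 0.15)
        if estimate_F:
            scales[0] = 0.25
        chains.append(
            metropolis_run(
                post,
                x0,
                n_iter,
                blocks=post.blocks,
                scales=scales,
                target_acceptance=target_acceptance,
                seed=cs,
            )
        )
        names = post.param_names()
    return StepResult(
        chains=chains,
        internal_names=names,
        burn_frac=burn_frac,
        records=list(records),
        congener_names=[c.name for c in congeners],
    )


def calibrate_two_step(
    records: list[StudyRecord],
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    phys: NLEPhysiology | None = None,
    priors: PriorSpec | None = None,
    induction_constants: InductionParams | None = None,
    n_iter: int = 10_000,
    n_chains: int = 3,
    seed: int | None = 0,
    target_acceptance: float = 0.10,
    burn_frac: float = 0.4,
    fast_opts: dict | None = None,
) -> tuple[StepResult, StepResult | None]:
    """Two-step calibration: basal clearances at low dose, then induction.

    Returns ``(step1, step2)``; ``step2`` is ``None`` when the records span
    a single dose level.  Emits a warning if more than 5% of step-2 per-rat
    clearance samples sit at the prior bounds (the cue to re-optimize the
    population parameters).
    """
    priors = PriorSpec() if priors is None else priors
    doses = sorted({r.dose_level for r in records})
    low = [r for r in records if r.dose_level == doses[0]]
    high = [r for r in records if r.dose_level > doses[0]]
    step1 = run_step(
        low,
        congeners,
        phys,
        priors,
        induction_constants,
        estimate_F=False,
        n_iter=n_iter,
        n_chains=n_chains,
        seed=seed,
        target_acceptance=target_acceptance,
        burn_frac=burn_frac,
        fast_opts=fast_opts,
    )
    if not high:
        return step1, None
    names = [c.name for c in congeners]
    mu_fixed = np.array([math.log(step1.median(f"mu_v0_{n}")) for n in names])
    sigma_fixed = np.array([step1.median(f"log_sigma_v0_{n}") for n in names])
    step2 = run_step(
        high,
        congeners,
        phys,
        priors,
        induction_constants,
        estimate_F=True,
        fixed_pop=(mu_fixed, sigma_fixed),
        n_iter=n_iter,
        n_chains=n_chains,
        seed=None if seed is None else seed + 1,
        target_acceptance=target_acceptance,
        burn_frac=burn_frac,
        fast_opts=fast_opts,
    )
    frac = step2.bound_pileup_fraction(priors)
    if frac > 0.05:
        warnings.warn(
            f"{frac:.1%} of step-2 per-rat clearance samples sit at the prior "
            "bounds; re-optimize the population parameters (step 1) before "
            "trusting the induction factors",
            RuntimeWarning,
        )
    return step1, step2


def pooled_v0_variant(
    records: list[StudyRecord],
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    phys: NLEPhysiology | None = None,
    priors: PriorSpec | None = None,
    induction_constants: InductionParams | None = None,
    n_iter: int = 10_000,
    n_chains: int = 3,
    seed: int | None = 0,
    **kw,
) -> StepResult:
    """Step-1 variant with a single population distribution for all PCBs."""
    doses = sorted({r.dose_level for r in records})
    low = [r for r in records if r.dose_level == doses[0]]
    return run_step(
        low,
        congeners,
        phys,
        priors,
        induction_constants,
        estimate_F=False,
        pooled=True,
        n_iter=n_iter,
        n_chains=n_chains,
        seed=seed,
        **kw,
    )
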