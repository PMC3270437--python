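"""Reference PBTK forward model (stiff ODE integration).

Five lipid-basis compartments (blood, fat, liver, rapidly and slowly
perfused) per congener, coupled to the CYP1A/CYP2B turnover balance.  All
chemical state is mass in tissue neutral lipid equivalents (μg); time is in
hours.  Non-liver tissues follow

    dA_t/dt = Q_t (C_a - C_t),

the liver adds the metabolic sink ``- v0 (A_CYP/A0) C_liver``, and the blood
pool receives the flow-weighted venous return minus the arterial outflow.
Oral doses are instantaneous boluses into the liver NLE pool (100%
bioavailability) by default; a gut compartment with first-order absorption
is available as an option.  Integration restarts at every dose event, so the
solver never steps across a discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dosing import DoseSchedule
from .induction import DEFAULT_CONGENERS, CongenerSpec, InductionParams
from .physiology import (
    NLEPhysiology,
    RatCovariates,
    body_weight_at,
    default_nle_physiology,
)

__all__ = [
    "SimulationResult",
    "IntegrationError",
    "simulate",
    "disposition_matrix",
    "RatGeometry",
]

# Compartment order used throughout the solver.
COMPARTMENTS = ("blood", "fat", "liver", "rapid", "slow")
TISSUES = ("fat", "liver", "rapid", "slow")
LIVER = 2  # index into COMPARTMENTS

#: Tissues with reported observations, including the plasma observation basis.
OBSERVABLE_TISSUES = ("plasma", "liver", "fat")


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last good state and time."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


class RatGeometry:
    """Time-dependent lipid-basis physiology of one rat.

    Precomputes the base arrays and evaluates volumes/flows at any time from
    the linear body-weight trajectory (volumes ∝ BW, flows ∝ BW^0.75, liver
    volume from the measured liver-weight ratio when covariates are given).
    """

    def __init__(self, base: NLEPhysiology, cov: RatCovariates | None = None):
        self.base = base
        self.cov = cov
        self.ref_bw = base.reference_body_weight
        self.V0 = np.array([base.nle_volumes[c] for c in COMPARTMENTS])
        self.Q0 = np.array([base.nle_flows[t] for t in TISSUES])
        self.QC0 = base.nle_cardiac_output
        self.liver_nle_ratio = base.lipid_content["liver"].nle_ratio
        self.nle_per_tl = np.array(
            [base.nle_per_total_lipid(c) for c in COMPARTMENTS]
        )
        self.plasma_nle_per_tl = base.lipid_content["plasma"].nle_per_total_lipid

    def body_weight(self, t_h: float) -> float:
        if self.cov is None:
            return self.ref_bw
        return body_weight_at(self.cov, t_h / 24.0)

    def at(self, t_h: float) -> tuple[np.ndarray, np.ndarray, float, float]:
        """(V[5], Q[4], QC, bw_g) at time ``t_h``."""
        bw = self.body_weight(t_h)
        rv = bw / self.ref_bw
        V = self.V0 * rv
        if self.cov is not None:
            V[LIVER] = self.cov.liver_weight_ratio * bw * self.liver_nle_ratio
        rq = rv**0.75
        return V, self.Q0 * rq, self.QC0 * rq, bw


def disposition_matrix(V: np.ndarray, Q: np.ndarray, QC: float, vcl: float) -> np.ndarray:
    """Constant-coefficient 5x5 system matrix for one congener.

    Acts on compartment masses ordered (blood, fat, liver, rapid, slow);
    ``vcl`` is the (induced) metabolic clearance in mL NLE/h.  Used for
    eigenvalue analysis of the no-induction (linear) system and by the fast
    likelihood propagator.
    """
    A = np.zeros((5, 5))
    A[0, 0] = -QC / V[0]
    for j, q in enumerate(Q, start=1):
        A[0, j] = q / V[j]  # venous return
        A[j, 0] = q / V[0]  # arterial inflow
        A[j, j] = -q / V[j]
    A[LIVER, LIVER] -= vcl / V[LIVER]
    return A


def _rhs_factory(geom, congeners, p, ka):
    n_c = len(congeners)
    v0 = np.array([c.v0 for c in congeners])
    is_1a = np.array([c.metabolizing_enzyme == "CYP1A" for c in congeners])

    def rhs(t, y):
        V, Q, QC, bw = geom.at(t)
        x = y[: 5 * n_c].reshape(n_c, 5)
        A1A, A2B = y[5 * n_c], y[5 * n_c + 1]
        gut = y[5 * n_c + 2 + n_c :]
        C = x / V
        Ca = C[:, 0]
        dx = np.empty_like(x)
        dx[:, 0] = (Q * C[:, 1:]).sum(axis=1) - QC * Ca
        dx[:, 1:] = Q * (Ca[:, None] - C[:, 1:])
        ratio = np.where(is_1a, A1A, A2B) / p.A0
        vcl = v0 * (bw / 1000.0) ** 0.75 * ratio
        c_liver = C[:, LIVER]
        dmet = vcl * c_liver
        dx[:, LIVER] -= dmet
        dgut = np.zeros(n_c)
        if ka is not None:
            dgut = -ka * gut
            dx[:, LIVER] += ka * gut
        c1a = max(float(np.where(is_1a, c_liver, 0.0).sum()), 0.0)
        c2b = max(float(c_liver.sum()), 0.0)
        dA1A = p.k0 - p.ke * A1A + p.k0 * p.F_1A * c1a
        dA2B = p.k0 - p.ke * A2B + p.k0 * p.F_2B * c2b
        return np.concatenate([dx.ravel(), [dA1A, dA2B], dmet, dgut])

    def jac(t, y):
        V, Q, QC, bw = geom.at(t)
        n = 5 * n_c + 2 + 2 * n_c
        J = np.zeros((n, n))
        A1A, A2B = y[5 * n_c], y[5 * n_c + 1]
        A_enz = np.where(is_1a, A1A, A2B)
        bwp = (bw / 1000.0) ** 0.75
        dvcl_dA = v0 * bwp / p.A0
        vcl = dvcl_dA * A_enz
        i1a, i2b = 5 * n_c, 5 * n_c + 1
        for c in range(n_c):
            o = 5 * c
            J[o : o + 5, o : o + 5] = disposition_matrix(V, Q, QC, vcl[c])
            c_liv = y[o + LIVER] / V[LIVER]
            icyp = i1a if is_1a[c] else i2b
            J[o + LIVER, icyp] = -dvcl_dA[c] * c_liv
            imet = 5 * n_c + 2 + c
            J[imet, o + LIVER] = vcl[c] / V[LIVER]
            J[imet, icyp] = dvcl_dA[c] * c_liv
            if is_1a[c]:
                J[i1a, o + LIVER] += p.k0 * p.F_1A / V[LIVER]
            J[i2b, o + LIVER] += p.k0 * p.F_2B / V[LIVER]
            if ka is not None:
                igut = 5 * n_c + 2 + n_c + c
                J[igut, igut] = -ka
                J[o + LIVER, igut] = ka
        J[i1a, i1a] = -p.ke
        J[i2b, i2b] = -p.ke
        return J

    return rhs, jac


@dataclass
class SimulationResult:
    """Concentration time courses of one simulated rat.

    ``c_nl``/``c_tl`` have shape (n_times, n_congeners, 6) over the tissue
    axis (blood, fat, liver, rapid, slow, plasma), in μg/mL NLE and μg/mL
    total lipid respectively.  ``cyp_ratio`` holds A/A0 for (CYP1A, CYP2B).
    """

    t_h: np.ndarray
    congeners: tuple[CongenerSpec, ...]
    c_nl: np.ndarray
    c_tl: np.ndarray
    masses: np.ndarray  # (n_times, n_congeners, 5) μg in NLE
    cyp_ratio: np.ndarray  # (n_times, 2)
    metabolized: np.ndarray  # (n_times, n_congeners) cumulative μg
    absorbed: np.ndarray  # (n_times, n_congeners) cumulative dosed μg
    gut: np.ndarray  # (n_times, n_congeners) μg awaiting absorption

    TISSUE_AXIS = ("blood", "fat", "liver", "rapid", "slow", "plasma")

    def concentration(self, congener: str, tissue: str, basis: str = "total_lipid"):
        ci = [c.name for c in self.congeners].index(str(congener))
        ti = self.TISSUE_AXIS.index(tissue)
        return (self.c_tl if basis == "total_lipid" else self.c_nl)[:, ci, ti]

    def mass_balance_error(self) -> float:
        """Max relative gap |dosed - (in body + gut + metabolized)| / dosed."""
        body = self.masses.sum(axis=2) + self.metabolized + self.gut
        dosed = self.absorbed
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(dosed - body) / np.where(dosed > 0, dosed, np.nan)
        return float(np.nanmax(rel)) if np.isfinite(rel).any() else 0.0

    def final(self, congener: str, tissue: str, basis: str = "total_lipid") -> float:
        return float(self.concentration(congener, tissue, basis)[-1])

    def to_frame(self, rat_id: str | int | None = None):
        """Tidy table: rat_id, time_h, congener, tissue, basis, concentration."""
        import pandas as pd

        rows = []
        for basis, arr in (("NLE", self.c_nl), ("total_lipid", self.c_tl)):
            for ci, cong in enumerate(self.congeners):
                for ti, tissue in enumerate(self.TISSUE_AXIS):
                    rows.append(
                        pd.DataFrame(
                            {
                                "rat_id": rat_id,
                                "time_h": self.t_h,
                                "congener": cong.name,
                                "tissue": tissue,
                                "basis": basis,
                                "concentration": arr[:, ci, ti],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def simulate(
    phys: NLEPhysiology | None = None,
    congeners: tuple[CongenerSpec, ...] = DEFAULT_CONGENERS,
    induction: InductionParams | None = None,
    schedule: DoseSchedule | None = None,
    covariates: RatCovariates | None = None,
    t_grid: np.ndarray | None = None,
    t_end_h: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    absorption: str = "bolus-liver",
    ka: float | None = None,
    recompute_dose_from_bw: bool = True,
) -> SimulationResult:
    """Simulate one rat under a dose schedule.

    Doses are applied as discrete state increments at event times (bolus to
    the liver NLE pool, or to the gut when ``absorption='gut-first-order'``),
    with the dose mass recomputed from the body weight at each event by
    default.  Output is reported on both the NLE and total-lipid bases;
    plasma total-lipid concentration assumes the plasma NLE concentration
    equals the blood NLE concentration.
    """
    phys = default_nle_physiology() if phys is None else phys
    induction = InductionParams() if induction is None else induction
    if absorption not in ("bolus-liver", "gut-first-order"):
        raise ValueError(f"unknown absorption mode {absorption!r}")
    if absorption == "gut-first-order" and (ka is None or ka <= 0):
        raise ValueError("gut-first-order absorption requires a positive ka (1/h)")
    use_gut = absorption == "gut-first-order"

    geom = RatGeometry(phys, covariates)
    if t_end_h is None:
        if covariates is not None:
            t_end_h = covariates.sacrifice_day * 24.0
        elif t_grid is not None:
            t_end_h = float(np.max(t_grid))
        else:
            raise ValueError("t_end_h, t_grid or covariates must fix the horizon")
    if t_grid is None:
        t_grid = np.linspace(0.0, t_end_h, 241)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] > 0.0:
        t_grid = np.concatenate([[0.0], t_grid])
    if np.any(t_grid < 0) or np.any(t_grid > t_end_h + 1e-9):
        raise ValueError("t_grid must lie within [0, sacrifice time]")

    n_c = len(congeners)
    event_times = (
        [t for t in schedule.times_h if t < t_end_h] if schedule is not None else []
    )
    rhs, jac = _rhs_factory(geom, congeners, induction, ka if use_gut else None)

    # state: chem (n_c*5) | cyp (2) | met (n_c) | gut (n_c)
    y = np.zeros(5 * n_c + 2 + 2 * n_c)
    y[5 * n_c] = induction.A0
    y[5 * n_c + 1] = induction.A0

    breaks = np.unique(np.concatenate([[0.0], event_times, [t_end_h]]))
    out_t, out_y, out_abs = [], [], []
    cum_dose = np.zeros(n_c)

    def record(t, yv):
        out_t.append(t)
        out_y.append(np.asarray(yv, dtype=float).copy())
        out_abs.append(cum_dose.copy())

    grid = np.unique(t_grid)
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        if ta in event_times:
            bw = geom.body_weight(ta) if recompute_dose_from_bw else geom.body_weight(0.0)
            dose = schedule.dose_per_kg * bw / 1000.0  # μg per congener
            if use_gut:
                y[5 * n_c + 2 + n_c :] += dose
            else:
                y[LIVER : 5 * n_c : 5] += dose
            cum_dose += dose
        if ta in grid:
            record(ta, y)  # post-dose state at event/grid times
        interior = grid[(grid > ta) & (grid < tb)]
        sol = solve_ivp(
            rhs,
            (ta, tb),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            jac=jac,
            t_eval=np.concatenate([interior, [tb]]),
        )
        if not sol.success or np.any(np.isnan(sol.y)):
            raise IntegrationError(
                f"ODE solver failed in [{ta}, {tb}] h: {sol.message}",
                t_last=float(sol.t[-1]) if len(sol.t) else ta,
                y_last=sol.y[:, -1] if sol.y.size else y,
            )
        for k, tg in enumerate(sol.t[:-1]):
            record(tg, sol.y[:, k])
        y = sol.y[:, -1].copy()
    if t_end_h in grid:
        record(t_end_h, y)

    t_out = np.array(out_t)
    Y = np.array(out_y)
    absorbed = np.array(out_abs)

    masses = Y[:, : 5 * n_c].reshape(len(t_out), n_c, 5)
    cyp = Y[:, 5 * n_c : 5 * n_c + 2] / induction.A0
    met = Y[:, 5 * n_c + 2 : 5 * n_c + 2 + n_c]
    gut = Y[:, 5 * n_c + 2 + n_c :]

    c_nl = np.empty((len(t_out), n_c, 6))
    c_tl = np.empty_like(c_nl)
    for k, t in enumerate(t_out):
        V, _, _, _ = geom.at(t)
        cn = masses[k] / V
        c_nl[k, :, :5] = cn
        c_nl[k, :, 5] = cn[:, 0]  # plasma NLE conc = blood NLE conc
        c_tl[k, :, :5] = cn * geom.nle_per_tl
        c_tl[k, :, 5] = cn[:, 0] * geom.plasma_nle_per_tl

    return SimulationResult(
        t_h=t_out,
        congeners=tuple(congeners),
        c_nl=c_nl,
        c_tl=c_tl,
        masses=masses,
        cyp_ratio=cyp,
        metabolized=met,
        absorbed=absorbed,
        gut=gut,
    )
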