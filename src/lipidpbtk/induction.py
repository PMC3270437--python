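"""PCB congener metabolism and CYP450 turnover/induction.

Each of the six congeners carries a basal metabolic clearance ``v0``
(mL/h/kg^0.75) and is metabolized through one CYP pathway: the mono-ortho
congener PCB 118 via CYP1A, the multi-ortho congeners (138, 153, 170, 180,
187) via CYP2B.  Hepatic CYP amounts follow a zero-order synthesis /
first-order degradation balance

    dA/dt = k0 - ke * A + S(t),        S(t) = k0 * F * C_IND,

where ``C_IND`` is the inducer concentration in the neutral lipid space of
the liver: PCB 118 alone for CYP1A, the sum of all six congeners for CYP2B.
At zero inducer the balance sits at the basal steady state A0 = k0/ke.
Metabolic clearance scales with the relative enzyme amount,

    v_cl = v0 * BW_kg^0.75 * A / A0.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CongenerSpec",
    "InductionParams",
    "CYPState",
    "DEFAULT_CONGENERS",
    "CONGENER_NAMES",
    "cyp_derivative",
    "induced_clearance",
    "cyp_steady_state",
]

MONO_ORTHO = "mono-ortho"
MULTI_ORTHO = "multi-ortho"


@dataclass(frozen=True)
class CongenerSpec:
    """One PCB congener: identity, ortho class, CYP pathway, basal clearance.

    ``v0`` is in mL/h per kg body weight to the 0.75 power.
    """

    name: str
    ortho_class: str
    metabolizing_enzyme: str
    v0: float

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError(f"PCB {self.name}: v0 must be positive, got {self.v0}")
        if self.ortho_class not in (MONO_ORTHO, MULTI_ORTHO):
            raise ValueError(f"unknown ortho class {self.ortho_class!r}")
        if self.metabolizing_enzyme not in ("CYP1A", "CYP2B"):
            raise ValueError(f"unknown enzyme {self.metabolizing_enzyme!r}")


# Default basal clearances are the population posterior medians of the
# calibrated model (geometric means of the population lognormal).
DEFAULT_CONGENERS: tuple[CongenerSpec, ...] = (
    CongenerSpec("118", MONO_ORTHO, "CYP1A", 0.038),
    CongenerSpec("138", MULTI_ORTHO, "CYP2B", 0.026),
    CongenerSpec("153", MULTI_ORTHO, "CYP2B", 0.025),
    CongenerSpec("170", MULTI_ORTHO, "CYP2B", 0.029),
    CongenerSpec("180", MULTI_ORTHO, "CYP2B", 0.035),
    CongenerSpec("187", MULTI_ORTHO, "CYP2B", 0.017),
)

CONGENER_NAMES: tuple[str, ...] = tuple(c.name for c in DEFAULT_CONGENERS)


@dataclass(frozen=True)
class InductionParams:
    """CYP450 turnover constants and linear induction slopes.

    A0 in nmol/g protein, ke in 1/h, k0 in nmol/h/g protein; the steady-state
    closure k0 = ke * A0 must hold (to 1e-6 relative).  The same turnover
    constants are used for CYP1A and CYP2B; the induction slopes F differ.
    """

    A0: float = 0.1
    ke: float = 0.04
    k0: float = 0.004
    F_1A: float = 0.045
    F_2B: float = 0.0025

    def __post_init__(self) -> None:
        if min(self.A0, self.ke, self.k0) <= 0:
            raise ValueError("A0, ke and k0 must be positive")
        if self.F_1A < 0 or self.F_2B < 0:
            raise ValueError("induction slopes must be nonnegative")
        if abs(self.k0 - self.ke * self.A0) > 1e-6 * self.k0:
            raise ValueError(
                f"steady-state closure violated: k0={self.k0} but "
                f"ke*A0={self.ke * self.A0}"
            )

    def slope(self, enzyme: str) -> float:
        return self.F_1A if enzyme == "CYP1A" else self.F_2B


@dataclass
class CYPState:
    """Hepatic CYP1A and CYP2B amounts (nmol/g protein)."""

    A_1A: float
    A_2B: float

    def __post_init__(self) -> None:
        if self.A_1A < 0 or self.A_2B < 0:
            raise ValueError("CYP amounts must be nonnegative")


def cyp_steady_state(k0: float, ke: float) -> float:
    """Basal enzyme amount A0 implied by the steady-state closure.

    Solves ``k0 - ke * A = 0`` for A (the zero-inducer fixed point of the
    turnover balance).
    """
    if ke <= 0:
        raise ValueError("ke must be positive")
    return k0 / ke


def cyp_derivative(
    state: CYPState,
    c_ind_1a: float,
    c_ind_2b: float,
    p: InductionParams,
) -> tuple[float, float]:
    """Time derivatives (d A_1A/dt, d A_2B/dt) of the CYP balance.

    ``c_ind_1a`` is the liver-NLE concentration of PCB 118, ``c_ind_2b`` the
    summed liver-NLE concentration of all six congeners (μg/mL NLE).
    """
    if c_ind_1a < 0 or c_ind_2b < 0:
        raise ValueError("inducer concentrations must be nonnegative")
    d1a = p.k0 - p.ke * state.A_1A + p.k0 * p.F_1A * c_ind_1a
    d2b = p.k0 - p.ke * state.A_2B + p.k0 * p.F_2B * c_ind_2b
    return d1a, d2b


def induced_clearance(v0: float, bw_g: float, A: float, A0: float) -> float:
    """Metabolic clearance (mL/h) at enzyme amount ``A``.

    ``v0`` in mL/h/kg^0.75, ``bw_g`` the body weight in grams.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    return v0 * (bw_g / 1000.0) ** 0.75 * (A / A0)
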