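"""Lipid-basis (NLE) rat physiology.

The disposition network of the PBTK model lives entirely in neutral lipid
equivalents (NLE): the effective lipid volume of a tissue, taken as all
neutral lipids plus 30% of the phospholipids.  Conventional blood flows and
tissue volumes for a standard 225 g rat are converted to the lipid basis by
multiplying volumes with each tissue's NLE ratio (mL NLE per mL tissue) and
flows with the *blood* NLE ratio.  Concentrations in tissue NLE are converted
to the measurable total-lipid basis through each tissue's NLE/total-lipid
fraction.

Compartments of the flow network are blood, fat, liver, rapidly perfused and
poorly (slowly) perfused tissue.  Plasma appears only as an observation
basis: plasma lipid is assumed to carry the same NLE-basis concentration as
blood lipid, and is converted to total lipid with the plasma NLE/total-lipid
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "LipidContent",
    "ConventionalPhysiology",
    "NLEPhysiology",
    "RatCovariates",
    "DEFAULT_LIPID_CONTENT",
    "DEFAULT_CONVENTIONAL",
    "scale_to_nle",
    "scale_for_body_weight",
    "body_weight_at",
    "default_nle_physiology",
    "load_physiology_config",
]

#: Compartments of the flow network, in canonical order.
FLOW_COMPARTMENTS = ("blood", "fat", "liver", "rapid", "slow")
#: Perfused compartments (everything that exchanges with blood).
TISSUE_COMPARTMENTS = ("fat", "liver", "rapid", "slow")


class ConfigurationError(ValueError):
    """A physiological configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class LipidContent:
    """Lipid content of one tissue.

    Parameters
    ----------
    tissue : str
        Compartment label (``blood``, ``plasma``, ``fat``, ``liver``,
        ``rapid``, ``slow``).
    nle_ratio : float
        mL NLE per mL tissue (dimensionless).
    nle_per_total_lipid : float
        mL NLE per mL total lipid (dimensionless).
    """

    tissue: str
    nle_ratio: float
    nle_per_total_lipid: float

    def __post_init__(self) -> None:
        if not 0.0 < self.nle_ratio < 1.0:
            raise ValueError(
                f"{self.tissue}: nle_ratio must lie in (0, 1), got {self.nle_ratio}"
            )
        if not 0.0 < self.nle_per_total_lipid <= 1.0:
            raise ValueError(
                f"{self.tissue}: nle_per_total_lipid must lie in (0, 1], "
                f"got {self.nle_per_total_lipid}"
            )


#: Default lipid content of rat tissues (NLE ratio, NLE per total lipid).
DEFAULT_LIPID_CONTENT: dict[str, LipidContent] = {
    lc.tissue: lc
    for lc in (
        LipidContent("blood", 0.0019, 0.576),
        LipidContent("plasma", 0.0009, 0.748),
        LipidContent("fat", 0.8536, 0.998),
        LipidContent("liver", 0.0425, 0.710),
        LipidContent("rapid", 0.0425, 0.710),
        LipidContent("slow", 0.0120, 0.632),
    )
}


@dataclass(frozen=True)
class ConventionalPhysiology:
    """Conventional (whole-tissue) physiology of a reference rat.

    Flows in mL blood/h, volumes in mL, body weight in g.  Tissue blood
    flows must sum to the cardiac output within 1%.
    """

    tissue_flows: dict[str, float]
    tissue_volumes: dict[str, float]
    cardiac_output: float
    reference_body_weight: float = 225.0

    def __post_init__(self) -> None:
        for name, table in (("flow", self.tissue_flows), ("volume", self.tissue_volumes)):
            for tissue, value in table.items():
                if value <= 0:
                    raise ValueError(f"{tissue} {name} must be positive, got {value}")
        if self.cardiac_output <= 0 or self.reference_body_weight <= 0:
            raise ValueError("cardiac output and reference body weight must be positive")
        total = sum(self.tissue_flows.values())
        if abs(total - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValueError(
                f"tissue flows sum to {total} mL/h but cardiac output is "
                f"{self.cardiac_output} mL/h (>1% imbalance)"
            )


#: Default physiology of a standard 225 g rat.
DEFAULT_CONVENTIONAL = ConventionalPhysiology(
    tissue_flows={"fat": 448.0, "liver": 1245.0, "rapid": 2540.0, "slow": 747.0},
    tissue_volumes={
        "blood": 20.0,
        "fat": 17.5,
        "liver": 10.0,
        "rapid": 12.5,
        "slow": 167.5,
    },
    cardiac_output=4980.0,
    reference_body_weight=225.0,
)


@dataclass(frozen=True)
class NLEPhysiology:
    """Lipid-basis physiology: NLE flows/volumes and total-lipid volumes.

    ``nle_flows`` (mL NLE/h) and ``nle_cardiac_output`` are the conventional
    flows scaled by the blood NLE ratio; ``nle_volumes`` (mL NLE) are the
    conventional volumes scaled by each tissue's own NLE ratio;
    ``total_lipid_volumes`` (mL total lipid) divide the NLE volumes by the
    tissue NLE/total-lipid fraction.
    """

    nle_flows: dict[str, float]
    nle_volumes: dict[str, float]
    total_lipid_volumes: dict[str, float]
    nle_cardiac_output: float
    reference_body_weight: float = 225.0
    lipid_content: dict[str, LipidContent] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_CONTENT)
    )

    def nle_per_total_lipid(self, tissue: str) -> float:
        """V_nlt/V_tlt for a compartment."""
        return self.nle_volumes[tissue] / self.total_lipid_volumes[tissue]


def scale_to_nle(
    conv: ConventionalPhysiology,
    lipids: dict[str, LipidContent] | None = None,
) -> NLEPhysiology:
    """Convert conventional physiology to the lipid (NLE) basis.

    Volumes are multiplied by each tissue's NLE ratio; all flows and the
    cardiac output are multiplied by the *blood* NLE ratio.  Total-lipid
    volumes are NLE volumes divided by the tissue NLE/total-lipid fraction.

    Raises
    ------
    ConfigurationError
        If a compartment of ``conv`` has no lipid-content entry.
    """
    lipids = dict(DEFAULT_LIPID_CONTENT) if lipids is None else lipids
    if "blood" not in lipids:
        raise ConfigurationError("missing lipid content for compartment 'blood'")
    blood_ratio = lipids["blood"].nle_ratio

    nle_volumes: dict[str, float] = {}
    total_lipid_volumes: dict[str, float] = {}
    for tissue, volume in conv.tissue_volumes.items():
        if tissue not in lipids:
            raise ConfigurationError(f"missing lipid content for compartment '{tissue}'")
        lc = lipids[tissue]
        nle_volumes[tissue] = volume * lc.nle_ratio
        total_lipid_volumes[tissue] = nle_volumes[tissue] / lc.nle_per_total_lipid

    nle_flows = {t: q * blood_ratio for t, q in conv.tissue_flows.items()}
    return NLEPhysiology(
        nle_flows=nle_flows,
        nle_volumes=nle_volumes,
        total_lipid_volumes=total_lipid_volumes,
        nle_cardiac_output=conv.cardiac_output * blood_ratio,
        reference_body_weight=conv.reference_body_weight,
        lipid_content=dict(lipids),
    )


def default_nle_physiology() -> NLEPhysiology:
    """Lipid-basis physiology of the standard 225 g rat."""
    return scale_to_nle(DEFAULT_CONVENTIONAL, DEFAULT_LIPID_CONTENT)


@dataclass(frozen=True)
class RatCovariates:
    """Measured covariates of one rat.

    Body weights in g; ``liver_weight_ratio`` is liver weight as a fraction
    of body weight (liver density taken as 1 g/mL); ``sacrifice_day`` in
    days.
    """

    initial_body_weight: float
    final_body_weight: float
    sacrifice_day: float
    liver_weight_ratio: float

    def __post_init__(self) -> None:
        if self.initial_body_weight <= 0 or self.final_body_weight <= 0:
            raise ValueError("body weights must be positive")
        if not 0.0 < self.liver_weight_ratio < 0.1:
            raise ValueError(
                f"liver weight ratio must lie in (0, 0.1), got {self.liver_weight_ratio}"
            )
        if self.sacrifice_day <= 0:
            raise ValueError("sacrifice day must be positive")


def body_weight_at(cov: RatCovariates, t_days: float) -> float:
    """Body weight (g) at study day ``t_days``.

    Linear interpolation between the initial and final weight over the
    study; constant extrapolation outside [0, sacrifice_day].
    """
    if t_days <= 0:
        return cov.initial_body_weight
    if t_days >= cov.sacrifice_day:
        return cov.final_body_weight
    frac = t_days / cov.sacrifice_day
    return cov.initial_body_weight + frac * (
        cov.final_body_weight - cov.initial_body_weight
    )


def scale_for_body_weight(
    base: NLEPhysiology,
    current_bw: float,
    reference_bw: float | None = None,
    covariates: RatCovariates | None = None,
) -> NLEPhysiology:
    """Allometric rescaling of lipid-basis physiology to a body weight.

    Volumes scale linearly with body weight, flows (and cardiac output) with
    body weight to the 0.75 power.  When ``covariates`` are supplied the
    liver NLE volume is overridden with the measured liver weight ratio:
    ``liver_weight_ratio * current_bw * liver NLE ratio`` (liver density
    1 g/mL).

    Raises
    ------
    ValueError
        For a nonpositive body weight.
    """
    if current_bw <= 0:
        raise ValueError(f"body weight must be positive, got {current_bw}")
    reference_bw = base.reference_body_weight if reference_bw is None else reference_bw
    rv = current_bw / reference_bw
    rq = rv**0.75

    nle_volumes = {t: v * rv for t, v in base.nle_volumes.items()}
    if covariates is not None:
        liver_ratio = base.lipid_content["liver"].nle_ratio
        nle_volumes["liver"] = covariates.liver_weight_ratio * current_bw * liver_ratio
    total_lipid_volumes = {
        t: nle_volumes[t] / base.nle_per_total_lipid(t) for t in nle_volumes
    }
    return NLEPhysiology(
        nle_flows={t: q * rq for t, q in base.nle_flows.items()},
        nle_volumes=nle_volumes,
        total_lipid_volumes=total_lipid_volumes,
        nle_cardiac_output=base.nle_cardiac_output * rq,
        reference_body_weight=current_bw,
        lipid_content=dict(base.lipid_content),
    )


def load_physiology_config(path) -> tuple[ConventionalPhysiology, dict[str, LipidContent]]:
    """Read conventional physiology and lipid-content tables from YAML.

    Expected keys: ``lipid_content`` (tissue -> {nle_ratio,
    nle_per_total_lipid}), ``tissue_flows``, ``tissue_volumes``,
    ``cardiac_output``, ``reference_body_weight``.  Missing top-level keys
    fall back to the built-in defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    lipids = dict(DEFAULT_LIPID_CONTENT)
    for tissue, entry in (cfg.get("lipid_content") or {}).items():
        lipids[tissue] = LipidContent(
            tissue, float(entry["nle_ratio"]), float(entry["nle_per_total_lipid"])
        )
    conv = ConventionalPhysiology(
        tissue_flows={
            t: float(v)
            for t, v in (cfg.get("tissue_flows") or DEFAULT_CONVENTIONAL.tissue_flows).items()
        },
        tissue_volumes={
            t: float(v)
            for t, v in (
                cfg.get("tissue_volumes") or DEFAULT_CONVENTIONAL.tissue_volumes
            ).items()
        },
        cardiac_output=float(cfg.get("cardiac_output", DEFAULT_CONVENTIONAL.cardiac_output)),
        reference_body_weight=float(
            cfg.get("reference_body_weight", DEFAULT_CONVENTIONAL.reference_body_weight)
        ),
    )
    return conv, lipids
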