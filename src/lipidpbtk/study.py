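"""Study designs, per-rat records, and delimited-text study tables.

A study is stored as two tables: a *design* table with one row per rat
(design cell, body weights, liver-weight ratio, and — for synthetic data —
the generating per-rat clearances) and an *observation* table with one row
per measured concentration (rat, congener, tissue, μg/mL total lipid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .dosing import PROTOCOLS
from .physiology import RatCovariates

__all__ = ["StudyDesign", "Observation", "StudyRecord", "write_study", "read_study"]


class ParseError(ValueError):
    """A study table is malformed; the message names the row/column."""


@dataclass(frozen=True)
class StudyDesign:
    """Factorial frame of a rat study.

    The defaults reproduce the mixture study's frame: dose levels
    {5, 50, 500} μg/kg of each congener per administration, four dose
    protocols, sacrifice at 41 or 90 days, six rats per cell.
    """

    dose_levels: tuple[float, ...] = (5.0, 50.0, 500.0)
    protocols: tuple[str, ...] = PROTOCOLS
    sacrifice_days: tuple[int, ...] = (41, 90)
    rats_per_cell: int = 6
    seed: int = 0
    #: optional per-cell overrides {(dose, protocol, day): n}; the study's
    #: exact per-cell counts (totalling 142) are unpublished, so the uniform
    #: default gives 144 and overrides let a caller match any total.
    cell_overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.rats_per_cell < 1:
            raise ValueError("rats_per_cell must be >= 1")
        if len(self.dose_levels) == 0 or len(self.protocols) == 0:
            raise ValueError("design must have at least one dose level and protocol")
        if self.cell_overrides:
            known = set(self.cells())
            for cell, n in self.cell_overrides.items():
                if tuple(cell) not in known:
                    raise ValueError(f"cell override {cell} is not a design cell")
                if n < 0:
                    raise ValueError("cell counts must be nonnegative")

    def rats_in(self, dose, protocol, day) -> int:
        if self.cell_overrides:
            return int(self.cell_overrides.get((dose, protocol, day), self.rats_per_cell))
        return self.rats_per_cell

    @property
    def n_rats(self) -> int:
        return sum(self.rats_in(*cell) for cell in self.cells())

    def cells(self):
        for dose in self.dose_levels:
            for protocol in self.protocols:
                for day in self.sacrifice_days:
                    yield dose, protocol, day


@dataclass(frozen=True)
class Observation:
    congener: str
    tissue: str
    concentration: float  # μg/mL total lipid

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(
                f"concentration must be positive "
                f"(PCB {self.congener}, {self.tissue}): {self.concentration}"
            )


@dataclass
class StudyRecord:
    """One rat: design cell, covariates, observations, optional truth."""

    rat_id: str
    dose_level: float
    protocol: str
    sacrifice_day: int
    covariates: RatCovariates
    observations: list[Observation] = field(default_factory=list)
    true_v0: dict[str, float] | None = None

    def observed(self, congener: str, tissue: str) -> float:
        for o in self.observations:
            if o.congener == congener and o.tissue == tissue:
                return o.concentration
        raise KeyError(f"no observation for PCB {congener} in {tissue}")


def _records_to_tables(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    drows, orows = [], []
    for r in records:
        row = {
            "rat_id": r.rat_id,
            "dose_level": r.dose_level,
            "protocol": r.protocol,
            "sacrifice_day": r.sacrifice_day,
            "initial_body_weight": r.covariates.initial_body_weight,
            "final_body_weight": r.covariates.final_body_weight,
            "liver_weight_ratio": r.covariates.liver_weight_ratio,
        }
        if r.true_v0 is not None:
            for name, v in r.true_v0.items():
                row[f"true_v0_{name}"] = v
        drows.append(row)
        for o in r.observations:
            orows.append(
                {
                    "rat_id": r.rat_id,
                    "congener": o.congener,
                    "tissue": o.tissue,
                    "concentration": o.concentration,
                }
            )
    design = pd.DataFrame(
        drows,
        columns=None
        if drows
        else [
            "rat_id",
            "dose_level",
            "protocol",
            "sacrifice_day",
            "initial_body_weight",
            "final_body_weight",
            "liver_weight_ratio",
        ],
    )
    obs = pd.DataFrame(
        orows, columns=None if orows else ["rat_id", "congener", "tissue", "concentration"]
    )
    return design, obs


def write_study(records, design_path, observations_path) -> None:
    """Write records as design + observation CSV tables.

    Floats are written with 12 significant digits so a write/read round
    trip reproduces the records to that precision.
    """
    design, obs = _records_to_tables(records)
    design.to_csv(design_path, index=False, float_format="%.12g")
    obs.to_csv(observations_path, index=False, float_format="%.12g")


_DESIGN_REQUIRED = (
    "rat_id",
    "dose_level",
    "protocol",
    "sacrifice_day",
    "initial_body_weight",
    "final_body_weight",
    "liver_weight_ratio",
)
_OBS_REQUIRED = ("rat_id", "congener", "tissue", "concentration")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")


def read_study(design_path, observations_path) -> list[StudyRecord]:
    """Read a study written by :func:`write_study` back into records."""
    design = pd.read_csv(design_path, dtype={"rat_id": str, "protocol": str})
    obs = pd.read_csv(
        observations_path, dtype={"rat_id": str, "congener": str, "tissue": str}
    )
    _require_columns(design, _DESIGN_REQUIRED, design_path)
    _require_columns(obs, _OBS_REQUIRED, observations_path)

    true_cols = [c for c in design.columns if c.startswith("true_v0_")]
    obs_by_rat: dict[str, list[Observation]] = {}
    for i, row in obs.iterrows():
        try:
            ob = Observation(
                str(row["congener"]), str(row["tissue"]), float(row["concentration"])
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{observations_path}: row {i}, column 'concentration': {exc}"
            ) from exc
        obs_by_rat.setdefault(str(row["rat_id"]), []).append(ob)

    records = []
    for i, row in design.iterrows():
        try:
            cov = RatCovariates(
                initial_body_weight=float(row["initial_body_weight"]),
                final_body_weight=float(row["final_body_weight"]),
                sacrifice_day=float(row["sacrifice_day"]),
                liver_weight_ratio=float(row["liver_weight_ratio"]),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{design_path}: row {i}: {exc}") from exc
        true_v0 = None
        if true_cols and not any(pd.isna(row[c]) for c in true_cols):
            true_v0 = {c[len("true_v0_") :]: float(row[c]) for c in true_cols}
        records.append(
            StudyRecord(
                rat_id=str(row["rat_id"]),
                dose_level=float(row["dose_level"]),
                protocol=str(row["protocol"]),
                sacrifice_day=int(row["sacrifice_day"]),
                covariates=cov,
                observations=obs_by_rat.get(str(row["rat_id"]), []),
                true_v0=true_v0,
            )
        )
    return records
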