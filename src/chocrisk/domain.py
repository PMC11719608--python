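"""Domain types, toxicological constants, tabular I/O and regulatory QC.

The objects here describe one food-contaminant survey: chocolate products
with a measured cadmium concentration, the consumer groups whose intake is
assessed, the toxicological reference values the risk indices need, and the
EU maximum residue levels (MRLs) the samples are screened against
(Commission Regulation (EU) 2023/915: 0.1 / 0.3 / 0.8 mg/kg Cd for milk
chocolate <30% cacao, milk chocolate 30–<50% and dark chocolate >=50%).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ChocolateType",
    "ChocolateSample",
    "RegulatoryLimit",
    "DEFAULT_MRL_SCHEDULE",
    "mrl_for",
    "ComplianceResult",
    "check_compliance",
    "PopulationGroup",
    "GROUP_NAMES",
    "ToxicologyConstants",
    "QCBlankSet",
    "lod_loq",
    "read_samples",
    "write_samples",
    "read_population",
    "write_population",
    "apply_loq_policy",
]


class ChocolateType(str, Enum):
    MILK = "milk"
    DARK = "dark"


#: Canonical population-group names, in the reporting order used throughout.
GROUP_NAMES: tuple[str, ...] = (
    "toddlers",
    "other_children",
    "adolescents",
    "adults",
    "elderly",
    "pregnant_women",
    "vegetarians",
)


@dataclass(frozen=True)
class ChocolateSample:
    """One chocolate product with its measured Cd concentration.

    Parameters
    ----------
    sample_id : str
        Opaque identifier.
    chocolate_type : ChocolateType
        ``milk`` or ``dark``; drives which ingestion rate applies. Stored
        explicitly rather than derived from ``cacao_pct`` because consumption
        statistics are per product type while MRLs are per cacao band; a
        mismatch (e.g. "milk" at 55% cacao) is logged as a warning, not an
        error.
    cacao_pct : float
        Cacao content, percent in [0, 100].
    cd_conc : float
        Cadmium concentration, mg/kg; must be non-negative.
    """

    sample_id: str
    chocolate_type: ChocolateType
    cacao_pct: float
    cd_conc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chocolate_type", ChocolateType(self.chocolate_type))
        if not 0.0 <= self.cacao_pct <= 100.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: cacao_pct {self.cacao_pct} not in [0, 100]"
            )
        if self.cd_conc < 0.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: cd_conc {self.cd_conc} is negative"
            )
        if self.chocolate_type is ChocolateType.DARK and self.cacao_pct < 50.0:
            logger.warning(
                "sample %s: labelled dark but cacao_pct=%.1f < 50",
                self.sample_id, self.cacao_pct,
            )
        elif self.chocolate_type is ChocolateType.MILK and self.cacao_pct >= 50.0:
            logger.warning(
                "sample %s: labelled milk but cacao_pct=%.1f >= 50",
                self.sample_id, self.cacao_pct,
            )


@dataclass(frozen=True)
class RegulatoryLimit:
    """One MRL band: half-open cacao interval [cacao_low, cacao_high) -> mrl.

    The last band closes at 100 (a 100%-cacao product belongs to it).
    """

    category: str
    cacao_low: float
    cacao_high: float
    mrl: float

    def __post_init__(self) -> None:
        if self.mrl <= 0:
            raise DomainError(f"MRL for {self.category!r} must be positive")
        if not 0 <= self.cacao_low < self.cacao_high <= 100:
            raise DomainError(f"invalid cacao bounds for {self.category!r}")

    def contains(self, cacao_pct: float) -> bool:
        if self.cacao_high == 100.0:  # close the top band
            return self.cacao_low <= cacao_pct <= 100.0
        return self.cacao_low <= cacao_pct < self.cacao_high


DEFAULT_MRL_SCHEDULE: tuple[RegulatoryLimit, ...] = (
    RegulatoryLimit("milk_lt30", 0.0, 30.0, 0.1),
    RegulatoryLimit("milk_30to50", 30.0, 50.0, 0.3),
    RegulatoryLimit("dark_ge50", 50.0, 100.0, 0.8),
)


def mrl_for(
    cacao_pct: float,
    schedule: Sequence[RegulatoryLimit] = DEFAULT_MRL_SCHEDULE,
) -> float:
    """Maximum residue level (mg/kg) applying to a given cacao content.

    Band boundaries belong to the upper category (30% -> the 30–<50 band),
    matching the regulation's ">=" side.
    """
    if not 0.0 <= cacao_pct <= 100.0:
        raise DomainError(f"cacao_pct {cacao_pct} not in [0, 100]")
    for band in schedule:
        if band.contains(cacao_pct):
            return band.mrl
    raise DomainError(f"MRL schedule does not cover cacao_pct={cacao_pct}")


@dataclass(frozen=True)
class ComplianceResult:
    sample_id: str
    compliant: bool
    mrl: float
    margin: float  # mrl - cd_conc; negative when non-compliant


def check_compliance(
    sample: ChocolateSample,
    schedule: Sequence[RegulatoryLimit] = DEFAULT_MRL_SCHEDULE,
) -> ComplianceResult:
    """Screen one sample against its MRL band; compliant iff cd_conc <= MRL."""
    mrl = mrl_for(sample.cacao_pct, schedule)
    margin = mrl - sample.cd_conc
    return ComplianceResult(sample.sample_id, sample.cd_conc <= mrl, mrl, margin)


@dataclass(frozen=True)
class PopulationGroup:
    """Consumption and exposure parameters for one consumer class.

    Weekly ingestion rates are in kg chocolate per kg body weight per week
    (per-body-weight convention of consumption surveys); ``bw_nominal`` is
    used only in absolute-intake mode and as the location of the body-weight
    distribution in the Monte Carlo model.
    """

    name: str
    ingr_w_milk: float  # kg/kg bw/week
    ingr_w_dark: float  # kg/kg bw/week
    ed_years: float     # exposure duration, years
    bw_nominal: float = 70.0  # kg

    def __post_init__(self) -> None:
        if self.ingr_w_milk < 0 or self.ingr_w_dark < 0:
            raise ValidationError(f"group {self.name!r}: ingestion rates must be >= 0")
        if self.ed_years <= 0:
            raise ValidationError(f"group {self.name!r}: ed_years must be > 0")
        if self.bw_nominal <= 0:
            raise ValidationError(f"group {self.name!r}: bw_nominal must be > 0")


@dataclass(frozen=True)
class ToxicologyConstants:
    """Toxicological reference values and exposure-model constants.

    Attributes
    ----------
    ptwi : float
        Provisional tolerable weekly intake for Cd, µg/kg bw/week (EFSA: 2.5).
    rfd : float
        Oral reference dose, mg/kg/day (USEPA chronic oral RfD for Cd in
        food, 1e-3 — a documented assumption of this package).
    csf : float
        Cancer slope factor, (mg/kg/day)^-1 (6.1 for Cd).
    cf : float
        Unit conversion factor, 1e-3 (grams ingested -> kilograms).
    ef : float
        Exposure frequency, days/year (350).
    at_c : float
        Averaging time for cancer risk, days (70 y x 365 = 25550, all groups).
    """

    ptwi: float = 2.5
    rfd: float = 1e-3
    csf: float = 6.1
    cf: float = 1e-3
    ef: float = 350.0
    at_c: float = 25550.0
    mrl_schedule: tuple[RegulatoryLimit, ...] = DEFAULT_MRL_SCHEDULE

    def __post_init__(self) -> None:
        for name in ("ptwi", "rfd", "csf", "cf", "ef", "at_c"):
            if getattr(self, name) <= 0:
                raise DomainError(f"constant {name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToxicologyConstants":
        raw = yaml.safe_load(Path(path).read_text())
        schedule = tuple(
            RegulatoryLimit(**band) for band in raw.pop("mrl_schedule", [])
        ) or DEFAULT_MRL_SCHEDULE
        return cls(mrl_schedule=schedule, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "ptwi": self.ptwi, "rfd": self.rfd, "csf": self.csf,
            "cf": self.cf, "ef": self.ef, "at_c": self.at_c,
            "mrl_schedule": [asdict(b) for b in self.mrl_schedule],
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass(frozen=True)
class QCBlankSet:
    """Procedural-blank statistics for LOD/LOQ estimation."""

    blank_sd: float  # standard deviation of blank responses, signal units
    slope: float     # calibration slope, signal units per concentration

    def __post_init__(self) -> None:
        if self.blank_sd < 0:
            raise DomainError("blank_sd must be >= 0")
        if self.slope <= 0:
            raise DomainError("calibration slope must be > 0")


def lod_loq(qc: QCBlankSet) -> tuple[float, float]:
    """Limit of detection and quantification from blank noise.

    LOD = 3·sd/slope, LOQ = 10·sd/slope, so LOQ/LOD = 10/3 by construction.
    """
    lod = 3.0 * qc.blank_sd / qc.slope
    loq = 10.0 * qc.blank_sd / qc.slope
    return lod, loq


def apply_loq_policy(
    samples: Iterable[ChocolateSample],
    loq: float,
    policy: str | None = None,
) -> list[ChocolateSample]:
    """Optionally substitute concentrations below the LOQ.

    ``policy=None`` (default) keeps measured values as reported;
    ``policy="half_loq"`` replaces values below ``loq`` with ``loq/2``.
    """
    samples = list(samples)
    if policy is None:
        return samples
    if policy != "half_loq":
        raise DomainError(f"unknown LOQ policy {policy!r}")
    out = []
    for s in samples:
        if s.cd_conc < loq:
            out.append(ChocolateSample(s.sample_id, s.chocolate_type, s.cacao_pct, loq / 2.0))
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O (CSV with header row; column order free)
# ---------------------------------------------------------------------------

_SAMPLE_COLS = ("sample_id", "chocolate_type", "cacao_pct", "cd_conc")
_POP_COLS = ("name", "ingr_w_milk", "ingr_w_dark", "ed_years", "bw_nominal")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_samples(path: str | Path) -> list[ChocolateSample]:
    """Read a per-sample Cd table; rejects invalid rows with row-indexed messages."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SAMPLE_COLS, "sample")
    samples: list[ChocolateSample] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        try:
            samples.append(
                ChocolateSample(
                    sample_id=str(row["sample_id"]),
                    chocolate_type=ChocolateType(str(row["chocolate_type"]).strip().lower()),
                    cacao_pct=float(row["cacao_pct"]),
                    cd_conc=float(row["cd_conc"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("invalid sample rows:\n" + "\n".join(problems))
    return samples


def write_samples(samples: Iterable[ChocolateSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chocolate_type": s.chocolate_type.value,
                "cacao_pct": s.cacao_pct,
                "cd_conc": s.cd_conc,
            }
            for s in samples
        ],
        columns=list(_SAMPLE_COLS),
    )
    # shortest round-trip decimal representation
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_population(path: str | Path) -> list[PopulationGroup]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _POP_COLS[:-1], "population")  # bw_nominal optional
    groups: list[PopulationGroup] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        try:
            groups.append(
                PopulationGroup(
                    name=str(row["name"]),
                    ingr_w_milk=float(row["ingr_w_milk"]),
                    ingr_w_dark=float(row["ingr_w_dark"]),
                    ed_years=float(row["ed_years"]),
                    bw_nominal=float(row["bw_nominal"]) if "bw_nominal" in df.columns
                    and not pd.isna(row.get("bw_nominal", np.nan)) else 70.0,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("invalid population rows:\n" + "\n".join(problems))
    return groups


def write_population(groups: Iterable[PopulationGroup], path: str | Path) -> None:
    df = pd.DataFrame([asdict(g) for g in groups], columns=list(_POP_COLS))
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
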