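"""Point-estimate exposure and risk indices.

For a contaminant concentration C and a consumer group's ingestion rate the
module computes four indices:

* ``EWI = IngR_w · C`` — estimated weekly intake, µg/kg bw/week, with C in
  µg/kg and IngR_w in kg/kg bw/week;
* ``%PTWI = 100 · EWI / PTWI`` — the intake as a percentage of the
  provisional tolerable weekly intake;
* ``HQ = EF·ED·C·IngR·CF / (AT_nc·RfD)`` — the non-carcinogenic hazard
  quotient, with AT_nc = 365·ED days so that ED cancels algebraically;
* ``CR = EF·ED·C·IngR·CF·CSF / AT_c`` — incremental lifetime cancer risk
  averaged over AT_c = 25550 days.

HQ and CR are evaluated per body weight by default (IngR in g/kg bw/day, BW
omitted); pass ``bw`` to use absolute intakes (IngR in g/day, divided by BW).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import ChocolateSample, ChocolateType, PopulationGroup, ToxicologyConstants
from .errors import DomainError

__all__ = [
    "ewi",
    "pct_ptwi",
    "daily_from_weekly",
    "hq",
    "cr",
    "HQClass",
    "CRClass",
    "RiskClass",
    "classify",
    "ExposureResult",
    "evaluate_samples",
    "GroupSummary",
    "group_summary",
    "ENDPOINTS",
]

ENDPOINTS = ("ewi", "pct_ptwi", "hq", "cr")

MG_PER_KG_TO_UG_PER_KG = 1000.0
DAYS_PER_YEAR = 365.0


def ewi(c: float, ingr_w: float) -> float:
    """Estimated weekly intake, µg/kg bw/week.

    Parameters: ``c`` in µg/kg (callers convert mg/kg by x1000),
    ``ingr_w`` in kg/kg bw/week.
    """
    if c < 0 or ingr_w < 0:
        raise DomainError("ewi: concentration and ingestion rate must be >= 0")
    return c * ingr_w


def pct_ptwi(ewi_value: float, ptwi: float) -> float:
    """Weekly intake as a percentage of the tolerable weekly intake."""
    if ptwi <= 0:
        raise DomainError("pct_ptwi: PTWI must be > 0")
    if ewi_value < 0:
        raise DomainError("pct_ptwi: EWI must be >= 0")
    return 100.0 * ewi_value / ptwi


def daily_from_weekly(ingr_w: float) -> float:
    """Convert a weekly rate (kg/kg bw/week) to a daily rate (g/kg bw/day)."""
    if ingr_w < 0:
        raise DomainError("daily_from_weekly: rate must be >= 0")
    return ingr_w / 7.0 * 1000.0


def hq(
    c: float,
    ingr_d: float,
    consts: ToxicologyConstants,
    ed_years: float,
    bw: float | None = None,
) -> float:
    """Hazard quotient for chronic (non-carcinogenic) Cd exposure.

    ``c`` in mg/kg; ``ingr_d`` in g/kg bw/day (per-bw mode, ``bw=None``) or
    g/day with ``bw`` in kg (absolute mode). AT_nc is derived internally as
    365·ed_years, which makes HQ independent of the exposure duration.
    """
    if min(c, ingr_d, ed_years) < 0:
        raise DomainError("hq: inputs must be >= 0")
    if consts.rfd <= 0:
        raise DomainError("hq: RfD must be > 0")
    at_nc = DAYS_PER_YEAR * ed_years
    value = (consts.ef * ed_years * c * ingr_d * consts.cf) / (at_nc * consts.rfd)
    if bw is not None:
        if bw <= 0:
            raise DomainError("hq: body weight must be > 0")
        value /= bw
    return value


def cr(
    c: float,
    ingr_d: float,
    consts: ToxicologyConstants,
    ed_years: float,
    bw: float | None = None,
) -> float:
    """Incremental lifetime cancer risk; strictly increasing in exposure duration."""
    if min(c, ingr_d, ed_years) < 0:
        raise DomainError("cr: inputs must be >= 0")
    if consts.at_c <= 0:
        raise DomainError("cr: AT_c must be > 0")
    value = (consts.ef * ed_years * c * ingr_d * consts.cf * consts.csf) / consts.at_c
    if bw is not None:
        if bw <= 0:
            raise DomainError("cr: body weight must be > 0")
        value /= bw
    return value


class HQClass(str, Enum):
    SAFE = "safe"          # HQ <= 1
    ADVERSE = "adverse"    # HQ > 1


class CRClass(str, Enum):
    NEGLIGIBLE = "negligible"      # CR <= 1e-6
    MODERATE = "moderate"          # 1e-6 < CR <= 1e-4
    UNACCEPTABLE = "unacceptable"  # CR > 1e-4


@dataclass(frozen=True)
class RiskClass:
    hq_class: HQClass
    cr_class: CRClass


def classify(hq_value: float, cr_value: float) -> RiskClass:
    """Apply the regulatory risk thresholds (boundaries inclusive on the safe side)."""
    if hq_value < 0 or cr_value < 0:
        raise DomainError("classify: indices must be >= 0")
    hq_class = HQClass.SAFE if hq_value <= 1.0 else HQClass.ADVERSE
    if cr_value <= 1e-6:
        cr_class = CRClass.NEGLIGIBLE
    elif cr_value <= 1e-4:
        cr_class = CRClass.MODERATE
    else:
        cr_class = CRClass.UNACCEPTABLE
    return RiskClass(hq_class, cr_class)


@dataclass(frozen=True)
class ExposureResult:
    """All four indices for one sample under one group's consumption pattern."""

    sample_id: str
    group: str
    chocolate_type: ChocolateType
    ewi: float       # µg/kg bw/week
    pct_ptwi: float  # percent
    hq: float
    cr: float


def _rate_for(group: PopulationGroup, choc_type: ChocolateType) -> float:
    return group.ingr_w_milk if choc_type is ChocolateType.MILK else group.ingr_w_dark


def evaluate_samples(
    samples: Iterable[ChocolateSample],
    groups: Iterable[PopulationGroup],
    consts: ToxicologyConstants,
    mode: str = "per_bw",
) -> pd.DataFrame:
    """Evaluate every sample x group pair with the type-matched ingestion rate.

    Returns a long-format frame with columns sample_id, group,
    chocolate_type, ewi, pct_ptwi, hq, cr, hq_class, cr_class.
    """
    if mode not in ("per_bw", "absolute"):
        raise DomainError(f"unknown mode {mode!r}")
    rows = []
    for group in groups:
        for s in samples:
            ingr_w = _rate_for(group, s.chocolate_type)
            ingr_d = daily_from_weekly(ingr_w)  # g/kg bw/day
            bw = None
            if mode == "absolute":
                ingr_d = ingr_d * group.bw_nominal  # g/day
                bw = group.bw_nominal
            e = ewi(s.cd_conc * MG_PER_KG_TO_UG_PER_KG, ingr_w)
            h = hq(s.cd_conc, ingr_d, consts, group.ed_years, bw=bw)
            k = cr(s.cd_conc, ingr_d, consts, group.ed_years, bw=bw)
            rc = classify(h, k)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": group.name,
                    "chocolate_type": s.chocolate_type.value,
                    "ewi": e,
                    "pct_ptwi": pct_ptwi(e, consts.ptwi),
                    "hq": h,
                    "cr": k,
                    "hq_class": rc.hq_class.value,
                    "cr_class": rc.cr_class.value,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupSummary:
    """min/mean/max of one endpoint over a sample collection, for one group."""

    group: str
    endpoint: str
    minimum: float
    mean: float
    maximum: float
    cr_class_fractions: Mapping[str, float]  # fractions over samples, sum to 1

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise DomainError("GroupSummary: min <= mean <= max violated")


def group_summary(
    samples: Sequence[ChocolateSample],
    group: PopulationGroup,
    consts: ToxicologyConstants,
    mode: str = "per_bw",
    by_type: bool = False,
) -> dict[str, GroupSummary] | dict[tuple[str, str], GroupSummary]:
    """Summaries of every endpoint for one group over a sample collection.

    Each sample is evaluated under the ingestion rate matching its own
    chocolate type; with ``by_type=True`` summaries are keyed by
    (chocolate_type, endpoint) instead of pooling milk and dark.
    """
    samples = list(samples)
    if not samples:
        raise DomainError("group_summary: empty sample collection")
    table = evaluate_samples(samples, [group], consts, mode=mode)

    def _summarise(sub: pd.DataFrame, key):
        out = {}
        fractions = sub["cr_class"].value_counts(normalize=True).to_dict()
        fractions = {c.value: float(fractions.get(c.value, 0.0)) for c in CRClass}
        for endpoint in ENDPOINTS:
            vals = sub[endpoint].to_numpy()
            out[key(endpoint)] = GroupSummary(
                group=group.name,
                endpoint=endpoint,
                minimum=float(np.min(vals)),
                mean=float(np.mean(vals)),
                maximum=float(np.max(vals)),
                cr_class_fractions=fractions,
            )
        return out

    if not by_type:
        return _summarise(table, key=lambda ep: ep)
    out: dict[tuple[str, str], GroupSummary] = {}
    for choc_type, sub in table.groupby("chocolate_type"):
        out.update(_summarise(sub, key=lambda ep: (str(choc_type), ep)))
    return out
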