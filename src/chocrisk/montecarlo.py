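"""Seeded Monte Carlo propagation of input uncertainty through HQ and CR.

Each model input is a :class:`~chocrisk.distributions.DistributionSpec`
(point / triangular / lognormal, mirroring the distribution families used in
probabilistic dietary risk assessment: concentration lognormal, ingestion
rate and exposure frequency triangular, body weight lognormal, the
toxicological constants point). Milk- and dark-chocolate exposures carry
their own concentration and ingestion-rate draws and are summed into one
intake term per iteration:

    intake_i = C_milk,i · IngR_milk,i + C_dark,i · IngR_dark,i

HQ_i = EF_i·intake_i·CF_i / (365·RfD_i [· BW_i]) (the exposure duration
cancels against AT_nc = 365·ED), and
CR_i = EF_i·ED_i·intake_i·CF_i·CSF_i / (AT_i [· BW_i]).

Every symbol draws from its own deterministic substream of the root seed, so
changing one input's spec never perturbs the other inputs' draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deterministic import DAYS_PER_YEAR, daily_from_weekly
from .distributions import DistributionSpec
from .domain import PopulationGroup, ToxicologyConstants
from .errors import DomainError, SpecError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MCSResult",
    "run_mcs",
    "percentile",
    "SpreadConfig",
    "build_group_model",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (5.0, 50.0, 90.0, 95.0, 99.0)

#: Symbols of each endpoint's equation. AT appears only for CR: the
#: non-carcinogenic averaging time is always derived as 365·ED so that the
#: HQ/exposure-duration cancellation stays exact.
_HQ_SYMBOLS = ("C_milk", "C_dark", "IngR_milk", "IngR_dark", "EF", "ED", "CF", "RfD")
_CR_SYMBOLS = ("C_milk", "C_dark", "IngR_milk", "IngR_dark", "EF", "ED", "CF", "CSF", "AT")

#: Denominator symbols whose draws must be strictly positive; non-positive
#: draws are rejected and redrawn (with a log notice).
_POSITIVE_SYMBOLS = ("RfD", "BW", "AT", "CSF")


@dataclass(frozen=True)
class ModelSpec:
    """Complete specification of one Monte Carlo risk model.

    Parameters
    ----------
    endpoint : {"HQ", "CR"}
    group : str
        Population-group name (metadata echoed into the result).
    dists : mapping symbol -> DistributionSpec
        Required symbols: C_milk, C_dark, IngR_milk, IngR_dark, EF, ED, CF
        plus RfD (HQ) or CSF and AT (CR), plus BW in absolute mode.
    mode : {"per_bw", "absolute"}
        per_bw: IngR in g/kg bw/day, BW omitted. absolute: IngR in g/day,
        output divided by the BW draw.
    iterations : int
    seed : int
    """

    endpoint: str
    group: str
    dists: Mapping[str, DistributionSpec]
    mode: str = "per_bw"
    iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endpoint not in ("HQ", "CR"):
            raise SpecError(f"unknown endpoint {self.endpoint!r}")
        if self.mode not in ("per_bw", "absolute"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.iterations < 1:
            raise SpecError("iterations must be >= 1")
        required = set(self.symbols)
        given = set(self.dists)
        if missing := required - given:
            raise SpecError(f"missing distribution spec(s): {sorted(missing)}")
        if extra := given - required:
            raise SpecError(
                f"unexpected symbol(s) {sorted(extra)} for endpoint {self.endpoint} "
                f"in {self.mode} mode (AT is derived as 365*ED for HQ)"
            )
        object.__setattr__(self, "dists", dict(self.dists))

    @property
    def symbols(self) -> tuple[str, ...]:
        base = _HQ_SYMBOLS if self.endpoint == "HQ" else _CR_SYMBOLS
        return base + ("BW",) if self.mode == "absolute" else base


@dataclass(frozen=True)
class MCSResult:
    """Draws, outputs and percentile summary of one Monte Carlo run."""

    model: ModelSpec
    draws: pd.DataFrame          # iterations x symbols
    output: np.ndarray           # length = iterations
    percentiles: Mapping[float, float]
    seed: int

    def percentile(self, p: float) -> float:
        return percentile(self.output, p)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": self.model.group, "endpoint": self.model.endpoint,
             "p": p, "value": v}
            for p, v in sorted(self.percentiles.items())
        ]
        return pd.DataFrame(rows)


def percentile(values: Sequence[float] | np.ndarray, p: float) -> float:
    """Type-7 (linear-interpolation) percentile; p=0 -> min, p=100 -> max."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("percentile: empty input")
    if not 0.0 <= p <= 100.0:
        raise DomainError(f"percentile: p={p} not in [0, 100]")
    return float(np.percentile(values, p))


def _symbol_rng(seed: int, symbol: str) -> np.random.Generator:
    # per-symbol substream: stable under addition/removal of other symbols
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(symbol.encode())]))


def _draw_symbol(spec: DistributionSpec, n: int, rng: np.random.Generator,
                 symbol: str) -> np.ndarray:
    draws = spec.sample(n, rng)
    if symbol in _POSITIVE_SYMBOLS:
        redraws = 0
        bad = draws <= 0
        while bad.any():
            draws[bad] = spec.sample(int(bad.sum()), rng)
            redraws += int(bad.sum())
            if redraws > 100 * n:
                raise SpecError(f"symbol {symbol}: cannot draw positive values")
            bad = draws <= 0
        if redraws:
            logger.warning("symbol %s: redrew %d non-positive draws", symbol, redraws)
    return draws


def run_mcs(
    model: ModelSpec,
    requested_percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> MCSResult:
    """Run the simulation: draw every symbol, evaluate the endpoint per iteration."""
    n = model.iterations
    cols = {
        sym: _draw_symbol(model.dists[sym], n, _symbol_rng(model.seed, sym), sym)
        for sym in model.symbols
    }
    intake = cols["C_milk"] * cols["IngR_milk"] + cols["C_dark"] * cols["IngR_dark"]
    if model.endpoint == "HQ":
        at_nc = DAYS_PER_YEAR * cols["ED"]
        out = cols["EF"] * cols["ED"] * intake * cols["CF"] / (at_nc * cols["RfD"])
    else:
        out = (cols["EF"] * cols["ED"] * intake * cols["CF"] * cols["CSF"]) / cols["AT"]
    if model.mode == "absolute":
        out = out / cols["BW"]
    pcts = {float(p): percentile(out, p) for p in requested_percentiles}
    return MCSResult(
        model=model,
        draws=pd.DataFrame(cols, columns=list(model.symbols)),
        output=np.asarray(out, dtype=float),
        percentiles=pcts,
        seed=model.seed,
    )


# ---------------------------------------------------------------------------
# Default model construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpreadConfig:
    """Spread assumptions for the stochastic inputs.

    The distribution families are fixed by the assessment design; the spread
    magnitudes below are this package's documented defaults (consumption
    surveys constrain ingestion rates fairly tightly, exposure frequency is
    bounded above by 365 days, anthropometric body-weight variation is wide):

    * ``ingr_rel`` — triangular ingestion rate as (0.9, 1.0, 1.1) x nominal;
    * ``ef_days`` — triangular exposure frequency (300, 350, 365) days/year;
    * ``bw_cv`` — lognormal body weight with CV 0.2 around the nominal mean.
    """

    ingr_rel: tuple[float, float, float] = (0.9, 1.0, 1.1)
    ef_days: tuple[float, float, float] = (300.0, 350.0, 365.0)
    bw_cv: float = 0.2

    def __post_init__(self) -> None:
        if not self.ingr_rel[0] <= self.ingr_rel[1] <= self.ingr_rel[2]:
            raise SpecError("ingr_rel must be ordered min <= mode <= max")
        if not self.ef_days[0] <= self.ef_days[1] <= self.ef_days[2]:
            raise SpecError("ef_days must be ordered min <= mode <= max")
        if self.bw_cv < 0:
            raise SpecError("bw_cv must be >= 0")


def _triangular_scaled(nominal: float, rel: tuple[float, float, float]) -> DistributionSpec:
    if nominal == 0:
        return DistributionSpec.point(0.0)
    return DistributionSpec.triangular(nominal * rel[0], nominal * rel[1], nominal * rel[2])


def build_group_model(
    group: PopulationGroup,
    endpoint: str,
    conc_specs: Mapping[str, DistributionSpec],
    consts: ToxicologyConstants,
    mode: str = "absolute",
    spread: SpreadConfig | None = None,
    iterations: int = 10_000,
    seed: int = 0,
) -> ModelSpec:
    """Assemble the default ModelSpec for one group and endpoint.

    ``conc_specs`` maps ``"milk"``/``"dark"`` to concentration distributions
    in mg/kg (typically lognormal fitted from the sample table's mean and
    median per chocolate type). Ingestion rates are taken from the group's
    weekly per-bw rates, converted to g/kg bw/day (per_bw mode) or g/day via
    the nominal body weight (absolute mode), and given triangular spreads.
    """
    spread = spread or SpreadConfig()
    if set(conc_specs) != {"milk", "dark"}:
        raise SpecError("conc_specs must have exactly the keys 'milk' and 'dark'")
    scale = group.bw_nominal if mode == "absolute" else 1.0
    dists: dict[str, DistributionSpec] = {
        "C_milk": conc_specs["milk"],
        "C_dark": conc_specs["dark"],
        "IngR_milk": _triangular_scaled(daily_from_weekly(group.ingr_w_milk) * scale,
                                        spread.ingr_rel),
        "IngR_dark": _triangular_scaled(daily_from_weekly(group.ingr_w_dark) * scale,
                                        spread.ingr_rel),
        "EF": DistributionSpec.triangular(*spread.ef_days),
        "ED": DistributionSpec.point(group.ed_years),
        "CF": DistributionSpec.point(consts.cf),
    }
    if endpoint == "HQ":
        dists["RfD"] = DistributionSpec.point(consts.rfd)
    else:
        dists["CSF"] = DistributionSpec.point(consts.csf)
        dists["AT"] = DistributionSpec.point(consts.at_c)
    if mode == "absolute":
        dists["BW"] = DistributionSpec.lognormal_from_mean_cv(group.bw_nominal, spread.bw_cv)
    return ModelSpec(
        endpoint=endpoint, group=group.name, dists=dists,
        mode=mode, iterations=iterations, seed=seed,
    )
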