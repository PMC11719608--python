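"""Declarative random-variable specifications for the Monte Carlo model.

Three families cover the probabilistic exposure model: ``point`` (a constant
treated as a degenerate distribution), ``triangular`` (min/mode/max) and
``lognormal`` (parameterised on the log scale). Lognormal specs can also be
built from summary statistics: (arithmetic mean, median) or (arithmetic
mean, coefficient of variation), the two forms survey tables usually print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import SpecError

__all__ = [
    "DistributionSpec",
    "sample",
    "lognormal_params_from_mean_median",
    "lognormal_params_from_mean_cv",
]


def lognormal_params_from_mean_median(arith_mean: float, median: float) -> tuple[float, float]:
    """Lognormal (log_mean, log_sd) matching an arithmetic mean and a median.

    From mean = exp(µ + σ²/2) and median = exp(µ):
    µ = ln(median), σ = sqrt(2·ln(mean/median)). A lognormal has mean >=
    median, so ``arith_mean < median`` is infeasible.
    """
    if median <= 0:
        raise SpecError("lognormal fit: median must be > 0")
    if arith_mean < median:
        raise SpecError(
            f"lognormal fit infeasible: arithmetic mean {arith_mean} < median {median}"
        )
    log_mean = math.log(median)
    log_sd = math.sqrt(2.0 * math.log(arith_mean / median))
    return log_mean, log_sd


def lognormal_params_from_mean_cv(arith_mean: float, cv: float) -> tuple[float, float]:
    """Lognormal (log_mean, log_sd) matching an arithmetic mean and a CV."""
    if arith_mean <= 0:
        raise SpecError("lognormal fit: mean must be > 0")
    if cv < 0:
        raise SpecError("lognormal fit: CV must be >= 0")
    sigma2 = math.log(1.0 + cv * cv)
    log_mean = math.log(arith_mean) - sigma2 / 2.0
    return log_mean, math.sqrt(sigma2)


@dataclass(frozen=True)
class DistributionSpec:
    """One random input of the risk model.

    ``kind`` is one of ``point`` / ``triangular`` / ``lognormal``; ``params``
    holds {value} / {min, mode, max} / {log_mean, log_sd} respectively.
    """

    kind: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        p = dict(self.params)
        if self.kind == "point":
            if set(p) != {"value"} or not math.isfinite(p["value"]):
                raise SpecError(f"point spec requires a finite 'value', got {p}")
        elif self.kind == "triangular":
            if set(p) != {"min", "mode", "max"}:
                raise SpecError(f"triangular spec requires min/mode/max, got {p}")
            if not p["min"] <= p["mode"] <= p["max"]:
                raise SpecError("triangular spec requires min <= mode <= max")
        elif self.kind == "lognormal":
            if set(p) != {"log_mean", "log_sd"}:
                raise SpecError(f"lognormal spec requires log_mean/log_sd, got {p}")
            if p["log_sd"] < 0:
                raise SpecError("lognormal spec requires log_sd >= 0")
        else:
            raise SpecError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "params", MappingProxyType(p))

    # -- constructors -------------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    @classmethod
    def triangular(cls, minimum: float, mode: float, maximum: float) -> "DistributionSpec":
        return cls("triangular", {"min": float(minimum), "mode": float(mode), "max": float(maximum)})

    @classmethod
    def lognormal(cls, log_mean: float, log_sd: float) -> "DistributionSpec":
        return cls("lognormal", {"log_mean": float(log_mean), "log_sd": float(log_sd)})

    @classmethod
    def lognormal_from_mean_median(cls, arith_mean: float, median: float) -> "DistributionSpec":
        return cls.lognormal(*lognormal_params_from_mean_median(arith_mean, median))

    @classmethod
    def lognormal_from_mean_cv(cls, arith_mean: float, cv: float) -> "DistributionSpec":
        return cls.lognormal(*lognormal_params_from_mean_cv(arith_mean, cv))

    # -- properties ---------------------------------------------------------
    @property
    def is_stochastic(self) -> bool:
        if self.kind == "point":
            return False
        if self.kind == "triangular":
            return self.params["min"] < self.params["max"]
        return self.params["log_sd"] > 0

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        p = self.params
        if self.kind == "point":
            return p["value"]
        if self.kind == "triangular":
            return (p["min"] + p["mode"] + p["max"]) / 3.0
        return math.exp(p["log_mean"] + p["log_sd"] ** 2 / 2.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample(self, n, rng)


def sample(dist: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` variates from a spec using the given generator.

    Identical (spec, generator state, n) give identical draws; a point spec
    returns a constant vector without consuming random state so that adding
    or removing point inputs never perturbs other streams.
    """
    if n < 1:
        raise SpecError("sample: n must be >= 1")
    p = dist.params
    if dist.kind == "point":
        return np.full(n, p["value"], dtype=float)
    if dist.kind == "triangular":
        if p["min"] == p["max"]:
            return np.full(n, p["min"], dtype=float)
        return rng.triangular(p["min"], p["mode"], p["max"], size=n)
    # lognormal
    if p["log_sd"] == 0:
        return np.full(n, math.exp(p["log_mean"]), dtype=float)
    return rng.lognormal(mean=p["log_mean"], sigma=p["log_sd"], size=n)
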