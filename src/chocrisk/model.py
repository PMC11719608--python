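"""Model/Results front end for the dietary cadmium risk assessment.

:class:`CadmiumRiskModel` is built from a sample table, a population table
and the toxicological constants; ``fit()`` evaluates the deterministic
indices (EWI, %PTWI, HQ, CR) for every sample x group pair and returns a
:class:`CadmiumRiskResults` carrying the long table, group summaries,
MRL-compliance screen and a text ``summary()``. ``simulate()`` runs the
probabilistic (Monte Carlo) model per group and endpoint and returns a
:class:`MonteCarloResults` with percentile tables and contribution-to-
variance sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import deterministic as det
from .distributions import DistributionSpec
from .domain import (
    ChocolateSample,
    ChocolateType,
    PopulationGroup,
    ToxicologyConstants,
    check_compliance,
    read_population,
    read_samples,
)
from .errors import DomainError, SpecError
from .montecarlo import (
    DEFAULT_PERCENTILES,
    MCSResult,
    SpreadConfig,
    build_group_model,
    run_mcs,
)
from .sensitivity import SensitivityResult, sensitivity_of

__all__ = ["CadmiumRiskModel", "CadmiumRiskResults", "MonteCarloResults"]


class CadmiumRiskModel:
    """Dietary Cd risk model for a set of chocolate samples and consumer groups.

    Parameters
    ----------
    samples : iterable of ChocolateSample
    population : iterable of PopulationGroup
    constants : ToxicologyConstants, optional
        Defaults to the package's reference values (PTWI 2.5 µg/kg bw/week,
        RfD 1e-3 mg/kg/day, CSF 6.1 (mg/kg/day)^-1, EF 350 d/y, AT_c 25550 d).
    mode : {"per_bw", "absolute"}
        Deterministic evaluation mode. Per body weight is the default (BW
        cancels out of the survey's per-bw ingestion rates); absolute mode
        multiplies by the nominal body weight and divides the indices by it.

    Examples
    --------
    >>> from chocrisk import CadmiumRiskModel
    >>> model = CadmiumRiskModel.from_study_fixture(seed=1)
    >>> res = model.fit()
    >>> res.table.shape[0]  # 150 samples x 7 groups
    1050
    """

    def __init__(
        self,
        samples: Iterable[ChocolateSample],
        population: Iterable[PopulationGroup],
        constants: ToxicologyConstants | None = None,
        mode: str = "per_bw",
    ) -> None:
        self.samples = list(samples)
        self.population = list(population)
        self.constants = constants or ToxicologyConstants()
        if mode not in ("per_bw", "absolute"):
            raise DomainError(f"unknown mode {mode!r}")
        self.mode = mode
        if not self.samples:
            raise DomainError("model requires at least one sample")
        if not self.population:
            raise DomainError("model requires at least one population group")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        samples_path: str | Path,
        population_path: str | Path,
        constants_path: str | Path | None = None,
        mode: str = "per_bw",
    ) -> "CadmiumRiskModel":
        constants = (
            ToxicologyConstants.from_yaml(constants_path) if constants_path else None
        )
        return cls(read_samples(samples_path), read_population(population_path),
                   constants, mode=mode)

    @classmethod
    def from_study_fixture(cls, seed: int = 0, scale: int = 1,
                           mode: str = "per_bw") -> "CadmiumRiskModel":
        from .synthetic import builtin_study_fixture

        fx = builtin_study_fixture(seed=seed, scale=scale)
        return cls(fx.samples, fx.population, fx.constants, mode=mode)

    # -- estimation ---------------------------------------------------------
    def fit(self) -> "CadmiumRiskResults":
        """Evaluate the deterministic indices for every sample x group pair."""
        table = det.evaluate_samples(
            self.samples, self.population, self.constants, mode=self.mode
        )
        summaries = {
            g.name: det.group_summary(self.samples, g, self.constants, mode=self.mode)
            for g in self.population
        }
        compliance = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "compliant": c.compliant,
                    "mrl": c.mrl,
                    "margin": c.margin,
                }
                for c in (
                    check_compliance(s, self.constants.mrl_schedule)
                    for s in self.samples
                )
            ]
        )
        return CadmiumRiskResults(self, table, summaries, compliance)

    # -- simulation ---------------------------------------------------------
    def concentration_specs(self) -> dict[str, DistributionSpec]:
        """Lognormal concentration spec per chocolate type, fitted from the samples."""
        out: dict[str, DistributionSpec] = {}
        for name, choc_type in (("milk", ChocolateType.MILK), ("dark", ChocolateType.DARK)):
            conc = np.array(
                [s.cd_conc for s in self.samples if s.chocolate_type is choc_type]
            )
            if conc.size == 0:
                out[name] = DistributionSpec.point(0.0)
            elif conc.size == 1 or conc.std() == 0:
                out[name] = DistributionSpec.point(float(conc[0]))
            else:
                out[name] = DistributionSpec.lognormal_from_mean_median(
                    float(conc.mean()), float(np.median(conc))
                )
        return out

    def simulate(
        self,
        endpoints: Sequence[str] = ("HQ", "CR"),
        iterations: int = 10_000,
        seed: int = 0,
        mode: str = "absolute",
        spread: SpreadConfig | None = None,
        conc_specs: Mapping[str, DistributionSpec] | None = None,
        percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    ) -> "MonteCarloResults":
        """Monte Carlo propagation for every group and requested endpoint.

        Absolute mode is the probabilistic default: body weight enters as a
        lognormal variable there, which is the point of running the
        simulation per group.
        """
        conc = dict(conc_specs) if conc_specs is not None else self.concentration_specs()
        results: dict[tuple[str, str], MCSResult] = {}
        for group in self.population:
            for endpoint in endpoints:
                if endpoint not in ("HQ", "CR"):
                    raise SpecError(f"unknown endpoint {endpoint!r}")
                spec = build_group_model(
                    group, endpoint, conc, self.constants,
                    mode=mode, spread=spread, iterations=iterations, seed=seed,
                )
                results[(group.name, endpoint)] = run_mcs(spec, percentiles)
        return MonteCarloResults(results, seed=seed, iterations=iterations)


@dataclass
class CadmiumRiskResults:
    """Deterministic assessment results.

    Attributes
    ----------
    table : pandas.DataFrame
        Long format, one row per sample x group with all four indices and
        their risk classes.
    group_summaries : mapping group -> endpoint -> GroupSummary
    compliance : pandas.DataFrame
        MRL screen per sample (compliant flag and margin in mg/kg).
    """

    model: CadmiumRiskModel
    table: pd.DataFrame
    group_summaries: Mapping[str, Mapping[str, det.GroupSummary]]
    compliance: pd.DataFrame

    def summary_table(self) -> pd.DataFrame:
        """Group x endpoint min/mean/max in one tidy frame."""
        rows = []
        for group, by_ep in self.group_summaries.items():
            for endpoint, gs in by_ep.items():
                rows.append(
                    {
                        "group": group,
                        "endpoint": endpoint,
                        "min": gs.minimum,
                        "mean": gs.mean,
                        "max": gs.maximum,
                    }
                )
        return pd.DataFrame(rows)

    def pct_ptwi_range(self) -> pd.DataFrame:
        """Per-group min/max %PTWI (the headline weekly-intake comparison)."""
        g = self.table.groupby("group")["pct_ptwi"]
        return pd.DataFrame({"min": g.min(), "max": g.max()}).reset_index()

    def summary(self) -> str:
        n_samples = len(self.model.samples)
        n_groups = len(self.model.population)
        n_noncompliant = int((~self.compliance["compliant"]).sum())
        lines = [
            "Dietary cadmium risk assessment (deterministic)",
            "=" * 64,
            f"samples: {n_samples}   groups: {n_groups}   mode: {self.model.mode}",
            f"MRL screen: {n_samples - n_noncompliant}/{n_samples} compliant",
            "",
            "%PTWI by group (min–max):",
        ]
        for _, row in self.pct_ptwi_range().iterrows():
            lines.append(f"  {row['group']:<16s} {row['min']:6.2f}% – {row['max']:6.2f}%")
        lines.append("")
        lines.append("HQ / CR by group (min, mean, max):")
        for group, by_ep in self.group_summaries.items():
            hq_s, cr_s = by_ep["hq"], by_ep["cr"]
            lines.append(
                f"  {group:<16s} HQ {hq_s.minimum:9.3e} {hq_s.mean:9.3e} "
                f"{hq_s.maximum:9.3e}   CR {cr_s.minimum:9.3e} {cr_s.mean:9.3e} "
                f"{cr_s.maximum:9.3e}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


@dataclass
class MonteCarloResults:
    """Per-(group, endpoint) Monte Carlo results with sensitivity accessors."""

    results: Mapping[tuple[str, str], MCSResult]
    seed: int
    iterations: int
    _sens_cache: dict = field(default_factory=dict, repr=False)

    def __getitem__(self, key: tuple[str, str]) -> MCSResult:
        return self.results[key]

    def percentile_table(self) -> pd.DataFrame:
        frames = [res.summary() for res in self.results.values()]
        return pd.concat(frames, ignore_index=True)

    def sensitivity(self, group: str, endpoint: str) -> SensitivityResult:
        key = (group, endpoint)
        if key not in self._sens_cache:
            self._sens_cache[key] = sensitivity_of(self.results[key])
        return self._sens_cache[key]

    def sensitivity_table(self) -> pd.DataFrame:
        rows = []
        for (group, endpoint) in self.results:
            sens = self.sensitivity(group, endpoint)
            for factor, contrib in sens.contributions.items():
                rows.append(
                    {
                        "group": group,
                        "endpoint": endpoint,
                        "factor": factor,
                        "contribution_pct": contrib,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Dietary cadmium risk assessment (Monte Carlo)",
            "=" * 64,
            f"iterations: {self.iterations}   seed: {self.seed}",
            "",
            "90th percentiles:",
        ]
        for (group, endpoint), res in sorted(self.results.items()):
            lines.append(f"  {group:<16s} {endpoint}: {res.percentile(90):9.3e}")
        lines.append("=" * 64)
        return "\n".join(lines)
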