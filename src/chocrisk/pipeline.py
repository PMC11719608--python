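"""End-to-end pipeline: validate -> compliance -> deterministic risk -> MCS
-> sensitivity, with a reproducibility manifest.

All stages run off one :class:`RunConfig`; any stage failure removes the
partially written outputs and re-raises with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .domain import ToxicologyConstants
from .errors import ChocriskError
from .model import CadmiumRiskModel
from .montecarlo import DEFAULT_PERCENTILES, SpreadConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(ChocriskError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    ``samples_path``/``population_path`` may be None, in which case the
    built-in synthetic study fixture (regenerated from ``seed``) is used.
    """

    out_dir: Path
    samples_path: Path | None = None
    population_path: Path | None = None
    constants_path: Path | None = None
    mode: str = "per_bw"          # deterministic evaluation mode
    mcs_mode: str = "absolute"    # probabilistic evaluation mode
    iterations: int = 10_000
    seed: int = 0
    percentiles: Sequence[float] = DEFAULT_PERCENTILES
    spread: SpreadConfig = field(default_factory=SpreadConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ChocriskError("iterations must be >= 1")
        if any(not 0 <= p <= 100 for p in self.percentiles):
            raise ChocriskError("percentiles must lie in [0, 100]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle into ``config.out_dir``.

    Returns a mapping of output names to written paths. On failure all
    partial outputs of this run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "setup"

    def _write_csv(name: str, frame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path

    try:
        t0 = time.perf_counter()
        stage = "load"
        if config.samples_path is not None and config.population_path is not None:
            model = CadmiumRiskModel.from_csv(
                config.samples_path, config.population_path,
                config.constants_path, mode=config.mode,
            )
            input_hashes = {
                "samples": _sha256(Path(config.samples_path)),
                "population": _sha256(Path(config.population_path)),
            }
        else:
            model = CadmiumRiskModel.from_study_fixture(seed=config.seed, mode=config.mode)
            input_hashes = {"fixture_seed": config.seed}
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "deterministic"
        fit = model.fit()
        _write_csv("compliance", fit.compliance)
        _write_csv("risk_long", fit.table)
        _write_csv("group_summary", fit.summary_table())
        _write_csv("pct_ptwi_range", fit.pct_ptwi_range())
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "monte_carlo"
        mc = model.simulate(
            iterations=config.iterations, seed=config.seed,
            mode=config.mcs_mode, spread=config.spread,
            percentiles=config.percentiles,
        )
        _write_csv("mcs_percentiles", mc.percentile_table())
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "sensitivity"
        _write_csv("sensitivity", mc.sensitivity_table())
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        manifest = {
            "package": "chocrisk",
            "version": __version__,
            "seed": config.seed,
            "iterations": config.iterations,
            "mode": config.mode,
            "mcs_mode": config.mcs_mode,
            "percentiles": list(map(float, config.percentiles)),
            "spread": {
                "ingr_rel": list(config.spread.ingr_rel),
                "ef_days": list(config.spread.ef_days),
                "bw_cv": config.spread.bw_cv,
            },
            "inputs": input_hashes,
            "constants": _constants_dict(model.constants),
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return written


def _constants_dict(consts: ToxicologyConstants) -> dict:
    return {
        "ptwi": consts.ptwi, "rfd": consts.rfd, "csf": consts.csf,
        "cf": consts.cf, "ef": consts.ef, "at_c": consts.at_c,
        "mrl_schedule": [
            {"category": b.category, "cacao_low": b.cacao_low,
             "cacao_high": b.cacao_high, "mrl": b.mrl}
            for b in consts.mrl_schedule
        ],
    }
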