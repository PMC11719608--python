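"""Contribution-to-variance sensitivity analysis of Monte Carlo outputs.

The convention implemented is the one spreadsheet risk simulators made
standard for tornado charts: for each stochastic input compute the Spearman
rank correlation with the output, square it, normalize the squared values
across inputs so they sum to 100%, then reattach the correlation's sign.
Point-valued (constant) inputs contribute exactly 0 and never affect the
other factors' shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .montecarlo import MCSResult

__all__ = ["SensitivityResult", "contribution_to_variance", "rank_factors", "sensitivity_of"]


@dataclass(frozen=True)
class SensitivityResult:
    """Signed percentage contribution of each input to the output's variance."""

    contributions: Mapping[str, float]  # factor -> signed percent
    degenerate: bool = False            # True when the output had zero variance

    def ranking(self) -> list[str]:
        return rank_factors(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"factor": f, "contribution_pct": c} for f, c in self.contributions.items()]
        ).sort_values("contribution_pct", key=lambda s: s.abs(), ascending=False,
                      ignore_index=True)


def contribution_to_variance(
    draws: pd.DataFrame,
    output: Sequence[float] | np.ndarray,
) -> SensitivityResult:
    """Signed, normalized squared rank correlations of each factor with the output.

    ``draws`` has one column per factor, aligned row-wise with ``output``.
    With zero output variance the result is flagged degenerate and every
    contribution is 0.
    """
    output = np.asarray(output, dtype=float)
    if len(draws) != output.size:
        raise DomainError("draws and output must have the same number of rows")
    if output.size < 2:
        raise DomainError("need at least 2 iterations for a sensitivity analysis")
    if np.min(output) == np.max(output):
        return SensitivityResult({f: 0.0 for f in draws.columns}, degenerate=True)

    rhos: dict[str, float] = {}
    for factor in draws.columns:
        x = draws[factor].to_numpy(dtype=float)
        if np.min(x) == np.max(x):
            rhos[factor] = 0.0  # constant input: zero before normalization
            continue
        rho = stats.spearmanr(x, output).statistic
        rhos[factor] = float(rho) if np.isfinite(rho) else 0.0
    total = sum(r * r for r in rhos.values())
    if total == 0.0:
        return SensitivityResult({f: 0.0 for f in draws.columns}, degenerate=True)
    contributions = {
        f: float(np.sign(r)) * 100.0 * r * r / total for f, r in rhos.items()
    }
    return SensitivityResult(contributions, degenerate=False)


def sensitivity_of(result: MCSResult) -> SensitivityResult:
    """Convenience wrapper: sensitivity of one MCS run over its own draw matrix."""
    return contribution_to_variance(result.draws, result.output)


def rank_factors(result: SensitivityResult) -> list[str]:
    """Factor names by descending absolute contribution; ties alphabetical."""
    return sorted(result.contributions, key=lambda f: (-abs(result.contributions[f]), f))
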