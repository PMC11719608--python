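"""Optional matplotlib charts: sensitivity tornado and percentile bars."""

from __future__ import annotations

import pandas as pd

from .sensitivity import SensitivityResult, rank_factors


def plot_sensitivity(result: SensitivityResult, ax=None, title: str | None = None):
    """Horizontal tornado-style bar chart of signed variance contributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    factors = rank_factors(result)[::-1]  # largest on top
    values = [result.contributions[f] for f in factors]
    ax.barh(factors, values, color=["tab:red" if v < 0 else "tab:blue" for v in values])
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("contribution to variance (%)")
    if title:
        ax.set_title(title)
    return ax


def plot_percentiles(table: pd.DataFrame, endpoint: str, p: float = 90.0, ax=None):
    """Bar chart of one percentile level of one endpoint across groups.

    ``table`` is the frame produced by ``MonteCarloResults.percentile_table()``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    sub = table[(table["endpoint"] == endpoint) & (table["p"] == p)]
    ax.bar(sub["group"], sub["value"], color="tab:blue")
    ax.set_ylabel(f"{endpoint} p{p:g}")
    ax.tick_params(axis="x", rotation=45)
    return ax
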