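"""Spearman rank-order sensitivity analysis of Monte Carlo outputs.

Each stochastic input factor is ranked by the magnitude of its Spearman
correlation with the simulated risk output.  The signed "contribution"
mirrors the contribution-to-variance bars of commercial risk packages and is
computed as ρ²/Σρ² carrying ρ's sign — an approximation, documented as such,
since the vendor algorithm is unpublished.  Factors entering the dose
denominator (body weight) correlate negatively; numerator factors
(concentration, intake rates) positively.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ValidationError

log = logging.getLogger(__name__)

__all__ = ["FactorSensitivity", "SensitivityResult", "analyze", "spearman_rho",
           "tornado_plot"]


def spearman_rho(x, y) -> float | None:
    """Spearman rank correlation: Pearson correlation of midrank vectors.

    Returns None (an absent value, not zero) when either input has zero
    variance, where the statistic is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValidationError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class FactorSensitivity:
    factor: str
    rho: float
    contribution: float  # signed normalised rho^2, in [-1, 1]
    rank: int            # 1-based, by |rho|


@dataclass
class SensitivityResult:
    """Ranked sensitivity entries for one simulated target."""

    target: str
    entries: list[FactorSensitivity]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(e) for e in self.entries])
        df.insert(0, "target", self.target)
        return df

    def top(self) -> FactorSensitivity:
        return self.entries[0]

    def rho_of(self, factor: str) -> float:
        for e in self.entries:
            if e.factor == factor:
                return e.rho
        raise KeyError(factor)


def analyze(draws: pd.DataFrame, output, target: str = "") -> SensitivityResult:
    """Rank input factors by Spearman correlation with one output vector.

    Constant (point-valued) draw columns are dropped with a warning: rank
    correlation is undefined for them.  Entries come back sorted by rank;
    ties in |ρ| break deterministically by factor name.
    """
    output = np.asarray(output, float)
    if len(draws) != len(output):
        raise ValidationError("draw matrix and output length differ")
    rhos: dict[str, float] = {}
    for col in draws.columns:
        rho = spearman_rho(draws[col].to_numpy(), output)
        if rho is None:
            log.warning("factor %s is constant; dropped from sensitivity "
                        "analysis of %s", col, target or "output")
            continue
        rhos[col] = rho
    if not rhos:
        return SensitivityResult(target, [])
    total = sum(r * r for r in rhos.values())
    order = sorted(rhos, key=lambda f: (-abs(rhos[f]), f))
    entries = [
        FactorSensitivity(
            factor=f,
            rho=rhos[f],
            contribution=(np.sign(rhos[f]) * rhos[f] ** 2 / total) if total > 0 else 0.0,
            rank=i + 1,
        )
        for i, f in enumerate(order)
    ]
    return SensitivityResult(target, entries)


def tornado_plot(result: SensitivityResult, path: str | Path) -> None:
    """Write a horizontal-bar (tornado) chart of signed contributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_frame().iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(df) + 1.5))
    colors = ["#c0392b" if c < 0 else "#2980b9" for c in df["contribution"]]
    ax.barh(df["factor"], df["contribution"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("signed contribution (ρ²/Σρ²)")
    ax.set_title(result.target)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
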