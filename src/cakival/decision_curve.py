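"""Decision curve analysis: net benefit across threshold probabilities.

At a threshold probability t, patients with predicted risk >= t are treated;
the net benefit is ``TP/n - (FP/n) * t/(1-t)`` — true positives credited in
full, false positives debited at the odds of the threshold.  Model curves are
compared against the treat-all reference ``pi - (1-pi) * t/(1-t)`` (pi = event
prevalence) and the treat-none reference 0; a curve below 0 signals net harm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["NetBenefitCurve", "net_benefit", "decision_curve", "default_threshold_grid"]


def default_threshold_grid(start: float = 0.005, stop: float = 0.50, step: float = 0.005) -> np.ndarray:
    """Default DCA grid: 0.005 to 0.50 in steps of 0.005."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def net_benefit(probabilities, outcomes, threshold: float) -> float:
    """Net benefit of treating patients with predicted risk >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("outcomes must be binary 0/1")
    n = len(y)
    treat = p >= threshold
    tp = float(np.sum(treat & (y == 1.0)))
    fp = float(np.sum(treat & (y == 0.0)))
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


@dataclass(frozen=True)
class NetBenefitCurve:
    """Net-benefit table for a set of strategies plus the references."""

    table: pd.DataFrame        # index: threshold; one column per strategy
    n: int
    prevalence: float

    @property
    def thresholds(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def net_harm_regions(self) -> dict[str, np.ndarray]:
        """Thresholds at which each model strategy falls below zero."""
        out: dict[str, np.ndarray] = {}
        for col in self.table.columns:
            if col in ("treat_all", "treat_none"):
                continue
            mask = self.table[col].to_numpy() < 0.0
            out[col] = self.thresholds[mask]
        return out


def decision_curve(
    strategies: Mapping[str, Sequence[float]],
    outcomes,
    thresholds: Sequence[float] | None = None,
) -> NetBenefitCurve:
    """Net benefit of each strategy over a threshold grid, plus treat-all and
    treat-none references.

    ``strategies`` maps a strategy name to its per-patient predicted
    probabilities (all on the same patient set as ``outcomes``).
    """
    y = np.asarray(outcomes, dtype=float)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("outcomes must be binary 0/1")
    grid = default_threshold_grid() if thresholds is None else np.asarray(
        thresholds, dtype=float
    )
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(y)
    pi = float(y.mean())
    cols: dict[str, np.ndarray] = {}
    for name, probs in strategies.items():
        p = np.asarray(probs, dtype=float)
        if p.shape != y.shape:
            raise ValueError(f"strategy {name!r} does not cover the patient set")
        cols[name] = np.asarray([net_benefit(p, y, t) for t in grid])
    cols["treat_all"] = pi - (1.0 - pi) * grid / (1.0 - grid)
    cols["treat_none"] = np.zeros_like(grid)
    table = pd.DataFrame(cols, index=pd.Index(grid, name="threshold"))
    return NetBenefitCurve(table=table, n=n, prevalence=pi)
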