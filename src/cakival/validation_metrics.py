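"""Discrimination, calibration and overall-fit metrics with bootstrap inference.

The external-validation report rests on four estimators:

* **AUROC** — probability that a random event patient outranks a random
  non-event patient, ties credited 0.5 (rank / Mann-Whitney form, so it is
  invariant to strictly increasing transforms of the predictions);
* **calibration-in-the-large (CITL)** — intercept of a logistic regression of
  the outcome on logit(p-hat) with the slope fixed at 1 (offset formulation);
  0 is ideal, negative means systematic overestimation;
* **calibration slope** — coefficient on logit(p-hat) in an unconstrained
  logistic refit; 1 is ideal, < 1 means overly extreme predictions;
* **Brier score** — mean squared difference between predicted probability and
  the binary outcome.

Uncertainty is quantified by resampling patients with replacement: point
estimates are bootstrap means and intervals are 2.5/97.5 percentile bounds,
by default over 1,000 replicates.  Replicates whose resampled outcome is
single-class are redrawn (and counted).  Calibration curves use ten
equal-count risk groups plus a lowess smoother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._glm import ConvergenceError, SeparationError, fit_logistic

__all__ = [
    "MetricEstimate",
    "AurocComparison",
    "CalibrationCurve",
    "SingleClassError",
    "auroc",
    "citl",
    "calibration_slope",
    "brier",
    "bootstrap_metrics",
    "compare_auroc",
    "calibration_curve",
    "PROB_CLIP_EPS",
]

# probabilities are clipped into [eps, 1-eps] before logit
PROB_CLIP_EPS = 1e-9

METRIC_NAMES = ("auroc", "citl", "slope", "brier")


class SingleClassError(ValueError):
    """Outcome vector contains a single class; rank/calibration metrics are
    undefined."""


@dataclass(frozen=True)
class MetricEstimate:
    """Bootstrap summary of one metric: ``point`` is the bootstrap mean,
    ``observed`` the full-sample value, CI bounds are percentile 2.5/97.5."""

    name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    observed: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "observed": self.observed,
        }


@dataclass(frozen=True)
class AurocComparison:
    """Paired-bootstrap comparison of two models' AUROCs on the same patients."""

    auroc_a: float
    auroc_b: float
    delta: float            # bootstrap mean of AUROC_A - AUROC_B
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "auroc_a": self.auroc_a,
            "auroc_b": self.auroc_b,
            "delta": self.delta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _as_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("outcomes must be binary 0/1")
    return y


def _clip_logit(probabilities) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must be finite and in [0, 1]")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn(
            f"probabilities at 0/1 clipped to eps={PROB_CLIP_EPS:g} before logit",
            RuntimeWarning,
            stacklevel=3,
        )
    return logit(np.clip(p, PROB_CLIP_EPS, 1.0 - PROB_CLIP_EPS))


def auroc(predictions, outcomes) -> float:
    """Area under the ROC curve via mid-ranks (ties counted 0.5).

    Accepts raw scores or mapped probabilities interchangeably: any strictly
    increasing transform of the predictions leaves the value unchanged.
    """
    x = np.asarray(predictions, dtype=float)
    y = _as_binary(outcomes)
    if not np.all(np.isfinite(x)):
        raise ValueError("predictions must be finite")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUROC undefined: need at least one event and one non-event")
    ranks = rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def citl(probabilities, outcomes) -> float:
    """Calibration-in-the-large: intercept of outcome ~ offset(logit p-hat)."""
    y = _as_binary(outcomes)
    lp = _clip_logit(probabilities)
    beta = fit_logistic(np.ones((len(y), 1)), y, offset=lp)
    return float(beta[0])


def calibration_slope(probabilities, outcomes) -> float:
    """Calibration slope: coefficient on logit(p-hat) in a logistic refit."""
    y = _as_binary(outcomes)
    lp = _clip_logit(probabilities)
    if np.ptp(lp) == 0.0:
        raise ValueError("predictions are constant; calibration slope undefined")
    X = np.column_stack([np.ones(len(y)), lp])
    beta = fit_logistic(X, y)
    return float(beta[1])


def brier(probabilities, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must be in [0, 1]")
    y = _as_binary(outcomes)
    return float(np.mean((p - y) ** 2))


def _metrics_once(p: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """One pass over the four metrics; calibration fits that are undefined on
    the sample (constant or separating predictions) are recorded as NaN."""
    out = {"auroc": auroc(p, y), "brier": brier(p, y)}
    try:
        out["citl"] = citl(p, y)
    except (SeparationError, ConvergenceError):
        out["citl"] = float("nan")
    try:
        out["slope"] = calibration_slope(p, y) if np.ptp(p) > 0 else float("nan")
    except (SeparationError, ConvergenceError):
        out["slope"] = float("nan")
    return out


def bootstrap_metrics(
    probabilities,
    outcomes,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 100_000,
) -> dict[str, MetricEstimate]:
    """Bootstrap the four validation metrics by resampling patients.

    Replicates with a single-class resampled outcome are redrawn; the number
    of redraws is reported via a warning when non-zero.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary(outcomes)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(
            "need at least 2 events and 2 non-events to bootstrap validation metrics"
        )
    rng = np.random.default_rng(seed)
    n = len(y)
    observed = _metrics_once(p, y)
    draws: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    redraws = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        rep = _metrics_once(p[idx], yb)
        for m in METRIC_NAMES:
            draws[m].append(rep[m])
        done += 1
    if redraws:
        warnings.warn(
            f"{redraws} single-class bootstrap replicates redrawn", RuntimeWarning
        )
    out: dict[str, MetricEstimate] = {}
    for m in METRIC_NAMES:
        arr = np.asarray(draws[m])
        ok = arr[~np.isnan(arr)]
        if len(ok) == 0:
            point = lo = hi = float("nan")
        else:
            point = float(ok.mean())
            lo = float(np.percentile(ok, 2.5))
            hi = float(np.percentile(ok, 97.5))
        out[m] = MetricEstimate(
            name=m, point=point, ci_low=lo, ci_high=hi,
            n_boot=n_boot, seed=seed, observed=observed[m],
        )
    return out


def compare_auroc(
    predictions_a,
    predictions_b,
    outcomes,
    n_boot: int = 1000,
    seed: int = 0,
) -> AurocComparison:
    """Paired patient-level bootstrap test for the difference of two AUROCs.

    The two-sided p-value is ``2 * min(P(delta <= 0), P(delta >= 0))`` over
    the replicates, floored at ``1/n_boot``; the CI is percentile-based.
    """
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    y = _as_binary(outcomes)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("both prediction vectors must cover the same patients")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    rng = np.random.default_rng(seed)
    n = len(y)
    deltas = np.empty(n_boot)
    done = 0
    redraws = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            redraws += 1
            if redraws > 100_000:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        deltas[done] = auroc(a[idx], yb) - auroc(b[idx], yb)
        done += 1
    frac_le = float(np.mean(deltas <= 0.0))
    frac_ge = float(np.mean(deltas >= 0.0))
    p = max(min(2.0 * min(frac_le, frac_ge), 1.0), 1.0 / n_boot)
    return AurocComparison(
        auroc_a=auroc(a, y),
        auroc_b=auroc(b, y),
        delta=float(deltas.mean()),
        ci_low=float(np.percentile(deltas, 2.5)),
        ci_high=float(np.percentile(deltas, 97.5)),
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Risk-group calibration table plus a lowess-smoothed curve."""

    bins: pd.DataFrame        # columns: mean_predicted, observed_rate, n, events
    smooth_grid: np.ndarray   # predicted-probability grid
    smooth_observed: np.ndarray


def calibration_curve(
    probabilities, outcomes, n_bins: int = 10, smooth_frac: float = 0.75
) -> CalibrationCurve:
    """Split patients into ``n_bins`` equal-count risk groups (ties kept
    together; groups merged with a warning when the predictions support fewer
    distinct quantiles) and smooth observed risk with lowess (span 0.75)."""
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary(outcomes)
    if len(p) < n_bins:
        raise ValueError("need at least n_bins patients")
    try:
        groups = pd.qcut(p, q=n_bins, duplicates="drop")
        codes = groups.codes
    except ValueError:  # all predictions identical
        codes = np.zeros(len(p), dtype=int)
    n_groups = int(codes.max()) + 1
    if n_groups < n_bins:
        warnings.warn(
            f"fewer distinct prediction quantiles than bins: merged into {n_groups}",
            RuntimeWarning,
        )
    frame = pd.DataFrame({"p": p, "y": y, "bin": codes})
    table = (
        frame.groupby("bin")
        .agg(mean_predicted=("p", "mean"), observed_rate=("y", "mean"),
             n=("y", "size"), events=("y", "sum"))
        .reset_index(drop=True)
    )
    table["events"] = table["events"].astype(int)
    grid = np.linspace(p.min(), p.max(), 101)
    if np.ptp(p) == 0.0:
        smooth = np.full_like(grid, y.mean())
    else:
        smooth = lowess(y, p, frac=smooth_frac, xvals=grid)
    return CalibrationCurve(bins=table, smooth_grid=grid, smooth_observed=smooth)
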