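"""Point scores and score-to-probability mappers for the two C-AKI models.

Two published integer/half-point scoring systems are implemented:

* the Motwani score (age, hypertension, cisplatin dose, albumin; 0-10 points),
  developed against mild C-AKI, with a closed-form probability mapping
  (incidence 0.04 at score 0, odds ratio 1.49 per point);
* the Gupta simple score (age, hypertension, diabetes, smoking, dose,
  hemoglobin, WBC, albumin, magnesium; 0-22.5 points), developed against
  severe C-AKI, with its published four-band risk stratification.  The Gupta
  development study maps scores to probabilities through a cubic-spline
  logistic model whose coefficients are not published, so the mapper slot is
  pluggable; the default refits a restricted-cubic-spline logistic model on a
  designated reference cohort.

Continuous predictors bin by the printed edges, read inclusively: a range such
as dose "101-150 mg" is the half-open interval (100, 150].  Albumin and
hemoglobin are in g/dL.  All point increments are multiples of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import expit

from ._glm import fit_logistic

__all__ = [
    "MOTWANI_MAX_POINTS",
    "GUPTA_MAX_POINTS",
    "MissingPredictorError",
    "RiskPrediction",
    "motwani_score",
    "gupta_score",
    "gupta_risk_group",
    "motwani_probability",
    "gupta_probability",
    "ProbabilityMapper",
    "ConstantMapper",
    "MotwaniMapper",
    "SplineScoreMapper",
    "mapper_from_dict",
    "MOTWANI_BASELINE_RISK",
    "MOTWANI_ODDS_RATIO_PER_POINT",
    "RISK_GROUP_CUTOFFS",
]

# published mapper constants for the Motwani model
MOTWANI_BASELINE_RISK = 0.04     # incidence at a score of 0
MOTWANI_ODDS_RATIO_PER_POINT = 1.49

MOTWANI_MAX_POINTS = 9.5   # age 2.5 + hypertension 2 + dose 3 + albumin 2
GUPTA_MAX_POINTS = 22.5

# Gupta simple-score risk bands: low 0-5.5, moderate 6-9.5, high 10-15.5,
# very high >= 16 points.
RISK_GROUP_CUTOFFS = {"low": 5.5, "moderate": 9.5, "high": 15.5}
RISK_GROUP_ORDER = ("low", "moderate", "high", "very_high")


class MissingPredictorError(ValueError):
    """A required predictor is absent (None/NaN); scoring expects the cohort
    to have been imputed first."""


@dataclass(frozen=True)
class RiskPrediction:
    """One model's output for one patient."""

    model: str                      # "motwani" | "gupta"
    points: float                   # non-negative multiple of 0.5
    probability: float | None = None
    risk_group: str | None = None   # Gupta only
    mapper_id: str | None = None


def _get(record, name: str) -> object:
    if isinstance(record, Mapping):
        return record.get(name)
    return getattr(record, name, None)


def _require(record, names: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    missing = []
    for name in names:
        value = _get(record, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            missing.append(name)
        else:
            out[name] = value
    if missing:
        raise MissingPredictorError(
            f"missing required predictor(s): {', '.join(missing)}"
        )
    return out


def motwani_score(record) -> float:
    """Motwani points: age (<=60: 0; 61-70: 1.5; >70: 2.5) + hypertension (2)
    + cisplatin dose mg (<=100: 0; 101-150: 1; >150: 3) + albumin g/dL
    (>3.5: 0; <=3.5: 2)."""
    v = _require(record, ["age", "hypertension", "cddp_dose", "albumin"])
    age, dose, alb = float(v["age"]), float(v["cddp_dose"]), float(v["albumin"])
    pts = 0.0
    if age > 70:
        pts += 2.5
    elif age > 60:
        pts += 1.5
    if v["hypertension"]:
        pts += 2.0
    if dose > 150:
        pts += 3.0
    elif dose > 100:
        pts += 1.0
    if alb <= 3.5:
        pts += 2.0
    return pts


def gupta_score(record, include_magnesium: bool = True) -> float:
    """Gupta simple-model points (see module docstring for the bin edges).

    ``include_magnesium=False`` gives the sensitivity variant that drops the
    magnesium item (0 or 1 point), used when serum magnesium is unmeasured.
    """
    fields = [
        "age", "hypertension", "diabetes", "smoker", "cddp_dose",
        "hemoglobin", "wbc", "albumin",
    ]
    if include_magnesium:
        fields.append("magnesium")
    v = _require(record, fields)
    age, dose = float(v["age"]), float(v["cddp_dose"])
    hb, wbc, alb = float(v["hemoglobin"]), float(v["wbc"]), float(v["albumin"])

    pts = 0.0
    if age > 70:
        pts += 4.5
    elif age > 60:
        pts += 3.5
    elif age > 45:
        pts += 2.5
    if v["hypertension"]:
        pts += 1.0
    if v["diabetes"]:
        pts += 1.0
    if v["smoker"]:
        pts += 1.0
    if dose > 200:
        pts += 9.5
    elif dose > 150:
        pts += 7.5
    elif dose > 125:
        pts += 5.0
    elif dose > 100:
        pts += 3.0
    elif dose > 75:
        pts += 2.5
    elif dose > 50:
        pts += 2.0
    if hb < 11.0:
        pts += 1.5
    elif hb < 12.0:
        pts += 1.0
    if wbc > 12.0:
        pts += 1.5
    if alb < 3.3:
        pts += 1.5
    elif alb <= 3.8:
        pts += 1.0
    if include_magnesium and float(v["magnesium"]) < 2.0:
        pts += 1.0
    return pts


def gupta_risk_group(points: float) -> str:
    """Map a Gupta score to its published risk band."""
    points = float(points)
    if points < 0 or round(points * 2) != points * 2:
        raise ValueError(
            f"points must be a non-negative multiple of 0.5, got {points}"
        )
    if points <= RISK_GROUP_CUTOFFS["low"]:
        return "low"
    if points <= RISK_GROUP_CUTOFFS["moderate"]:
        return "moderate"
    if points <= RISK_GROUP_CUTOFFS["high"]:
        return "high"
    return "very_high"


def motwani_probability(points) -> float | np.ndarray:
    """Predicted C-AKI probability under the published Motwani mapping:
    odds(s) = (0.04/0.96) * 1.49**s."""
    pts = np.asarray(points, dtype=float)
    if np.any(pts < 0):
        raise ValueError("points must be non-negative")
    odds = (MOTWANI_BASELINE_RISK / (1.0 - MOTWANI_BASELINE_RISK)) * (
        MOTWANI_ODDS_RATIO_PER_POINT ** pts
    )
    prob = odds / (1.0 + odds)
    return float(prob) if np.isscalar(points) else prob


# ---------------------------------------------------------------------------
# score -> probability mappers
# ---------------------------------------------------------------------------

@runtime_checkable
class ProbabilityMapper(Protocol):
    """A monotone-intent score-to-probability mapping with an identity and a
    JSON-serializable parameterization."""

    mapper_id: str

    def predict(self, points) -> np.ndarray: ...

    def to_dict(self) -> dict: ...


@dataclass(frozen=True)
class ConstantMapper:
    """Degenerate mapper returning a fixed probability (plug-in contract and
    treat-all/treat-none style references)."""

    probability: float
    mapper_id: str = "constant"

    def predict(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.full(pts.shape, self.probability, dtype=float)

    def to_dict(self) -> dict:
        return {"kind": "constant", "probability": self.probability}


@dataclass(frozen=True)
class MotwaniMapper:
    """The published Motwani closed-form mapping as a mapper object."""

    mapper_id: str = "motwani-published"

    def predict(self, points) -> np.ndarray:
        return np.asarray(motwani_probability(np.asarray(points, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "kind": "motwani",
            "baseline_risk": MOTWANI_BASELINE_RISK,
            "odds_ratio_per_point": MOTWANI_ODDS_RATIO_PER_POINT,
        }


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterization): linear term
    plus k-2 curvature terms, linear beyond the boundary knots."""
    k = len(knots)
    t = knots
    span2 = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        num = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(num / span2)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineScoreMapper:
    """Restricted-cubic-spline logistic mapping of score to event probability,
    fitted on a designated reference cohort.

    Default knots sit at the {5, 35, 65, 95}% quantiles of the reference
    scores.  When the score distribution is too discrete to support distinct
    knots the basis degrades gracefully to fewer curvature terms (down to a
    plain logistic-linear fit).
    """

    knots: tuple[float, ...]
    coef: tuple[float, ...]       # intercept first, then basis coefficients
    mapper_id: str = "gupta-rcs"
    fit_n: int = 0
    fit_events: int = 0

    KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)

    @classmethod
    def fit(
        cls,
        scores: Sequence[float],
        outcomes: Sequence[int],
        knot_quantiles: Sequence[float] = KNOT_QUANTILES,
        mapper_id: str = "gupta-rcs",
    ) -> "SplineScoreMapper":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(outcomes, dtype=float)
        if s.shape != y.shape:
            raise ValueError("scores and outcomes must have the same length")
        knots = np.unique(np.quantile(s, list(knot_quantiles)))
        if len(knots) >= 3:
            basis = _rcs_basis(s, knots)
        else:
            basis = s[:, None]
            knots = np.asarray([])
        X = np.column_stack([np.ones(len(s)), basis])
        beta = fit_logistic(X, y)
        return cls(
            knots=tuple(float(t) for t in knots),
            coef=tuple(float(b) for b in beta),
            mapper_id=mapper_id,
            fit_n=len(s),
            fit_events=int(y.sum()),
        )

    def predict(self, points) -> np.ndarray:
        pts = np.atleast_1d(np.asarray(points, dtype=float))
        if len(self.knots) >= 3:
            basis = _rcs_basis(pts, np.asarray(self.knots))
        else:
            basis = pts[:, None]
        X = np.column_stack([np.ones(len(pts)), basis])
        return expit(X @ np.asarray(self.coef))

    def to_dict(self) -> dict:
        return {
            "kind": "rcs",
            "mapper_id": self.mapper_id,
            "knots": list(self.knots),
            "coef": list(self.coef),
            "fit_n": self.fit_n,
            "fit_events": self.fit_events,
        }


def mapper_from_dict(d: Mapping) -> ProbabilityMapper:
    kind = d.get("kind")
    if kind == "constant":
        return ConstantMapper(float(d["probability"]))
    if kind == "motwani":
        return MotwaniMapper()
    if kind == "rcs":
        return SplineScoreMapper(
            knots=tuple(d["knots"]),
            coef=tuple(d["coef"]),
            mapper_id=d.get("mapper_id", "gupta-rcs"),
            fit_n=int(d.get("fit_n", 0)),
            fit_events=int(d.get("fit_events", 0)),
        )
    raise ValueError(f"unknown mapper kind {kind!r}")


def gupta_probability(points, mapper: ProbabilityMapper) -> float | np.ndarray:
    """Evaluate a fitted/loaded mapper at the given Gupta score(s)."""
    if mapper is None:
        raise ValueError("mapper must be fitted or loaded before use")
    prob = mapper.predict(points)
    return float(np.asarray(prob).ravel()[0]) if np.isscalar(points) else prob
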