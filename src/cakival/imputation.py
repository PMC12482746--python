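"""Deterministic regression-based single imputation of missing baseline labs.

For each lab with missing entries, an ordinary-least-squares sub-model is
fitted on the complete cases, regressing the lab on the always-complete
covariates (age, sex, cisplatin dose, baseline creatinine, and the
comorbidity/smoking flags).  Missing cells are replaced by the fitted
conditional mean (no stochastic residual draw), clipped to positive support;
observed cells are never touched, and outcome labels are excluded from the
predictor set to avoid leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import LAB_FIELDS, PatientRecord

__all__ = ["ImputationModel", "ImputationError", "fit_imputer", "impute",
           "IMPUTATION_PREDICTORS"]

IMPUTATION_PREDICTORS = (
    "age", "male", "cddp_dose", "baseline_creatinine",
    "hypertension", "diabetes", "smoker",
)

# fitted conditional means are clipped to this physiological floor (> 0)
POSITIVE_FLOOR = 0.01

MIN_COMPLETE_RECOMMENDED = 20


class ImputationError(ValueError):
    """Raised when a sub-model cannot be fitted; the message names the lab."""


def _design(records: Sequence[PatientRecord]) -> np.ndarray:
    cols = [np.ones(len(records))]
    for name in IMPUTATION_PREDICTORS:
        if name == "male":
            cols.append(np.asarray([1.0 if r.sex == "male" else 0.0 for r in records]))
        else:
            cols.append(np.asarray([float(getattr(r, name)) for r in records]))
    return np.column_stack(cols)


@dataclass(frozen=True)
class SubModel:
    """One lab's linear predictor: intercept + coefficients over the fixed
    predictor list, with fit diagnostics."""

    target: str
    intercept: float
    coef: tuple[float, ...]
    n_used: int
    residual_sd: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        beta = np.concatenate([[self.intercept], self.coef])
        return X @ beta


@dataclass(frozen=True)
class ImputationModel:
    """Per-lab OLS sub-models (one per incomplete lab)."""

    predictors: tuple[str, ...]
    submodels: Mapping[str, SubModel] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "submodels": {
                t: {
                    "intercept": m.intercept,
                    "coef": list(m.coef),
                    "n_used": m.n_used,
                    "residual_sd": m.residual_sd,
                }
                for t, m in self.submodels.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImputationModel":
        subs = {
            t: SubModel(
                target=t,
                intercept=float(s["intercept"]),
                coef=tuple(s["coef"]),
                n_used=int(s["n_used"]),
                residual_sd=float(s["residual_sd"]),
            )
            for t, s in d["submodels"].items()
        }
        return cls(predictors=tuple(d["predictors"]), submodels=subs)


def fit_imputer(records: Sequence[PatientRecord]) -> ImputationModel:
    """Fit one OLS sub-model per lab that has at least one missing value.

    Complete cases for the target lab are used.  Fitting fails (naming the
    lab) when complete cases number fewer than predictors + 2; a warning is
    issued below 20.
    """
    n_par = len(IMPUTATION_PREDICTORS) + 1
    submodels: dict[str, SubModel] = {}
    for lab in LAB_FIELDS:
        values = np.asarray(
            [np.nan if getattr(r, lab) is None else float(getattr(r, lab))
             for r in records]
        )
        if not np.any(np.isnan(values)):
            continue
        obs = ~np.isnan(values)
        n_obs = int(obs.sum())
        if n_obs < n_par + 2:
            raise ImputationError(
                f"cannot fit imputation sub-model for {lab!r}: "
                f"{n_obs} complete cases < {n_par + 2} required"
            )
        if n_obs < MIN_COMPLETE_RECOMMENDED:
            warnings.warn(
                f"only {n_obs} complete cases for {lab!r}; imputation may be unstable"
            )
        X = _design([r for r, keep in zip(records, obs) if keep])
        yv = values[obs]
        beta, _res, _rank, _sv = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = max(n_obs - n_par, 1)
        submodels[lab] = SubModel(
            target=lab,
            intercept=float(beta[0]),
            coef=tuple(float(b) for b in beta[1:]),
            n_used=n_obs,
            residual_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
        )
    return ImputationModel(predictors=IMPUTATION_PREDICTORS, submodels=submodels)


def impute(
    records: Sequence[PatientRecord], model: ImputationModel
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Fill missing labs with fitted conditional means.

    Returns the imputed records and a per-cell provenance table (True where a
    value was imputed).  Observed cells are untouched; fills are clipped to
    positive support.  Idempotent: imputing an already-complete cohort is the
    identity.
    """
    X = _design(records)
    preds: dict[str, np.ndarray] = {
        lab: sub.predict(X) for lab, sub in model.submodels.items()
    }
    out: list[PatientRecord] = []
    flag_rows = []
    for i, rec in enumerate(records):
        fills = {}
        flags = {}
        for lab in LAB_FIELDS:
            missing = getattr(rec, lab) is None
            flags[lab] = missing
            if missing:
                if lab not in preds:
                    raise ImputationError(
                        f"record {rec.patient_id}: no fitted sub-model for {lab!r}"
                    )
                fills[lab] = float(max(preds[lab][i], POSITIVE_FLOOR))
        out.append(replace(rec, **fills) if fills else rec)
        flag_rows.append({"patient_id": rec.patient_id, **flags})
    flags_df = pd.DataFrame(flag_rows)
    return out, flags_df
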