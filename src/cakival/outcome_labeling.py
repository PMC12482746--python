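"""KDIGO-anchored outcome labelling for cisplatin-associated AKI (C-AKI).

C-AKI is defined from the serum-creatinine trajectory within 14 days of
cisplatin exposure: an absolute rise >= 0.3 mg/dL from baseline OR a >= 1.5-fold
rise.  Severe C-AKI (KDIGO stage >= 2 analog) is a >= 2.0-fold rise OR the
initiation of renal replacement therapy (RRT), whichever occurs.  All threshold
comparisons are inclusive, and only trajectory points with day <= window are
used (day 0 is the pre-dose baseline; post-exposure days are counted from 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

__all__ = [
    "OutcomeLabels",
    "OutcomeUnassessableError",
    "label_outcomes",
    "CAKI_ABS_RISE_MGDL",
    "CAKI_FOLD_RISE",
    "SEVERE_FOLD_RISE",
    "DEFAULT_WINDOW_DAYS",
]

CAKI_ABS_RISE_MGDL = 0.3
CAKI_FOLD_RISE = 1.5
SEVERE_FOLD_RISE = 2.0
DEFAULT_WINDOW_DAYS = 14


class OutcomeUnassessableError(ValueError):
    """No post-exposure creatinine inside the window and no RRT: the outcome
    cannot be assigned (mirrors exclusion of patients with missing outcome
    data)."""


@dataclass(frozen=True)
class OutcomeLabels:
    """Derived outcome labels for one patient.

    ``stage`` is ``"none"``, ``"stage1"`` (C-AKI but not severe) or
    ``"stage2plus"`` (severe).  ``max_post_creatinine`` and ``fold_change``
    are ``None`` when the labels rest on RRT alone.
    """

    caki: bool
    severe_caki: bool
    stage: str
    max_post_creatinine: float | None
    fold_change: float | None

    def __post_init__(self) -> None:
        if self.severe_caki and not self.caki:
            raise ValueError("severe C-AKI implies C-AKI")
        expected = (
            "stage2plus" if self.severe_caki else ("stage1" if self.caki else "none")
        )
        if self.stage != expected:
            raise ValueError(f"stage {self.stage!r} inconsistent with flags")


def _window_values(
    series: Iterable[Tuple[int, float]], window_days: int
) -> list[float]:
    vals = []
    last_day = 0
    for day, value in series:
        if day <= last_day:
            raise ValueError("trajectory day offsets must be strictly increasing")
        if day < 1:
            raise ValueError("post-exposure day offsets start at 1")
        last_day = day
        if day <= window_days:
            vals.append(float(value))
    return vals


def label_outcomes(record, window_days: int = DEFAULT_WINDOW_DAYS) -> OutcomeLabels:
    """Label C-AKI / severe C-AKI from a patient's creatinine trajectory.

    Parameters
    ----------
    record:
        Any object with ``baseline_creatinine`` (mg/dL, > 0),
        ``creatinine_series`` (ordered ``(day, value)`` pairs) and
        ``rrt_within_window`` attributes.
    window_days:
        Post-exposure assessment window (days); trajectory points beyond it
        never affect the labels.

    Raises
    ------
    OutcomeUnassessableError
        If there is no creatinine value inside the window and no RRT.
    """
    baseline = float(record.baseline_creatinine)
    if not baseline > 0.0:
        raise ValueError("baseline creatinine must be positive")
    rrt = bool(record.rrt_within_window)
    post = _window_values(record.creatinine_series or (), window_days)

    if not post:
        if rrt:
            return OutcomeLabels(True, True, "stage2plus", None, None)
        raise OutcomeUnassessableError(
            "no post-exposure creatinine within the window and no RRT"
        )

    peak = max(post)
    fold = peak / baseline
    caki = (peak - baseline >= CAKI_ABS_RISE_MGDL) or (fold >= CAKI_FOLD_RISE)
    severe = (fold >= SEVERE_FOLD_RISE) or rrt
    caki = caki or severe
    stage = "stage2plus" if severe else ("stage1" if caki else "none")
    return OutcomeLabels(caki, severe, stage, peak, fold)
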