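"""Semiquantitative vertebral deformity grading and the Spine Deformity Index.

Each vertebra from T4 to L4 receives a grade 0-3 from the fractional loss of
its anterior, middle or posterior height relative to the expected (reference)
posterior height: grade 1 (mild) for a 20-25% reduction, grade 2 (moderate)
for 25-40%, grade 3 (severe) for >= 40%.  The Spine Deformity Index (SDI) is
the sum of the 13 per-level grades; a one-unit increase of the SDI between
two visits defines an incident vertebral (re)fracture, which serves as the
event in the survival analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

SDI_LEVELS = (
    "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4",
)

#: Height-reduction thresholds (t1, t2, t3) for grades 1, 2, 3.
DEFAULT_GRADE_THRESHOLDS = (0.20, 0.25, 0.40)


@dataclass(frozen=True)
class VertebralHeights:
    """Morphometric heights of one vertebra (all in mm)."""

    level: str
    anterior_mm: float
    middle_mm: float
    posterior_mm: float
    reference_mm: float

    def __post_init__(self) -> None:
        for name in ("anterior_mm", "middle_mm", "posterior_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reference_mm <= 0:
            raise ValueError("reference_mm (expected posterior height) must be positive")

    @property
    def reduction(self) -> float:
        """Fractional height reduction, floored at zero."""
        return max(0.0, 1.0 - min(self.anterior_mm, self.middle_mm, self.posterior_mm)
                   / self.reference_mm)


@dataclass(frozen=True)
class SDIRecord:
    """Per-level deformity grades at one visit and their sum."""

    date_days: float
    grades: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level, g in self.grades.items():
            if g not in (0, 1, 2, 3):
                raise ValueError(f"grade for {level} must be an integer 0-3, got {g!r}")

    @property
    def sdi(self) -> int:
        return int(sum(self.grades.values()))


def genant_grade(heights: VertebralHeights,
                 thresholds: tuple[float, float, float] = DEFAULT_GRADE_THRESHOLDS) -> int:
    """Grade one vertebra 0-3 from its fractional height reduction."""
    t1, t2, t3 = thresholds
    if not 0 < t1 < t2 < t3:
        raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3")
    # tiny tolerance so ratios like 1 - 24/30 land on their threshold
    r = heights.reduction + 1e-9
    if r < t1:
        return 0
    if r < t2:
        return 1
    if r < t3:
        return 2
    return 3


def compute_sdi(grades: dict, date_days: float = 0.0) -> SDIRecord:
    """Sum per-level grades over T4-L4 into an :class:`SDIRecord`.

    Levels absent from ``grades`` contribute zero (with a warning), matching
    the clinical convention of reading only evaluable vertebrae.
    """
    unknown = set(grades) - set(SDI_LEVELS)
    if unknown:
        raise ValueError(f"unknown vertebral levels: {sorted(unknown)}")
    missing = [lv for lv in SDI_LEVELS if lv not in grades]
    if missing:
        warnings.warn(
            f"{len(missing)} vertebral level(s) missing from grading "
            f"({', '.join(missing)}); they contribute 0 to the SDI",
            stacklevel=2,
        )
    full = {lv: int(grades.get(lv, 0)) for lv in SDI_LEVELS}
    return SDIRecord(date_days=date_days, grades=full)


def refracture_event(baseline: SDIRecord, followups: list[SDIRecord]) -> tuple[bool, float]:
    """Derive the refracture event from serial SDI records.

    The event occurs at the first follow-up visit whose SDI exceeds the
    baseline SDI by at least one unit; otherwise the subject is right-censored
    at the last visit.  Returns ``(event, time_days)`` with time measured from
    the baseline visit date.
    """
    if not followups:
        raise ValueError("at least one follow-up record is required")
    dates = [baseline.date_days] + [r.date_days for r in followups]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("follow-up records must be strictly ordered after baseline")
    for rec in followups:
        if rec.sdi >= baseline.sdi + 1:
            return True, rec.date_days - baseline.date_days
    return False, followups[-1].date_days - baseline.date_days
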