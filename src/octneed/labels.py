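"""Ground-truth treatment-need labels from visit trajectories.

Three binary endpoints are defined on each patient's two-year T&E course:

* ``first_interval_label`` — the first adequate interval after treatment
  initiation, judged from the extend/non-extend decisions at Visits 4-7:
  fewer than 3 extension decisions means a short interval (< 12 weeks),
  3 or 4 extensions a long one (>= 12 weeks).
* ``yearly_need_label`` — injection frequency per study year: high means
  >= 8 injections in Year 1 or >= 5 in Year 2.
* ``final_interval_label`` — the last assigned interval: short < 12 weeks,
  long >= 12 weeks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import Decision, PatientRecord

__all__ = [
    "Interval",
    "Need",
    "LabelSet",
    "first_interval_label",
    "yearly_need_label",
    "final_interval_label",
    "label_patient",
]

YEAR_WEEKS = 52
YEAR1_HIGH_INJECTIONS = 8
YEAR2_HIGH_INJECTIONS = 5
LONG_INTERVAL_WEEKS = 12
FIRST_INTERVAL_EXTENSIONS = 3  # extensions at Visits 4-7 needed for "long"


class Interval(str, enum.Enum):
    SHORT = "short"
    LONG = "long"


class Need(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


def _as_decision(d) -> Decision:
    if isinstance(d, Decision):
        return d
    try:
        return Decision(str(d))
    except ValueError as err:
        raise ValueError(f"unknown decision token: {d!r}") from err


def first_interval_label(decisions: Sequence) -> Interval:
    """Short/long first-interval group from the four Visit 4-7 decisions.

    Only extension decisions count; maintain and shorten are both
    non-extensions.  Fewer than 3 extensions -> short, else long.
    """
    if len(decisions) != 4:
        raise ValueError("exactly four decisions (Visits 4-7) are required")
    n_extend = sum(_as_decision(d) is Decision.EXTEND for d in decisions)
    return Interval.LONG if n_extend >= FIRST_INTERVAL_EXTENSIONS else Interval.SHORT


def yearly_need_label(injection_weeks: Sequence[int], year: int) -> Need:
    """High/low injection need in study year 1 or 2.

    Year 1 covers weeks [0, 52), year 2 weeks [52, 104); the high cutoffs
    are >= 8 and >= 5 injections respectively.
    """
    weeks = list(injection_weeks)
    if any(w < 0 for w in weeks):
        raise ValueError("injection weeks must be nonnegative")
    if sorted(weeks) != weeks:
        raise ValueError("injection weeks must be sorted")
    if year == 1:
        lo, hi, cut = 0, YEAR_WEEKS, YEAR1_HIGH_INJECTIONS
    elif year == 2:
        lo, hi, cut = YEAR_WEEKS, 2 * YEAR_WEEKS, YEAR2_HIGH_INJECTIONS
    else:
        raise ValueError("year must be 1 or 2")
    n = sum(lo <= w < hi for w in weeks)
    return Need.HIGH if n >= cut else Need.LOW


def final_interval_label(last_assigned_interval_weeks: int) -> Interval:
    """Short (< 12 weeks) vs long (>= 12 weeks) final assigned interval."""
    if last_assigned_interval_weeks is None:
        raise ValueError("final interval is missing")
    if last_assigned_interval_weeks <= 0:
        raise ValueError("interval must be positive")
    return Interval.LONG if last_assigned_interval_weeks >= LONG_INTERVAL_WEEKS else Interval.SHORT


@dataclass(frozen=True)
class LabelSet:
    first_interval: Optional[Interval]
    year1_need: Optional[Need]
    year2_need: Optional[Need]
    final_interval: Optional[Interval]


def label_patient(patient: PatientRecord) -> LabelSet:
    """All defined endpoint labels for one simulated/imported patient.

    Labels whose preconditions are not met (e.g. fewer than four decision
    visits, or a trajectory not covering the year window) are left None.
    """
    decisions = patient.decisions_from_visit4(4)
    first = first_interval_label(decisions) if len(decisions) == 4 else None

    weeks = patient.injection_weeks
    assigned_all = [v.assigned_interval_weeks for v in patient.visits if v.assigned_interval_weeks]
    # follow-up is complete through a window when the next scheduled visit
    # would fall beyond it
    next_due = (max(weeks) + assigned_all[-1]) if (weeks and assigned_all) else -1
    year1 = yearly_need_label(weeks, 1) if next_due > YEAR_WEEKS else None
    year2 = yearly_need_label(weeks, 2) if next_due > 2 * YEAR_WEEKS else None

    assigned = [v.assigned_interval_weeks for v in patient.visits if v.assigned_interval_weeks]
    final = final_interval_label(assigned[-1]) if assigned else None
    return LabelSet(first_interval=first, year1_need=year1, year2_need=year2, final_interval=final)
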