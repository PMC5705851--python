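"""Cycle-level clinical response classification, flare and relapse detection.

Response at ~6 months after a treatment-cycle start is classified into three
mutually exclusive categories:

* **major** -- every domain active (A/B) at baseline improved to grade C or
  better, no domain newly active, and no interim A/B flare;
* **partial** -- exactly one domain persists at grade B, every other
  baseline-active domain improved to C or better, nothing newly active, and
  no interim flare;
* **non-response** -- everything else.

An interim *flare* is any grade A or B at a visit between baseline and the
6-month assessment that is strictly worse than that domain's baseline grade
(so B after a baseline A is improvement, never a flare).  A new A/B at the
6-month visit in a domain that was quiescent (<=C) at baseline is treated as
a flare at the endpoint and forces non-response.

*Relapse* after a major/partial response is a new grade A anywhere, or a
grade B in a domain that was C or better at the 6-month visit.  The single
persistent-B domain of a partial responder does not count as a relapse while
it stays at B; it does if it worsens to A.

A note on conventions the three-way rule does not pin down: a baseline-A
domain found at grade B at 6 months has improved, but not to C.  It is
counted here as the (single allowed) persistent B, so such a patient is a
partial responder; the classification output flags it so a sensitivity
analysis can re-code these.  This keeps the categories an exact partition of
all grade configurations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .bilag import (
    DOMAINS,
    BilagDomain,
    DomainGrade,
    VisitAssessment,
    is_active_grade,
)

#: Assessment-window bounds (weeks from cycle start) for the 6-month visit.
SIX_MONTH_WEEK = 26
SIX_MONTH_WINDOW = (20, 32)


class ResponseCategory(enum.Enum):
    MAJOR = "major"
    PARTIAL = "partial"
    NON_RESPONSE = "non_response"

    @property
    def responded(self) -> bool:
        return self is not ResponseCategory.NON_RESPONSE


class RelapseTrigger(enum.Enum):
    NEW_A = "new_A"
    RECURRENT_B = "recurrent_B"


@dataclass(frozen=True)
class RelapseEvent:
    week: int
    trigger: RelapseTrigger
    domain: BilagDomain


@dataclass(frozen=True)
class CycleResponse:
    """Classification result with provenance for sensitivity analyses."""

    category: ResponseCategory
    persistent_b_domain: Optional[BilagDomain] = None
    #: True when the persistent B arose from a baseline A (improved but not
    #: to C); re-code these to non-response for a stricter reading.
    persistent_b_from_a: bool = False
    flare: Optional[tuple[int, BilagDomain]] = None


class UnevaluableCycleError(ValueError):
    """Raised when a cycle lacks an assessable 6-month visit."""


def _check_ordered(visits: Sequence[VisitAssessment]) -> None:
    weeks = [v.week for v in visits]
    if any(b < a for a, b in zip(weeks, weeks[1:])):
        raise ValueError(f"visits are not in chronological order: weeks {weeks}")


def detect_interim_flare(
    baseline: VisitAssessment,
    interim: Sequence[VisitAssessment],
) -> Optional[tuple[int, BilagDomain]]:
    """Earliest (week, domain) with an interim grade A/B worse than baseline.

    ``interim`` must be chronologically ordered and strictly between the
    baseline and 6-month visits.  Returns ``None`` when no flare occurred.
    """
    _check_ordered(interim)
    for visit in interim:
        for domain in DOMAINS:
            g = visit.grades[domain]
            if is_active_grade(g) and g.is_worse_than(baseline.grades[domain]):
                return (visit.week, domain)
    return None


def classify_cycle_response(
    baseline: VisitAssessment,
    six_month: VisitAssessment,
    interim: Sequence[VisitAssessment] = (),
) -> CycleResponse:
    """Classify a treatment cycle as major / partial / non-response.

    ``baseline`` and ``six_month`` must belong to the same patient; interim
    visits must be ordered.  The three categories partition every possible
    grade configuration.
    """
    if baseline.patient_id != six_month.patient_id:
        raise ValueError(
            f"baseline patient {baseline.patient_id!r} != "
            f"6-month patient {six_month.patient_id!r}"
        )
    flare = detect_interim_flare(baseline, interim)

    new_active: list[BilagDomain] = []   # A/B at 6 months, <=C at baseline
    residual_b: list[BilagDomain] = []   # B at 6 months, active at baseline
    residual_a = False
    for domain in DOMAINS:
        g6 = six_month.grades[domain]
        if not is_active_grade(g6):
            continue
        if not is_active_grade(baseline.grades[domain]):
            new_active.append(domain)
        elif g6 is DomainGrade.A:
            residual_a = True
        else:
            residual_b.append(domain)

    if flare is not None or new_active or residual_a or len(residual_b) > 1:
        return CycleResponse(ResponseCategory.NON_RESPONSE, flare=flare)
    if len(residual_b) == 1:
        domain = residual_b[0]
        return CycleResponse(
            ResponseCategory.PARTIAL,
            persistent_b_domain=domain,
            persistent_b_from_a=baseline.grades[domain] is DomainGrade.A,
        )
    return CycleResponse(ResponseCategory.MAJOR)


def find_six_month_visit(
    visits: Sequence[VisitAssessment],
    cycle_start_week: int,
    target: int = SIX_MONTH_WEEK,
    window: tuple[int, int] = SIX_MONTH_WINDOW,
) -> Optional[VisitAssessment]:
    """Visit closest to ``cycle_start_week + target`` within the window.

    Returns ``None`` (cycle unevaluable) when no visit falls inside
    ``cycle_start_week + [window[0], window[1]]``.  Ties break toward the
    earlier visit.
    """
    lo, hi = window
    candidates = [
        v for v in visits if lo <= v.week - cycle_start_week <= hi
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda v: (abs(v.week - cycle_start_week - target), v.week))


def detect_relapse(
    category: ResponseCategory,
    six_month: VisitAssessment,
    later_visits: Sequence[VisitAssessment],
) -> Optional[RelapseEvent]:
    """Earliest relapse after a major/partial response, if any.

    A relapse is a new grade A in any domain, or a grade B in a domain that
    was C or better at the 6-month visit.  Two qualifying domains at the same
    visit tie-break in the fixed domain reporting order; the event week is
    what matters analytically.
    """
    if category is ResponseCategory.NON_RESPONSE:
        raise ValueError("relapse is undefined after non-response")
    _check_ordered(later_visits)
    for visit in later_visits:
        if visit.week <= six_month.week:
            raise ValueError(
                f"later visit at week {visit.week} is not after the "
                f"6-month visit (week {six_month.week})"
            )
        for domain in DOMAINS:
            g = visit.grades[domain]
            if g is DomainGrade.A:
                return RelapseEvent(visit.week, RelapseTrigger.NEW_A, domain)
            if g is DomainGrade.B and not is_active_grade(six_month.grades[domain]):
                return RelapseEvent(visit.week, RelapseTrigger.RECURRENT_B, domain)
    return None


def response_duration(
    cycle_start_week: int,
    relapse: Optional[RelapseEvent],
    censor_week: int,
) -> tuple[int, bool]:
    """Duration of response in weeks and a censoring flag.

    Duration runs from cycle start to relapse (uncensored) or to
    ``censor_week`` (censored).  Because relapse can only follow the 6-month
    response assessment, the minimum uncensored duration is 26 weeks.
    """
    if censor_week < cycle_start_week + SIX_MONTH_WEEK:
        raise ValueError(
            "censor_week must be at least 26 weeks after cycle start"
        )
    if relapse is None:
        return (censor_week - cycle_start_week, True)
    duration = relapse.week - cycle_start_week
    if duration < SIX_MONTH_WEEK:
        raise ValueError(
            f"relapse at week {relapse.week} precedes the 6-month response "
            f"assessment of the cycle starting week {cycle_start_week}"
        )
    return (duration, False)
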