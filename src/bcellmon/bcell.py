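"""B-cell biomarker rules: depletion, plasmablast relapse prediction, 2NDNR.

Thresholds (all on the x10^9 cells/L scale, strict/inclusive exactly as used
clinically):

* complete B-cell depletion: total count < 0.0001; repopulation: >= 0.0001;
* earlier-relapse prediction: 6-month plasmablasts > 0.0008 (strict);
* anti-drug-antibody positivity: concentration > 140 AU/mL (strict).

Secondary non-depletion non-response (2NDNR) is the triad, in a repeat cycle
of a patient who previously achieved depletion and clinical response:
(1) a severe infusion reaction at the second infusion of the cycle,
(2) failure to deplete CD20+ (naive + memory) B-cells, and
(3) clinical non-response.  Plasmablasts are CD20-negative, so criterion (2)
is evaluated on the naive + memory compartment only, whereas the 6-week
depletion marker used to predict response uses the total count.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .bilag import BCellPanel, VisitAssessment
from .response import ResponseCategory

DEPLETION_THRESHOLD = 0.0001
PLASMABLAST_RELAPSE_THRESHOLD = 0.0008
ADA_POSITIVE_THRESHOLD_AU_ML = 140.0

#: Window (weeks from cycle start) in which a panel counts as the 6-week one.
SIX_WEEK_WINDOW = (4, 10)


class DepletionLevel(enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class DepletionStatus:
    value: DepletionLevel
    measured_week: int

    @property
    def complete(self) -> bool:
        return self.value is DepletionLevel.COMPLETE


class RelapseTiming(enum.Enum):
    EARLIER = "earlier"
    LATER = "later"


@dataclass(frozen=True)
class RelapsePrediction:
    value: RelapseTiming
    plasmablast_26wk: float


class Agent(enum.Enum):
    RITUXIMAB = "rituximab"
    OCRELIZUMAB = "ocrelizumab"
    OFATUMUMAB = "ofatumumab"


@dataclass(frozen=True)
class TreatmentCycle:
    """One anti-CD20 treatment cycle with its per-cycle outcomes."""

    cycle_number: int
    start_week: int
    agent: Agent = Agent.RITUXIMAB
    second_infusion_given: bool = True
    severe_infusion_reaction: bool = False
    panel_6wk: Optional[BCellPanel] = None
    response: Optional[ResponseCategory] = None
    concomitant_immunosuppressant: bool = False
    anti_drug_antibody_au_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cycle_number < 1:
            raise ValueError(f"cycle_number must be >= 1, got {self.cycle_number}")
        if self.anti_drug_antibody_au_ml is not None and not (
            self.anti_drug_antibody_au_ml >= 0
        ):
            raise ValueError("anti-drug antibody concentration must be >= 0")

    @property
    def depletion_at_6wk(self) -> Optional[DepletionStatus]:
        """Total-count depletion status at the 6-week panel, if measured."""
        if self.panel_6wk is None:
            return None
        return classify_depletion(self.panel_6wk, self.start_week + 6)

    @property
    def cd20_depleted_at_6wk(self) -> Optional[bool]:
        """CD20+ (naive+memory) depletion at 6 weeks; None if unmeasured."""
        if self.panel_6wk is None:
            return None
        return self.panel_6wk.cd20_positive < DEPLETION_THRESHOLD


def classify_depletion(panel: BCellPanel, week: int) -> DepletionStatus:
    """COMPLETE iff the total B-cell count is < 0.0001 x10^9/L.

    A count of exactly 0.0001 means repopulation (INCOMPLETE): depletion and
    repopulation are complementary at the boundary.
    """
    level = (
        DepletionLevel.COMPLETE
        if panel.total < DEPLETION_THRESHOLD
        else DepletionLevel.INCOMPLETE
    )
    return DepletionStatus(level, week)


def predict_relapse_timing(panel_26wk: BCellPanel) -> RelapsePrediction:
    """Predict earlier (<=12 months) vs later relapse from 6-month plasmablasts.

    EARLIER iff plasmablasts strictly exceed 0.0008 x10^9/L; a count equal to
    the threshold falls in the LATER group.
    """
    timing = (
        RelapseTiming.EARLIER
        if panel_26wk.plasmablast > PLASMABLAST_RELAPSE_THRESHOLD
        else RelapseTiming.LATER
    )
    return RelapsePrediction(timing, panel_26wk.plasmablast)


def anti_drug_antibody_positive(concentration_au_ml: float) -> bool:
    """Positive anti-rituximab antibody test: concentration > 140 AU/mL."""
    if not (concentration_au_ml >= 0):
        raise ValueError(
            f"antibody concentration must be >= 0, got {concentration_au_ml}"
        )
    return concentration_au_ml > ADA_POSITIVE_THRESHOLD_AU_ML


def detect_2ndnr(history: Sequence[TreatmentCycle]) -> list[int]:
    """Flag cycles meeting the 2NDNR triad over an ordered cycle history.

    A cycle k (k >= 2) is flagged iff the severe-infusion-reaction,
    CD20+ non-depletion and clinical non-response criteria all hold at
    cycle k AND some earlier cycle achieved CD20+ depletion together with a
    major or partial response.  Cycle 1 is never flagged: the syndrome is by
    definition *secondary*.

    Cycles without a 6-week panel or response category cannot satisfy
    (or establish eligibility for) the criteria and are passed over.
    """
    numbers = [c.cycle_number for c in history]
    if any(b <= a for a, b in zip(numbers, numbers[1:])):
        raise ValueError(
            f"cycle numbers must be strictly increasing, got {numbers}"
        )
    if not history:
        return []
    evaluable = [
        c for c in history if c.panel_6wk is not None and c.response is not None
    ]
    if not any(c.cycle_number < history[-1].cycle_number for c in evaluable):
        warnings.warn(
            "no prior evaluable cycle in history; 2NDNR cannot be established",
            stacklevel=2,
        )
        return []

    flagged: list[int] = []
    prior_depleted_responder = False
    for cycle in history:
        if cycle.panel_6wk is None or cycle.response is None:
            continue
        if (
            cycle.cycle_number >= 2
            and prior_depleted_responder
            and cycle.severe_infusion_reaction
            and not cycle.cd20_depleted_at_6wk
            and cycle.response is ResponseCategory.NON_RESPONSE
        ):
            flagged.append(cycle.cycle_number)
        if cycle.cd20_depleted_at_6wk and cycle.response.responded:
            prior_depleted_responder = True
    return flagged


@dataclass(frozen=True)
class DepletionFeatures:
    """Baseline covariates for the complete-depletion prediction model."""

    complement_low: bool
    #: plasmablast count x 1000 (counts are rescaled so regression odds
    #: ratios are per 0.001 x10^9/L, the scale clinical reports use)
    plasmablast_scaled: float
    dsdna_titre: float


COUNT_REGRESSION_SCALE = 1000.0


def depletion_predictor_features(
    baseline: VisitAssessment,
) -> Optional[DepletionFeatures]:
    """Assemble the depletion-model covariates from a baseline visit.

    Returns ``None`` when any required laboratory value is missing, so the
    caller can apply complete-case exclusion explicitly.
    """
    if (
        baseline.complement_low is None
        or baseline.bcells is None
        or baseline.dsdna_titre is None
    ):
        return None
    return DepletionFeatures(
        complement_low=baseline.complement_low,
        plasmablast_scaled=baseline.bcells.plasmablast * COUNT_REGRESSION_SCALE,
        dsdna_titre=baseline.dsdna_titre,
    )
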