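"""Patient-level containers tying visits, treatment cycles and safety events."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bcell import TreatmentCycle
from .bilag import VisitAssessment


@dataclass(frozen=True)
class SeriousInfection:
    """Infection causing >24 h hospitalisation or needing IV antibiotics."""

    patient_id: str
    week: int


@dataclass
class PatientRecord:
    """One patient: covariates plus ordered visits, cycles and events."""

    patient_id: str
    age: float
    female: bool
    ethnicity: str
    concomitant_immunosuppressant: bool
    concomitant_antimalarial: bool
    visits: list[VisitAssessment] = field(default_factory=list)
    cycles: list[TreatmentCycle] = field(default_factory=list)
    infections: list[SeriousInfection] = field(default_factory=list)

    def __post_init__(self) -> None:
        weeks = [v.week for v in self.visits]
        if any(b < a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visits out of order ({weeks})"
            )
        starts = [c.start_week for c in self.cycles]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError(
                f"patient {self.patient_id}: cycle starts out of order ({starts})"
            )
        numbers = [c.cycle_number for c in self.cycles]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"patient {self.patient_id}: cycle numbers not increasing "
                f"({numbers})"
            )

    @property
    def baseline(self) -> Optional[VisitAssessment]:
        return self.visits[0] if self.visits else None

    def visits_between(self, after_week: int, before_week: int) -> list[VisitAssessment]:
        """Visits with after_week < week < before_week, in order."""
        return [v for v in self.visits if after_week < v.week < before_week]

    def visits_after(self, week: int) -> list[VisitAssessment]:
        return [v for v in self.visits if v.week > week]


@dataclass
class CohortDataset:
    """A full cohort plus the parameters and seed that produced it (if any)."""

    patients: list[PatientRecord]
    params_used: Optional[object] = None  # CohortParams for simulated cohorts
    provenance: str = "external"

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)
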