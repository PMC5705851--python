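"""BILAG-2004 grades, organ domains, visit records and the global score.

The BILAG-2004 index grades lupus activity in nine organ domains from A
(severe, needing systemic therapy) through B (moderate), C (mild/stable),
D (previously active, now inactive) to E (never involved).  The numerical
"global BILAG" summary weights the grades A=12, B=8, C=1 and D/E=0 and sums
them over domains, giving a score in [0, 108].

Grades D and E are kept distinct in the data model (they differ in clinical
meaning) but are identical everywhere in scoring and response logic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class DomainGrade(enum.Enum):
    """Ordered BILAG-2004 activity grade for one organ domain."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    @property
    def weight(self) -> int:
        """Global-score weight: A=12, B=8, C=1, D/E=0."""
        return _GRADE_WEIGHT[self]

    @property
    def severity(self) -> int:
        """Ordinal severity for improvement/worsening logic; D and E tie."""
        return _GRADE_SEVERITY[self]

    def is_worse_than(self, other: "DomainGrade") -> bool:
        return self.severity > other.severity


_GRADE_WEIGHT = {
    DomainGrade.A: 12,
    DomainGrade.B: 8,
    DomainGrade.C: 1,
    DomainGrade.D: 0,
    DomainGrade.E: 0,
}

# A > B > C > D = E
_GRADE_SEVERITY = {
    DomainGrade.A: 4,
    DomainGrade.B: 3,
    DomainGrade.C: 2,
    DomainGrade.D: 1,
    DomainGrade.E: 1,
}


class BilagDomain(enum.Enum):
    """The nine BILAG-2004 organ domains, in conventional reporting order."""

    GENERAL = "General"
    MUCOCUTANEOUS = "Mucocutaneous"
    NEUROLOGICAL = "Neurological"
    MUSCULOSKELETAL = "Musculoskeletal"
    CARDIORESPIRATORY = "Cardiorespiratory"
    GASTROINTESTINAL = "Gastrointestinal"
    OPHTHALMIC = "Ophthalmic"
    RENAL = "Renal"
    HAEMATOLOGY = "Haematology"


DOMAINS: tuple[BilagDomain, ...] = tuple(BilagDomain)

MAX_GLOBAL_SCORE = 12 * len(DOMAINS)  # 108


@dataclass(frozen=True)
class BCellPanel:
    """B-cell subset counts from highly sensitive flow cytometry.

    All counts are in units of x10^9 cells/L, exactly the scale on which the
    clinical thresholds are defined (depletion 0.0001, plasmablast relapse
    rule 0.0008).  Plasmablasts are CD20-negative, so the CD20-positive
    compartment relevant to anti-CD20 depletion is naive + memory.
    """

    naive: float
    memory: float
    plasmablast: float

    def __post_init__(self) -> None:
        for name in ("naive", "memory", "plasmablast"):
            v = getattr(self, name)
            if not (v >= 0):  # also rejects NaN
                raise ValueError(f"B-cell count {name!r} must be >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.naive + self.memory + self.plasmablast

    @property
    def cd20_positive(self) -> float:
        """Naive + memory B-cells (the compartment rituximab targets)."""
        return self.naive + self.memory


@dataclass(frozen=True)
class VisitAssessment:
    """One patient-visit: BILAG grades plus optional laboratory results.

    ``week`` counts whole weeks since the first-ever rituximab infusion
    (cycle 1 day 1 = week 0).
    """

    patient_id: str
    week: int
    grades: Mapping[BilagDomain, DomainGrade]
    bcells: Optional[BCellPanel] = None
    dsdna_titre: Optional[float] = None
    complement_low: Optional[bool] = None
    prednisolone_mg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError(f"week must be >= 0, got {self.week}")
        missing = [d for d in DOMAINS if d not in self.grades]
        if missing:
            names = ", ".join(d.value for d in missing)
            raise ValueError(f"visit is missing BILAG grade(s) for: {names}")
        extra = [d for d in self.grades if d not in DOMAINS]
        if extra:
            raise ValueError(f"unknown BILAG domain(s): {extra}")
        if self.dsdna_titre is not None and not (self.dsdna_titre >= 0):
            raise ValueError(f"dsDNA titre must be >= 0, got {self.dsdna_titre}")
        if self.prednisolone_mg is not None and not (self.prednisolone_mg >= 0):
            raise ValueError(
                f"prednisolone dose must be >= 0, got {self.prednisolone_mg}"
            )
        object.__setattr__(self, "grades", dict(self.grades))

    def grade(self, domain: BilagDomain) -> DomainGrade:
        return self.grades[domain]


def global_bilag_score(visit: VisitAssessment) -> int:
    """Global BILAG score: sum over the nine domains of A=12, B=8, C=1, D/E=0.

    Range [0, 108]; 0 iff no domain is graded A, B or C.
    """
    return sum(visit.grades[d].weight for d in DOMAINS)


def is_active_grade(grade: DomainGrade) -> bool:
    """True iff the grade denotes active disease (A or B)."""
    return grade in (DomainGrade.A, DomainGrade.B)


def active_domains(visit: VisitAssessment) -> list[BilagDomain]:
    """Domains graded A or B at this visit, in fixed reporting order."""
    return [d for d in DOMAINS if is_active_grade(visit.grades[d])]


def validate_eligibility(baseline: VisitAssessment) -> bool:
    """Refractory-active-disease entry rule: >=1 grade A and/or >=2 grade B.

    Callers may accept ineligible baselines with a warning; a small minority
    of real-world patients are treated with a single B plus steroid burden.
    """
    n_a = sum(1 for d in DOMAINS if baseline.grades[d] is DomainGrade.A)
    n_b = sum(1 for d in DOMAINS if baseline.grades[d] is DomainGrade.B)
    return n_a >= 1 or n_b >= 2
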