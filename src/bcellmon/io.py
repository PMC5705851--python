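"""Readers and writers for the cohort CSV schema.

Four comma-delimited UTF-8 files with header rows:

* ``patients.csv`` -- patient_id, age, female, ethnicity, concomitant_is,
  antimalarial
* ``visits.csv`` -- patient_id, week, grade_<domain> x 9 (single characters
  A-E), naive, memory, plasmablast, dsdna, complement_low, pred_mg
* ``cycles.csv`` -- patient_id, cycle_number, agent, start_week,
  second_infusion, severe_infusion_reaction, naive_6wk, memory_6wk,
  plasmablast_6wk, response, concomitant_is, ada_au_ml
* ``events.csv`` -- patient_id, week, event_type

Counts are written as plain decimals (never scientific notation) so the
clinical thresholds stay visually auditable; missing numeric fields are
empty strings.  Writing is deterministic: the same dataset always produces
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .bcell import Agent, BCellPanel, TreatmentCycle
from .bilag import DOMAINS, BilagDomain, DomainGrade, VisitAssessment
from .cohort import CohortDataset, PatientRecord, SeriousInfection
from .response import ResponseCategory


class CohortValidationError(ValueError):
    """All schema/integrity failures of one read, with row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "cohort validation failed:\n  " + "\n  ".join(problems)
        )


_GRADE_COLUMNS = {d: f"grade_{d.value.lower()}" for d in DOMAINS}

PATIENT_COLUMNS = [
    "patient_id", "age", "female", "ethnicity", "concomitant_is", "antimalarial",
]
VISIT_COLUMNS = (
    ["patient_id", "week"]
    + [_GRADE_COLUMNS[d] for d in DOMAINS]
    + ["naive", "memory", "plasmablast", "dsdna", "complement_low", "pred_mg"]
)
CYCLE_COLUMNS = [
    "patient_id", "cycle_number", "agent", "start_week", "second_infusion",
    "severe_infusion_reaction", "naive_6wk", "memory_6wk", "plasmablast_6wk",
    "response", "concomitant_is", "ada_au_ml",
]
EVENT_COLUMNS = ["patient_id", "week", "event_type"]


def _fmt_count(x: Optional[float]) -> str:
    """Plain-decimal count with up to 7 decimals, no scientific notation."""
    if x is None:
        return ""
    s = f"{x:.7f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _fmt_bool(x: Optional[bool]) -> str:
    if x is None:
        return ""
    return "1" if x else "0"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "visits": directory / "visits.csv",
        "cycles": directory / "cycles.csv",
        "events": directory / "events.csv",
    }

    rows = []
    for p in dataset.patients:
        rows.append({
            "patient_id": p.patient_id,
            "age": _fmt_num(p.age),
            "female": _fmt_bool(p.female),
            "ethnicity": p.ethnicity,
            "concomitant_is": _fmt_bool(p.concomitant_immunosuppressant),
            "antimalarial": _fmt_bool(p.concomitant_antimalarial),
        })
    _write_csv(paths["patients"], PATIENT_COLUMNS, rows)

    rows = []
    for p in dataset.patients:
        for v in p.visits:
            row = {"patient_id": v.patient_id, "week": str(v.week)}
            for d in DOMAINS:
                row[_GRADE_COLUMNS[d]] = v.grades[d].value
            b = v.bcells
            row["naive"] = _fmt_count(b.naive if b else None)
            row["memory"] = _fmt_count(b.memory if b else None)
            row["plasmablast"] = _fmt_count(b.plasmablast if b else None)
            row["dsdna"] = _fmt_num(v.dsdna_titre)
            row["complement_low"] = _fmt_bool(v.complement_low)
            row["pred_mg"] = _fmt_num(v.prednisolone_mg)
            rows.append(row)
    _write_csv(paths["visits"], VISIT_COLUMNS, rows)

    rows = []
    for p in dataset.patients:
        for c in p.cycles:
            b = c.panel_6wk
            rows.append({
                "patient_id": p.patient_id,
                "cycle_number": str(c.cycle_number),
                "agent": c.agent.value,
                "start_week": str(c.start_week),
                "second_infusion": _fmt_bool(c.second_infusion_given),
                "severe_infusion_reaction": _fmt_bool(c.severe_infusion_reaction),
                "naive_6wk": _fmt_count(b.naive if b else None),
                "memory_6wk": _fmt_count(b.memory if b else None),
                "plasmablast_6wk": _fmt_count(b.plasmablast if b else None),
                "response": c.response.value if c.response else "",
                "concomitant_is": _fmt_bool(c.concomitant_immunosuppressant),
                "ada_au_ml": _fmt_num(c.anti_drug_antibody_au_ml),
            })
    _write_csv(paths["cycles"], CYCLE_COLUMNS, rows)

    rows = [
        {"patient_id": e.patient_id, "week": str(e.week),
         "event_type": "serious_infection"}
        for p in dataset.patients
        for e in p.infections
    ]
    _write_csv(paths["events"], EVENT_COLUMNS, rows)
    return paths


def _write_csv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(row.get(c, "") for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_table(path: Path, required: list[str], problems: list[str]) -> pd.DataFrame:
    if not path.exists():
        problems.append(f"{path}: file not found")
        return pd.DataFrame(columns=required)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        problems.append(f"{path.name}: missing column(s) {missing}")
        for c in missing:
            df[c] = ""
    return df


def _opt_float(s: str, where: str, problems: list[str]) -> Optional[float]:
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        problems.append(f"{where}: not a number: {s!r}")
        return None


def _opt_bool(s: str, where: str, problems: list[str]) -> Optional[bool]:
    if s == "":
        return None
    if s in ("0", "1"):
        return s == "1"
    problems.append(f"{where}: expected 0/1, got {s!r}")
    return None


def read_cohort(directory) -> CohortDataset:
    """Read and validate a cohort directory; raises
    :class:`CohortValidationError` listing every problem with row numbers."""
    directory = Path(directory)
    problems: list[str] = []
    patients_df = _read_table(directory / "patients.csv", PATIENT_COLUMNS, problems)
    visits_df = _read_table(directory / "visits.csv", VISIT_COLUMNS, problems)
    cycles_df = _read_table(directory / "cycles.csv", CYCLE_COLUMNS, problems)
    events_df = _read_table(directory / "events.csv", EVENT_COLUMNS, problems)
    if problems:
        raise CohortValidationError(problems)

    patients: dict[str, PatientRecord] = {}
    for i, row in patients_df.iterrows():
        where = f"patients.csv row {i + 2}"
        pid = row["patient_id"]
        if not pid:
            problems.append(f"{where}: empty patient_id")
            continue
        if pid in patients:
            problems.append(f"{where}: duplicate patient_id {pid!r}")
            continue
        try:
            patients[pid] = PatientRecord(
                patient_id=pid,
                age=_opt_float(row["age"], where, problems) or 0.0,
                female=bool(_opt_bool(row["female"], where, problems)),
                ethnicity=row["ethnicity"],
                concomitant_immunosuppressant=bool(
                    _opt_bool(row["concomitant_is"], where, problems)
                ),
                concomitant_antimalarial=bool(
                    _opt_bool(row["antimalarial"], where, problems)
                ),
            )
        except ValueError as exc:
            problems.append(f"{where}: {exc}")

    for i, row in visits_df.iterrows():
        where = f"visits.csv row {i + 2}"
        pid = row["patient_id"]
        if pid not in patients:
            problems.append(f"{where}: unknown patient_id {pid!r}")
            continue
        grades: dict[BilagDomain, DomainGrade] = {}
        ok = True
        for d in DOMAINS:
            raw = row[_GRADE_COLUMNS[d]]
            try:
                grades[d] = DomainGrade(raw)
            except ValueError:
                problems.append(
                    f"{where}: invalid grade {raw!r} for {d.value}"
                )
                ok = False
        counts = {
            k: _opt_float(row[k], where, problems)
            for k in ("naive", "memory", "plasmablast")
        }
        panel = None
        if any(v is not None for v in counts.values()):
            try:
                panel = BCellPanel(
                    naive=counts["naive"] or 0.0,
                    memory=counts["memory"] or 0.0,
                    plasmablast=counts["plasmablast"] or 0.0,
                )
            except ValueError as exc:
                problems.append(f"{where}: {exc}")
        if not ok:
            continue
        try:
            visit = VisitAssessment(
                patient_id=pid,
                week=int(float(row["week"])),
                grades=grades,
                bcells=panel,
                dsdna_titre=_opt_float(row["dsdna"], where, problems),
                complement_low=_opt_bool(row["complement_low"], where, problems),
                prednisolone_mg=_opt_float(row["pred_mg"], where, problems),
            )
        except ValueError as exc:
            problems.append(f"{where}: {exc}")
            continue
        patients[pid].visits.append(visit)

    for i, row in cycles_df.iterrows():
        where = f"cycles.csv row {i + 2}"
        pid = row["patient_id"]
        if pid not in patients:
            problems.append(f"{where}: unknown patient_id {pid!r}")
            continue
        counts = {
            k: _opt_float(row[k], where, problems)
            for k in ("naive_6wk", "memory_6wk", "plasmablast_6wk")
        }
        panel = None
        if any(v is not None for v in counts.values()):
            try:
                panel = BCellPanel(
                    naive=counts["naive_6wk"] or 0.0,
                    memory=counts["memory_6wk"] or 0.0,
                    plasmablast=counts["plasmablast_6wk"] or 0.0,
                )
            except ValueError as exc:
                problems.append(f"{where}: {exc}")
        response = None
        if row["response"]:
            try:
                response = ResponseCategory(row["response"])
            except ValueError:
                problems.append(
                    f"{where}: invalid response {row['response']!r}"
                )
        try:
            agent = Agent(row["agent"]) if row["agent"] else Agent.RITUXIMAB
        except ValueError:
            problems.append(f"{where}: invalid agent {row['agent']!r}")
            agent = Agent.RITUXIMAB
        try:
            cycle = TreatmentCycle(
                cycle_number=int(float(row["cycle_number"])),
                start_week=int(float(row["start_week"])),
                agent=agent,
                second_infusion_given=bool(
                    _opt_bool(row["second_infusion"], where, problems)
                ),
                severe_infusion_reaction=bool(
                    _opt_bool(row["severe_infusion_reaction"], where, problems)
                ),
                panel_6wk=panel,
                response=response,
                concomitant_immunosuppressant=bool(
                    _opt_bool(row["concomitant_is"], where, problems)
                ),
                anti_drug_antibody_au_ml=_opt_float(
                    row["ada_au_ml"], where, problems
                ),
            )
        except ValueError as exc:
            problems.append(f"{where}: {exc}")
            continue
        patients[pid].cycles.append(cycle)

    for i, row in events_df.iterrows():
        where = f"events.csv row {i + 2}"
        pid = row["patient_id"]
        if pid not in patients:
            problems.append(f"{where}: unknown patient_id {pid!r}")
            continue
        if row["event_type"] != "serious_infection":
            problems.append(
                f"{where}: unknown event_type {row['event_type']!r}"
            )
            continue
        patients[pid].infections.append(
            SeriousInfection(pid, int(float(row["week"])))
        )

    # chronological-order checks (collected, not raised one by one)
    for pid, p in patients.items():
        weeks = [v.week for v in p.visits]
        if any(b < a for a, b in zip(weeks, weeks[1:])):
            problems.append(f"visits.csv: patient {pid}: weeks not monotone {weeks}")
        numbers = [c.cycle_number for c in p.cycles]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            problems.append(
                f"cycles.csv: patient {pid}: cycle numbers not increasing {numbers}"
            )
    if problems:
        raise CohortValidationError(problems)
    return CohortDataset(patients=list(patients.values()), provenance="csv")
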