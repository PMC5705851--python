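"""Statistical toolkit and the end-to-end cohort analysis runner.

Contains the study-style primitives (two-sided Fisher exact test on 2x2
tables, Mann-Whitney U with an exact mid-rank permutation mode for small
samples, threshold sensitivity/specificity/AUC, logistic regression with
collinearity and separation guards) and ``run_paper_analysis``, which
aggregates a cohort into the standard result tables: response rates by
cycle, global-BILAG summaries, the depletion-by-response cross-table, the
plasmablast relapse-prediction metrics, the 2NDNR association table, and
serious-infection rates by depletion group.

Conventions: the two-sided Fisher p sums the probabilities of all
margin-preserving tables no more probable than the observed one; quartiles
use lower interpolation so summaries are reproducible bit-for-bit; B-cell
counts entering regressions are rescaled x1000 (odds ratios per
0.001 x10^9/L).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .bcell import (
    PLASMABLAST_RELAPSE_THRESHOLD,
    RelapseTiming,
    detect_2ndnr,
    predict_relapse_timing,
)
from .bilag import global_bilag_score
from .cohort import CohortDataset, PatientRecord
from .response import (
    ResponseCategory,
    classify_cycle_response,
    detect_relapse,
    find_six_month_visit,
)

EXACT_MW_MAX_N = 20


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist.

    Consider excluding the offending covariate or a penalized fit.
    """


class CollinearityError(ValueError):
    """Pairwise covariate correlation above the allowed threshold."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # (a*d)/(b*c); NaN when a margin product is zero
    p_two_sided: float


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test, two-sided by the sum-of-smaller-probabilities rule."""
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    if table.b * table.c == 0:
        odds = float("inf") if table.a * table.d > 0 else float("nan")
    else:
        odds = (table.a * table.d) / (table.b * table.c)
    return FisherResult(odds_ratio=odds, p_two_sided=float(p))


def _u_from_ranks(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p.

    Exact mid-rank permutation p (all label assignments enumerated) when the
    combined sample size is <= 20; otherwise the normal approximation with
    tie correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_obs = _u_from_ranks(ranks[:n], n, m)
    if n + m <= EXACT_MW_MAX_N:
        total = n * m
        u_lo = min(u_obs, total - u_obs)
        count = 0
        n_assign = 0
        for idx in itertools.combinations(range(n + m), n):
            u = _u_from_ranks(ranks[list(idx)], n, m)
            n_assign += 1
            if min(u, total - u) <= u_lo + 1e-9:
                count += 1
        return u_obs, count / n_assign
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


@dataclass(frozen=True)
class ThresholdMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fn: int
    tn: int
    fp: int
    auc: Optional[float] = None


def threshold_metrics(
    values: Sequence[float],
    labels: Sequence[bool],
    threshold: float,
    strict_greater: bool = True,
    compute_auc: bool = False,
) -> ThresholdMetrics:
    """Sensitivity/specificity of ``value > threshold`` (``>=`` when not
    strict) for a binary outcome; positive label = event (earlier relapse).

    With a single-class input the undefined metric is ``None``, never zero.
    AUC is the rank (Mann-Whitney) statistic over all thresholds.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    pred = values > threshold if strict_greater else values >= threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    auc = None
    if compute_auc and (tp + fn) > 0 and (tn + fp) > 0:
        ranks = sps.rankdata(values)
        n_pos = tp + fn
        n_neg = tn + fp
        u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
        auc = float(u / (n_pos * n_neg))
    return ThresholdMetrics(sens, spec, tp, fn, tn, fp, auc)


@dataclass(frozen=True)
class LogisticEstimate:
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def logistic_model(
    outcome: Sequence[int],
    covariates: pd.DataFrame,
    complete_case: bool = True,
    collinearity_threshold: float = 0.8,
    min_rows_per_covariate: int = 10,
) -> list[LogisticEstimate]:
    """Maximum-likelihood logistic fit with Wald 95% CIs per covariate.

    Pairwise covariate correlation above ``collinearity_threshold`` raises
    :class:`CollinearityError` naming the pairs; perfect separation raises
    :class:`SeparationError` (a penalized fallback is a caller decision).
    """
    y = pd.Series(np.asarray(outcome), name="outcome").reset_index(drop=True)
    X = covariates.reset_index(drop=True).astype(float)
    if complete_case:
        keep = X.notna().all(axis=1) & y.notna()
        X, y = X[keep], y[keep]
    if X.shape[0] < min_rows_per_covariate * X.shape[1]:
        warnings.warn(
            f"only {X.shape[0]} complete-case rows for {X.shape[1]} covariates",
            stacklevel=2,
        )
    const = X.columns[X.nunique() <= 1].tolist()
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if X.shape[1] > 1:
        corr = X.corr().abs()
        pairs = [
            (corr.index[i], corr.columns[j])
            for i in range(len(corr))
            for j in range(i + 1, len(corr))
            if corr.iloc[i, j] > collinearity_threshold
        ]
        if pairs:
            raise CollinearityError(
                f"covariate pairs exceed |r| > {collinearity_threshold}: {pairs}"
            )
    design = sm.add_constant(X, prepend=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y.astype(float), design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(str(exc)) from exc
        fitted = fit.predict(design)
    eps = 1e-8
    if np.all((fitted < eps) | (fitted > 1 - eps)) or np.any(
        np.abs(fit.params.to_numpy()) > 30
    ):
        raise SeparationError(
            "perfect separation detected; consider a penalized fit"
        )
    conf = fit.conf_int()
    out = []
    for name in X.columns:
        out.append(
            LogisticEstimate(
                covariate=name,
                odds_ratio=float(np.exp(fit.params[name])),
                ci_low=float(np.exp(conf.loc[name, 0])),
                ci_high=float(np.exp(conf.loc[name, 1])),
                p_value=float(fit.pvalues[name]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# aggregation helpers
# ---------------------------------------------------------------------------

def summarize_response(categories: Iterable[ResponseCategory]) -> dict:
    """Counts and the headline percentages for a set of cycle outcomes."""
    cats = list(categories)
    n = len(cats)
    counts = {c.value: sum(1 for x in cats if x is c) for c in ResponseCategory}
    responders = counts["major"] + counts["partial"]
    return {
        "n": n,
        "counts": counts,
        "responder_pct": 100.0 * responders / n if n else None,
        "major_pct": 100.0 * counts["major"] / n if n else None,
        "partial_pct": 100.0 * counts["partial"] / n if n else None,
    }


def median_iqr(values: Sequence[float]) -> dict:
    """Median and IQR with lower-interpolation quartiles (bit-reproducible)."""
    arr = np.asarray(sorted(values), dtype=float)
    if arr.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="lower")
    return {"n": int(arr.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Deterministic paper-analogue report over one cohort."""

    n_patients: int
    response_by_cycle: dict
    global_score: dict
    depletion_response: dict
    relapse_prediction: dict
    retreatment: dict
    two_ndnr: dict
    infections: dict
    exclusions: dict

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "response_by_cycle": self.response_by_cycle,
            "global_score": self.global_score,
            "depletion_response": self.depletion_response,
            "relapse_prediction": self.relapse_prediction,
            "retreatment": self.retreatment,
            "two_ndnr": self.two_ndnr,
            "infections": self.infections,
            "exclusions": self.exclusions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [
            "# Cohort analysis report",
            "",
            f"Patients: {self.n_patients}",
            "",
        ]
        for section, content in d.items():
            if section == "n_patients":
                continue
            lines.append(f"## {section.replace('_', ' ')}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(content, indent=2, sort_keys=True))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)


def _classify_patient_cycles(patient: PatientRecord) -> list[dict]:
    """Re-derive per-cycle response/relapse from the visit record."""
    results = []
    for cycle in patient.cycles:
        start = cycle.start_week
        baseline = next((v for v in patient.visits if v.week == start), None)
        if baseline is None:
            candidates = [v for v in patient.visits if v.week <= start]
            baseline = candidates[-1] if candidates else None
        six_month = find_six_month_visit(patient.visits, start)
        if baseline is None or six_month is None:
            results.append(
                {"cycle": cycle.cycle_number, "evaluable": False}
            )
            continue
        interim = patient.visits_between(baseline.week, six_month.week)
        cls = classify_cycle_response(baseline, six_month, interim)
        relapse = None
        if cls.category.responded:
            later = [v for v in patient.visits if v.week > six_month.week]
            next_start = next(
                (
                    c.start_week
                    for c in patient.cycles
                    if c.cycle_number == cycle.cycle_number + 1
                ),
                None,
            )
            if next_start is not None:
                later = [v for v in later if v.week <= next_start]
            relapse = detect_relapse(cls.category, six_month, later)
        results.append(
            {
                "cycle": cycle.cycle_number,
                "evaluable": True,
                "category": cls.category,
                "persistent_b_from_a": cls.persistent_b_from_a,
                "relapse_week": relapse.week if relapse else None,
                "relapse_trigger": relapse.trigger.value if relapse else None,
            }
        )
    return results


def run_paper_analysis(cohort: CohortDataset) -> AnalysisReport:
    """Run every paper-analogue analysis over a (real or synthetic) cohort."""
    per_patient = {p.patient_id: _classify_patient_cycles(p) for p in cohort}
    exclusions: dict[str, int] = {}

    # --- response by cycle ------------------------------------------------
    response_by_cycle: dict[str, dict] = {}
    max_cycle = max(
        (c.cycle_number for p in cohort for c in p.cycles), default=0
    )
    for k in range(1, max_cycle + 1):
        cats = [
            r["category"]
            for rows in per_patient.values()
            for r in rows
            if r["cycle"] == k and r.get("evaluable")
        ]
        unevaluable = sum(
            1
            for rows in per_patient.values()
            for r in rows
            if r["cycle"] == k and not r.get("evaluable")
        )
        summary = summarize_response(cats)
        summary["unevaluable"] = unevaluable
        response_by_cycle[f"cycle_{k}"] = summary
    exclusions["unevaluable_cycles"] = sum(
        s["unevaluable"] for s in response_by_cycle.values()
    )

    # --- global BILAG score pre/post cycle 1 -------------------------------
    pre, post = [], []
    for p in cohort:
        if not p.visits:
            continue
        baseline = p.visits[0]
        six = find_six_month_visit(p.visits, baseline.week)
        pre.append(global_bilag_score(baseline))
        if six is not None:
            post.append(global_bilag_score(six))
    global_score = {"baseline": median_iqr(pre), "six_months": median_iqr(post)}

    # --- depletion vs response (cycle 1) -----------------------------------
    dep_resp = {"complete": [0, 0], "incomplete": [0, 0]}  # [resp, non-resp]
    missing_panel = 0
    for p in cohort:
        rows = per_patient[p.patient_id]
        r1 = next((r for r in rows if r["cycle"] == 1 and r.get("evaluable")), None)
        c1 = next((c for c in p.cycles if c.cycle_number == 1), None)
        if r1 is None or c1 is None:
            continue
        status = c1.depletion_at_6wk
        if status is None:
            missing_panel += 1
            continue
        key = "complete" if status.complete else "incomplete"
        dep_resp[key][0 if r1["category"].responded else 1] += 1
    exclusions["missing_6wk_panel"] = missing_panel
    a, b = dep_resp["complete"]
    c, d = dep_resp["incomplete"]
    depletion_response = {
        "table": dep_resp,
        "response_rate_complete_pct": 100.0 * a / (a + b) if a + b else None,
        "response_rate_incomplete_pct": 100.0 * c / (c + d) if c + d else None,
    }
    if min(a + b, c + d) > 0:
        fr = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        depletion_response["fisher_p"] = fr.p_two_sided

    # --- plasmablast relapse prediction (cycle-1 responders) ----------------
    values, labels = [], []
    for p in cohort:
        rows = per_patient[p.patient_id]
        r1 = next((r for r in rows if r["cycle"] == 1 and r.get("evaluable")), None)
        if r1 is None or not r1["category"].responded or r1["relapse_week"] is None:
            continue
        six = find_six_month_visit(p.visits, p.cycles[0].start_week)
        if six is None or six.bcells is None:
            continue
        values.append(six.bcells.plasmablast)
        labels.append(r1["relapse_week"] <= p.cycles[0].start_week + 52)
    if values and any(labels) and not all(labels):
        tm = threshold_metrics(
            values, labels, PLASMABLAST_RELAPSE_THRESHOLD, compute_auc=True
        )
        relapse_prediction = {
            "n": len(values),
            "threshold": PLASMABLAST_RELAPSE_THRESHOLD,
            "sensitivity_pct": 100.0 * tm.sensitivity,
            "specificity_pct": 100.0 * tm.specificity,
            "auc": tm.auc,
            "tp": tm.tp,
            "fn": tm.fn,
            "tn": tm.tn,
            "fp": tm.fp,
        }
    else:
        relapse_prediction = {"n": len(values), "insufficient_data": True}

    # --- retreatment and 2NDNR ---------------------------------------------
    flagged_2ndnr: dict[str, list[int]] = {}
    retreated, c2_cats = 0, []
    for p in cohort:
        if len(p.cycles) >= 2:
            retreated += 1
            rows = per_patient[p.patient_id]
            r2 = next(
                (r for r in rows if r["cycle"] == 2 and r.get("evaluable")), None
            )
            if r2 is not None:
                c2_cats.append(r2["category"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = detect_2ndnr(p.cycles) if p.cycles else []
        if flags:
            flagged_2ndnr[p.patient_id] = flags
    n_2ndnr = sum(1 for f in flagged_2ndnr.values() if 2 in f)
    retreat_summary = summarize_response(c2_cats)
    retreatment = {
        "n_retreated": retreated,
        "cycle_2": retreat_summary,
        "n_2ndnr_cycle_2": n_2ndnr,
        "incidence_2ndnr_pct": 100.0 * n_2ndnr / retreated if retreated else None,
    }

    # --- 2NDNR association table (Table-3 analogue) --------------------------
    two_ndnr = _two_ndnr_table(cohort, flagged_2ndnr)

    # --- serious infections by depletion (cycles 1-2) -------------------------
    inf_counts = {"complete": [0, 0], "incomplete": [0, 0]}  # [event, none]
    for p in cohort:
        for cycle in p.cycles:
            if cycle.cycle_number > 2:
                continue
            status = cycle.depletion_at_6wk
            if status is None:
                continue
            key = "complete" if status.complete else "incomplete"
            end = cycle.start_week + 26
            had = any(
                cycle.start_week < e.week <= end for e in p.infections
            )
            inf_counts[key][0 if had else 1] += 1
    a, b = inf_counts["complete"]
    c, d = inf_counts["incomplete"]
    infections = {
        "table": inf_counts,
        "rate_complete_pct": 100.0 * a / (a + b) if a + b else None,
        "rate_incomplete_pct": 100.0 * c / (c + d) if c + d else None,
    }
    if min(a + b, c + d) > 0:
        infections["fisher_p"] = fisher_exact_2x2(
            ContingencyTable2x2(a, b, c, d)
        ).p_two_sided

    return AnalysisReport(
        n_patients=len(cohort.patients),
        response_by_cycle=response_by_cycle,
        global_score=global_score,
        depletion_response=depletion_response,
        relapse_prediction=relapse_prediction,
        retreatment=retreatment,
        two_ndnr=two_ndnr,
        infections=infections,
        exclusions=exclusions,
    )


def _two_ndnr_table(cohort: CohortDataset, flagged: dict[str, list[int]]) -> dict:
    """Immunosuppressant and pre-retreatment plasmablast associations."""
    is_2ndnr, is_resp = [0, 0], [0, 0]  # [on IS, not on IS]
    pb_2ndnr, pb_resp = [], []
    for p in cohort:
        if len(p.cycles) < 2:
            continue
        c2 = p.cycles[1]
        group_2ndnr = 2 in flagged.get(p.patient_id, [])
        responded_c2 = c2.response is not None and c2.response.responded
        if not group_2ndnr and not responded_c2:
            continue  # other non-responders are in neither comparison group
        bucket = is_2ndnr if group_2ndnr else is_resp
        bucket[0 if p.concomitant_immunosuppressant else 1] += 1
        panels = [
            v.bcells
            for v in p.visits
            if v.bcells is not None and v.week < c2.start_week
        ]
        if panels:
            (pb_2ndnr if group_2ndnr else pb_resp).append(panels[-1].plasmablast)
    out: dict = {
        "n_responders": sum(is_resp),
        "n_2ndnr": sum(is_2ndnr),
        "immunosuppressant_table": {
            "responders": is_resp,
            "two_ndnr": is_2ndnr,
        },
        "plasmablast_median_responders": median_iqr(pb_resp),
        "plasmablast_median_2ndnr": median_iqr(pb_2ndnr),
    }
    if min(sum(is_resp), sum(is_2ndnr)) > 0:
        out["immunosuppressant_fisher_p"] = fisher_exact_2x2(
            ContingencyTable2x2(is_resp[0], is_resp[1], is_2ndnr[0], is_2ndnr[1])
        ).p_two_sided
    if pb_resp and pb_2ndnr:
        _, p_mw = mann_whitney_u(pb_resp, pb_2ndnr)
        out["plasmablast_mann_whitney_p"] = p_mw
    return out
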