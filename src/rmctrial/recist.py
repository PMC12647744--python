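"""RECIST 1.1 response classification and hyperprogression calling.

Works on longitudinal lesion tables with one row per (patient, week,
lesion): columns ``patient_id, week, lesion_id, organ,
longest_diameter_mm, is_target, is_new``.  Week 0 rows are the baseline.

Timepoint categories follow RECIST 1.1: the tumor burden scalar is the
sum of longest diameters (SLD) of the baseline target lesions; PD is a
>=20% increase from nadir with a >=5 mm absolute increase, or any new
lesion; PR is a >=30% decrease from baseline; CR is disappearance of all
target lesions (with no new lesions); otherwise SD.  Non-target lesions
contribute only through the new-lesion flag.

Hyperprogression is early PD with a large absolute and relative burden
increase: progressive disease within the first 8 weeks after treatment
start, a >=10 mm absolute increase in target-lesion SLD versus baseline,
plus (i) a >=40% SLD increase versus baseline and/or (ii) a >=20% SLD
increase versus baseline with new lesions appearing in at least two
different organs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LESION_COLUMNS",
    "NotEvaluableError",
    "TimepointAssessment",
    "HyperprogressionCall",
    "BestOverallResponse",
    "sum_longest_diameters",
    "classify_timepoint",
    "assess_timeline",
    "classify_hyperprogression",
    "best_overall_response",
    "cohort_summary",
]

LESION_COLUMNS = [
    "patient_id",
    "week",
    "lesion_id",
    "organ",
    "longest_diameter_mm",
    "is_target",
    "is_new",
]

HYPERPROGRESSION_WINDOW_WEEKS = 8.0
HYPERPROGRESSION_MIN_INCREASE_MM = 10.0
PD_PCT_FROM_NADIR = 0.20
PD_MIN_INCREASE_MM = 5.0
PR_PCT_FROM_BASELINE = -0.30
CONFIRMATION_MIN_WEEKS = 4.0


class NotEvaluableError(ValueError):
    """Raised when a timeline has no evaluable baseline target lesions."""


@dataclass(frozen=True)
class TimepointAssessment:
    week: float
    sld: float
    pct_change_from_baseline: float
    pct_change_from_nadir: float
    new_lesion_organs: frozenset = frozenset()
    category: str = "NE"  # CR | PR | SD | PD | NE


@dataclass(frozen=True)
class HyperprogressionCall:
    patient_id: str
    evaluable: bool
    is_hyperprogression: bool
    window_pd: bool = False
    criterion_i: bool = False
    criterion_ii: bool = False
    absolute_increase_mm: float = float("nan")


@dataclass(frozen=True)
class BestOverallResponse:
    patient_id: str
    bor: str
    confirmed: bool
    max_pct_change: float  # waterfall value: largest-magnitude SLD change
    weeks_on_therapy: float


def sum_longest_diameters(measurements: pd.DataFrame) -> float:
    """Sum of longest diameters (mm) of target lesions at one timepoint."""
    targets = measurements[measurements["is_target"].astype(bool)]
    if targets.empty:
        raise NotEvaluableError("no target lesions at this timepoint")
    return float(targets["longest_diameter_mm"].sum())


def classify_timepoint(
    baseline_sld: float,
    nadir_sld: float,
    current_sld: float,
    new_lesions: bool = False,
    all_disappeared: bool = False,
) -> str:
    """RECIST 1.1 category for one timepoint given burden history."""
    if baseline_sld <= 0:
        raise NotEvaluableError("baseline SLD must be positive")
    increase = current_sld - nadir_sld
    pct_from_nadir = increase / nadir_sld if nadir_sld > 0 else np.inf
    if new_lesions or (
        pct_from_nadir >= PD_PCT_FROM_NADIR and increase >= PD_MIN_INCREASE_MM
    ):
        return "PD"
    if all_disappeared and current_sld == 0:
        return "CR"
    if (current_sld - baseline_sld) / baseline_sld <= PR_PCT_FROM_BASELINE:
        return "PR"
    return "SD"


def _patient_table(timeline: pd.DataFrame) -> pd.DataFrame:
    t = timeline.copy()
    t["is_target"] = t["is_target"].astype(bool)
    t["is_new"] = t["is_new"].astype(bool)
    return t.sort_values(["week", "lesion_id"])


def assess_timeline(timeline: pd.DataFrame) -> list[TimepointAssessment]:
    """Per-timepoint RECIST assessments for one patient's lesion table.

    A follow-up week missing any baseline target lesion is flagged NE
    and does not update the nadir.
    """
    t = _patient_table(timeline)
    weeks = sorted(t["week"].unique())
    if not weeks or weeks[0] != 0:
        raise NotEvaluableError("timeline must contain a week-0 baseline")
    base = t[t["week"] == 0]
    baseline_targets = set(base.loc[base["is_target"], "lesion_id"])
    if not baseline_targets:
        raise NotEvaluableError("no baseline target lesions")
    baseline_sld = sum_longest_diameters(base)

    out: list[TimepointAssessment] = []
    nadir = baseline_sld
    seen_new_organs: set[str] = set()
    for week in weeks:
        rows = t[t["week"] == week]
        measured_targets = set(
            rows.loc[rows["is_target"] & ~rows["is_new"], "lesion_id"]
        )
        new_rows = rows[rows["is_new"]]
        seen_new_organs |= set(new_rows["organ"])
        if week > 0 and not baseline_targets <= measured_targets:
            out.append(
                TimepointAssessment(week, np.nan, np.nan, np.nan,
                                    frozenset(seen_new_organs), "NE")
            )
            continue
        sld = float(
            rows.loc[rows["is_target"] & rows["lesion_id"].isin(baseline_targets),
                     "longest_diameter_mm"].sum()
        )
        all_gone = sld == 0 and not new_rows["is_target"].any()
        category = (
            "baseline"
            if week == 0
            else classify_timepoint(
                baseline_sld, nadir, sld,
                new_lesions=len(new_rows) > 0,
                all_disappeared=all_gone,
            )
        )
        out.append(
            TimepointAssessment(
                week=week,
                sld=sld,
                pct_change_from_baseline=(sld - baseline_sld) / baseline_sld,
                pct_change_from_nadir=(sld - nadir) / nadir if nadir > 0 else np.inf,
                new_lesion_organs=frozenset(seen_new_organs),
                category=category,
            )
        )
        nadir = min(nadir, sld)
    return out


def classify_hyperprogression(timeline: pd.DataFrame) -> HyperprogressionCall:
    """Apply the hyperprogression definition to one patient's timeline.

    Requires baseline plus at least one evaluable assessment within the
    closed 8-week window; otherwise the call is not evaluable.
    """
    patient_id = str(timeline["patient_id"].iloc[0])
    assessments = assess_timeline(timeline)
    baseline_sld = assessments[0].sld
    window = [
        a
        for a in assessments[1:]
        if a.week <= HYPERPROGRESSION_WINDOW_WEEKS and a.category != "NE"
    ]
    if not window:
        return HyperprogressionCall(patient_id, evaluable=False,
                                    is_hyperprogression=False)
    for a in window:
        if a.category != "PD":
            continue
        abs_increase = a.sld - baseline_sld
        pct = a.pct_change_from_baseline
        crit_i = pct >= 0.40
        crit_ii = pct >= 0.20 and len(a.new_lesion_organs) >= 2
        is_hp = abs_increase >= HYPERPROGRESSION_MIN_INCREASE_MM and (
            crit_i or crit_ii
        )
        if is_hp:
            return HyperprogressionCall(
                patient_id, True, True, True, crit_i, crit_ii, abs_increase
            )
    any_pd = any(a.category == "PD" for a in window)
    last_pd = next((a for a in reversed(window) if a.category == "PD"), None)
    abs_inc = (last_pd.sld - baseline_sld) if last_pd is not None else float("nan")
    return HyperprogressionCall(
        patient_id, True, False, any_pd,
        absolute_increase_mm=abs_inc,
    )


def best_overall_response(
    timeline: pd.DataFrame, require_confirmation: bool = True
) -> BestOverallResponse:
    """Best overall response for one patient per the RECIST hierarchy.

    Assessments after the first PD do not contribute.  With confirmation
    required, a CR/PR must be backed by a repeat qualifying assessment at
    least 4 weeks later; a response on a single measurement stays
    unconfirmed and does not count toward the objective response rate.
    """
    patient_id = str(timeline["patient_id"].iloc[0])
    assessments = assess_timeline(timeline)
    post = []
    for a in assessments[1:]:
        post.append(a)
        if a.category == "PD":
            break

    order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3, "NE": 4}
    evaluable = [a for a in post if a.category != "NE"]
    if not evaluable:
        bor, confirmed = "NE", False
    else:
        bor = min((a.category for a in evaluable), key=order.__getitem__)
        confirmed = True
        if bor in ("CR", "PR") and require_confirmation:
            hits = [a for a in evaluable if order[a.category] <= order[bor]]
            # bor keeps the response category either way; the confirmed
            # flag decides whether it counts toward ORR
            confirmed = any(
                later.week - first.week >= CONFIRMATION_MIN_WEEKS
                for i, first in enumerate(hits)
                for later in hits[i + 1:]
            )
    changes = [a.pct_change_from_baseline for a in post if not np.isnan(a.sld)]
    max_change = (
        100 * max(changes, key=abs) if changes else float("nan")
    )
    weeks_on = max(a.week for a in assessments)
    return BestOverallResponse(patient_id, bor, confirmed, max_change, weeks_on)


def cohort_summary(
    responses: list[BestOverallResponse],
    hyperprogression: list[HyperprogressionCall] | None = None,
    require_confirmation: bool = True,
) -> dict:
    """Cohort-level endpoints from per-patient best responses.

    ORR counts confirmed CR/PR (unconfirmed responses are excluded when
    confirmation is required); DCR counts best response of CR, PR or SD.
    """
    if not responses:
        raise ValueError("cohort must contain at least one patient")
    n = len(responses)
    responders = [
        r
        for r in responses
        if r.bor in ("CR", "PR") and (r.confirmed or not require_confirmation)
    ]
    controlled = [r for r in responses if r.bor in ("CR", "PR", "SD")]
    out = {
        "n": n,
        "orr": len(responders) / n,
        "dcr": len(controlled) / n,
        "waterfall": {r.patient_id: r.max_pct_change for r in responses},
        "swimmer": {r.patient_id: r.weeks_on_therapy for r in responses},
    }
    if hyperprogression is not None:
        out["hyperprogression_count"] = sum(
            c.is_hyperprogression for c in hyperprogression
        )
    return out
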