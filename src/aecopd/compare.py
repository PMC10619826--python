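"""Agreement between algorithms and concordance against ground truth.

Detected events are matched one-to-one to true events per patient by a
greedy earliest-first scan with a date tolerance; event-level sensitivity
(matched / true) and positive predictive value (matched / detected) follow.
Frequent-exacerbator classifications from two algorithms are cross-tabulated
with percent agreement and Cohen's kappa.  The A&E sensitivity analysis
measures how many patients have an emergency-department respiratory
attendance with no corresponding qualifying hospital admission.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .algorithms import detect_apc_events
from .analysis import frequent_flags
from .emr import EmrBundle

__all__ = [
    "ConcordanceResult",
    "AgreementResult",
    "match_events",
    "sensitivity_ppv",
    "classification_agreement",
    "cohens_kappa",
    "ae_without_admission",
]


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    algorithm_id: int
    tolerance_days: int
    event_sensitivity: float | None   # None when n_true == 0
    event_ppv: float | None           # None when n_detected == 0
    n_true: int
    n_detected: int
    n_matched: int


@dataclasses.dataclass(frozen=True)
class AgreementResult:
    algorithm_a: int
    algorithm_b: int
    both_positive: int
    a_only: int
    b_only: int
    both_negative: int
    percent_agreement: float
    cohens_kappa: float


def match_events(detected: pd.DataFrame, truth: pd.DataFrame,
                 tolerance_days: int = 0) -> pd.DataFrame:
    """Greedy one-to-one matching of detected to true events per patient.

    Detected events are scanned in date order; each matches the earliest
    still-unmatched true event within ``±tolerance_days``.  Deterministic
    given sorted inputs.  Returns the detected table with a ``matched``
    boolean column.
    """
    if tolerance_days < 0:
        raise ValueError("tolerance_days must be >= 0")
    det = detected[["patient_id", "event_date"]].sort_values(
        ["patient_id", "event_date"]).reset_index(drop=True)
    tru = truth[["patient_id", "event_date"]].sort_values(
        ["patient_id", "event_date"])
    true_by_pid: dict = {
        pid: list(grp["event_date"].to_numpy().astype("datetime64[D]").astype(np.int64))
        for pid, grp in tru.groupby("patient_id")
    }
    matched = np.zeros(len(det), dtype=bool)
    det_days = det["event_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    used: dict = {}
    for i, (pid, day) in enumerate(zip(det["patient_id"].to_numpy(), det_days)):
        pool = true_by_pid.get(pid)
        if not pool:
            continue
        taken = used.setdefault(pid, np.zeros(len(pool), dtype=bool))
        for j, t in enumerate(pool):
            if taken[j] or t < day - tolerance_days:
                continue
            if t > day + tolerance_days:
                break
            taken[j] = True
            matched[i] = True
            break
    det["matched"] = matched
    return det


def sensitivity_ppv(matching: pd.DataFrame, truth: pd.DataFrame,
                    algorithm_id: int = 0, tolerance_days: int = 0) -> ConcordanceResult:
    """Event-level sensitivity and PPV from a matching table.

    Undefined ratios (zero denominators) are reported as None, not 0.
    """
    n_true = len(truth)
    n_detected = len(matching)
    n_matched = int(matching["matched"].sum()) if n_detected else 0
    return ConcordanceResult(
        algorithm_id=algorithm_id,
        tolerance_days=tolerance_days,
        event_sensitivity=(n_matched / n_true) if n_true else None,
        event_ppv=(n_matched / n_detected) if n_detected else None,
        n_true=n_true,
        n_detected=n_detected,
        n_matched=n_matched,
    )


def concordance(detected: pd.DataFrame, truth: pd.DataFrame,
                algorithm_id: int = 0, tolerance_days: int = 0) -> ConcordanceResult:
    """Convenience: match then score."""
    matching = match_events(detected, truth, tolerance_days)
    return sensitivity_ppv(matching, truth, algorithm_id, tolerance_days)


def cohens_kappa(a: int, b: int, c: int, d: int) -> float:
    """Cohen's kappa from 2x2 cell counts (a=++, b=+-, c=-+, d=--).

    Chance agreement comes from the marginals; when expected agreement is 1
    (both classifications constant) kappa is 1 for identical classifications
    and NaN otherwise.
    """
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1 - p_e)


def classification_agreement(events_a: pd.DataFrame, events_b: pd.DataFrame,
                             cohort: pd.DataFrame,
                             window: str | tuple = "baseline",
                             algorithm_a: int = 0, algorithm_b: int = 0) -> AgreementResult:
    """Cross-tabulate frequent-exacerbator status from two algorithms."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    fa = frequent_flags(events_a, cohort, window).to_numpy()
    fb = frequent_flags(events_b, cohort, window).to_numpy()
    a = int((fa & fb).sum())
    b = int((fa & ~fb).sum())
    c = int((~fa & fb).sum())
    d = int((~fa & ~fb).sum())
    return AgreementResult(
        algorithm_a=algorithm_a,
        algorithm_b=algorithm_b,
        both_positive=a, a_only=b, b_only=c, both_negative=d,
        percent_agreement=100.0 * (a + d) / len(cohort),
        cohens_kappa=cohens_kappa(a, b, c, d),
    )


def ae_without_admission(bundle: EmrBundle, cohort: pd.DataFrame,
                         link_window_days: int = 1) -> pd.Series:
    """Proportion of members with an unlinked A&E respiratory attendance.

    An attendance is "linked" when a qualifying hospital admission (the
    ICD-10 J44 rule) occurs within ``[attendance, attendance +
    link_window_days]``.  Returns the proportion counting non-asthma
    respiratory attendances only, and additionally counting bronchial-asthma
    attendances; attendances are restricted to each member's follow-up.
    """
    apc = detect_apc_events(bundle.hospital_episodes)
    apc_days = {
        pid: grp["event_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        for pid, grp in apc.groupby("patient_id")
    }
    span = cohort.set_index("patient_id")[["index_date", "followup_end"]]

    def unlinked_patients(categories: tuple[str, ...]) -> set:
        att = bundle.ae_attendances
        att = att[att["diagnosis_category"].isin(categories)]
        att = att.merge(span, left_on="patient_id", right_index=True)
        att = att[(att["attendance_date"] >= att["index_date"])
                  & (att["attendance_date"] <= att["followup_end"])]
        hits = set()
        days = att["attendance_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        for pid, day in zip(att["patient_id"].to_numpy(), days):
            if pid in hits:
                continue
            admissions = apc_days.get(pid)
            linked = admissions is not None and bool(
                ((admissions >= day) & (admissions <= day + link_window_days)).any())
            if not linked:
                hits.add(pid)
        return hits

    n = len(cohort)
    resp = unlinked_patients(("resp_nonasthma",))
    resp_or_asthma = unlinked_patients(("resp_nonasthma", "bronchial_asthma"))
    return pd.Series({
        "n_cohort": n,
        "n_resp_unlinked": len(resp),
        "prop_resp_unlinked": len(resp) / n if n else np.nan,
        "n_resp_or_asthma_unlinked": len(resp_or_asthma),
        "prop_resp_or_asthma_unlinked": len(resp_or_asthma) / n if n else np.nan,
    })
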