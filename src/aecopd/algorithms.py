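"""Six rule-based algorithms for identifying COPD exacerbation events.

Each algorithm is a composition of day-level event detectors and two optional
post-filters.  Detectors fire per (patient, day):

* ``exacerbation_code`` — any primary-care exacerbation code.
* ``lrti_code`` — any lower-respiratory-tract-infection code.
* ``symptom_triad_rx`` — at least two of {chronic cough, breathlessness,
  sputum} coded the same day as a respiratory antibiotic AND an oral
  corticosteroid (OCS) prescribed for 5–14 days.
* ``lrti_plus_rx`` — an LRTI code the same day as an OCS or a respiratory
  antibiotic (no duration requirement).
* ``ocs_only`` — an OCS prescription for 5–14 days, alone.
* ``apc_icd10`` (severe) — hospital admission with ICD-10 J44.1 or J44.0 in
  any diagnosis position, or J44.9 as the primary diagnosis.
* ``ae_resp`` (severe) — an A&E attendance for a non-asthma respiratory cause.

The filters drop events recorded on the same day as a COPD annual-review
visit (retrospective-coding artifacts; hospital-sourced events are exempt)
and deduplicate events within a 14-day window by a greedy forward scan.
Candidates from several detectors on the same day merge into a single event
whose provenance records every detector that fired; the event is severe if
any severe detector fired that day.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .emr import EmrBundle, categorize_codes, normalize_icd10, records_in_category

__all__ = [
    "AlgorithmSpec",
    "ALGORITHMS",
    "MODERATE_DETECTORS",
    "SEVERE_DETECTORS",
    "run_algorithm",
    "detect_code_events",
    "detect_symptom_triad_rx",
    "detect_lrti_plus_rx",
    "detect_ocs_only",
    "detect_apc_events",
    "detect_ae_events",
    "merge_candidates",
    "exclude_annual_review_days",
    "dedup_window",
]

MODERATE_DETECTORS = (
    "exacerbation_code",
    "lrti_code",
    "symptom_triad_rx",
    "lrti_plus_rx",
    "ocs_only",
)
SEVERE_DETECTORS = ("apc_icd10", "ae_resp")

_SYMPTOMS = ("cough", "breathlessness", "sputum")
_EVENT_COLUMNS = ["patient_id", "event_date", "severity", "provenance", "algorithm_id"]


@dataclasses.dataclass(frozen=True)
class AlgorithmSpec:
    """Declarative description of one algorithm: detectors + filters."""

    algorithm_id: int
    moderate_detectors: frozenset
    severe_detectors: frozenset
    apply_annual_review_exclusion: bool
    apply_window_dedup: bool
    dedup_window_days: int = 14
    ocs_duration_range: tuple[int, int] = (5, 14)

    def __post_init__(self) -> None:
        if not self.moderate_detectors <= set(MODERATE_DETECTORS):
            raise ValueError(f"unknown moderate detectors: {self.moderate_detectors}")
        if not self.severe_detectors <= set(SEVERE_DETECTORS):
            raise ValueError(f"unknown severe detectors: {self.severe_detectors}")
        if self.dedup_window_days <= 0:
            raise ValueError("dedup_window_days must be positive")
        if self.ocs_duration_range[0] > self.ocs_duration_range[1]:
            raise ValueError("empty OCS duration range")


def _spec(i, moderate, severe, filters):
    return AlgorithmSpec(i, frozenset(moderate), frozenset(severe), filters, filters)


#: The six fixed algorithm compositions.
ALGORITHMS: dict[int, AlgorithmSpec] = {
    1: _spec(1, {"exacerbation_code", "lrti_code", "symptom_triad_rx"}, {"apc_icd10"}, True),
    2: _spec(2, {"exacerbation_code", "lrti_code", "symptom_triad_rx"}, set(), True),
    3: _spec(3, {"lrti_plus_rx"}, set(), False),
    4: _spec(4, {"exacerbation_code"}, set(), False),
    5: _spec(5, {"ocs_only"}, set(), False),
    6: _spec(6, {"exacerbation_code", "lrti_code", "symptom_triad_rx"},
             {"apc_icd10", "ae_resp"}, True),
}


def _candidates(frame_pid, frame_date) -> pd.DataFrame:
    out = pd.DataFrame({"patient_id": frame_pid, "event_date": frame_date})
    return out.drop_duplicates(ignore_index=True)


def detect_code_events(clinical_events: pd.DataFrame, category: str) -> pd.DataFrame:
    """One candidate per (patient, day) with >=1 code of ``category``."""
    sub = records_in_category(clinical_events, category)
    return _candidates(sub["patient_id"], sub["event_date"])


def _ocs_in_range(prescriptions: pd.DataFrame, duration_range: tuple[int, int]) -> pd.DataFrame:
    ocs = records_in_category(prescriptions, "ocs")
    dur = pd.to_numeric(ocs["duration_days"], errors="coerce")
    # Missing duration fails the criterion (conservative default).
    ok = dur.notna() & (dur >= duration_range[0]) & (dur <= duration_range[1])
    return ocs.loc[ok]


def detect_symptom_triad_rx(
    clinical_events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    duration_range: tuple[int, int] = (5, 14),
) -> pd.DataFrame:
    """Symptom-pair + same-day antibiotic + same-day 5–14-day OCS."""
    sym_frames = []
    for cat in _SYMPTOMS:
        sub = records_in_category(clinical_events, cat)
        if len(sub):
            sym_frames.append(pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy(),
                "event_date": sub["event_date"].to_numpy(),
                "symptom": cat,
            }))
    if not sym_frames:
        return _candidates(pd.Series(dtype=object), pd.Series(dtype="datetime64[ns]"))
    sym = pd.concat(sym_frames, ignore_index=True).drop_duplicates()
    counts = sym.groupby(["patient_id", "event_date"])["symptom"].nunique()
    days = counts[counts >= 2].reset_index()[["patient_id", "event_date"]]

    abx = records_in_category(prescriptions, "resp_antibiotic")
    abx_days = _candidates(abx["patient_id"], abx["issue_date"]).rename(
        columns={"issue_date": "event_date"})
    ocs = _ocs_in_range(prescriptions, duration_range)
    ocs_days = _candidates(ocs["patient_id"], ocs["issue_date"]).rename(
        columns={"issue_date": "event_date"})

    out = days.merge(abx_days, on=["patient_id", "event_date"])
    out = out.merge(ocs_days, on=["patient_id", "event_date"])
    return out.drop_duplicates(ignore_index=True)


def detect_lrti_plus_rx(
    clinical_events: pd.DataFrame, prescriptions: pd.DataFrame
) -> pd.DataFrame:
    """LRTI code the same day as an OCS or respiratory antibiotic."""
    lrti = detect_code_events(clinical_events, "lrti")
    rx_frames = []
    for cat in ("ocs", "resp_antibiotic"):
        sub = records_in_category(prescriptions, cat)
        if len(sub):
            rx_frames.append(pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy(),
                "event_date": sub["issue_date"].to_numpy(),
            }))
    if not rx_frames or lrti.empty:
        return lrti.iloc[0:0]
    rx = pd.concat(rx_frames, ignore_index=True).drop_duplicates()
    return lrti.merge(rx, on=["patient_id", "event_date"]).drop_duplicates(ignore_index=True)


def detect_ocs_only(
    prescriptions: pd.DataFrame, duration_range: tuple[int, int] = (5, 14)
) -> pd.DataFrame:
    """Any OCS prescription with duration inside the range (boundaries inclusive)."""
    ocs = _ocs_in_range(prescriptions, duration_range)
    return _candidates(ocs["patient_id"], ocs["issue_date"]).rename(
        columns={"issue_date": "event_date"})


def detect_apc_events(hospital_episodes: pd.DataFrame) -> pd.DataFrame:
    """Admissions with J44.1/J44.0 in any position or J44.9 as primary."""
    if hospital_episodes.empty:
        return pd.DataFrame({"patient_id": pd.Series(dtype=object),
                             "event_date": pd.Series(dtype="datetime64[ns]")})
    hosp = hospital_episodes.copy()
    icd = hosp["icd10_code"].map(normalize_icd10)
    any_pos = icd.isin(["J441", "J440"])
    primary = (icd == "J449") & (hosp["position"].astype(int) == 1)
    hit = hosp.loc[any_pos | primary]
    return _candidates(hit["patient_id"], hit["admission_date"]).rename(
        columns={"admission_date": "event_date"})


def detect_ae_events(ae_attendances: pd.DataFrame) -> pd.DataFrame:
    """A&E attendances with a non-asthma respiratory diagnosis category."""
    hit = ae_attendances.loc[ae_attendances["diagnosis_category"] == "resp_nonasthma"]
    return _candidates(hit["patient_id"], hit["attendance_date"]).rename(
        columns={"attendance_date": "event_date"})


def merge_candidates(per_detector: dict[str, pd.DataFrame], algorithm_id: int) -> pd.DataFrame:
    """Union same-day candidates into single events with provenance/severity."""
    frames = []
    for detector, cands in per_detector.items():
        if cands is None or cands.empty:
            continue
        f = cands[["patient_id", "event_date"]].copy()
        f["detector"] = detector
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    allc = pd.concat(frames, ignore_index=True)
    grouped = allc.groupby(["patient_id", "event_date"])["detector"].agg(
        lambda s: tuple(sorted(set(s))))
    out = grouped.reset_index().rename(columns={"detector": "provenance"})
    severe = out["provenance"].map(lambda p: any(d in SEVERE_DETECTORS for d in p))
    out["severity"] = np.where(severe, "severe", "moderate")
    out["algorithm_id"] = algorithm_id
    return out[_EVENT_COLUMNS].sort_values(
        ["patient_id", "event_date"], ignore_index=True)


def exclude_annual_review_days(
    events: pd.DataFrame, clinical_events: pd.DataFrame
) -> pd.DataFrame:
    """Drop moderate events dated on an annual-review visit day.

    Severe (hospital/A&E-sourced) events are exempt: the artifact this filter
    targets is retrospective primary-care coding at review visits.
    """
    if events.empty:
        return events
    reviews = detect_code_events(clinical_events, "annual_review")
    if reviews.empty:
        return events
    key = events.merge(reviews.assign(_review=True), on=["patient_id", "event_date"], how="left")
    drop = key["_review"].notna().to_numpy() & (events["severity"] == "moderate").to_numpy()
    return events.loc[~drop].reset_index(drop=True)


def dedup_window(events: pd.DataFrame, window_days: int = 14) -> pd.DataFrame:
    """Greedy forward-scan deduplication within ``window_days``.

    Per patient, the earliest event is always retained; each later event is
    retained iff its gap from the last *retained* event exceeds
    ``window_days`` (a gap of exactly ``window_days`` counts as "within" and
    is dropped).  Idempotent.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    if events.empty:
        return events
    ev = events.sort_values(["patient_id", "event_date"]).reset_index(drop=True)
    pids = ev["patient_id"].to_numpy()
    days = ev["event_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    keep = np.zeros(len(ev), dtype=bool)
    last_pid = None
    last_day = 0
    for i in range(len(ev)):
        if pids[i] != last_pid or days[i] - last_day > window_days:
            keep[i] = True
            last_pid = pids[i]
            last_day = days[i]
    return ev.loc[keep].reset_index(drop=True)


def run_algorithm(
    bundle: EmrBundle,
    cohort: pd.DataFrame,
    algorithm_id: int,
    observation_window: tuple[int | None, int | None] | None = None,
    filter_mode: str = "as_defined",
) -> pd.DataFrame:
    """Identify exacerbation events for cohort members under one algorithm.

    Parameters
    ----------
    bundle:
        Validated EMR bundle (categorized on the fly if needed).
    cohort:
        Cohort member table from :func:`aecopd.cohort.build_cohort`.
    algorithm_id:
        1–6, selecting a composition from :data:`ALGORITHMS`.
    observation_window:
        Optional ``(lo, hi)`` day offsets relative to each member's index
        date (``None`` end = open).  Independently of this, only events
        between registration start and follow-up end are ever returned.
    filter_mode:
        ``"as_defined"`` applies the algorithm's own filters (on for
        algorithms 1, 2, 6); ``"full"`` forces both filters on; ``"none"``
        forces both off.

    Returns a table of events: patient_id, event_date, severity, provenance,
    algorithm_id.  Filters run on each patient's full in-span event stream
    (annual-review exclusion before deduplication), then the observation
    window is applied.
    """
    if algorithm_id not in ALGORITHMS:
        raise ValueError(f"unknown algorithm_id: {algorithm_id}")
    if filter_mode not in ("as_defined", "none", "full"):
        raise ValueError(f"unknown filter_mode: {filter_mode}")
    spec = ALGORITHMS[algorithm_id]

    if "categories" not in bundle.clinical_events.columns:
        bundle = categorize_codes(bundle)

    per_detector: dict[str, pd.DataFrame] = {}
    for det in sorted(spec.moderate_detectors):
        if det == "exacerbation_code":
            per_detector[det] = detect_code_events(bundle.clinical_events, "exacerbation")
        elif det == "lrti_code":
            per_detector[det] = detect_code_events(bundle.clinical_events, "lrti")
        elif det == "symptom_triad_rx":
            per_detector[det] = detect_symptom_triad_rx(
                bundle.clinical_events, bundle.prescriptions, spec.ocs_duration_range)
        elif det == "lrti_plus_rx":
            per_detector[det] = detect_lrti_plus_rx(bundle.clinical_events, bundle.prescriptions)
        elif det == "ocs_only":
            per_detector[det] = detect_ocs_only(bundle.prescriptions, spec.ocs_duration_range)
    for det in sorted(spec.severe_detectors):
        if det == "apc_icd10":
            per_detector[det] = detect_apc_events(bundle.hospital_episodes)
        elif det == "ae_resp":
            per_detector[det] = detect_ae_events(bundle.ae_attendances)

    events = merge_candidates(per_detector, algorithm_id)

    # Restrict to cohort members and their record span.
    span = cohort[["patient_id", "index_date", "followup_end", "registration_start"]]
    events = events.merge(span, on="patient_id", how="inner")
    events = events[
        (events["event_date"] >= events["registration_start"])
        & (events["event_date"] <= events["followup_end"])
    ].reset_index(drop=True)

    if filter_mode == "full":
        do_review, do_dedup = True, True
    elif filter_mode == "none":
        do_review, do_dedup = False, False
    else:
        do_review = spec.apply_annual_review_exclusion
        do_dedup = spec.apply_window_dedup

    if do_review:
        events = exclude_annual_review_days(events, bundle.clinical_events)
    if do_dedup:
        events = dedup_window(events, spec.dedup_window_days)

    if observation_window is not None:
        lo, hi = observation_window
        offset = (events["event_date"] - events["index_date"]).dt.days
        mask = pd.Series(True, index=events.index)
        if lo is not None:
            mask &= offset >= lo
        if hi is not None:
            mask &= offset < hi
        events = events.loc[mask].reset_index(drop=True)

    return events[_EVENT_COLUMNS + ["index_date", "followup_end"]].sort_values(
        ["patient_id", "event_date"], ignore_index=True)
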