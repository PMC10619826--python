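"""Cohort eligibility, index dates, follow-up and baseline covariates.

The study population is people with a coded COPD diagnosis, aged 40 or over,
current or ex-smokers, linkage-eligible, with at least one year of
registration and one prior GP consultation.  A patient's index date is the
first day on which every criterion holds, computed as the maximum of the
individual criterion dates; follow-up runs to the study end, death or
deregistration, whichever is earliest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .emr import EmrBundle, categorize_codes, records_in_category

__all__ = [
    "CohortSpec",
    "build_cohort",
    "derive_index_date",
    "baseline_covariates",
    "describe_cohort",
]

_SMOKING_CATEGORIES = ("smoking_current", "smoking_ex", "smoking_never")
#: Same-day ties between smoking-status records resolve worst-case first.
_SMOKING_PRIORITY = {"smoking_current": 0, "smoking_ex": 1, "smoking_never": 2}
_SMOKING_LABEL = {"smoking_current": "current", "smoking_ex": "ex", "smoking_never": "never"}

#: Attrition criteria, applied in this fixed order.
ATTRITION_ORDER = (
    "no COPD diagnosis code",
    "under minimum age throughout",
    "not current/ex-smoker at index",
    "not linkage eligible",
    "under 1 year registration",
    "no prior consultation",
    "no follow-up time",
)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Eligibility rules and the study window.

    Defaults encode the study design: adults over 40, current or ex-smokers,
    study window 2010-01-01 to 2019-12-30, at least 365 days of registration
    and one consultation before index, HES linkage required.
    """

    min_age_years: int = 40
    allowed_smoking: frozenset = frozenset({"current", "ex"})
    study_start: dt.date = dt.date(2010, 1, 1)
    study_end: dt.date = dt.date(2019, 12, 30)
    min_registration_days: int = 365
    require_prior_consultation: bool = True
    require_linkage: bool = True

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be >= 0")


def _nth_birthday(birth: pd.Timestamp, years: int) -> pd.Timestamp:
    """Birthday ``years`` after birth; 29 February maps to 1 March."""
    try:
        return birth.replace(year=birth.year + years)
    except ValueError:
        return pd.Timestamp(dt.date(birth.year + years, 3, 1))


def derive_index_date(
    patient: pd.Series,
    first_copd: pd.Timestamp | None,
    first_consultation: pd.Timestamp | None,
    spec: CohortSpec,
) -> pd.Timestamp | None:
    """Earliest date on which all date-based criteria hold, or None.

    The index is the maximum of: first COPD code date, the ``min_age_years``-th
    birthday, registration start + ``min_registration_days``, the study start,
    and the day after the first consultation ("prior to index" is strict).
    Absence of a COPD code or consultation, or an index at/after the end of
    follow-up, yields None.  Smoking and linkage are checked by the caller
    (they are not date maxima).
    """
    if first_copd is None or pd.isna(first_copd):
        return None
    if spec.require_prior_consultation and (
        first_consultation is None or pd.isna(first_consultation)
    ):
        return None
    candidates = [
        pd.Timestamp(first_copd),
        _nth_birthday(pd.Timestamp(patient["birth_date"]), spec.min_age_years),
        pd.Timestamp(patient["registration_start"]) + pd.Timedelta(days=spec.min_registration_days),
        pd.Timestamp(spec.study_start),
    ]
    if spec.require_prior_consultation:
        candidates.append(pd.Timestamp(first_consultation) + pd.Timedelta(days=1))
    index = max(candidates)
    if index >= _followup_end(patient, spec):
        return None
    return index


def _followup_end(patient: pd.Series, spec: CohortSpec) -> pd.Timestamp:
    end = pd.Timestamp(spec.study_end)
    for col in ("death_date", "registration_end"):
        value = patient.get(col)
        if value is not None and not pd.isna(value):
            end = min(end, pd.Timestamp(value))
    return end


def build_cohort(bundle: EmrBundle, spec: CohortSpec | None = None):
    """Apply the eligibility rules to every patient in the bundle.

    Returns ``(members, attrition)``: a DataFrame of cohort members with index
    date, follow-up end and baseline covariates, and an attrition report with
    one row per criterion in the fixed order plus the exclusion and remaining
    counts.  Exclusions plus final cohort size always equal the input patient
    count (each patient is counted under its first failed criterion).
    """
    spec = spec or CohortSpec()
    bundle = categorize_codes(bundle)
    events = bundle.clinical_events

    pats = bundle.patients.reset_index(drop=True)
    pid = pats["patient_id"]

    def first_date_by_patient(category: str) -> pd.Series:
        sub = records_in_category(events, category)
        if sub.empty:
            return pd.Series(pd.NaT, index=pats.index)
        firsts = sub.groupby("patient_id")["event_date"].min()
        return pid.map(firsts)

    first_copd = first_date_by_patient("copd_diagnosis")
    first_consult = first_date_by_patient("consultation")
    hf_first = first_date_by_patient("heart_failure")

    # Follow-up end: study end, death or deregistration, whichever first.
    fend = pd.Series(pd.Timestamp(spec.study_end), index=pats.index)
    for col in ("death_date", "registration_end"):
        other = pd.to_datetime(pats[col])
        fend = fend.where(other.isna() | (fend <= other), other)

    birthday = pd.to_datetime(pats["birth_date"]).map(
        lambda b: _nth_birthday(pd.Timestamp(b), spec.min_age_years)
    )
    reg_ready = pd.to_datetime(pats["registration_start"]) + pd.Timedelta(
        days=spec.min_registration_days
    )

    # Index = max of the criterion dates; NaT-free only when COPD code (and,
    # if required, a consultation) exists.
    pieces = [first_copd, birthday, reg_ready,
              pd.Series(pd.Timestamp(spec.study_start), index=pats.index)]
    if spec.require_prior_consultation:
        pieces.append(first_consult + pd.Timedelta(days=1))
    index = pd.concat(pieces, axis=1).max(axis=1, skipna=False)

    # Smoking status at the candidate index (fend - 1d probe when index is
    # undefined, so the smoking criterion is assessed before later criteria).
    probe = index.fillna(fend - pd.Timedelta(days=1))
    smoke_frames = []
    for cat in _SMOKING_CATEGORIES:
        sub = records_in_category(events, cat)
        if len(sub):
            smoke_frames.append(pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy(),
                "date": sub["event_date"].to_numpy(),
                "pri": _SMOKING_PRIORITY[cat],
                "label": _SMOKING_LABEL[cat],
            }))
    smoking = pd.Series(None, index=pats.index, dtype=object)
    if smoke_frames:
        smoke = pd.concat(smoke_frames, ignore_index=True)
        smoke = smoke.merge(
            pd.DataFrame({"patient_id": pid, "probe": probe.to_numpy()}),
            on="patient_id",
        )
        smoke = smoke[smoke["date"] <= smoke["probe"]]
        # Latest record wins; same-day ties resolve current > ex > never.
        smoke = smoke.sort_values(["patient_id", "date", "pri"], ascending=[True, True, False])
        latest = smoke.groupby("patient_id").tail(1).set_index("patient_id")["label"]
        smoking = pid.map(latest)

    fails = [
        ("no COPD diagnosis code", first_copd.isna()),
        ("under minimum age throughout", pd.Series(birthday.to_numpy() >= fend.to_numpy(), index=pats.index)),
        ("not current/ex-smoker at index", ~smoking.isin(sorted(spec.allowed_smoking))),
        ("not linkage eligible",
         ~pats["linkage_eligible"].astype(bool) if spec.require_linkage
         else pd.Series(False, index=pats.index)),
        ("under 1 year registration", reg_ready >= fend),
        ("no prior consultation",
         first_consult.isna() if spec.require_prior_consultation
         else pd.Series(False, index=pats.index)),
        ("no follow-up time", index.isna() | (index >= fend)),
    ]
    assert [label for label, _ in fails] == list(ATTRITION_ORDER)

    failed = pd.Series(False, index=pats.index)
    excluded = {}
    for label, mask in fails:
        newly = mask & ~failed
        excluded[label] = int(newly.sum())
        failed = failed | newly

    keep = ~failed
    age = (index - pd.to_datetime(pats["birth_date"])).dt.days / 365.25
    members_df = pd.DataFrame({
        "patient_id": pid[keep],
        "index_date": index[keep],
        "followup_end": fend[keep],
        "age_at_index": age[keep],
        "sex": pats.loc[keep, "sex"],
        "smoking_at_index": smoking[keep],
        "heart_failure_baseline": (hf_first[keep].notna() & (hf_first[keep] <= index[keep])),
        "region": pats.loc[keep, "region"],
        "imd_quintile": pats.loc[keep, "imd_quintile"].astype(int) if keep.any() else pats.loc[keep, "imd_quintile"],
        "registration_start": pd.to_datetime(pats.loc[keep, "registration_start"]),
    }).reset_index(drop=True)

    remaining = len(pats)
    rows = []
    for label in ATTRITION_ORDER:
        remaining -= excluded[label]
        rows.append({"criterion": label, "excluded": excluded[label], "remaining": remaining})
    attrition = pd.DataFrame(rows, columns=["criterion", "excluded", "remaining"])
    return members_df, attrition


def _smoking_at(rows: list[tuple[pd.Timestamp, int, str]], when: pd.Timestamp) -> str | None:
    """Category label of the most recent smoking record on/before ``when``."""
    eligible = [r for r in rows if r[0] <= when]
    if not eligible:
        return None
    # Latest date wins; same-day ties resolve by priority (current > ex > never).
    date, _, cat = max(eligible, key=lambda r: (r[0].toordinal(), -r[1]))
    return _SMOKING_LABEL[cat]


def baseline_covariates(member: pd.Series, bundle: EmrBundle) -> pd.Series:
    """Recompute baseline covariates for one cohort member.

    Heart failure is positive iff a heart-failure-category code is dated on or
    before the index date (boundary inclusive); smoking at index is the most
    recent smoking-status record on/before index; age is whole days from birth
    to index divided by 365.25.
    """
    bundle = categorize_codes(bundle)
    events = bundle.clinical_events[bundle.clinical_events["patient_id"] == member["patient_id"]]
    index = pd.Timestamp(member["index_date"])

    hf = records_in_category(events, "heart_failure")
    smoking_rows = []
    for cat in _SMOKING_CATEGORIES:
        sub = records_in_category(events, cat)
        smoking_rows += [(d, _SMOKING_PRIORITY[cat], cat) for d in sub["event_date"]]
    smoking = _smoking_at(smoking_rows, index)
    if smoking is None:
        raise ValueError(
            f"patient {member['patient_id']}: no smoking record on/before index "
            "(violates cohort eligibility)"
        )
    patient = bundle.patients.set_index("patient_id").loc[member["patient_id"]]
    return pd.Series(
        {
            "heart_failure_baseline": bool((hf["event_date"] <= index).any()),
            "smoking_at_index": smoking,
            "age_at_index": (index - pd.Timestamp(patient["birth_date"])).days / 365.25,
        }
    )


def describe_cohort(members: pd.DataFrame, strata: pd.Series | None = None) -> pd.DataFrame:
    """Baseline characteristics table, one column block per stratum.

    Reports mean (sample-SD) age, count (%) male, count (%) current smokers,
    and counts (%) by region and IMD quintile; percentages are of the stratum
    size.  Empty strata are emitted with zero counts.
    """
    if members.empty:
        raise ValueError("describe_cohort requires a non-empty cohort")
    if strata is None:
        strata = pd.Series("all", index=members.index)
    rows = []
    for stratum in pd.unique(strata):
        grp = members.loc[strata == stratum]
        n = len(grp)

        def pct(k: int) -> float:
            return 100.0 * k / n if n else 0.0

        rows.append({"stratum": stratum, "variable": "n", "value": n, "percent": np.nan})
        rows.append({
            "stratum": stratum, "variable": "age_mean", "percent": np.nan,
            "value": grp["age_at_index"].mean() if n else np.nan,
        })
        rows.append({
            "stratum": stratum, "variable": "age_sd", "percent": np.nan,
            "value": grp["age_at_index"].std(ddof=1) if n > 1 else np.nan,
        })
        male = int((grp["sex"] == "male").sum())
        rows.append({"stratum": stratum, "variable": "male", "value": male, "percent": pct(male)})
        cur = int((grp["smoking_at_index"] == "current").sum())
        rows.append({"stratum": stratum, "variable": "current_smoker", "value": cur, "percent": pct(cur)})
        for region, k in grp["region"].value_counts().sort_index().items():
            rows.append({"stratum": stratum, "variable": f"region:{region}", "value": int(k), "percent": pct(int(k))})
        for q in range(1, 6):
            k = int((grp["imd_quintile"] == q).sum())
            rows.append({"stratum": stratum, "variable": f"imd:{q}", "value": k, "percent": pct(k)})
    return pd.DataFrame(rows, columns=["stratum", "variable", "value", "percent"])
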