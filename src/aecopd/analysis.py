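"""Frequent-exacerbator classification, person-time rates and the Cox model.

Three analyses, each run per algorithm so misclassification effects can be
compared:

* the proportion of patients with >=2 events in a single year (baseline year
  before index, and each 365-day year of follow-up among patients still
  under follow-up for the whole year);
* event rates per 100 person-years over follow-up, and per 1000
  person-months within each calendar year (follow-up split at 1 January
  boundaries, person-months = days / 30.44);
* a Cox proportional-hazards model (Efron ties) for baseline heart failure
  and time to first exacerbation, adjusted for age, sex and smoking status.

Conventions: index-anchored "years" are 365 days; calendar splitting uses
true calendar boundaries; rate confidence intervals are exact
(chi-square/Poisson) below 100 events and log-normal above.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import run_algorithm
from .emr import EmrBundle

__all__ = [
    "RateResult",
    "CoxResult",
    "classify_frequent",
    "frequent_flags",
    "baseline_frequent_proportion",
    "annual_frequent_proportions",
    "followup_rate",
    "calendar_year_rates",
    "time_to_first_event",
    "fit_cox",
    "hr_across_algorithms",
    "DegenerateModelError",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44
EXACT_CI_MAX_EVENTS = 100


class DegenerateModelError(ValueError):
    """The survival model cannot be fit (no events, constant covariate...)."""


@dataclasses.dataclass(frozen=True)
class RateResult:
    events: int
    person_time: float      # years or months, per `scale`
    rate: float
    ci_low: float
    ci_high: float
    scale: str              # "per 100 person-years" | "per 1000 person-months"


@dataclasses.dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    covariates: tuple[str, ...]
    n: int
    n_events: int


def _window_counts(events: pd.DataFrame, cohort: pd.DataFrame,
                   start: pd.Series, end: pd.Series) -> pd.Series:
    """Events per cohort member with start <= date < end (member-aligned)."""
    bounds = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy(),
        "_w0": start.to_numpy(),
        "_w1": end.to_numpy(),
    })
    ev = events[["patient_id", "event_date"]].merge(bounds, on="patient_id")
    inside = (ev["event_date"] >= ev["_w0"]) & (ev["event_date"] < ev["_w1"])
    counts = ev.loc[inside].groupby("patient_id").size()
    return cohort["patient_id"].map(counts).fillna(0).astype(int)


def frequent_flags(events: pd.DataFrame, cohort: pd.DataFrame,
                   window: str | tuple = "baseline", threshold: int = 2) -> pd.Series:
    """Frequent-exacerbator flag per member for a window.

    ``window="baseline"`` is the half-open year before index,
    ``[index - 365, index)``; ``window=(lo, hi)`` selects index-relative day
    offsets ``[lo, hi)``.  Returns a boolean Series aligned to ``cohort``.
    """
    index = pd.to_datetime(cohort["index_date"])
    if window == "baseline":
        lo, hi = -365, 0
    else:
        lo, hi = window
    start = index + pd.to_timedelta(lo, unit="D")
    end = index + pd.to_timedelta(hi, unit="D")
    return _window_counts(events, cohort, start, end) >= threshold


def classify_frequent(events: pd.DataFrame, member: pd.Series,
                      window: str | tuple = "baseline") -> bool:
    """Single-member frequent-exacerbator classification (>=2 events/window)."""
    cohort = member.to_frame().T
    ev = events[events["patient_id"] == member["patient_id"]]
    return bool(frequent_flags(ev, cohort, window).iloc[0])


def baseline_frequent_proportion(events: pd.DataFrame, cohort: pd.DataFrame) -> pd.Series:
    flags = frequent_flags(events, cohort, "baseline")
    n = len(cohort)
    return pd.Series({
        "window": "baseline",
        "n_classified": int(flags.sum()),
        "n_at_risk": n,
        "proportion": flags.sum() / n if n else np.nan,
    })


def annual_frequent_proportions(events: pd.DataFrame, cohort: pd.DataFrame,
                                n_years: int) -> pd.DataFrame:
    """Frequent-exacerbator proportion for each follow-up year 1..n_years.

    Year k covers index-relative days [365(k-1), 365k); the denominator is
    members whose follow-up extends to at least the end of the year (active
    follow-up for the whole year of interest).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    index = pd.to_datetime(cohort["index_date"])
    fend = pd.to_datetime(cohort["followup_end"])
    rows = []
    for k in range(1, n_years + 1):
        lo, hi = 365 * (k - 1), 365 * k
        active = fend >= index + pd.to_timedelta(hi, unit="D")
        sub = cohort.loc[active]
        flags = frequent_flags(events, sub, (lo, hi)) if len(sub) else pd.Series(dtype=bool)
        rows.append({
            "window": f"year {k}",
            "n_classified": int(flags.sum()),
            "n_at_risk": int(active.sum()),
            "proportion": flags.sum() / active.sum() if active.any() else np.nan,
        })
    return pd.DataFrame(rows)


def _poisson_ci(events: int, person_time: float) -> tuple[float, float]:
    """95% CI for a Poisson rate; exact below the event-count threshold."""
    if events < EXACT_CI_MAX_EVENTS:
        lo = stats.chi2.ppf(0.025, 2 * events) / 2 if events > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (events + 1)) / 2
        return lo / person_time, hi / person_time
    log_rate = np.log(events / person_time)
    se = 1.0 / np.sqrt(events)
    return float(np.exp(log_rate - 1.959963984540054 * se)), \
        float(np.exp(log_rate + 1.959963984540054 * se))


def followup_rate(events: pd.DataFrame, cohort: pd.DataFrame) -> RateResult:
    """Event rate per 100 person-years over [index, followup_end]."""
    index = pd.to_datetime(cohort["index_date"])
    fend = pd.to_datetime(cohort["followup_end"])
    person_years = float((fend - index).dt.days.sum()) / DAYS_PER_YEAR
    if person_years <= 0:
        raise ValueError("zero person-time")
    counts = _window_counts(events, cohort, index,
                            fend + pd.to_timedelta(1, unit="D"))
    n_events = int(counts.sum())
    rate = 100.0 * n_events / person_years
    lo, hi = _poisson_ci(n_events, person_years)
    return RateResult(n_events, person_years, rate, 100 * lo, 100 * hi,
                      "per 100 person-years")


def calendar_year_rates(events: pd.DataFrame, cohort: pd.DataFrame,
                        years: range | list[int] = range(2010, 2020)) -> pd.DataFrame:
    """Rates per 1000 person-months by calendar year.

    Each member's follow-up is split at 1 January boundaries; person-months
    are days/30.44.  Years with zero person-time are omitted rather than
    divided by zero.
    """
    index = pd.to_datetime(cohort["index_date"])
    fend = pd.to_datetime(cohort["followup_end"])
    rows = []
    ev = events.merge(cohort[["patient_id"]], on="patient_id")
    ev = ev.merge(pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy(),
                                "_i": index.to_numpy(), "_f": fend.to_numpy()}),
                  on="patient_id")
    in_fu = (ev["event_date"] >= ev["_i"]) & (ev["event_date"] <= ev["_f"])
    ev_years = ev.loc[in_fu, "event_date"].dt.year
    for year in years:
        y0 = pd.Timestamp(year, 1, 1)
        y1 = pd.Timestamp(year + 1, 1, 1)
        # Half-open [index, fend) split at 1 January: conserves person-time.
        seg_start = index.clip(lower=y0)
        seg_end = fend.clip(upper=y1)
        days = (seg_end - seg_start).dt.days.clip(lower=0)
        person_months = float(days.sum()) / DAYS_PER_MONTH
        if person_months <= 0:
            continue
        n_events = int((ev_years == year).sum())
        rate = 1000.0 * n_events / person_months
        lo, hi = _poisson_ci(n_events, person_months)
        rows.append({"year": year, "events": n_events,
                     "person_months": person_months, "rate": rate,
                     "ci_low": 1000 * lo, "ci_high": 1000 * hi,
                     "scale": "per 1000 person-months"})
    return pd.DataFrame(rows)


def time_to_first_event(events: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Survival records for time from index to first exacerbation.

    Time is days from index to the first event on/after index (event = 1) or
    to follow-up end (event = 0).  Members whose first event falls on the
    index date itself have zero survival time — undefined in the partial
    likelihood — and are excluded from the risk set.
    """
    index = pd.to_datetime(cohort["index_date"])
    fend = pd.to_datetime(cohort["followup_end"])
    bounds = pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy(),
                           "_i": index.to_numpy()})
    ev = events[["patient_id", "event_date"]].merge(bounds, on="patient_id")
    firsts = ev.loc[ev["event_date"] >= ev["_i"]].groupby("patient_id")["event_date"].min()
    first = cohort["patient_id"].map(firsts)

    time = np.where(first.notna(),
                    (pd.to_datetime(first) - index).dt.days,
                    (fend - index).dt.days)
    flag = first.notna().astype(int)
    out = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy(),
        "time_days": time,
        "event": flag.to_numpy(),
        "heart_failure": cohort["heart_failure_baseline"].astype(int).to_numpy(),
        "age": cohort["age_at_index"].to_numpy(),
        "sex_male": (cohort["sex"] == "male").astype(int).to_numpy(),
        "smoking_current": (cohort["smoking_at_index"] == "current").astype(int).to_numpy(),
    })
    if (out["time_days"] < 0).any():
        raise ValueError("negative survival time: upstream windowing bug")
    return out.loc[out["time_days"] > 0].reset_index(drop=True)


def fit_cox(survival: pd.DataFrame,
            covariates: tuple[str, ...] = ("heart_failure", "age", "sex_male",
                                           "smoking_current"),
            exposure: str = "heart_failure") -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) via lifelines.

    Returns the hazard ratio of ``exposure`` with a 95% Wald CI.  Raises
    :class:`DegenerateModelError` when there are no events or a covariate is
    constant, instead of returning silent garbage.
    """
    from lifelines import CoxPHFitter

    if survival["event"].sum() == 0:
        raise DegenerateModelError("no events in the risk set")
    for cov in covariates:
        if survival[cov].nunique() < 2:
            raise DegenerateModelError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    cph.fit(survival[["time_days", "event", *covariates]],
            duration_col="time_days", event_col="event")
    summ = cph.summary.loc[exposure]
    return CoxResult(
        hazard_ratio=float(np.exp(summ["coef"])),
        ci_low=float(np.exp(summ["coef lower 95%"])),
        ci_high=float(np.exp(summ["coef upper 95%"])),
        covariates=tuple(covariates),
        n=len(survival),
        n_events=int(survival["event"].sum()),
    )


def hr_across_algorithms(bundle: EmrBundle, cohort: pd.DataFrame,
                         filter_mode: str = "as_defined",
                         algorithm_ids=(1, 2, 3, 4, 5, 6)) -> pd.DataFrame:
    """Heart-failure HR for time to first exacerbation, per algorithm.

    One row per algorithm; a fit failure (e.g. empty event stream) is
    reported in the ``error`` column rather than aborting the table.
    """
    rows = []
    for aid in algorithm_ids:
        row: dict = {"algorithm_id": aid, "filter_mode": filter_mode}
        try:
            events = run_algorithm(bundle, cohort, aid, filter_mode=filter_mode)
            surv = time_to_first_event(events, cohort)
            res = fit_cox(surv)
            row.update(hazard_ratio=res.hazard_ratio, ci_low=res.ci_low,
                       ci_high=res.ci_high, n=res.n, n_events=res.n_events,
                       error="")
        except (DegenerateModelError, ValueError) as exc:
            row.update(hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       n=0, n_events=0, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
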