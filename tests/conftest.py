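"""Shared fixtures: hand-built micro-bundles and cached simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aecopd.cohort import build_cohort
from aecopd.emr import EmrBundle, empty_bundle
from aecopd.simulate import default_codelists, scenario_config, simulate_cohort


def _dates(values):
    return pd.to_datetime(pd.Series(list(values), dtype=object))


def make_patient(pid="P1", birth="1950-06-15", sex="male", region="London",
                 imd=3, reg_start="2005-01-01", reg_end=None, death=None,
                 linked=True) -> dict:
    return dict(patient_id=pid, birth_date=birth, sex=sex, region=region,
                imd_quintile=imd, registration_start=reg_start,
                registration_end=reg_end, death_date=death,
                linkage_eligible=linked)


def eligibility_rows(pid="P1", copd="2008-03-01", consult="2006-02-01",
                     smoking_code="SMOKCUR1", smoking_date="2006-02-01"):
    """Clinical rows making a patient pass every cohort criterion."""
    rows = [(pid, consult, "CONS001"), (pid, smoking_date, smoking_code)]
    if copd is not None:
        rows.append((pid, copd, "COPD001"))
    return rows


def make_bundle(patients, clinical=(), rx=(), hosp=(), ae=()) -> EmrBundle:
    """Build a validated bundle from plain tuples.

    clinical: (pid, date, code); rx: (pid, date, code, duration);
    hosp: (pid, date, episode_id, icd10, position); ae: (pid, date, category).
    """
    base = empty_bundle(default_codelists())
    pat = pd.DataFrame(patients)
    for col in ("birth_date", "registration_start", "registration_end", "death_date"):
        pat[col] = _dates(pat[col])
    clin = pd.DataFrame(clinical, columns=["patient_id", "event_date", "code"])
    clin["event_date"] = _dates(clin["event_date"]) if len(clin) else clin.get("event_date")
    rxf = pd.DataFrame(rx, columns=["patient_id", "issue_date", "code", "duration_days"])
    rxf["issue_date"] = _dates(rxf["issue_date"]) if len(rxf) else rxf.get("issue_date")
    hospf = pd.DataFrame(hosp, columns=["patient_id", "admission_date", "episode_id",
                                        "icd10_code", "position"])
    hospf["admission_date"] = _dates(hospf["admission_date"]) if len(hospf) \
        else hospf.get("admission_date")
    aef = pd.DataFrame(ae, columns=["patient_id", "attendance_date", "diagnosis_category"])
    aef["attendance_date"] = _dates(aef["attendance_date"]) if len(aef) \
        else aef.get("attendance_date")
    bundle = EmrBundle(
        patients=pat,
        clinical_events=clin if len(clin) else base.clinical_events,
        prescriptions=rxf if len(rxf) else base.prescriptions,
        hospital_episodes=hospf if len(hospf) else base.hospital_episodes,
        ae_attendances=aef if len(aef) else base.ae_attendances,
        codelists=default_codelists(),
    )
    return bundle.validate()


def single_member_cohort(pid="P1", index="2010-01-01", fend="2019-12-30",
                         reg_start="2005-01-01", hf=False, age=60.0,
                         sex="male", smoking="current") -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": pid,
        "index_date": pd.Timestamp(index),
        "followup_end": pd.Timestamp(fend),
        "age_at_index": age,
        "sex": sex,
        "smoking_at_index": smoking,
        "heart_failure_baseline": hf,
        "region": "London",
        "imd_quintile": 3,
        "registration_start": pd.Timestamp(reg_start),
    }])


@pytest.fixture(scope="session")
def mixed_sim():
    """A moderate validated-mix simulation shared across tests."""
    bundle, truth = simulate_cohort(scenario_config("validated-mix", 400, seed=11))
    cohort, attrition = build_cohort(bundle)
    return {"bundle": bundle, "truth": truth, "cohort": cohort, "attrition": attrition}


@pytest.fixture(scope="session")
def perfect_sim():
    """Perfect single-channel coding: detected events == true events."""
    bundle, truth = simulate_cohort(scenario_config("perfect-coding", 300, seed=5))
    cohort, _ = build_cohort(bundle)
    return {"bundle": bundle, "truth": truth, "cohort": cohort}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
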