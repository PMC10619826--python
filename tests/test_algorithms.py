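"""Detector rules, filters, and algorithm composition invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecopd.algorithms import (ALGORITHMS, dedup_window, detect_apc_events,
                               detect_ae_events, detect_code_events,
                               detect_lrti_plus_rx, detect_ocs_only,
                               detect_symptom_triad_rx, exclude_annual_review_days,
                               merge_candidates, run_algorithm)
from aecopd.emr import categorize_codes

from conftest import eligibility_rows, make_bundle, make_patient, single_member_cohort


def _cat(bundle):
    return categorize_codes(bundle)


def _days(frame):
    return sorted(frame["event_date"].dt.strftime("%Y-%m-%d"))


class TestDetectors:
    def test_same_day_codes_collapse_to_one_candidate(self):
        b = _cat(make_bundle([make_patient()], clinical=[
            ("P1", "2012-01-05", "EXAC001"), ("P1", "2012-01-05", "EXAC002"),
            ("P1", "2012-01-06", "EXAC001")]))
        out = detect_code_events(b.clinical_events, "exacerbation")
        assert _days(out) == ["2012-01-05", "2012-01-06"]

    def test_category_filter_is_strict(self):
        b = _cat(make_bundle([make_patient()], clinical=[("P1", "2012-01-05", "LRTI001")]))
        assert detect_code_events(b.clinical_events, "exacerbation").empty
        assert len(detect_code_events(b.clinical_events, "lrti")) == 1

    @pytest.mark.parametrize("symptoms,abx,ocs_dur,expected", [
        (["COUGH001", "BRTH001"], True, 7.0, 1),      # 2-of-3 + both scripts
        (["COUGH001", "BRTH001", "SPUT001"], True, 7.0, 1),
        (["COUGH001"], True, 7.0, 0),                 # fails 2-of-3
        (["COUGH001", "SPUT001"], True, 4.0, 0),      # OCS outside 5-14
        (["COUGH001", "SPUT001"], True, None, 0),     # missing duration fails
        (["COUGH001", "SPUT001"], False, 7.0, 0),     # no antibiotic
    ])
    def test_symptom_triad_rule(self, symptoms, abx, ocs_dur, expected):
        clinical = [("P1", "2012-01-05", s) for s in symptoms]
        rx = [("P1", "2012-01-05", "OCS001", ocs_dur)]
        if abx:
            rx.append(("P1", "2012-01-05", "RABX001", 5.0))
        b = _cat(make_bundle([make_patient()], clinical=clinical, rx=rx))
        out = detect_symptom_triad_rx(b.clinical_events, b.prescriptions)
        assert len(out) == expected

    @pytest.mark.parametrize("rx,expected", [
        ([("P1", "2012-01-05", "RABX001", 5.0)], 1),           # lrti + abx
        ([], 0),                                               # lrti alone
        ([("P1", "2012-01-05", "OCS001", None)], 1),           # OCS, duration irrelevant
        ([("P1", "2012-01-06", "RABX001", 5.0)], 0),           # different day
    ])
    def test_lrti_plus_prescription_rule(self, rx, expected):
        b = _cat(make_bundle([make_patient()],
                             clinical=[("P1", "2012-01-05", "LRTI001")], rx=rx))
        assert len(detect_lrti_plus_rx(b.clinical_events, b.prescriptions)) == expected

    @pytest.mark.parametrize("duration,expected", [
        (5.0, 1), (14.0, 1), (4.0, 0), (15.0, 0), (None, 0),
    ])
    def test_ocs_only_duration_boundaries(self, duration, expected):
        b = _cat(make_bundle([make_patient()],
                             rx=[("P1", "2012-01-05", "OCS001", duration)]))
        assert len(detect_ocs_only(b.prescriptions)) == expected

    @pytest.mark.parametrize("icd,pos,expected", [
        ("J441", 3, 1),   # any position
        ("J440", 1, 1),
        ("J449", 1, 1),   # primary only
        ("J449", 2, 0),
        ("J189", 1, 0),
    ])
    def test_hospital_icd10_position_rules(self, icd, pos, expected):
        rows = [("P1", "2012-01-05", 1, "I109", p) for p in range(1, pos)]
        rows.append(("P1", "2012-01-05", 1, icd, pos))
        b = make_bundle([make_patient()], hosp=rows)
        assert len(detect_apc_events(b.hospital_episodes)) == expected

    @pytest.mark.parametrize("category,expected", [
        ("resp_nonasthma", 1), ("bronchial_asthma", 0), ("other", 0),
    ])
    def test_ae_category_rule(self, category, expected):
        b = make_bundle([make_patient()], ae=[("P1", "2012-01-05", category)])
        assert len(detect_ae_events(b.ae_attendances)) == expected


class TestMergeAndFilters:
    def test_same_day_detectors_merge_to_one_severe_event(self):
        d = pd.Timestamp("2012-01-05")
        cands = {
            "exacerbation_code": pd.DataFrame({"patient_id": ["P1"], "event_date": [d]}),
            "apc_icd10": pd.DataFrame({"patient_id": ["P1"], "event_date": [d]}),
        }
        out = merge_candidates(cands, algorithm_id=1)
        assert len(out) == 1
        assert out["severity"].iloc[0] == "severe"
        assert out["provenance"].iloc[0] == ("apc_icd10", "exacerbation_code")

    def test_annual_review_drops_moderate_same_day_only(self):
        b = _cat(make_bundle([make_patient()], clinical=[
            ("P1", "2012-01-05", "AREV001"), ("P1", "2012-01-06", "AREV001")]))
        events = pd.DataFrame({
            "patient_id": ["P1", "P1", "P1"],
            "event_date": pd.to_datetime(["2012-01-05", "2012-01-04", "2012-01-06"]),
            "severity": ["moderate", "moderate", "severe"],
            "provenance": [("exacerbation_code",)] * 2 + [("apc_icd10",)],
            "algorithm_id": [1, 1, 1],
        })
        kept = exclude_annual_review_days(events, b.clinical_events)
        # moderate on review day dropped; moderate the day before kept;
        # severe on a review day exempt
        assert _days(kept) == ["2012-01-04", "2012-01-06"]


def _event_frame(days):
    return pd.DataFrame({
        "patient_id": ["P1"] * len(days),
        "event_date": pd.Timestamp("2012-01-01") + pd.to_timedelta(days, unit="D"),
        "severity": ["moderate"] * len(days),
        "provenance": [("exacerbation_code",)] * len(days),
        "algorithm_id": [4] * len(days),
    })


class TestDedupWindow:
    @pytest.mark.parametrize("days,window,kept", [
        ([0, 10, 20], 14, [0, 20]),   # 10 within 14 of 0; 20 > 14 after 0
        ([0, 14], 14, [0]),           # gap of exactly 14 is "within"
        ([0, 15], 14, [0, 15]),
        ([], 14, []),
        ([5], 14, [5]),
        ([0, 10, 20, 30], 14, [0, 20]),  # chain anchors on retained events
    ])
    def test_greedy_forward_scan(self, days, window, kept):
        out = dedup_window(_event_frame(days), window)
        got = sorted((out["event_date"] - pd.Timestamp("2012-01-01")).dt.days)
        assert got == kept

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            dedup_window(_event_frame([0]), 0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 120), min_size=0, max_size=12),
           st.integers(1, 30))
    def test_idempotent_and_gaps_exceed_window(self, days, window):
        out = dedup_window(_event_frame(sorted(set(days))), window)
        again = dedup_window(out, window)
        assert out.reset_index(drop=True).equals(again.reset_index(drop=True))
        gaps = out["event_date"].diff().dt.days.dropna()
        assert (gaps > window).all()
        if days:
            assert out["event_date"].min() == \
                pd.Timestamp("2012-01-01") + pd.Timedelta(days=min(days))


class TestRunAlgorithm:
    def test_unknown_algorithm_rejected(self, mixed_sim):
        with pytest.raises(ValueError, match="algorithm_id"):
            run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], 7)

    def test_primary_care_algorithm_blind_to_hospital_data(self):
        bundle = make_bundle(
            [make_patient("P1")],
            clinical=eligibility_rows("P1"),
            hosp=[("P1", "2012-01-05", 1, "J441", 1)])
        cohort = single_member_cohort("P1")
        assert run_algorithm(bundle, cohort, 2).empty
        assert len(run_algorithm(bundle, cohort, 1)) == 1

    def test_candidate_sets_nest_2_in_1_in_6(self, mixed_sim):
        sets = {}
        for aid in (1, 2, 6):
            ev = run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], aid,
                               filter_mode="none")
            sets[aid] = set(zip(ev["patient_id"], ev["event_date"]))
        assert sets[2] <= sets[1] <= sets[6]

    def test_filters_only_remove_events(self, mixed_sim):
        for aid in range(1, 7):
            full = run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], aid,
                                 filter_mode="full")
            none = run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], aid,
                                 filter_mode="none")
            assert len(full) <= len(none)

    def test_observation_window_restricts_relative_days(self, mixed_sim):
        ev = run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], 4,
                           observation_window=(0, 365), filter_mode="none")
        offset = (ev["event_date"] - ev["index_date"]).dt.days
        assert ((offset >= 0) & (offset < 365)).all()

    def test_events_confined_to_registration_and_followup(self, mixed_sim):
        ev = run_algorithm(mixed_sim["bundle"], mixed_sim["cohort"], 6)
        assert (ev["event_date"] <= ev["followup_end"]).all()
        merged = ev.merge(mixed_sim["cohort"][["patient_id", "registration_start"]],
                          on="patient_id")
        assert (merged["event_date"] >= merged["registration_start"]).all()
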