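"""Frequent-exacerbator windows, rates, calendar splitting and the Cox fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aecopd.analysis import (DegenerateModelError, annual_frequent_proportions,
                             baseline_frequent_proportion, calendar_year_rates,
                             classify_frequent, fit_cox, followup_rate,
                             frequent_flags, hr_across_algorithms,
                             time_to_first_event)

from conftest import single_member_cohort


def _events(pid_days, base="2010-01-01"):
    pids, days = zip(*pid_days) if pid_days else ((), ())
    return pd.DataFrame({
        "patient_id": list(pids),
        "event_date": pd.Timestamp(base) + pd.to_timedelta(list(days), unit="D"),
    })


class TestFrequentExacerbators:
    def test_no_events_is_not_frequent(self):
        cohort = single_member_cohort()
        assert not classify_frequent(_events([]), cohort.iloc[0])

    def test_two_events_in_baseline_year(self):
        cohort = single_member_cohort(index="2010-01-01")
        ev = _events([("P1", -100), ("P1", -10)])
        assert classify_frequent(ev, cohort.iloc[0], "baseline")

    def test_event_on_index_date_outside_baseline_window(self):
        """Baseline window is [index-365, index): the index-day event does not
        count, leaving one qualifying event -> not frequent."""
        cohort = single_member_cohort(index="2010-01-01")
        ev = _events([("P1", -10), ("P1", 0)])
        assert not classify_frequent(ev, cohort.iloc[0], "baseline")

    def test_annual_denominator_requires_active_followup(self):
        cohort = pd.concat([
            single_member_cohort("A", index="2010-01-01", fend="2019-12-30"),
            single_member_cohort("B", index="2010-01-01", fend="2010-06-01"),
        ], ignore_index=True)
        res = annual_frequent_proportions(_events([]), cohort, 1)
        assert res.loc[0, "n_at_risk"] == 1  # B censored mid-year 1

    def test_zero_events_gives_zero_proportions(self):
        cohort = single_member_cohort()
        res = annual_frequent_proportions(_events([]), cohort, 3)
        assert (res["proportion"] == 0).all()

    def test_stationary_process_gives_flat_yearly_proportions(self, perfect_sim):
        from aecopd.algorithms import run_algorithm
        ev = run_algorithm(perfect_sim["bundle"], perfect_sim["cohort"], 4,
                           filter_mode="none")
        res = annual_frequent_proportions(ev, perfect_sim["cohort"], 5)
        p = res["proportion"]
        se = np.sqrt(p * (1 - p) / res["n_at_risk"]).max()
        assert p.max() - p.min() < 6 * se


class TestRates:
    def test_rate_arithmetic(self):
        """50 events over ~100 person-years -> 50 per 100 PY."""
        cohort = pd.concat([
            single_member_cohort(pid, index="2010-01-01", fend="2019-12-30")
            for pid in ("A", "B", "C", "D", "E", "F", "G", "H", "I", "J")
        ], ignore_index=True)
        ev = _events([(pid, 5 + 7 * k) for pid in "ABCDE" for k in range(10)])
        res = followup_rate(ev, cohort)
        assert res.events == 50
        assert res.rate == pytest.approx(100.0 * 50 / res.person_time)

    def test_zero_events_rate_and_ci_floor(self):
        cohort = single_member_cohort()
        res = followup_rate(_events([]), cohort)
        assert res.rate == 0.0
        assert res.ci_low == 0.0
        assert res.ci_high > 0.0

    def test_exact_poisson_ci_matches_chi2_quantiles(self):
        """10 events / 20 PY: CI bounds equal the chi-square closed form."""
        cohort = pd.concat([
            single_member_cohort(pid, index="2010-01-01", fend="2019-12-30")
            for pid in ("A", "B")
        ], ignore_index=True)
        ev = _events([("A", 30 * k) for k in range(10)])
        res = followup_rate(ev, cohort)
        pt = res.person_time
        lo = stats.chi2.ppf(0.025, 20) / 2 / pt * 100
        hi = stats.chi2.ppf(0.975, 22) / 2 / pt * 100
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)
        assert res.ci_low <= res.rate <= res.ci_high

    def test_zero_person_time_is_fatal(self):
        cohort = single_member_cohort(index="2010-01-01", fend="2010-01-01")
        with pytest.raises(ValueError, match="person-time"):
            followup_rate(_events([]), cohort)


class TestCalendarRates:
    def test_midyear_followup_splits_into_six_month_halves(self):
        cohort = single_member_cohort(index="2010-07-01", fend="2011-06-30")
        res = calendar_year_rates(_events([]), cohort, [2010, 2011]).set_index("year")
        assert res.loc[2010, "person_months"] == pytest.approx(6.0, abs=0.2)
        assert res.loc[2011, "person_months"] == pytest.approx(6.0, abs=0.2)

    def test_split_person_time_conserved(self, mixed_sim):
        cohort = mixed_sim["cohort"]
        res = calendar_year_rates(_events([]), cohort, range(2009, 2021))
        total_days = (cohort["followup_end"] - cohort["index_date"]).dt.days.sum()
        assert res["person_months"].sum() * 30.44 == pytest.approx(total_days, abs=1e-6)

    def test_year_without_persontime_omitted(self):
        cohort = single_member_cohort(index="2010-01-01", fend="2012-06-30")
        res = calendar_year_rates(_events([]), cohort, range(2010, 2020))
        assert set(res["year"]) == {2010, 2011, 2012}

    def test_events_assigned_to_their_calendar_year(self):
        cohort = single_member_cohort(index="2010-01-01", fend="2011-12-30")
        ev = _events([("P1", 10), ("P1", 400)])
        res = calendar_year_rates(ev, cohort, [2010, 2011]).set_index("year")
        assert res.loc[2010, "events"] == 1
        assert res.loc[2011, "events"] == 1


class TestSurvival:
    def test_censored_without_events(self):
        cohort = single_member_cohort(index="2010-01-01", fend="2012-01-01")
        surv = time_to_first_event(_events([]), cohort)
        assert surv.loc[0, "event"] == 0
        assert surv.loc[0, "time_days"] == 730

    def test_first_event_defines_time(self):
        cohort = single_member_cohort()
        surv = time_to_first_event(_events([("P1", 30), ("P1", 200)]), cohort)
        assert surv.loc[0, "event"] == 1
        assert surv.loc[0, "time_days"] == 30

    def test_event_on_index_date_excluded_from_risk_set(self):
        cohort = single_member_cohort()
        surv = time_to_first_event(_events([("P1", 0)]), cohort)
        assert surv.empty

    def test_baseline_events_ignored(self):
        cohort = single_member_cohort()
        surv = time_to_first_event(_events([("P1", -50), ("P1", 90)]), cohort)
        assert surv.loc[0, "time_days"] == 90


def _simulated_survival(n=800, seed=4):
    from aecopd.algorithms import run_algorithm
    from aecopd.cohort import build_cohort
    from aecopd.simulate import scenario_config, simulate_cohort
    bundle, _ = simulate_cohort(scenario_config("high-fidelity", n, seed=seed))
    cohort, _ = build_cohort(bundle)
    events = run_algorithm(bundle, cohort, 1)
    return time_to_first_event(events, cohort)


class TestCox:
    def test_agrees_with_independent_reference_fit(self):
        """lifelines fit must match statsmodels PHReg (Efron ties) to 4
        significant figures on the heart-failure coefficient."""
        import statsmodels.api as sm

        surv = _simulated_survival()
        res = fit_cox(surv)
        covs = ["heart_failure", "age", "sex_male", "smoking_current"]
        ref = sm.PHReg(surv["time_days"], surv[covs], status=surv["event"],
                       ties="efron").fit()
        beta_ref = ref.params[0]
        assert np.log(res.hazard_ratio) == pytest.approx(beta_ref, rel=5e-4)
        # Wald CI agrees too
        se_ref = ref.bse[0]
        assert np.log(res.ci_low) == pytest.approx(beta_ref - 1.96 * se_ref, abs=2e-3)

    def test_no_events_diagnosed(self):
        surv = pd.DataFrame({
            "time_days": [10, 20], "event": [0, 0], "heart_failure": [0, 1],
            "age": [60.0, 70.0], "sex_male": [1, 0], "smoking_current": [0, 1],
        })
        with pytest.raises(DegenerateModelError, match="no events"):
            fit_cox(surv)

    def test_constant_covariate_diagnosed(self):
        surv = pd.DataFrame({
            "time_days": [10, 20, 30], "event": [1, 1, 0], "heart_failure": [1, 1, 1],
            "age": [60.0, 70.0, 65.0], "sex_male": [1, 0, 1],
            "smoking_current": [0, 1, 0],
        })
        with pytest.raises(DegenerateModelError, match="constant"):
            fit_cox(surv)

    def test_hr_table_reports_fit_failures_per_row(self, perfect_sim):
        """Algorithm rows that cannot be fit carry an error, others fit."""
        table = hr_across_algorithms(perfect_sim["bundle"], perfect_sim["cohort"],
                                     "as_defined", algorithm_ids=(4, 5))
        row4 = table.set_index("algorithm_id").loc[4]
        row5 = table.set_index("algorithm_id").loc[5]
        assert row4["error"] == "" and row4["hazard_ratio"] > 0
        # perfect-coding emits no prescriptions: algorithm 5 has no events
        assert row5["error"] != "" and np.isnan(row5["hazard_ratio"])
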