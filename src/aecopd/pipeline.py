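"""End-to-end study runner: simulate → cohort → phenotype → analyze → compare.

Produces a directory of delimited-text result tables plus a JSON manifest
recording the configuration hash, seed and per-stage row counts, so a run is
reproducible and auditable.  Timestamps are deliberately excluded from the
manifest: determinism checks compare content, not clocks.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .algorithms import ALGORITHMS, run_algorithm
from .analysis import (annual_frequent_proportions, baseline_frequent_proportion,
                       calendar_year_rates, followup_rate, frequent_flags,
                       hr_across_algorithms)
from .cohort import CohortSpec, build_cohort, describe_cohort
from .compare import ae_without_admission, classification_agreement, concordance
from .emr import EmrBundle, read_bundle, write_bundle
from .simulate import (CodingModel, Demographics, EventProcess, GroundTruth,
                       NoiseModel, scenario_config, simulate_cohort)

__all__ = ["run_study", "write_events", "write_ground_truth", "load_run_config"]


_SIM_SECTIONS = {"demographics": Demographics, "process": EventProcess,
                 "coding": CodingModel, "noise": NoiseModel}


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run configuration into :func:`run_study` keyword arguments.

    Recognised keys: ``scenario``, ``n_patients``, ``seed``, ``filter_mode``,
    ``algorithm_ids``, ``n_followup_years``, ``tolerance_days``; a ``cohort``
    mapping of :class:`~aecopd.cohort.CohortSpec` fields; and a ``simulation``
    mapping of :class:`~aecopd.simulate.SimulationConfig` overrides, with
    nested ``demographics`` / ``process`` / ``coding`` / ``noise`` sections.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("scenario", "n_patients", "seed", "filter_mode",
                "n_followup_years", "tolerance_days"):
        if key in raw:
            kwargs[key] = raw[key]
    if "algorithm_ids" in raw:
        kwargs["algorithm_ids"] = tuple(int(a) for a in raw["algorithm_ids"])
    if "cohort" in raw:
        fields = dict(raw["cohort"])
        for key in ("study_start", "study_end"):
            if key in fields:
                fields[key] = dt.date.fromisoformat(str(fields[key]))
        if "allowed_smoking" in fields:
            fields["allowed_smoking"] = frozenset(fields["allowed_smoking"])
        kwargs["cohort_spec"] = CohortSpec(**fields)
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        for key in ("study_start", "study_end"):
            if key in sim:
                sim[key] = dt.date.fromisoformat(str(sim[key]))
        for section, cls in _SIM_SECTIONS.items():
            if section in sim:
                fields = dict(sim[section])
                for drift in ("calendar_drift", "retro_calendar_drift"):
                    if drift in fields and fields[drift] is not None:
                        fields[drift] = {int(y): float(m)
                                         for y, m in fields[drift].items()}
                sim[section] = cls(**fields)
        kwargs["sim_overrides"] = sim
    return kwargs


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj


def write_events(events: pd.DataFrame, path: Path) -> None:
    out = events.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out["provenance"] = out["provenance"].map(";".join)
    out[["patient_id", "event_date", "severity", "provenance", "algorithm_id"]].to_csv(
        path, index=False)


def write_ground_truth(truth: GroundTruth, directory: Path) -> None:
    ev = truth.events.copy()
    ev["event_date"] = ev["event_date"].dt.strftime("%Y-%m-%d")
    ev.to_csv(directory / "ground_truth_events.csv", index=False)
    pat = truth.patients.copy()
    for col in ("index_date", "followup_end"):
        pat[col] = pd.to_datetime(pat[col]).dt.strftime("%Y-%m-%d")
    pat.to_csv(directory / "ground_truth_patients.csv", index=False)


def run_study(
    out_dir: str | Path,
    scenario: str = "validated-mix",
    n_patients: int = 2000,
    seed: int = 0,
    bundle: EmrBundle | None = None,
    bundle_dir: str | Path | None = None,
    cohort_spec: CohortSpec | None = None,
    algorithm_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    filter_mode: str = "as_defined",
    tolerance_days: int = 0,
    n_followup_years: int = 5,
    write_bundle_files: bool = True,
    sim_overrides: dict | None = None,
) -> dict:
    """Run the full study pipeline and write all result tables.

    Input is either a pre-built/previously written bundle (``bundle`` /
    ``bundle_dir``) or, by default, a fresh simulation of ``scenario`` with
    ``n_patients`` and ``seed``.  Returns the manifest dictionary (also
    written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if bundle is None and bundle_dir is not None:
        bundle = read_bundle(bundle_dir)
        config_desc = {"bundle_dir": str(bundle_dir)}
    elif bundle is None:
        config = scenario_config(scenario, n_patients, seed, **(sim_overrides or {}))
        bundle, truth = simulate_cohort(config)
        config_desc = {"scenario": scenario, **_jsonable(config)}
        if write_bundle_files:
            write_bundle(bundle, out / "bundle")
            write_ground_truth(truth, out)
    else:
        config_desc = {"bundle": "in-memory"}

    spec = cohort_spec or CohortSpec()
    cohort, attrition = build_cohort(bundle, spec)
    cohort_out = cohort.copy()
    for col in ("index_date", "followup_end", "registration_start"):
        cohort_out[col] = pd.to_datetime(cohort_out[col]).dt.strftime("%Y-%m-%d")
    cohort_out.to_csv(out / "cohort.csv", index=False)
    attrition.to_csv(out / "attrition.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config_desc,
        "config_hash": hashlib.sha256(json.dumps(
            [config_desc, _jsonable(spec), filter_mode, list(algorithm_ids)],
            sort_keys=True, default=str).encode()).hexdigest()[:16],
        "filter_mode": filter_mode,
        "stages": {"patients": int(bundle.n_patients), "cohort": int(len(cohort))},
    }

    freq_rows, rate_rows, cal_frames, char_frames = [], [], [], []
    events_by_alg: dict[int, pd.DataFrame] = {}
    for aid in algorithm_ids:
        events = run_algorithm(bundle, cohort, aid, filter_mode=filter_mode)
        events_by_alg[aid] = events
        write_events(events, out / f"events_alg{aid}.csv")
        manifest["stages"][f"events_alg{aid}"] = int(len(events))

        base = baseline_frequent_proportion(events, cohort)
        freq_rows.append({"algorithm_id": aid, **base.to_dict()})

        # Baseline characteristics of the frequent-exacerbator stratum.
        flags = frequent_flags(events, cohort, "baseline")
        if flags.any():
            chars = describe_cohort(cohort.loc[flags.to_numpy()])
            chars.insert(0, "algorithm_id", aid)
            char_frames.append(chars)
        annual = annual_frequent_proportions(events, cohort, n_followup_years)
        for _, r in annual.iterrows():
            freq_rows.append({"algorithm_id": aid, **r.to_dict()})

        for mode in ("none", "full"):
            ev_mode = run_algorithm(bundle, cohort, aid, filter_mode=mode)
            rr = followup_rate(ev_mode, cohort)
            rate_rows.append({"algorithm_id": aid, "filter_mode": mode,
                              **dataclasses.asdict(rr)})
        cal = calendar_year_rates(events, cohort)
        cal.insert(0, "algorithm_id", aid)
        cal_frames.append(cal)

    pd.DataFrame(freq_rows).to_csv(out / "frequent_exacerbators.csv", index=False)
    if char_frames:
        pd.concat(char_frames, ignore_index=True).to_csv(
            out / "baseline_characteristics.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
    pd.concat(cal_frames, ignore_index=True).to_csv(out / "calendar_rates.csv", index=False)

    cox = hr_across_algorithms(bundle, cohort, filter_mode, algorithm_ids)
    cox.to_csv(out / "cox_results.csv", index=False)

    ae = ae_without_admission(bundle, cohort)
    ae.to_frame().T.to_csv(out / "ae_sensitivity.csv", index=False)

    if truth is not None:
        conc_rows = []
        member_ids = set(cohort["patient_id"])
        tru = truth.events.merge(cohort[["patient_id", "index_date", "followup_end"]],
                                 on="patient_id")
        tru = tru[(tru["event_date"] >= tru["index_date"])
                  & (tru["event_date"] <= tru["followup_end"])]
        for aid in algorithm_ids:
            ev = events_by_alg[aid]
            ev = ev[(ev["event_date"] >= ev["index_date"])
                    & (ev["patient_id"].isin(member_ids))]
            res = concordance(ev, tru, aid, tolerance_days)
            conc_rows.append(dataclasses.asdict(res))
        pd.DataFrame(conc_rows).to_csv(out / "concordance.csv", index=False)

    agree_rows = []
    ids = list(algorithm_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = classification_agreement(events_by_alg[a], events_by_alg[b],
                                           cohort, "baseline", a, b)
            agree_rows.append(dataclasses.asdict(res))
    if agree_rows:
        pd.DataFrame(agree_rows).to_csv(out / "agreement.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
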