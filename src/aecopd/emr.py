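"""Data model for coded longitudinal EMR tables and codelists.

The package works on five delimited-text tables — patients, primary-care
clinical events, prescriptions, hospital episodes (one row per positioned
ICD-10 diagnosis) and emergency-department (A&E) attendances — plus a
codelist registry mapping raw codes to semantic categories (exacerbation,
LRTI, symptom, corticosteroid, ...).  All downstream logic is purely
category-driven: the primary-care coding system itself is opaque, only
codelist membership matters.  ICD-10 codes are the one exception and are
matched on their 4-character undotted form (``J44.1`` ≡ ``J441``).

Dates are held at day resolution (ISO-8601 on disk); all interval
arithmetic downstream is in whole days.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "AE_CATEGORIES",
    "Codelist",
    "CodelistRegistry",
    "EmrBundle",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "categorize_codes",
    "normalize_icd10",
]

#: Semantic categories a primary-care code may belong to.
CATEGORIES = (
    "copd_diagnosis",
    "exacerbation",
    "lrti",
    "cough",
    "breathlessness",
    "sputum",
    "annual_review",
    "consultation",
    "heart_failure",
    "ocs",
    "resp_antibiotic",
    "smoking_current",
    "smoking_ex",
    "smoking_never",
)

#: Allowed A&E diagnosis categories.
AE_CATEGORIES = ("resp_nonasthma", "bronchial_asthma", "other")

PATIENT_COLUMNS = (
    "patient_id",
    "birth_date",
    "sex",
    "region",
    "imd_quintile",
    "registration_start",
    "registration_end",
    "death_date",
    "linkage_eligible",
)
CLINICAL_COLUMNS = ("patient_id", "event_date", "code")
PRESCRIPTION_COLUMNS = ("patient_id", "issue_date", "code", "duration_days")
HOSPITAL_COLUMNS = ("patient_id", "admission_date", "episode_id", "icd10_code", "position")
AE_COLUMNS = ("patient_id", "attendance_date", "diagnosis_category")

_TABLE_FILES = {
    "patients": "patients.csv",
    "clinical_events": "clinical_events.csv",
    "prescriptions": "prescriptions.csv",
    "hospital_episodes": "hospital_episodes.csv",
    "ae_attendances": "ae_attendances.csv",
}
_CODELIST_FILE = "codelists.csv"

_DATE_COLUMNS = {
    "patients": ("birth_date", "registration_start", "registration_end", "death_date"),
    "clinical_events": ("event_date",),
    "prescriptions": ("issue_date",),
    "hospital_episodes": ("admission_date",),
    "ae_attendances": ("attendance_date",),
}


class BundleValidationError(ValueError):
    """A bundle (or a file being read into one) violates its invariants."""


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code to its undotted 4-character form.

    ``"J44.1"`` and ``"J441"`` both map to ``"J441"``; codes longer than four
    characters after removing the dot are truncated (sub-classification
    characters are not used by any rule here).
    """
    return str(code).strip().upper().replace(".", "")[:4]


@dataclasses.dataclass(frozen=True)
class Codelist:
    """A set of raw codes carrying one semantic category."""

    category: str
    coding_system: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise BundleValidationError(f"unknown codelist category: {self.category!r}")


class CodelistRegistry:
    """Collection of codelists, at most one per category, with a reverse map.

    The reverse lookup (:meth:`categories_of`) returns the set of categories a
    code belongs to; a code may legitimately appear in several lists (e.g. an
    exacerbation code recorded at an annual review).
    """

    def __init__(self, codelists: list[Codelist] | None = None) -> None:
        self._lists: dict[str, Codelist] = {}
        self._reverse: dict[str, set[str]] = {}
        for cl in codelists or []:
            self.add(cl)

    def add(self, codelist: Codelist) -> None:
        if codelist.category in self._lists:
            raise BundleValidationError(
                f"duplicate codelist for category {codelist.category!r}"
            )
        self._lists[codelist.category] = codelist
        for code in codelist.codes:
            self._reverse.setdefault(code.strip(), set()).add(codelist.category)

    def codes(self, category: str) -> frozenset[str]:
        if category not in self._lists:
            return frozenset()
        return self._lists[category].codes

    def categories_of(self, code: str) -> frozenset[str]:
        return frozenset(self._reverse.get(str(code).strip(), ()))

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self._lists))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodelistRegistry):
            return NotImplemented
        return self._lists == other._lists

    def __len__(self) -> int:
        return len(self._lists)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cl.category, cl.coding_system, code)
            for cl in self._lists.values()
            for code in sorted(cl.codes)
        ]
        return pd.DataFrame(rows, columns=["category", "coding_system", "code"]).sort_values(
            ["category", "code"], ignore_index=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodelistRegistry":
        reg = cls()
        if frame.empty:
            return reg
        for (category, system), grp in frame.groupby(["category", "coding_system"], sort=True):
            codes = [str(c).strip() for c in grp["code"]]
            if len(codes) != len(set(codes)):
                raise BundleValidationError(
                    f"duplicate codes within codelist {category!r}"
                )
            reg.add(Codelist(str(category), str(system), frozenset(codes)))
        return reg


@dataclasses.dataclass
class EmrBundle:
    """The five raw record tables plus the codelist registry.

    Tables are pandas DataFrames with fixed column schemas and
    ``datetime64[ns]`` date columns.  ``validate`` enforces referential
    integrity (every event's patient exists) and the per-table invariants.
    """

    patients: pd.DataFrame
    clinical_events: pd.DataFrame
    prescriptions: pd.DataFrame
    hospital_episodes: pd.DataFrame
    ae_attendances: pd.DataFrame
    codelists: CodelistRegistry

    def validate(self) -> "EmrBundle":
        errors: list[str] = []
        for name, cols in (
            ("patients", PATIENT_COLUMNS),
            ("clinical_events", CLINICAL_COLUMNS),
            ("prescriptions", PRESCRIPTION_COLUMNS),
            ("hospital_episodes", HOSPITAL_COLUMNS),
            ("ae_attendances", AE_COLUMNS),
        ):
            frame = getattr(self, name)
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                errors.append(f"{name}: missing columns {missing}")
        if errors:
            raise BundleValidationError("; ".join(errors))

        pat = self.patients
        if pat["patient_id"].duplicated().any():
            errors.append("patients: duplicate patient_id")
        known = set(pat["patient_id"])
        for name, frame in (
            ("clinical_events", self.clinical_events),
            ("prescriptions", self.prescriptions),
            ("hospital_episodes", self.hospital_episodes),
            ("ae_attendances", self.ae_attendances),
        ):
            unknown = set(frame["patient_id"]) - known
            if unknown:
                errors.append(f"{name}: unknown patient_id(s) e.g. {sorted(unknown)[:3]}")

        both = pat["registration_end"].notna()
        bad = pat.loc[both & (pat["registration_start"] >= pat["registration_end"])]
        if len(bad):
            errors.append(
                f"patients: registration_start >= registration_end for {list(bad['patient_id'][:3])}"
            )
        died = pat["death_date"].notna()
        bad = pat.loc[died & (pat["death_date"] < pat["registration_start"])]
        if len(bad):
            errors.append(f"patients: death before registration for {list(bad['patient_id'][:3])}")
        imd = pd.to_numeric(pat["imd_quintile"], errors="coerce")
        if imd.isna().any() or not imd.isin([1, 2, 3, 4, 5]).all():
            errors.append("patients: imd_quintile outside 1..5")
        if not pat["sex"].isin(["male", "female"]).all():
            errors.append("patients: sex outside {male, female}")

        dur = self.prescriptions["duration_days"]
        if (pd.to_numeric(dur, errors="coerce").dropna() < 0).any():
            errors.append("prescriptions: negative duration_days")

        hosp = self.hospital_episodes
        if len(hosp):
            pos = pd.to_numeric(hosp["position"], errors="coerce")
            if pos.isna().any() or (pos < 1).any():
                errors.append("hospital_episodes: positions must be integers >= 1")
            else:
                by_ep = hosp.groupby("episode_id")["position"]
                if (by_ep.nunique() != by_ep.size()).any():
                    errors.append("hospital_episodes: duplicate positions within an episode")
                if (by_ep.min() != 1).any():
                    errors.append("hospital_episodes: episode without a primary (position 1) diagnosis")

        if not self.ae_attendances["diagnosis_category"].isin(AE_CATEGORIES).all():
            errors.append("ae_attendances: unknown diagnosis_category")

        if errors:
            raise BundleValidationError("; ".join(errors))
        return self

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def equals(self, other: "EmrBundle") -> bool:
        """Content equality up to row order (rows compared in canonical order)."""
        if self.codelists != other.codelists:
            return False
        for name in _TABLE_FILES:
            a = _canonical(getattr(self, name), name)
            b = _canonical(getattr(other, name), name)
            if not a.equals(b):
                return False
        return True


def _canonical(frame: pd.DataFrame, table: str) -> pd.DataFrame:
    cols = {
        "patients": list(PATIENT_COLUMNS),
        "clinical_events": list(CLINICAL_COLUMNS),
        "prescriptions": list(PRESCRIPTION_COLUMNS),
        "hospital_episodes": list(HOSPITAL_COLUMNS),
        "ae_attendances": list(AE_COLUMNS),
    }[table]
    out = frame[cols].copy()
    for c in _DATE_COLUMNS[table]:
        out[c] = pd.to_datetime(out[c])
    return out.sort_values(cols, ignore_index=True)


def _parse_dates(frame: pd.DataFrame, table: str, path: Path) -> pd.DataFrame:
    """Parse declared date columns, reporting the file and 1-based data line of
    the first malformed value."""
    frame = frame.copy()
    for col in _DATE_COLUMNS[table]:
        raw = frame[col].astype("string").str.strip()
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw != "")
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise BundleValidationError(
                f"{path.name}: unparseable date {raw.iloc[idx]!r} in column "
                f"{col!r} at line {idx + 2}"
            )
        frame[col] = parsed
    return frame


def read_bundle(directory: str | Path) -> EmrBundle:
    """Read and validate a bundle from a directory of delimited text tables.

    Expects ``patients.csv``, ``clinical_events.csv``, ``prescriptions.csv``,
    ``hospital_episodes.csv``, ``ae_attendances.csv`` and ``codelists.csv``
    (long format: category, coding_system, code).  Missing tables and
    malformed dates are fatal, with the offending file (and line) named.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for table, filename in _TABLE_FILES.items():
        path = directory / filename
        if not path.exists():
            raise BundleValidationError(f"missing table file: {path}")
        frame = pd.read_csv(path, dtype={"patient_id": str, "code": str, "icd10_code": str})
        missing = [c for c in {
            "patients": PATIENT_COLUMNS,
            "clinical_events": CLINICAL_COLUMNS,
            "prescriptions": PRESCRIPTION_COLUMNS,
            "hospital_episodes": HOSPITAL_COLUMNS,
            "ae_attendances": AE_COLUMNS,
        }[table] if c not in frame.columns]
        if missing:
            raise BundleValidationError(f"{path.name}: missing columns {missing}")
        frames[table] = _parse_dates(frame, table, path)

    cl_path = directory / _CODELIST_FILE
    if not cl_path.exists():
        raise BundleValidationError(f"missing codelist file: {cl_path}")
    registry = CodelistRegistry.from_frame(pd.read_csv(cl_path, dtype=str))

    pats = frames["patients"]
    pats["linkage_eligible"] = pats["linkage_eligible"].astype(bool)
    pats["imd_quintile"] = pats["imd_quintile"].astype(int)
    hosp = frames["hospital_episodes"]
    if len(hosp):
        hosp["position"] = hosp["position"].astype(int)
        hosp["episode_id"] = hosp["episode_id"].astype(int)
    return EmrBundle(
        patients=pats,
        clinical_events=frames["clinical_events"],
        prescriptions=frames["prescriptions"],
        hospital_episodes=frames["hospital_episodes"],
        ae_attendances=frames["ae_attendances"],
        codelists=registry,
    ).validate()


def write_bundle(bundle: EmrBundle, directory: str | Path) -> list[Path]:
    """Write a validated bundle as the six CSV files, deterministically.

    Rows are sorted by patient_id then date (then remaining columns) so two
    writes of equal bundles are byte-identical; dates are ISO-8601.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for table, filename in _TABLE_FILES.items():
        frame = _canonical(getattr(bundle, table), table).copy()
        for c in _DATE_COLUMNS[table]:
            frame[c] = frame[c].dt.strftime("%Y-%m-%d")
        path = directory / filename
        frame.to_csv(path, index=False)
        written.append(path)
    path = directory / _CODELIST_FILE
    bundle.codelists.to_frame().to_csv(path, index=False)
    written.append(path)
    return written


def categorize_codes(bundle: EmrBundle) -> EmrBundle:
    """Annotate clinical events and prescriptions with codelist categories.

    Adds a ``categories`` column holding a sorted tuple of the categories the
    record's code belongs to, or ``("uncategorized",)`` when it belongs to
    none.  Record counts and dates are never changed; uncategorized records
    are retained.
    """
    reg = bundle.codelists

    def annotate(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        codes = frame["code"].astype(str).str.strip()
        uniq = {c: tuple(sorted(reg.categories_of(c))) or ("uncategorized",) for c in codes.unique()}
        frame["categories"] = codes.map(uniq)
        return frame

    return dataclasses.replace(
        bundle,
        clinical_events=annotate(bundle.clinical_events),
        prescriptions=annotate(bundle.prescriptions),
    )


def records_in_category(frame: pd.DataFrame, category: str) -> pd.DataFrame:
    """Rows of a categorized table whose code carries ``category``."""
    if "categories" not in frame.columns:
        raise ValueError("table is not categorized; call categorize_codes first")
    mask = frame["categories"].map(lambda cats: category in cats)
    return frame.loc[mask]


def empty_bundle(codelists: CodelistRegistry | None = None) -> EmrBundle:
    """A structurally valid bundle with zero patients (useful as a template)."""
    def make(cols: tuple[str, ...], dates: tuple[str, ...]) -> pd.DataFrame:
        frame = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in dates:
            frame[c] = pd.Series(dtype="datetime64[ns]")
        return frame

    return EmrBundle(
        patients=make(PATIENT_COLUMNS, _DATE_COLUMNS["patients"]),
        clinical_events=make(CLINICAL_COLUMNS, _DATE_COLUMNS["clinical_events"]),
        prescriptions=make(PRESCRIPTION_COLUMNS, _DATE_COLUMNS["prescriptions"]),
        hospital_episodes=make(HOSPITAL_COLUMNS, _DATE_COLUMNS["hospital_episodes"]),
        ae_attendances=make(AE_COLUMNS, _DATE_COLUMNS["ae_attendances"]),
        codelists=codelists or CodelistRegistry(),
    )
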