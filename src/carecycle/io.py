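"""Read and write cohort tables, element matrices, and estimate tables.

All interchange is comma-separated UTF-8 text with a mandatory header row
and ISO-8601 (YYYY-MM-DD) dates.  A cohort is five tables joined on
``patient_id``: patients (demographics and stratum), diagnoses (ICD
codes), labs, medications, and procedures.  Loading is order-insensitive:
tables are canonically sorted, so shuffled inputs produce identical
datasets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import numpy as np
import pandas as pd

from .spec import normalize_code

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDataset",
    "PatientRecord",
    "CohortIOError",
    "read_cohort",
    "write_cohort",
    "write_element_matrix",
    "read_element_matrix",
    "write_estimates",
    "estimates_to_json",
]

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "age_years", "sex", "stratum"],
    "diagnoses": ["patient_id", "code_system", "code", "date"],
    "labs": ["patient_id", "analyte", "value", "units", "date"],
    "medications": ["patient_id", "drug_class", "date"],
    "procedures": ["patient_id", "code", "date", "is_amputation"],
}

# optional columns preserved when present
OPTIONAL_COLUMNS: dict[str, list[str]] = {
    "medications": ["route"],
    "procedures": ["body_site"],
    "diagnoses": ["body_site"],
}

_SORT_KEYS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "diagnoses": ["patient_id", "date", "code_system", "code"],
    "labs": ["patient_id", "date", "analyte", "value"],
    "medications": ["patient_id", "date", "drug_class"],
    "procedures": ["patient_id", "date", "code"],
}


class CohortIOError(ValueError):
    """Raised for malformed cohort tables (missing columns, bad dates, ...)."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics plus dated clinical events."""

    patient_id: str
    age_years: float
    sex: str
    stratum: str
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    procedures: pd.DataFrame


@dataclass
class CohortDataset:
    """A longitudinal cohort as five canonical tables joined on patient_id."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    procedures: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def iter_patients(self) -> Iterator[PatientRecord]:
        groups = {
            name: dict(tuple(self.table(name).groupby("patient_id", sort=False)))
            for name in ("diagnoses", "labs", "medications", "procedures")
        }
        empties = {name: self.table(name).iloc[0:0] for name in groups}
        for row in self.patients.itertuples(index=False):
            yield PatientRecord(
                patient_id=row.patient_id,
                age_years=row.age_years,
                sex=row.sex,
                stratum=row.stratum,
                diagnoses=groups["diagnoses"].get(row.patient_id, empties["diagnoses"]),
                labs=groups["labs"].get(row.patient_id, empties["labs"]),
                medications=groups["medications"].get(row.patient_id, empties["medications"]),
                procedures=groups["procedures"].get(row.patient_id, empties["procedures"]),
            )

    def patient(self, patient_id: str) -> PatientRecord:
        sub = self.patients[self.patients["patient_id"] == patient_id]
        if sub.empty:
            raise KeyError(patient_id)
        row = sub.iloc[0]
        return PatientRecord(
            patient_id=row["patient_id"],
            age_years=row["age_years"],
            sex=row["sex"],
            stratum=row["stratum"],
            **{
                name: self.table(name)[self.table(name)["patient_id"] == patient_id]
                for name in ("diagnoses", "labs", "medications", "procedures")
            },
        )

    def equals(self, other: "CohortDataset") -> bool:
        return all(
            self.table(n).reset_index(drop=True).equals(other.table(n).reset_index(drop=True))
            for n in TABLE_COLUMNS
        )


def _require_columns(df: pd.DataFrame, table: str, path: str) -> None:
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise CohortIOError(
            f"{table} table {path!r} is missing required column(s): {', '.join(missing)}"
        )


def _parse_dates(df: pd.DataFrame, table: str, path: str) -> pd.DataFrame:
    if "date" not in df.columns or df.empty:
        return df
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortIOError(
            f"unparseable date {df['date'].iloc[row]!r} in {table} table {path!r} "
            f"(data row {row + 1}); dates must be YYYY-MM-DD"
        )
    out = df.copy()
    out["date"] = parsed
    return out


def _canonical_sort(df: pd.DataFrame, table: str) -> pd.DataFrame:
    keys = [k for k in _SORT_KEYS[table] if k in df.columns]
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def read_cohort(
    patients_path,
    diagnoses_path,
    labs_path,
    medications_path,
    procedures_path,
) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from the five cohort CSV tables.

    ICD and procedure codes are normalized (dots stripped, upper-cased);
    event rows whose patient_id is absent from the patients table are
    dropped with a logged count; duplicate patient ids are an error.
    """
    paths = {
        "patients": patients_path,
        "diagnoses": diagnoses_path,
        "labs": labs_path,
        "medications": medications_path,
        "procedures": procedures_path,
    }
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        df = pd.read_csv(path, dtype={"patient_id": str})
        _require_columns(df, name, str(path))
        keep = TABLE_COLUMNS[name] + [
            c for c in OPTIONAL_COLUMNS.get(name, []) if c in df.columns
        ]
        df = df[keep]
        tables[name] = _parse_dates(df, name, str(path))

    pats = tables["patients"]
    dup = pats["patient_id"].duplicated()
    if dup.any():
        raise CohortIOError(
            f"duplicate patient_id in patients table: {pats.loc[dup, 'patient_id'].iloc[0]!r}"
        )
    pats = pats.assign(age_years=pd.to_numeric(pats["age_years"], errors="raise"))

    known = set(pats["patient_id"])
    for name in ("diagnoses", "labs", "medications", "procedures"):
        df = tables[name]
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            logger.warning("dropping %d orphan row(s) from %s table", int(orphan.sum()), name)
            df = df[~orphan]
        tables[name] = df

    dx = tables["diagnoses"].copy()
    dx["code"] = dx["code"].map(normalize_code)
    dx["code_system"] = dx["code_system"].astype(str).str.strip().str.upper().str.replace(
        "ICD-", "ICD", regex=False
    )
    tables["diagnoses"] = dx
    pr = tables["procedures"].copy()
    pr["code"] = pr["code"].map(normalize_code)
    pr["is_amputation"] = pr["is_amputation"].astype(int).astype(bool)
    tables["procedures"] = pr
    labs = tables["labs"].copy()
    labs["value"] = pd.to_numeric(labs["value"], errors="raise")
    labs["analyte"] = labs["analyte"].astype(str).str.strip().str.lower()
    tables["labs"] = labs
    meds = tables["medications"].copy()
    meds["drug_class"] = meds["drug_class"].astype(str).str.strip().str.lower()
    tables["medications"] = meds

    tables = {name: _canonical_sort(df, name) for name, df in tables.items()}
    return CohortDataset(
        patients=tables["patients"],
        diagnoses=tables["diagnoses"],
        labs=tables["labs"],
        medications=tables["medications"],
        procedures=tables["procedures"],
        provenance={"source": {n: str(p) for n, p in paths.items()}},
    )


def write_cohort(cohort: CohortDataset, out_dir) -> dict[str, str]:
    """Write the five cohort tables as CSVs into ``out_dir``; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in TABLE_COLUMNS:
        df = cohort.table(name).copy()
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
        if "is_amputation" in df.columns:
            df["is_amputation"] = df["is_amputation"].astype(int)
        path = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_cohort_dir(cohort_dir) -> CohortDataset:
    """Read a cohort from a directory holding the five standard CSVs."""
    return read_cohort(*(os.path.join(cohort_dir, f"{n}.csv") for n in TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# Element matrix
# ---------------------------------------------------------------------------

_MATRIX_META = ["patient_id", "stratum", "age_years", "sex"]


def write_element_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an element matrix: one row per patient, 0/1 element columns in cycle order."""
    if matrix.empty:
        raise CohortIOError("element matrix is empty; nothing to write")
    element_cols = [c for c in matrix.columns if c not in _MATRIX_META]
    out = matrix[_MATRIX_META + element_cols].copy()
    for c in element_cols:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_element_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _MATRIX_META if c not in df.columns]
    if missing:
        raise CohortIOError(f"element matrix {path!r} missing column(s): {', '.join(missing)}")
    for c in df.columns:
        if c not in _MATRIX_META:
            df[c] = df[c].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Estimates
# ---------------------------------------------------------------------------

OR_PRECISION = 6  # decimal places for ORs / CI bounds / p-values in CSV output


def _estimates_frame(est) -> pd.DataFrame:
    rows = []
    for r in est.results:
        rows.append(
            {
                "stratum": r.stratum,
                "element": r.element_id,
                "or": np.round(r.odds_ratio, OR_PRECISION),
                "ci_low": np.round(r.ci_low, OR_PRECISION),
                "ci_high": np.round(r.ci_high, OR_PRECISION),
                "p_value": np.round(r.p_value, OR_PRECISION),
                "significant": int(bool(r.significant)),
                "is_reference": int(bool(r.is_reference)),
                "n_events_stratum": r.n_events_stratum,
                "degenerate": int(bool(r.degenerate)),
            }
        )
    return pd.DataFrame(rows)


def write_estimates(est, path) -> None:
    """Write a long-form estimates table (stratum, element, OR, CI, p, flags)."""
    if not est.results:
        raise CohortIOError("no estimates to write")
    _estimates_frame(est).to_csv(path, index=False, lineterminator="\n")


def estimates_to_json(est, path: Optional[str] = None) -> str:
    """JSON export of estimates with full model metadata for programmatic use."""
    payload = {
        "spec_name": est.spec_name,
        "reference_stratum": est.reference_stratum,
        "covariates": list(est.covariates),
        "alpha": est.alpha,
        "n_per_model": est.n_per_model,
        "results": [
            {
                k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in dataclasses.asdict(r).items()
            }
            for r in est.results
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True, default=float)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def estimates_from_json(path):
    """Rebuild a ContinuumEstimates object from its JSON export."""
    from .estimation import ContinuumEstimates, ORResult

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    nan = float("nan")
    results = [
        ORResult(**{k: (nan if v is None else v) for k, v in r.items()})
        for r in payload["results"]
    ]
    return ContinuumEstimates(
        spec_name=payload["spec_name"],
        reference_stratum=payload["reference_stratum"],
        results=results,
        covariates=tuple(payload["covariates"]),
        alpha=payload["alpha"],
        n_per_model=payload.get("n_per_model", {}),
    )
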