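"""Rule-based phenotyping: from coded patient records to a boolean element matrix.

Each element of the continuum is decided by its :class:`~carecycle.spec.ElementRule`:
a disjunction of code-prefix, lab-threshold, medication-class and procedure
criteria for atomic elements, or an at-least-k-of-n combination of other
elements for composites.  Dated criteria may be restricted to a window
around the patient's *index infection date* — the earliest diagnosis of any
of the spec's qualifying infections — which also defines cohort inclusion:
patients with no qualifying infection diagnosis are excluded before the
matrix is derived.

Evaluation is deterministic: the matrix is a pure function of the cohort
and the spec.  Atomic elements are evaluated first, composites second in a
single topological pass.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CohortDataset, PatientRecord
from .spec import (
    CodeCriterion,
    ContinuumSpec,
    ElementRule,
    TimeWindow,
    default_msk_spec,
    validate_spec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "match_code",
    "index_infection_date",
    "within_window",
    "evaluate_rule",
    "derive_element_matrix",
    "ContinuumPhenotyper",
    "MissingAnchorError",
    "PhenotypingError",
]


class PhenotypingError(ValueError):
    pass


class MissingAnchorError(PhenotypingError):
    """Patient has no qualifying infection diagnosis to anchor windows on."""


def match_code(code: str, code_system: str, criterion: CodeCriterion) -> bool:
    """True iff ``code`` (already normalized) starts with any of the criterion's
    prefixes *and* belongs to the criterion's code system."""
    if str(code_system).upper() != criterion.code_system.upper():
        return False
    return str(code).startswith(tuple(criterion.prefixes))


def within_window(event_date, anchor, window: TimeWindow) -> bool:
    """True iff the event falls in [anchor+start, anchor+end], bounds inclusive."""
    event = pd.Timestamp(event_date)
    anchor = pd.Timestamp(anchor)
    lo = anchor + pd.Timedelta(days=window.start_offset_days)
    hi = anchor + pd.Timedelta(days=window.end_offset_days)
    return bool(lo <= event <= hi)


def _infection_code_criteria(spec: ContinuumSpec) -> list[CodeCriterion]:
    crits: list[CodeCriterion] = []
    for eid in spec.infection_elements:
        crits.extend(spec.element(eid).code_criteria)
    return crits


def _code_mask(dx: pd.DataFrame, criteria) -> pd.Series:
    """Row mask over a diagnoses table for a set of code criteria."""
    if dx.empty or not criteria:
        return pd.Series(False, index=dx.index)
    mask = pd.Series(False, index=dx.index)
    systems = dx["code_system"].astype(str).str.upper()
    codes = dx["code"].astype(str)
    for c in criteria:
        mask |= (systems == c.code_system.upper()) & codes.str.startswith(tuple(c.prefixes))
    return mask


def _anchor_series(cohort: CohortDataset, spec: ContinuumSpec) -> pd.Series:
    """Index infection date per patient_id (earliest qualifying diagnosis)."""
    crits = _infection_code_criteria(spec)
    dx = cohort.diagnoses
    hits = dx[_code_mask(dx, crits)]
    if hits.empty:
        return pd.Series(dtype="datetime64[ns]")
    return hits.groupby("patient_id")["date"].min()


def index_infection_date(patient: PatientRecord, spec: ContinuumSpec):
    """Earliest musculoskeletal-infection diagnosis date for one patient.

    Raises :class:`MissingAnchorError` when the patient has no qualifying
    diagnosis (such patients fail cohort inclusion).
    """
    dx = patient.diagnoses
    hits = dx[_code_mask(dx, _infection_code_criteria(spec))]
    if hits.empty:
        raise MissingAnchorError(
            f"patient {patient.patient_id!r} has no qualifying infection diagnosis"
        )
    return hits["date"].min()


# ---------------------------------------------------------------------------
# Vectorized element evaluation over a whole cohort
# ---------------------------------------------------------------------------

def _window_filter(events: pd.DataFrame, anchors: pd.Series, window: TimeWindow) -> pd.DataFrame:
    """Keep dated event rows inside each patient's anchored window."""
    if events.empty:
        return events
    a = events["patient_id"].map(anchors)
    lo = a + pd.Timedelta(days=window.start_offset_days)
    hi = a + pd.Timedelta(days=window.end_offset_days)
    keep = a.notna() & (events["date"] >= lo) & (events["date"] <= hi)
    return events[keep]


def _atomic_true_ids(cohort: CohortDataset, rule: ElementRule, anchors: pd.Series) -> set:
    """Patient ids satisfying an atomic rule (disjunction over criteria)."""
    true_ids: set = set()

    if rule.code_criteria:
        dx = cohort.diagnoses
        if rule.window is not None:
            dx = _window_filter(dx, anchors, rule.window)
        hits = dx[_code_mask(dx, rule.code_criteria)]
        true_ids |= set(hits["patient_id"])

    for crit in rule.lab_criteria:
        labs = cohort.labs
        sub = labs[labs["analyte"] == crit.analyte.lower()]
        if crit.units and "units" in sub.columns:
            unit_ok = sub["units"].astype(str).str.strip() == crit.units
            skipped = int((~unit_ok).sum())
            if skipped:
                logger.warning(
                    "skipping %d %s lab row(s) with units other than %r",
                    skipped, crit.analyte, crit.units,
                )
            sub = sub[unit_ok]
        if sub.empty:
            continue
        if crit.aggregation == "any":
            # at least one individual result satisfying the comparator
            per_row = sub["value"] >= crit.threshold if crit.comparator == "ge" \
                else sub["value"] <= crit.threshold
            true_ids |= set(sub.loc[per_row, "patient_id"])
            continue
        agg = sub.groupby("patient_id")["value"].agg(crit.aggregation)
        ok = agg >= crit.threshold if crit.comparator == "ge" else agg <= crit.threshold
        true_ids |= set(agg.index[ok])

    for crit in rule.med_criteria:
        meds = cohort.medications
        sub = meds[meds["drug_class"].astype(str).str.startswith(tuple(crit.drug_class_prefixes))]
        if crit.systemic_only and "route" in sub.columns:
            sub = sub[sub["route"].astype(str).str.lower() != "topical"]
        true_ids |= set(sub["patient_id"])

    for crit in rule.procedure_criteria:
        pr = cohort.procedures
        if rule.window is not None:
            pr = _window_filter(pr, anchors, rule.window)
        if crit.amputation_only:
            pr = pr[pr["is_amputation"].astype(bool)]
        if crit.prefixes:
            pr = pr[pr["code"].astype(str).str.startswith(tuple(crit.prefixes))]
        true_ids |= set(pr["patient_id"])

    return true_ids


def evaluate_rule(
    patient: PatientRecord,
    rule: ElementRule,
    anchor=None,
    resolved: Optional[Mapping[str, bool]] = None,
) -> bool:
    """Evaluate one element rule for one patient.

    ``anchor`` (the index infection date) is required for windowed rules;
    ``resolved`` must hold the member values for composite rules.
    """
    if rule.is_composite:
        assert rule.composite is not None
        if resolved is None or any(
            m not in resolved for m in rule.composite.member_elements
        ):
            raise PhenotypingError(
                f"composite element {rule.element_id!r} has unresolved members"
            )
        n_true = sum(bool(resolved[m]) for m in rule.composite.member_elements)
        return n_true >= rule.composite.min_count

    if rule.window is not None and anchor is None:
        raise PhenotypingError(
            f"windowed element {rule.element_id!r} evaluated without an anchor date"
        )

    mini = CohortDataset(
        patients=pd.DataFrame(
            [{"patient_id": patient.patient_id, "age_years": patient.age_years,
              "sex": patient.sex, "stratum": patient.stratum}]
        ),
        diagnoses=patient.diagnoses,
        labs=patient.labs,
        medications=patient.medications,
        procedures=patient.procedures,
    )
    anchors = pd.Series({patient.patient_id: pd.Timestamp(anchor)} if anchor is not None else {},
                        dtype="datetime64[ns]")
    return patient.patient_id in _atomic_true_ids(mini, rule, anchors)


def derive_element_matrix(cohort: CohortDataset, spec: Optional[ContinuumSpec] = None) -> pd.DataFrame:
    """Derive the patients x elements boolean matrix for a cohort.

    Returns a DataFrame with columns ``patient_id, stratum, age_years, sex``
    followed by one boolean column per cycle element in cycle order
    (``df.attrs["element_ids"]``).  Patients without a qualifying infection
    diagnosis are excluded with a logged count.
    """
    spec = spec if spec is not None else default_msk_spec()
    report = validate_spec(spec)
    if not report.ok:
        raise PhenotypingError(f"invalid continuum spec:\n{report}")
    if cohort.n_patients == 0:
        raise PhenotypingError("cohort is empty")

    anchors = _anchor_series(cohort, spec)
    patients = cohort.patients
    included = patients["patient_id"].isin(anchors.index)
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.warning(
            "excluding %d patient(s) without a qualifying infection diagnosis", n_excluded
        )
    patients = patients[included].reset_index(drop=True)
    if patients.empty:
        raise PhenotypingError("no patient meets the infection inclusion criteria")

    results: dict[str, pd.Series] = {}
    pid = patients["patient_id"]
    for rule in spec.iter_elements():
        if rule.is_composite:
            continue
        true_ids = _atomic_true_ids(cohort, rule, anchors)
        results[rule.element_id] = pid.isin(true_ids)
    for rule in spec.iter_elements():
        if not rule.is_composite:
            continue
        assert rule.composite is not None
        missing = [m for m in rule.composite.member_elements if m not in results]
        if missing:
            raise PhenotypingError(
                f"composite {rule.element_id!r} references unresolved member(s) {missing}"
            )
        count = sum(results[m].astype(int) for m in rule.composite.member_elements)
        results[rule.element_id] = count >= rule.composite.min_count

    matrix = patients[["patient_id", "stratum", "age_years", "sex"]].copy()
    for eid in spec.element_ids:
        matrix[eid] = results[eid].to_numpy(dtype=bool)
        logger.info("element %s: %d/%d true", eid, int(matrix[eid].sum()), len(matrix))
    matrix.attrs["element_ids"] = list(spec.element_ids)
    matrix.attrs["spec_name"] = spec.name
    return matrix


class ContinuumPhenotyper(BaseEstimator, TransformerMixin):
    """Transformer from a :class:`~carecycle.io.CohortDataset` to an element matrix.

    Stateless apart from the continuum spec: ``fit`` validates the spec and
    ``transform`` derives the boolean element matrix.

    Parameters
    ----------
    spec : ContinuumSpec, optional
        Continuum model; the default musculoskeletal-infection model when
        omitted.
    """

    def __init__(self, spec: Optional[ContinuumSpec] = None):
        self.spec = spec

    def fit(self, X: Optional[CohortDataset] = None, y=None) -> "ContinuumPhenotyper":
        spec = self.spec if self.spec is not None else default_msk_spec()
        report = validate_spec(spec)
        if not report.ok:
            raise PhenotypingError(f"invalid continuum spec:\n{report}")
        self.spec_ = spec
        self.element_ids_ = list(spec.element_ids)
        return self

    def transform(self, X: CohortDataset) -> pd.DataFrame:
        if not hasattr(self, "spec_"):
            self.fit()
        return derive_element_matrix(X, self.spec_)
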