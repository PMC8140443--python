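"""Rule evaluation and element-matrix derivation."""

import hashlib

import pandas as pd
import pytest

import carecycle as cc
from carecycle.phenotyping import (
    MissingAnchorError,
    PhenotypingError,
    evaluate_rule,
    index_infection_date,
    match_code,
    within_window,
)
from carecycle.spec import CodeCriterion, TimeWindow


def _patient(pid="P1", diagnoses=(), labs=(), medications=(), procedures=(),
             stratum="A", age=50.0, sex="female"):
    def frame(rows, cols):
        df = pd.DataFrame(list(rows), columns=cols)
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"])
        return df

    return cc.PatientRecord(
        patient_id=pid, age_years=age, sex=sex, stratum=stratum,
        diagnoses=frame(diagnoses, ["patient_id", "code_system", "code", "date"]),
        labs=frame(labs, ["patient_id", "analyte", "value", "units", "date"]),
        medications=frame(medications, ["patient_id", "drug_class", "date"]),
        procedures=frame(procedures, ["patient_id", "code", "date", "is_amputation"]),
    )


@pytest.mark.parametrize(
    "code, system, crit_system, prefixes, expected",
    [
        ("E119", "ICD10", "ICD10", ("E11",), True),
        ("E10", "ICD10", "ICD10", ("E11",), False),
        ("E119", "ICD9", "ICD10", ("E11",), False),  # system separation
        ("25000", "ICD9", "ICD9", ("250",), True),
    ],
)
def test_match_code(code, system, crit_system, prefixes, expected):
    crit = CodeCriterion(crit_system, prefixes)
    assert match_code(code, system, crit) is expected


@pytest.mark.parametrize(
    "offset_days, expected", [(90, True), (91, False), (-1, False), (0, True)]
)
def test_window_bounds_inclusive(offset_days, expected):
    anchor = pd.Timestamp("2012-03-01")
    w = TimeWindow("index_infection_date", 0, 90)
    assert within_window(anchor + pd.Timedelta(days=offset_days), anchor, w) is expected


def test_index_infection_date_is_earliest(spec):
    p = _patient(diagnoses=[
        ("P1", "ICD10", "M869", "2012-05-01"),   # osteomyelitis, later
        ("P1", "ICD10", "M009", "2012-03-01"),   # septic arthritis, earliest
    ])
    assert index_infection_date(p, spec) == pd.Timestamp("2012-03-01")
    single = _patient(diagnoses=[("P1", "ICD10", "M869", "2013-07-04")])
    assert index_infection_date(single, spec) == pd.Timestamp("2013-07-04")


def test_index_infection_date_missing_anchor(spec):
    with pytest.raises(MissingAnchorError):
        index_infection_date(_patient(diagnoses=[("P1", "ICD10", "E119", "2012-01-01")]), spec)


def test_diabetes_rule_lab_threshold(spec):
    rule = spec.element("diabetes_mellitus")
    hit = _patient(labs=[("P1", "hba1c", 5.9, "%", "2012-01-01"),
                         ("P1", "hba1c", 6.5, "%", "2012-06-01")])
    miss = _patient(labs=[("P1", "hba1c", 6.4, "%", "2012-01-01")])
    assert evaluate_rule(hit, rule) is True   # max 6.5 meets the >= 6.5 threshold
    assert evaluate_rule(miss, rule) is False


def test_diabetes_rule_is_disjunction(spec):
    rule = spec.element("diabetes_mellitus")
    by_med = _patient(medications=[("P1", "antidiabetic_insulin", "2012-01-01")])
    by_code = _patient(diagnoses=[("P1", "ICD9", "25000", "2012-01-01")])
    assert evaluate_rule(by_med, rule) is True
    assert evaluate_rule(by_code, rule) is True


def test_composite_two_or_more(spec):
    rule = spec.element("multiple_infections")
    assert evaluate_rule(_patient(), rule, resolved={
        "osteomyelitis": True, "septic_arthritis": True, "infectious_myositis": False
    }) is True
    assert evaluate_rule(_patient(), rule, resolved={
        "osteomyelitis": True, "septic_arthritis": False, "infectious_myositis": False
    }) is False
    with pytest.raises(PhenotypingError, match="unresolved"):
        evaluate_rule(_patient(), rule, resolved={"osteomyelitis": True})


def test_windowed_rule_requires_anchor(spec):
    rule = spec.element("amputation")
    p = _patient(procedures=[("P1", "AMP01", "2012-02-01", True)])
    with pytest.raises(PhenotypingError, match="anchor"):
        evaluate_rule(p, rule, anchor=None)
    assert evaluate_rule(p, rule, anchor=pd.Timestamp("2012-01-15")) is True


def _mini_cohort(amputation_day: int) -> cc.CohortDataset:
    date = (pd.Timestamp("2012-03-01") + pd.Timedelta(days=amputation_day)).date()
    return cc.CohortDataset(
        patients=pd.DataFrame([{"patient_id": "P1", "age_years": 60.0,
                                "sex": "male", "stratum": "A"},
                               {"patient_id": "P2", "age_years": 55.0,
                                "sex": "female", "stratum": "B"}]),
        diagnoses=pd.DataFrame([
            {"patient_id": "P1", "code_system": "ICD10", "code": "M869",
             "date": pd.Timestamp("2012-03-01")},
            {"patient_id": "P2", "code_system": "ICD10", "code": "M009",
             "date": pd.Timestamp("2012-03-01")},
        ]),
        labs=pd.DataFrame(columns=["patient_id", "analyte", "value", "units", "date"]),
        medications=pd.DataFrame(columns=["patient_id", "drug_class", "date"]),
        procedures=pd.DataFrame([{"patient_id": "P1", "code": "AMP01",
                                  "date": pd.Timestamp(date), "is_amputation": True}]),
    )


def test_amputation_inside_window_sets_both_surgical_elements(spec):
    matrix = cc.derive_element_matrix(_mini_cohort(30), spec).set_index("patient_id")
    assert bool(matrix.loc["P1", "amputation"]) and bool(matrix.loc["P1", "surgical_procedure"])


def test_amputation_outside_window_excluded(spec):
    matrix = cc.derive_element_matrix(_mini_cohort(120), spec).set_index("patient_id")
    assert not bool(matrix.loc["P1", "amputation"])


def test_matrix_is_deterministic(spec, sim_cohort):
    _, cohort, _ = sim_cohort
    digests = set()
    for _ in range(2):
        m = cc.derive_element_matrix(cohort, spec)
        digests.add(hashlib.sha256(m.to_csv(index=False).encode()).hexdigest())
    assert len(digests) == 1


def test_adding_qualifying_event_is_monotone(spec):
    base = _mini_cohort(30)
    m0 = cc.derive_element_matrix(base, spec).set_index("patient_id")
    richer = _mini_cohort(30)
    richer.diagnoses = pd.concat([richer.diagnoses, pd.DataFrame([
        {"patient_id": "P2", "code_system": "ICD10", "code": "E119",
         "date": pd.Timestamp("2012-04-01")}])], ignore_index=True)
    m1 = cc.derive_element_matrix(richer, spec).set_index("patient_id")
    for eid in spec.element_ids:
        assert (m0[eid] <= m1[eid]).all()  # no TRUE -> FALSE flips
    assert bool(m1.loc["P2", "diabetes_mellitus"])


def test_patients_without_infection_excluded(spec, caplog):
    cohort = _mini_cohort(30)
    cohort.patients = pd.concat([cohort.patients, pd.DataFrame([
        {"patient_id": "P3", "age_years": 40.0, "sex": "female", "stratum": "A"}])],
        ignore_index=True)
    with caplog.at_level("WARNING"):
        matrix = cc.derive_element_matrix(cohort, spec)
    assert set(matrix["patient_id"]) == {"P1", "P2"}


def test_matrix_matches_generator_truth(spec, sim_cohort, sim_matrix):
    _, _, truth = sim_cohort
    m = sim_matrix.sort_values("patient_id").reset_index(drop=True)
    t = truth.truth
    assert list(m["patient_id"]) == list(t["patient_id"])
    for eid in spec.element_ids:
        assert (m[eid].to_numpy() == t[eid].to_numpy()).all(), eid


def test_amputation_implies_surgical_procedure(sim_matrix):
    amp = sim_matrix["amputation"].to_numpy()
    surg = sim_matrix["surgical_procedure"].to_numpy()
    assert (surg[amp]).all()


def test_transformer_api(spec, sim_cohort):
    from sklearn.base import clone

    _, cohort, _ = sim_cohort
    ph = cc.ContinuumPhenotyper(spec)
    ph2 = clone(ph)
    matrix = ph2.fit_transform(cohort)
    assert ph2.element_ids_ == spec.element_ids
    assert list(matrix.columns[4:]) == spec.element_ids
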