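"""Odds-ratio estimation: closed-form oracle, reference selection, descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import carecycle as cc
from carecycle.estimation import (
    EstimationError,
    UninformativeElementError,
    fit_element_model,
)
from tests.conftest import two_by_two_matrix


def _cell_or_ci(a, b, c, d, alpha=0.05):
    """Closed-form cross-product OR and Wald CI for a 2x2 table."""
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    return or_, np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)


def test_two_by_two_matches_frozen_oracle():
    # a=20, b=30, c=10, d=40: OR = (20*40)/(30*10) = 2.6667, CI (1.090, 6.524)
    res = fit_element_model(two_by_two_matrix(20, 30, 10, 40), "outcome",
                            reference="A", covariates=())
    r = next(x for x in res if x.stratum == "B")
    assert r.odds_ratio == pytest.approx(2.666667, rel=1e-6)
    assert r.ci_low == pytest.approx(1.090059, rel=1e-4)
    assert r.ci_high == pytest.approx(6.523600, rel=1e-4)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(3, 60)] * 4))
def test_saturated_fit_equals_cross_product_ratio(cells):
    a, b, c, d = cells
    res = fit_element_model(two_by_two_matrix(a, b, c, d), "outcome",
                            reference="A", covariates=())
    r = next(x for x in res if x.stratum == "B")
    or_, lo, hi = _cell_or_ci(a, b, c, d)
    assert r.odds_ratio == pytest.approx(or_, rel=1e-6)
    assert r.ci_low == pytest.approx(lo, rel=1e-6)
    assert r.ci_high == pytest.approx(hi, rel=1e-6)


def test_reference_result_is_identity():
    res = fit_element_model(two_by_two_matrix(20, 30, 10, 40), "outcome",
                            reference="A", covariates=())
    ref = next(x for x in res if x.stratum == "A")
    assert ref.is_reference and ref.odds_ratio == 1.0


def test_swapping_reference_inverts_or():
    m = two_by_two_matrix(17, 23, 11, 49)
    r_ab = next(x for x in fit_element_model(m, "outcome", "A", covariates=())
                if x.stratum == "B")
    r_ba = next(x for x in fit_element_model(m, "outcome", "B", covariates=())
                if x.stratum == "A")
    assert abs(r_ab.odds_ratio * r_ba.odds_ratio - 1.0) < 1e-9


def test_zero_event_stratum_flagged_degenerate():
    m = two_by_two_matrix(0, 30, 10, 40)  # no events in stratum B
    r = next(x for x in fit_element_model(m, "outcome", "A", covariates=())
             if x.stratum == "B")
    assert r.degenerate and not np.isfinite(r.odds_ratio)
    assert not np.isfinite(r.ci_low)


def test_constant_element_rejected():
    m = two_by_two_matrix(20, 30, 10, 40)
    m["outcome"] = True
    with pytest.raises(UninformativeElementError):
        fit_element_model(m, "outcome", "A", covariates=())


def _matrix_with_odds(odds_by_stratum, n_per=40):
    rows = []
    for s, odds in odds_by_stratum.items():
        k = int(round(n_per * odds / (1 + odds)))
        for i in range(n_per):
            rows.append({"patient_id": f"{s}{i}", "stratum": s, "age_years": 50.0,
                         "sex": "female", "diabetes_mellitus": i < k})
    return pd.DataFrame(rows)


def test_reference_selection_is_argmin_of_crude_odds():
    m = _matrix_with_odds({"A": 0.5, "B": 0.8, "C": 1.2})
    assert cc.select_reference_stratum(m, "diabetes_mellitus") == "A"


def test_reference_selection_tie_breaks_lexicographically():
    m = _matrix_with_odds({"B": 0.5, "A": 0.5})
    assert cc.select_reference_stratum(m, "diabetes_mellitus") == "A"


def test_reference_selection_on_simulated_cohort(sim_estimates):
    # the analog of the group with lowest index-element odds is the reference
    assert sim_estimates.reference_stratum == "white_non_hispanic"


def test_estimate_continuum_covers_all_pairs(spec, sim_estimates):
    strata = sim_estimates.strata
    assert len(strata) == 5
    assert sim_estimates.element_ids == spec.element_ids
    for s in strata:
        for e in spec.element_ids:
            sim_estimates.result(s, e)  # raises KeyError if absent
    ref_rows = [r for r in sim_estimates.results if r.is_reference]
    assert len(ref_rows) == len(spec.element_ids)


def test_alpha_parameterization(spec, sim_matrix):
    est05 = cc.estimate_continuum(sim_matrix, spec, alpha=0.05)
    est01 = cc.estimate_continuum(sim_matrix, spec, alpha=0.01)
    widened = 0
    for r05 in est05.results:
        if r05.is_reference or r05.degenerate:
            continue
        r01 = est01.result(r05.stratum, r05.element_id)
        assert r01.ci_low <= r05.ci_low + 1e-12
        assert r01.ci_high >= r05.ci_high - 1e-12
        widened += 1
        assert r01.significant == (r01.ci_low > 1.0 or r01.ci_high < 1.0)
    assert widened > 0


def test_age_shift_leaves_stratum_ors_invariant(spec, sim_matrix):
    est = cc.estimate_continuum(sim_matrix, spec)
    shifted = sim_matrix.copy()
    shifted["age_years"] = shifted["age_years"] + 10.0
    shifted.attrs.update(sim_matrix.attrs)
    est2 = cc.estimate_continuum(shifted, spec)
    for r in est.results:
        if r.is_reference or r.degenerate:
            continue
        r2 = est2.result(r.stratum, r.element_id)
        assert r2.odds_ratio == pytest.approx(r.odds_ratio, abs=1e-8)


def test_describe_cohort_percentages():
    counts = {"hispanic_latinx": 662, "white_non_hispanic": 577,
              "native_american": 292, "other_or_multiple": 74,
              "black_non_hispanic": 43}
    rows = []
    for s, n in counts.items():
        for i in range(n):
            rows.append({"patient_id": f"{s}{i}", "stratum": s,
                         "age_years": 50.0, "sex": "female"})
    desc = cc.describe_cohort(pd.DataFrame(rows))
    per = desc.per_stratum.set_index("stratum")
    assert desc.total_n == 1648
    assert per.loc["hispanic_latinx", "percent"] == 40.2
    assert per.loc["white_non_hispanic", "percent"] == 35.0
    assert per.loc["native_american", "percent"] == 17.7
    assert per.loc["other_or_multiple", "percent"] == 4.5
    assert per.loc["black_non_hispanic", "percent"] == 2.6
    assert per["n"].sum() == 1648


def test_identical_age_lists_give_zero_anova_f():
    ages = [40.0, 50.0, 60.0, 70.0]
    rows = [{"patient_id": f"{s}{i}", "stratum": s, "age_years": a, "sex": "female"}
            for s in "AB" for i, a in enumerate(ages)]
    desc = cc.describe_cohort(pd.DataFrame(rows))
    assert desc.anova_f == pytest.approx(0.0, abs=1e-12)


def test_identical_sex_proportions_give_zero_chi2():
    rows = []
    for s in "AB":
        for i in range(20):
            rows.append({"patient_id": f"{s}{i}", "stratum": s,
                         "age_years": 50.0 + i, "sex": "female" if i < 10 else "male"})
    desc = cc.describe_cohort(pd.DataFrame(rows))
    assert desc.chi2 == pytest.approx(0.0, abs=1e-9)


def test_single_stratum_descriptives_warn():
    rows = [{"patient_id": f"P{i}", "stratum": "A", "age_years": 50.0 + i,
             "sex": "female"} for i in range(5)]
    with pytest.warns(UserWarning, match="single stratum"):
        desc = cc.describe_cohort(pd.DataFrame(rows))
    assert desc.anova_f is None and desc.chi2 is None


def test_sklearn_estimator_api(spec, sim_matrix):
    from sklearn.base import clone

    est = cc.ContinuumOddsEstimator(spec, alpha=0.05)
    params = est.get_params()
    assert params["alpha"] == 0.05 and params["reference"] == "auto"
    fitted = clone(est).fit(sim_matrix)
    assert fitted.reference_stratum_ == "white_non_hispanic"
    assert len(fitted.results_) == 5 * 8
    wide = fitted.or_matrix()
    assert wide.shape == (5, 8)
    assert wide.loc["white_non_hispanic"].eq(1.0).all()


def test_unknown_reference_rejected(spec, sim_matrix):
    with pytest.raises(EstimationError):
        cc.estimate_continuum(sim_matrix, spec, reference="nope")
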