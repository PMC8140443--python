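"""Stratified, covariate-adjusted odds-ratio estimation over the continuum.

For every element of the cycle one multivariable logistic model is fit,

    logit P(element = 1) = b0 + sum_g bg * [stratum = g] + b_age * age
                              + b_sex * [sex = male],

with strata dummy-coded against a reference stratum.  The reference is the
stratum with the lowest *crude* odds of the spec's index element (diabetes
mellitus in the default model), ties broken lexicographically.  Per
non-reference stratum the element's odds ratio is exp(bg) with a
two-sided Wald p-value and Wald confidence interval exp(bg +/- z * SE);
an element is flagged significant when the interval excludes 1.00.

Strata in which the element is constant (zero events or all events) cannot
support a finite maximum-likelihood estimate; such strata are excluded from
the fit and their results flagged degenerate rather than reported as
silent, diverging numbers.  Covariate handling is complete-case: rows with
missing age or a sex outside {female, male} are dropped per model with a
logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .spec import ContinuumSpec, default_msk_spec

logger = logging.getLogger(__name__)

__all__ = [
    "ORResult",
    "ContinuumEstimates",
    "CohortDescriptives",
    "EstimationError",
    "UninformativeElementError",
    "select_reference_stratum",
    "fit_element_model",
    "estimate_continuum",
    "describe_cohort",
    "ContinuumOddsEstimator",
]

MATRIX_META = ["patient_id", "stratum", "age_years", "sex"]
MAX_ITER = 100
TOL = 1e-8
# post-fit separation guards: a dummy coefficient beyond +/-20 on the log
# scale, or a Wald SE above 100, is numerically indistinguishable from a
# diverging MLE
COEF_LIMIT = 20.0
SE_LIMIT = 100.0


class EstimationError(ValueError):
    pass


class UninformativeElementError(EstimationError):
    """Element is constant over the whole matrix; no odds ratio is estimable."""


@dataclass(frozen=True)
class ORResult:
    """Adjusted odds ratio of one element for one stratum vs the reference."""

    stratum: str
    element_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    n_events_stratum: int
    degenerate: bool = False
    is_reference: bool = False


@dataclass
class ContinuumEstimates:
    """The full OR/CI/p surface of a continuum for one cohort."""

    spec_name: str
    reference_stratum: str
    results: list[ORResult]
    covariates: tuple[str, ...] = ("age_years", "sex")
    alpha: float = 0.05
    n_per_model: dict[str, int] = field(default_factory=dict)

    def result(self, stratum: str, element_id: str) -> ORResult:
        for r in self.results:
            if r.stratum == stratum and r.element_id == element_id:
                return r
        raise KeyError((stratum, element_id))

    @property
    def strata(self) -> list[str]:
        out: list[str] = []
        for r in self.results:
            if r.stratum not in out:
                out.append(r.stratum)
        return out

    @property
    def element_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.results:
            if r.element_id not in out:
                out.append(r.element_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        from .io import _estimates_frame

        return _estimates_frame(self)


def select_reference_stratum(matrix: pd.DataFrame, index_element: str) -> str:
    """Stratum with the lowest crude odds of the index element.

    Crude odds are TRUE count / FALSE count within each stratum; ties are
    broken lexicographically by stratum label.  A stratum with zero FALSE
    has infinite odds and can only be selected if every stratum is infinite,
    which is an error.
    """
    if index_element not in matrix.columns:
        raise EstimationError(f"index element {index_element!r} not in matrix")
    strata = sorted(matrix["stratum"].unique())
    if len(strata) < 2:
        raise EstimationError("reference selection needs at least 2 strata")
    y = matrix[index_element].astype(bool)
    if y.all() or not y.any():
        raise UninformativeElementError(
            f"index element {index_element!r} is constant over the cohort"
        )
    best: Optional[str] = None
    best_odds = np.inf
    for s in strata:  # lexicographic order => first minimum wins ties
        sub = y[matrix["stratum"] == s]
        t, f = int(sub.sum()), int((~sub).sum())
        odds = np.inf if f == 0 else t / f
        if odds < best_odds:
            best, best_odds = s, odds
    if best is None:
        raise EstimationError("every stratum has infinite crude odds of the index element")
    return best


def _prepare_rows(matrix: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Complete-case filter: drop rows with missing covariates or unknown sex."""
    df = matrix.copy()
    n0 = len(df)
    if "sex" in covariates:
        df = df[df["sex"].isin(["female", "male"])]
    for cov in covariates:
        if cov != "sex":
            df = df[pd.to_numeric(df[cov], errors="coerce").notna()]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d row(s) with missing/unusable covariates", dropped)
    return df


def _design(df: pd.DataFrame, reference: str, strata: Sequence[str],
            covariates: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    dummy_cols = []
    for s in strata:
        if s == reference:
            continue
        col = f"stratum[{s}]"
        X[col] = (df["stratum"] == s).astype(float)
        dummy_cols.append(col)
    for cov in covariates:
        if cov == "sex":
            X["sex[male]"] = (df["sex"] == "male").astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov]).astype(float)
    return X, dummy_cols


def fit_element_model(
    matrix: pd.DataFrame,
    element_id: str,
    reference: str,
    covariates: Sequence[str] = ("age_years", "sex"),
    alpha: float = 0.05,
) -> list[ORResult]:
    """Fit one element's adjusted logistic model; returns one ORResult per stratum.

    The reference stratum's result is the dummy-coding identity (OR exactly
    1).  Strata where the element is constant are excluded from the fit and
    flagged degenerate; model-level non-convergence flags every
    non-reference stratum degenerate.
    """
    if element_id not in matrix.columns:
        raise EstimationError(f"element {element_id!r} not in matrix")
    df = _prepare_rows(matrix, covariates)
    y = df[element_id].astype(int)
    if y.nunique() < 2:
        raise UninformativeElementError(
            f"element {element_id!r} is constant over the analysis rows"
        )
    strata = sorted(df["stratum"].unique())
    if reference not in strata:
        raise EstimationError(f"reference stratum {reference!r} not present")

    events = {s: int(y[df["stratum"] == s].sum()) for s in strata}
    totals = {s: int((df["stratum"] == s).sum()) for s in strata}
    degenerate = {s: events[s] == 0 or events[s] == totals[s] for s in strata}
    if degenerate[reference]:
        # no finite contrast against a zero-cell reference
        degenerate = {s: True for s in strata}

    def _nan_result(s: str) -> ORResult:
        return ORResult(s, element_id, float("nan"), float("nan"), float("nan"),
                        float("nan"), False, events[s], degenerate=True)

    results: list[ORResult] = []
    fit_strata = [s for s in strata if not degenerate[s]]
    fitted = None
    if reference in fit_strata and len(fit_strata) >= 1:
        sub = df[df["stratum"].isin(fit_strata)]
        X, dummy_cols = _design(sub, reference, fit_strata, covariates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fitted = sm.Logit(y.loc[sub.index], X).fit(
                    method="newton", maxiter=MAX_ITER, tol=TOL, disp=0
                )
                if not fitted.mle_retvals.get("converged", False):
                    fitted = None
            except Exception:  # separation / singular design
                fitted = None

    z = stats.norm.ppf(1 - alpha / 2)
    for s in strata:
        if s == reference and not degenerate[s]:
            results.append(ORResult(s, element_id, 1.0, float("nan"), float("nan"),
                                    float("nan"), False, events[s], is_reference=True))
            continue
        if degenerate[s] or fitted is None:
            r = _nan_result(s)
            results.append(replace(r, is_reference=(s == reference)))
            continue
        col = f"stratum[{s}]"
        beta = float(fitted.params[col])
        se = float(fitted.bse[col])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > COEF_LIMIT or se > SE_LIMIT:
            results.append(_nan_result(s))
            continue
        or_ = float(np.exp(beta))
        lo, hi = float(np.exp(beta - z * se)), float(np.exp(beta + z * se))
        p = float(2 * stats.norm.sf(abs(beta / se)))
        results.append(ORResult(s, element_id, or_, lo, hi, p,
                                significant=bool(lo > 1.0 or hi < 1.0),
                                n_events_stratum=events[s]))
    return results


def estimate_continuum(
    matrix: pd.DataFrame,
    spec: Optional[ContinuumSpec] = None,
    covariates: Sequence[str] = ("age_years", "sex"),
    alpha: float = 0.05,
    reference: str = "auto",
) -> ContinuumEstimates:
    """Fit every element's model and assemble the continuum's OR surface.

    ``reference="auto"`` selects the stratum with the lowest crude odds of
    the spec's index element; passing a stratum label overrides selection.
    One model is fit per cycle element (8 for the default model).
    """
    spec = spec if spec is not None else default_msk_spec()
    element_ids = [e for e in spec.element_ids if e in matrix.columns]
    if set(element_ids) != set(spec.element_ids):
        missing = set(spec.element_ids) - set(element_ids)
        raise EstimationError(f"matrix lacks element column(s): {sorted(missing)}")
    if reference == "auto":
        reference = select_reference_stratum(matrix, spec.index_element)
    elif reference not in set(matrix["stratum"]):
        raise EstimationError(f"reference stratum {reference!r} not in matrix")

    results: list[ORResult] = []
    n_per_model: dict[str, int] = {}
    for eid in element_ids:
        try:
            rs = fit_element_model(matrix, eid, reference, covariates, alpha)
        except EstimationError as exc:
            raise EstimationError(f"element {eid!r}: {exc}") from exc
        n_per_model[eid] = len(_prepare_rows(matrix, covariates))
        results.extend(rs)
    return ContinuumEstimates(
        spec_name=spec.name,
        reference_stratum=reference,
        results=results,
        covariates=tuple(covariates),
        alpha=alpha,
        n_per_model=n_per_model,
    )


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

@dataclass
class CohortDescriptives:
    """Per-stratum counts and age summaries plus across-strata comparisons."""

    per_stratum: pd.DataFrame  # stratum, n, percent, age_mean, age_median, age_sd
    total_n: int
    anova_f: Optional[float] = None
    anova_p: Optional[float] = None
    chi2: Optional[float] = None
    chi2_p: Optional[float] = None


def describe_cohort(matrix: pd.DataFrame) -> CohortDescriptives:
    """Cohort-characteristics descriptives: stratum sizes/percents, age summaries,
    one-way ANOVA for age across strata, Pearson chi-square for sex by stratum.

    Percents and age statistics are rounded to one decimal.  With a single
    stratum the across-strata comparisons are omitted with a warning.
    """
    n = len(matrix)
    if n == 0:
        raise EstimationError("empty matrix")
    g = matrix.groupby("stratum", sort=False)["age_years"]
    per = pd.DataFrame({
        "stratum": [s for s, _ in g],
        "n": [len(v) for _, v in g],
        "age_mean": [round(float(v.mean()), 1) for _, v in g],
        "age_median": [round(float(v.median()), 1) for _, v in g],
        "age_sd": [round(float(v.std(ddof=1)), 1) if len(v) > 1 else float("nan")
                   for _, v in g],
    })
    per["percent"] = (100.0 * per["n"] / n).round(1)
    per = per.sort_values(["n", "stratum"], ascending=[False, True]).reset_index(drop=True)
    per = per[["stratum", "n", "percent", "age_mean", "age_median", "age_sd"]]

    desc = CohortDescriptives(per_stratum=per, total_n=n)
    if per["stratum"].nunique() < 2:
        warnings.warn("single stratum: across-strata comparisons omitted")
        return desc

    samples = [v.to_numpy(float) for _, v in matrix.groupby("stratum")["age_years"]]
    if all(len(s) > 1 for s in samples):
        f, p = stats.f_oneway(*samples)
        desc.anova_f, desc.anova_p = float(f), float(p)
    sex = matrix[matrix["sex"].isin(["female", "male"])]
    tab = pd.crosstab(sex["stratum"], sex["sex"])
    if tab.shape == (per["stratum"].nunique(), 2) and (tab.to_numpy() >= 0).all() \
            and tab.to_numpy().sum() > 0 and (tab.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab)
        desc.chi2, desc.chi2_p = float(chi2), float(p)
    return desc


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class ContinuumOddsEstimator(BaseEstimator):
    """Estimator for the per-stratum, per-element adjusted odds-ratio surface.

    ``fit`` takes an element matrix (the output of
    :class:`~carecycle.phenotyping.ContinuumPhenotyper`) and exposes the
    fitted surface via trailing-underscore attributes, so the two compose
    into a standard pipeline::

        matrix = ContinuumPhenotyper(spec).fit_transform(cohort)
        est = ContinuumOddsEstimator(spec).fit(matrix)
        est.estimates_.to_frame()

    Parameters
    ----------
    spec : ContinuumSpec, optional
        Continuum model (default musculoskeletal-infection model).
    covariates : tuple of str
        Adjustment covariates; age enters linearly in years, sex as a
        male-vs-female indicator.
    alpha : float
        Significance level for Wald CIs and flags.
    reference : str
        ``"auto"`` (lowest crude odds of the index element) or an explicit
        stratum label.

    Attributes
    ----------
    reference_stratum_ : str
    estimates_ : ContinuumEstimates
    results_ : list of ORResult
    descriptives_ : CohortDescriptives
    """

    def __init__(
        self,
        spec: Optional[ContinuumSpec] = None,
        covariates: tuple[str, ...] = ("age_years", "sex"),
        alpha: float = 0.05,
        reference: str = "auto",
    ):
        self.spec = spec
        self.covariates = covariates
        self.alpha = alpha
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None) -> "ContinuumOddsEstimator":
        if not isinstance(X, pd.DataFrame) or "stratum" not in X.columns:
            raise EstimationError("fit expects an element matrix DataFrame")
        spec = self.spec if self.spec is not None else default_msk_spec()
        self.estimates_ = estimate_continuum(
            X, spec, covariates=self.covariates, alpha=self.alpha, reference=self.reference
        )
        self.reference_stratum_ = self.estimates_.reference_stratum
        self.results_ = self.estimates_.results
        self.descriptives_ = describe_cohort(X)
        self.element_ids_ = self.estimates_.element_ids
        return self

    def or_matrix(self) -> pd.DataFrame:
        """Wide strata x elements table of fitted odds ratios."""
        if not hasattr(self, "estimates_"):
            raise EstimationError("estimator is not fitted")
        df = self.estimates_.to_frame()
        return df.pivot(index="stratum", columns="element", values="or")[
            self.element_ids_
        ]
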