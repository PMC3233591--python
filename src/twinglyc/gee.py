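"""Twin-pair-clustered regression via generalized estimating equations.

Follow-up outcomes are regressed on baseline tertile exposure with covariate
adjustment (age, Tanner stage, smoking, BMI, physical activity); twin pairs
are the clusters, with an exchangeable working correlation (saturated for
clusters of size two) and robust sandwich standard errors.  Binary outcomes
use a logistic link and report odds ratios.  The trend test recodes the
tertile ordinally (1, 2, 3) and Wald-tests its coefficient against the
robust SE, the usual epidemiologic "P trend".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["RegressionSpec", "ClusteredGEE", "fit_clustered", "trend_test",
           "sex_interaction_test"]

DEFAULT_COVARIATES = ("age", "tanner", "smoking", "bmi", "activity")


@dataclass(frozen=True)
class RegressionSpec:
    """One regression model: outcome ~ baseline tertile + covariates."""

    outcome: str
    exposure: str = "tertile"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    family: str = "gaussian"          # or "binomial"
    cluster: str = "pair_id"

    def validate(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


def _covariate_terms(covariates) -> list[str]:
    terms = []
    for c in covariates:
        if c == "activity":
            terms.append("C(activity)")   # 3-level factor with explicit NA level
        elif c == "smoking":
            terms.append("C(smoking)")
        else:
            terms.append(c)               # age, tanner (ordinal integer), bmi
    return terms


def _check_design(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing model columns: {missing}")
    d = data.dropna(subset=cols).copy()
    if d.empty:
        raise ValueError("no complete cases for the model variables")
    return d


class ClusteredGEE(BaseEstimator):
    """Estimating-equation regression with twin-pair clusters.

    Parameters mirror :class:`RegressionSpec`; :meth:`fit` takes a long-format
    analysis table with one row per subject containing the outcome, exposure,
    covariates and cluster id.

    Attributes (after fit)
    ----------------------
    result_ : statsmodels GEEResults
    summary_ : DataFrame with per-exposure-level estimates (beta or OR),
        robust SE and 95% CI.
    trend_p_ : float, Wald p-value of the ordinal-coded exposure.
    """

    def __init__(self, outcome: str = "fpg_followup", exposure: str = "tertile",
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 family: str = "gaussian", cluster: str = "pair_id"):
        self.outcome = outcome
        self.exposure = exposure
        self.covariates = covariates
        self.family = family
        self.cluster = cluster

    def _spec(self) -> RegressionSpec:
        spec = RegressionSpec(self.outcome, self.exposure, tuple(self.covariates),
                              self.family, self.cluster)
        spec.validate()
        return spec

    def fit(self, data: pd.DataFrame, y=None):
        spec = self._spec()
        cols = [spec.outcome, spec.exposure, spec.cluster, *spec.covariates]
        d = _check_design(data, cols)
        fam = sm.families.Gaussian() if spec.family == "gaussian" else sm.families.Binomial()
        terms = [f"C({spec.exposure}, Treatment('T1'))"] + _covariate_terms(spec.covariates)
        formula = f"{spec.outcome} ~ " + " + ".join(terms)
        model = smf.gee(formula, groups=spec.cluster, data=d, family=fam,
                        cov_struct=sm.cov_struct.Exchangeable())
        try:
            res = model.fit()
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular design matrix: {err}") from err
        if spec.family == "binomial" and not np.all(np.isfinite(res.bse)):
            raise RuntimeError("logistic fit did not converge (possible separation); "
                               "robust SEs are not finite")
        self.result_ = res
        self.summary_ = self._summarize(res, spec)
        self.trend_p_ = trend_test(spec, d)
        return self

    @staticmethod
    def _summarize(res, spec: RegressionSpec) -> pd.DataFrame:
        rows = []
        z = stats.norm.ppf(0.975)
        for level in ("T2", "T3"):
            name = f"C({spec.exposure}, Treatment('T1'))[T.{level}]"
            beta = res.params[name]
            se = res.bse[name]
            if spec.family == "binomial":
                rows.append({"level": level, "estimate": float(np.exp(beta)),
                             "se": float(se), "scale": "odds_ratio",
                             "ci_low": float(np.exp(beta - z * se)),
                             "ci_high": float(np.exp(beta + z * se))})
            else:
                rows.append({"level": level, "estimate": float(beta),
                             "se": float(se), "scale": "beta",
                             "ci_low": float(beta - z * se),
                             "ci_high": float(beta + z * se)})
        return pd.DataFrame(rows).set_index("level")


def fit_clustered(spec: RegressionSpec, data: pd.DataFrame) -> ClusteredGEE:
    """Fit a pair-clustered GEE model; thin wrapper over ClusteredGEE."""
    return ClusteredGEE(outcome=spec.outcome, exposure=spec.exposure,
                        covariates=spec.covariates, family=spec.family,
                        cluster=spec.cluster).fit(data)


def trend_test(spec: RegressionSpec, data: pd.DataFrame) -> float:
    """Wald trend p-value with the tertile coded ordinally (T1,T2,T3 -> 1,2,3)."""
    spec.validate()
    cols = [spec.outcome, spec.exposure, spec.cluster, *spec.covariates]
    d = _check_design(data, cols)
    code = {"T1": 1.0, "T2": 2.0, "T3": 3.0}
    d["_exposure_ord"] = d[spec.exposure].map(code)
    if d["_exposure_ord"].isna().any():
        raise ValueError("exposure must be tertile labels T1/T2/T3")
    fam = sm.families.Gaussian() if spec.family == "gaussian" else sm.families.Binomial()
    formula = "%s ~ _exposure_ord + %s" % (
        spec.outcome, " + ".join(_covariate_terms(spec.covariates)) or "1")
    if not spec.covariates:
        formula = f"{spec.outcome} ~ _exposure_ord"
    res = smf.gee(formula, groups=spec.cluster, data=d, family=fam,
                  cov_struct=sm.cov_struct.Exchangeable()).fit()
    zval = res.params["_exposure_ord"] / res.bse["_exposure_ord"]
    return float(2.0 * stats.norm.sf(abs(zval)))


def sex_interaction_test(data: pd.DataFrame, *, baseline_col: str, outcome_col: str,
                         sex_col: str = "sex", cluster: str = "pair_id",
                         covariates: tuple[str, ...] = ()) -> float:
    """Wald p-value for a baseline-value x sex interaction on the follow-up value.

    Tests whether tracking strength (the slope of follow-up on baseline)
    differs between the sexes, with twin-pair clustering.  Requires both
    sexes to be present.
    """
    cols = [baseline_col, outcome_col, sex_col, cluster, *covariates]
    d = _check_design(data, cols)
    if d[sex_col].nunique() < 2:
        raise ValueError("sex interaction is inestimable with a single-sex input")
    terms = [f"{baseline_col} * C({sex_col})"] + _covariate_terms(covariates)
    formula = f"{outcome_col} ~ " + " + ".join(terms)
    res = smf.gee(formula, groups=cluster, data=d, family=sm.families.Gaussian(),
                  cov_struct=sm.cov_struct.Exchangeable()).fit()
    name = [p for p in res.params.index if ":" in p and baseline_col in p]
    if len(name) != 1:
        raise RuntimeError(f"could not locate interaction term among {list(res.params.index)}")
    zval = res.params[name[0]] / res.bse[name[0]]
    return float(2.0 * stats.norm.sf(abs(zval)))
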