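"""Classical twin-design variance decomposition.

The ACE model splits the variance of a standardized phenotype into additive
genetic (a2), shared/common environmental (c2), and unique environmental (e2)
proportions using the contrast between monozygotic (MZ) pairs, who share all
segregating genes, and same-sex dizygotic (DZ) pairs, who share half on
average.  The expected within-pair correlation is a2 + c2 for MZ pairs and
a2/2 + c2 for DZ pairs.

Continuous traits are fit by maximum likelihood on standardized pair data
(two-group Wishart deviance over 2x2 pair correlation matrices); binary
traits are fit on the liability scale: a latent standard-normal liability is
thresholded at the quantile implied by the trait's prevalence, observed twin
concordances are converted to tetrachoric (liability) correlations by
bivariate-normal root finding, and the same ACE decomposition is applied to
those correlations.

Confidence intervals are 95% profile-likelihood intervals truncated to the
admissible [0, 1] range, so components estimated on the nonnegativity
boundary report a lower bound of exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "TwinCorrelations",
    "ACEModel",
    "LiabilityACEModel",
    "twin_correlation",
    "fit_ace_continuous",
    "fit_ace_liability",
    "threshold_from_prevalence",
    "orthant_probability",
    "concordance_from_correlation",
    "tetrachoric_from_concordance",
    "compare_models",
]

# chi-square(1) 95% critical value used for profile-likelihood intervals
_CHI2_95 = stats.chi2.ppf(0.95, df=1)

# free-parameter count of each nested twin model (components estimated)
_MODEL_PARAMS = {"ACE": 2, "AE": 1, "CE": 1, "E": 0}


@dataclass(frozen=True)
class TwinCorrelations:
    """Within-pair trait correlations by zygosity, with pair counts."""

    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 2 or self.n_dz_pairs < 2:
            raise ValueError("need at least 2 pairs per zygosity group")
        for r, name in ((self.r_mz, "r_mz"), (self.r_dz, "r_dz")):
            if not np.isfinite(r) or not -1.0 <= r <= 1.0:
                raise ValueError(f"{name}={r!r} is not a correlation in [-1, 1]")


def twin_correlation(pairs: np.ndarray, zygosity: np.ndarray) -> TwinCorrelations:
    """Intraclass twin correlations via double-entry Pearson.

    Parameters
    ----------
    pairs : (n_pairs, 2) array
        Trait value of each twin in a pair (column order is arbitrary).
    zygosity : (n_pairs,) array of {"MZ", "DZ"}

    Each pair is entered in both orders before computing the Pearson
    correlation, which makes the estimate invariant to twin labelling.
    """
    pairs = np.asarray(pairs, dtype=float)
    zygosity = np.asarray(zygosity)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n_pairs, 2) array")
    out = {}
    for zyg in ("MZ", "DZ"):
        grp = pairs[zygosity == zyg]
        if len(grp) < 2:
            raise ValueError(f"need at least 2 complete {zyg} pairs")
        x = np.concatenate([grp[:, 0], grp[:, 1]])
        y = np.concatenate([grp[:, 1], grp[:, 0]])
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero variance in {zyg} group; correlation undefined")
            out[zyg] = (np.nan, len(grp))
            continue
        out[zyg] = (float(np.corrcoef(x, y)[0, 1]), len(grp))
    return TwinCorrelations(
        r_mz=out["MZ"][0], r_dz=out["DZ"][0],
        n_mz_pairs=out["MZ"][1], n_dz_pairs=out["DZ"][1],
    )


def _pair_deviance(r_obs: float, rho: float, n: int) -> float:
    """Wishart deviance of one zygosity group against the saturated model.

    Both observed and expected matrices are standardized 2x2 correlation
    matrices (unit diagonal); ``rho`` is the model-implied off-diagonal.
    """
    rho = min(max(rho, -0.999999), 0.999999)
    r_obs = min(max(r_obs, -0.999999), 0.999999)  # keep the saturated term finite
    det_model = 1.0 - rho * rho
    det_obs = 1.0 - r_obs * r_obs
    trace = (2.0 - 2.0 * r_obs * rho) / det_model
    return n * (np.log(det_model) + trace - np.log(det_obs) - 2.0)


def _deviance(a2, c2, corr: TwinCorrelations) -> float:
    return _pair_deviance(corr.r_mz, a2 + c2, corr.n_mz_pairs) + _pair_deviance(
        corr.r_dz, 0.5 * a2 + c2, corr.n_dz_pairs
    )


# multi-start points on the (a2, c2) simplex; the deviance surface can be
# nearly flat along a2 + 2*c2 contours near the boundary
_STARTS = [(0.1, 0.1), (0.6, 0.1), (0.1, 0.6), (0.3, 0.3), (0.45, 0.45)]


def _minimize(corr: TwinCorrelations, model: str):
    """Constrained ML fit of one nested model; returns (a2, c2, deviance, ok)."""
    if model == "E":
        return 0.0, 0.0, _deviance(0.0, 0.0, corr), True
    if model in ("AE", "CE"):
        def f1(x):
            return _deviance(x, 0.0, corr) if model == "AE" else _deviance(0.0, x, corr)
        res = optimize.minimize_scalar(f1, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-10})
        a2, c2 = (res.x, 0.0) if model == "AE" else (0.0, res.x)
        return float(a2), float(c2), float(res.fun), bool(res.success)
    if model != "ACE":
        raise ValueError(f"unknown model {model!r}")

    best = None
    ok = False
    cons = [{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}]
    for start in _STARTS:
        res = optimize.minimize(
            lambda x: _deviance(x[0], x[1], corr),
            x0=start, method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)], constraints=cons,
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    a2, c2 = (float(np.clip(v, 0.0, 1.0)) for v in best.x)
    if a2 + c2 > 1.0:  # clip back onto the simplex after numerical overshoot
        s = a2 + c2
        a2, c2 = a2 / s, c2 / s
    return a2, c2, float(_deviance(a2, c2, corr)), ok


def _profile(component: str, value: float, corr: TwinCorrelations, model: str) -> float:
    """Deviance profiled over the remaining free parameter at a fixed component."""
    if component == "e2":
        # e2 = 1 - a2 - c2 fixed; minimize over the split of the remainder
        rem = 1.0 - value
        if model == "ACE":
            res = optimize.minimize_scalar(
                lambda a: _deviance(a, rem - a, corr),
                bounds=(0.0, rem), method="bounded", options={"xatol": 1e-10},
            ) if rem > 0 else None
            return float(res.fun) if res is not None else _deviance(0.0, 0.0, corr)
        if model == "AE":
            return _deviance(rem, 0.0, corr)
        if model == "CE":
            return _deviance(0.0, rem, corr)
        return _deviance(0.0, 0.0, corr) if value == 1.0 else np.inf
    other_hi = 1.0 - value
    if component == "a2":
        if model in ("AE",):
            return _deviance(value, 0.0, corr)
        if model in ("CE", "E"):
            return _deviance(value, 0.0, corr) if value == 0.0 else np.inf
        res = optimize.minimize_scalar(
            lambda c: _deviance(value, c, corr),
            bounds=(0.0, max(other_hi, 1e-12)), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun)
    if component == "c2":
        if model in ("CE",):
            return _deviance(0.0, value, corr)
        if model in ("AE", "E"):
            return _deviance(0.0, value, corr) if value == 0.0 else np.inf
        res = optimize.minimize_scalar(
            lambda a: _deviance(a, value, corr),
            bounds=(0.0, max(other_hi, 1e-12)), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun)
    raise ValueError(f"unknown component {component!r}")


class ACEModel(BaseEstimator):
    """Maximum-likelihood ACE variance decomposition for a continuous trait.

    Parameters
    ----------
    model : {"ACE", "AE", "CE", "E"}
        Which nested variance-component model to fit.  Submodels fix the
        omitted components at zero.
    compute_ci : bool
        Whether :meth:`fit` also computes 95% profile-likelihood intervals.

    Attributes (after fit)
    ----------------------
    a2_, c2_, e2_ : float
        Variance proportions, nonnegative, summing to 1.
    deviance_ : float
        Two-group deviance against the saturated (observed-correlation) model.
    ci95_ : dict
        ``{"a2": (lo, hi), "c2": ..., "e2": ...}`` profile intervals.
    corr_ : TwinCorrelations
        The summary statistics the model was fit to.
    """

    def __init__(self, model: str = "ACE", compute_ci: bool = True):
        self.model = model
        self.compute_ci = compute_ci

    def fit(self, X, y=None):
        """Fit from raw pair data.

        X is an (n_pairs, 2) array of trait values; y gives each pair's
        zygosity ("MZ"/"DZ").  Data are reduced to double-entry correlations,
        so this is identical to :meth:`fit_from_correlations` on the
        correlations that X produces.
        """
        if y is None:
            raise ValueError("zygosity labels are required")
        return self.fit_from_correlations(twin_correlation(X, y))

    def fit_from_correlations(self, corr: TwinCorrelations | None = None, *,
                              r_mz=None, r_dz=None, n_mz=None, n_dz=None):
        """Fit from summary twin correlations and pair counts."""
        if corr is None:
            corr = TwinCorrelations(r_mz, r_dz, n_mz, n_dz)
        if self.model not in _MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        a2, c2, dev, ok = _minimize(corr, self.model)
        if not ok:
            warnings.warn(
                f"optimizer reported non-convergence for model {self.model} "
                f"(deviance {dev:.6g}); estimates may sit on a flat region"
            )
        self.corr_ = corr
        self.a2_, self.c2_ = a2, c2
        self.e2_ = 1.0 - a2 - c2
        self.deviance_ = dev
        self.n_params_ = _MODEL_PARAMS[self.model]
        self.converged_ = ok
        if self.compute_ci:
            self.ci95_ = {comp: self.profile_ci(comp) for comp in ("a2", "c2", "e2")}
        return self

    def profile_ci(self, component: str, level: float = 0.95):
        """Profile-likelihood interval for one component, truncated to [0, 1].

        Endpoints are the component values where the profiled deviance rises
        ``chi2_1(level)`` above the minimum; an estimate at the boundary
        reports that bound exactly.
        """
        est = {"a2": self.a2_, "c2": self.c2_, "e2": self.e2_}[component]
        cut = self.deviance_ + stats.chi2.ppf(level, df=1)

        def excess(v):
            return _profile(component, v, self.corr_, self.model) - cut

        # admissible range for the component under this model
        lo_adm, hi_adm = 0.0, 1.0
        if excess(lo_adm) <= 0 and excess(hi_adm) <= 0:
            warnings.warn(f"profile likelihood for {component} is flat; "
                          "interval spans the admissible range")
            return (lo_adm, hi_adm)
        lower = lo_adm if excess(lo_adm) <= 0 else float(
            optimize.brentq(excess, lo_adm, est, xtol=1e-6)
        ) if est > lo_adm else lo_adm
        upper = hi_adm if excess(hi_adm) <= 0 else float(
            optimize.brentq(excess, est, hi_adm, xtol=1e-6)
        ) if est < hi_adm else hi_adm
        return (max(lower, 0.0), min(upper, 1.0))


def fit_ace_continuous(corr: TwinCorrelations | None = None, *, pairs=None,
                       zygosity=None, model: str = "ACE",
                       compute_ci: bool = True, **kw) -> ACEModel:
    """Fit the twin variance-component model; thin wrapper over ACEModel.

    Accepts either a :class:`TwinCorrelations` (or r_mz/r_dz/n_mz/n_dz
    keywords) or raw ``pairs`` + ``zygosity`` arrays.
    """
    est = ACEModel(model=model, compute_ci=compute_ci)
    if pairs is not None:
        return est.fit(pairs, zygosity)
    return est.fit_from_correlations(corr, **kw)


# ---------------------------------------------------------------------------
# liability-threshold machinery for binary traits
# ---------------------------------------------------------------------------

def threshold_from_prevalence(prevalence: float) -> float:
    """Liability threshold: standard-normal quantile with upper tail = prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence!r}")
    return float(stats.norm.isf(prevalence))


def orthant_probability(z: float, r: float) -> float:
    """P(X1 > z, X2 > z) for standard bivariate normal with correlation r.

    Reduced to a one-dimensional integral
    ``int_z^inf phi(x) * Phi((r*x - z)/sqrt(1-r^2)) dx`` evaluated by
    adaptive quadrature, accurate well past 1e-9.
    """
    if r >= 1.0:
        return float(stats.norm.sf(z))
    if r <= -1.0:
        return float(max(0.0, 1.0 - 2.0 * stats.norm.cdf(z)))
    s = np.sqrt(1.0 - r * r)
    val, _ = integrate.quad(
        lambda x: stats.norm.pdf(x) * stats.norm.cdf((r * x - z) / s),
        z, np.inf, epsabs=1e-12, epsrel=1e-12, limit=200,
    )
    return float(val)


def concordance_from_correlation(r: float, prevalence: float,
                                 concordance_type: str = "probandwise") -> float:
    """Model-implied twin concordance given liability correlation r.

    probandwise: P(twin2 affected | twin1 affected) = P11 / prevalence.
    pairwise: concordant-affected pairs / pairs with >=1 affected
    = P11 / (2*prevalence - P11).
    """
    z = threshold_from_prevalence(prevalence)
    p11 = orthant_probability(z, r)
    if concordance_type == "probandwise":
        return p11 / prevalence
    if concordance_type == "pairwise":
        return p11 / (2.0 * prevalence - p11)
    raise ValueError(f"unknown concordance type {concordance_type!r}")


def tetrachoric_from_concordance(concordance: float, prevalence: float,
                                 concordance_type: str = "probandwise",
                                 nonnegative: bool = False) -> float:
    """Liability correlation whose implied concordance matches the observed one.

    Solved by root finding on r in (-1, 1); with ``nonnegative=True`` a
    concordance below the independence value returns r = 0 with a warning.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")

    def f(r):
        return concordance_from_correlation(r, prevalence, concordance_type) - concordance

    lo, hi = -0.999999, 0.999999
    if f(hi) < 0:  # concordance effectively 1: perfect dependence
        return 1.0
    if f(lo) > 0:
        return -1.0
    if nonnegative and f(0.0) > 0:
        warnings.warn("observed concordance below the independence value; "
                      "liability correlation clamped to 0")
        return 0.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


class LiabilityACEModel(BaseEstimator):
    """ACE decomposition of a binary trait on the latent liability scale.

    Observed MZ/DZ concordances are converted to tetrachoric liability
    correlations given the threshold implied by the trait's prevalence, and
    the standardized ACE model is then fit to those correlations exactly as
    for a continuous trait, with pair counts weighting the two groups.
    """

    def __init__(self, model: str = "ACE", concordance_type: str = "probandwise",
                 compute_ci: bool = True):
        self.model = model
        self.concordance_type = concordance_type
        self.compute_ci = compute_ci

    def fit(self, X, y=None, *, prevalence: float | None = None):
        """Fit from raw binary pair data (X: (n_pairs, 2) of 0/1, y: zygosity).

        Prevalence defaults to the observed affected proportion.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if set(np.unique(X)) - {0.0, 1.0}:
            raise ValueError("binary pair data must be 0/1")
        prev = float(X.mean()) if prevalence is None else prevalence
        conc = {}
        for zyg in ("MZ", "DZ"):
            grp = X[y == zyg]
            n11 = float(((grp[:, 0] == 1) & (grp[:, 1] == 1)).sum())
            n_any = float((grp.sum(axis=1) >= 1).sum())
            n_aff = float(grp.sum())
            if self.concordance_type == "probandwise":
                conc[zyg] = (2.0 * n11 / n_aff if n_aff else np.nan, len(grp))
            else:
                conc[zyg] = (n11 / n_any if n_any else np.nan, len(grp))
        return self.fit_from_concordances(
            conc_mz=conc["MZ"][0], conc_dz=conc["DZ"][0], prevalence=prev,
            n_mz=conc["MZ"][1], n_dz=conc["DZ"][1],
        )

    def fit_from_concordances(self, *, conc_mz: float, conc_dz: float,
                              prevalence: float, n_mz: int, n_dz: int):
        """Fit from summary concordances, prevalence and pair counts."""
        r_mz = tetrachoric_from_concordance(conc_mz, prevalence, self.concordance_type)
        r_dz = tetrachoric_from_concordance(conc_dz, prevalence, self.concordance_type)
        inner = ACEModel(model=self.model, compute_ci=self.compute_ci)
        inner.fit_from_correlations(
            TwinCorrelations(r_mz=r_mz, r_dz=r_dz, n_mz_pairs=n_mz, n_dz_pairs=n_dz)
        )
        self.r_mz_, self.r_dz_ = r_mz, r_dz
        self.threshold_ = threshold_from_prevalence(prevalence)
        self.prevalence_ = prevalence
        self.a2_, self.c2_, self.e2_ = inner.a2_, inner.c2_, inner.e2_
        self.deviance_ = inner.deviance_
        self.n_params_ = inner.n_params_
        self.converged_ = inner.converged_
        self.corr_ = inner.corr_
        if self.compute_ci:
            self.ci95_ = inner.ci95_
        self._inner = inner
        return self

    def profile_ci(self, component: str, level: float = 0.95):
        return self._inner.profile_ci(component, level=level)


def fit_ace_liability(*, conc_mz: float, conc_dz: float, prevalence: float,
                      n_mz: int, n_dz: int, model: str = "ACE",
                      concordance_type: str = "probandwise",
                      compute_ci: bool = True) -> LiabilityACEModel:
    """Liability-threshold ACE fit from summary concordances; wrapper."""
    return LiabilityACEModel(
        model=model, concordance_type=concordance_type, compute_ci=compute_ci
    ).fit_from_concordances(conc_mz=conc_mz, conc_dz=conc_dz,
                            prevalence=prevalence, n_mz=n_mz, n_dz=n_dz)


def compare_models(fits: dict[str, ACEModel]):
    """Likelihood-ratio and AIC comparison of nested twin models.

    ``fits`` maps model labels ({"ACE","AE","CE","E"}) to fitted estimators
    on identical data.  Single-component likelihood-ratio tests against the
    ACE fit use the 50:50 chi0/chi1 boundary mixture (the null value sits on
    the nonnegativity boundary).  Returns a DataFrame sorted by AIC with the
    preferred (lowest-AIC) model flagged.
    """
    import pandas as pd

    if "ACE" not in fits:
        raise ValueError("comparison requires the full ACE fit as reference")
    ref = fits["ACE"]
    corrs = {(f.corr_.r_mz, f.corr_.r_dz, f.corr_.n_mz_pairs, f.corr_.n_dz_pairs)
             for f in fits.values()}
    if len(corrs) != 1:
        raise ValueError("model comparison requires fits on identical data")
    rows = []
    for label, f in fits.items():
        if label not in _MODEL_PARAMS:
            raise ValueError(f"non-nested model {label!r} refused")
        delta = f.deviance_ - ref.deviance_
        df = ref.n_params_ - f.n_params_
        if label == "ACE":
            p = np.nan
        elif df == 1:
            # boundary mixture: 0.5*chi2_0 + 0.5*chi2_1
            p = 0.5 * stats.chi2.sf(max(delta, 0.0), df=1) if delta > 0 else 1.0
        else:
            p = float(stats.chi2.sf(max(delta, 0.0), df=df))
        rows.append({
            "model": label, "deviance": f.deviance_, "n_params": f.n_params_,
            "aic": f.deviance_ + 2 * f.n_params_,
            "lrt_vs_ACE": delta if label != "ACE" else np.nan,
            "p_boundary": p,
        })
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    out["preferred"] = out["aic"] == out["aic"].min()
    return out
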