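"""Longitudinal tracking of glycemic traits by age- and sex-specific tertiles.

Tracking here means maintenance of rank position within the population
distribution over time: subjects are cut into tertiles of a trait within
(sex, age-bin) strata at baseline, re-cut at follow-up, and summarised by a
3x3 transition matrix, a middle-or-top persistence proportion, and the
incidence of prediabetes at follow-up by baseline tertile among subjects who
were normoglycemic at baseline.  A tricube-weighted local-linear smoother
draws follow-up trait levels against age by baseline tertile group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TERTILES", "assign_tertiles", "TransitionMatrix", "transition_matrix",
           "incidence_by_tertile", "loess_track", "persistence_null"]

TERTILES = ("T1", "T2", "T3")

# null value of the middle-or-top persistence under independent re-ranking:
# P(follow in {T2,T3}) = 2/3 regardless of baseline tertile
PERSISTENCE_NULL = 2.0 / 3.0


def persistence_null() -> float:
    return PERSISTENCE_NULL


def _tertile_labels(values: np.ndarray) -> np.ndarray:
    """Label one stratum by empirical 1/3 and 2/3 quantile cut-points.

    Equal values always share a tertile (labels are a function of the value),
    so ties never straddle a cut-point.
    """
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    return np.select([values <= q1, values <= q2], ["T1", "T2"], default="T3")


def assign_tertiles(values, sex, age, *, age_bin_width: float = 2.0,
                    min_stratum: int = 3) -> pd.Series:
    """Assign age- and sex-specific tertiles of a trait.

    Cut-points are the empirical 1/3 and 2/3 quantiles within each
    (sex, age-bin) stratum; age bins are ``age_bin_width``-year intervals
    anchored at the youngest subject.  Strata with fewer than ``min_stratum``
    subjects are merged into the nearest age bin of the same sex (warning
    logged).  Returns a Series of "T1"/"T2"/"T3" aligned with the input.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    sex = pd.Series(np.asarray(sex)).reset_index(drop=True)
    age = pd.Series(np.asarray(age, dtype=float)).reset_index(drop=True)
    if not (len(values) == len(sex) == len(age)):
        raise ValueError("values, sex and age must be the same length")

    bins = np.floor((age - age.min()) / age_bin_width).astype(int)
    df = pd.DataFrame({"value": values.to_numpy(), "sex": sex, "bin": bins})

    # merge undersized bins into the nearest bin of the same sex
    for s in df["sex"].unique():
        while True:
            counts = df.loc[df["sex"] == s, "bin"].value_counts()
            small = counts[counts < min_stratum]
            if small.empty or len(counts) == 1:
                if not small.empty:
                    warnings.warn(f"sex {s}: a single stratum has fewer than "
                                  f"{min_stratum} subjects")
                break
            b = small.index[0]
            others = counts.index[counts.index != b]
            nearest = others[np.argmin(np.abs(others - b))]
            warnings.warn(f"merging stratum (sex={s}, age-bin {b}) with "
                          f"{counts[b]} subjects into bin {nearest}")
            df.loc[(df["sex"] == s) & (df["bin"] == b), "bin"] = nearest

    labels = pd.Series(index=df.index, dtype=object)
    for (_, _), idx in df.groupby(["sex", "bin"]).groups.items():
        labels.loc[idx] = _tertile_labels(df.loc[idx, "value"].to_numpy())
    labels.index = values.index
    return labels.rename("tertile")


@dataclass
class TransitionMatrix:
    """Baseline-tertile to follow-up-tertile transitions for one trait."""

    counts: pd.DataFrame        # 3x3, rows = baseline tertile
    proportions: pd.DataFrame   # row-stochastic
    persistence: float          # P(follow in {T2,T3} | base in {T2,T3})
    n_subjects: int
    n_excluded: int


def transition_matrix(base: pd.Series, follow: pd.Series) -> TransitionMatrix:
    """Cross-tabulate baseline vs follow-up tertiles over shared subjects.

    Both inputs are tertile labels indexed by subject id; subjects present at
    only one visit are excluded and tallied in ``n_excluded``.
    """
    common = base.index.intersection(follow.index)
    n_excluded = (len(base) - len(common)) + (len(follow) - len(common))
    b = base.loc[common]
    f = follow.loc[common]
    counts = pd.crosstab(b, f).reindex(index=TERTILES, columns=TERTILES, fill_value=0)
    counts.index.name, counts.columns.name = "baseline", "followup"
    row_sums = counts.sum(axis=1)
    props = counts.div(row_sums.replace(0, np.nan), axis=0)
    in23_base = b.isin(["T2", "T3"])
    if in23_base.sum() == 0:
        persistence = np.nan
    else:
        persistence = float((f[in23_base].isin(["T2", "T3"])).mean())
    return TransitionMatrix(counts=counts, proportions=props,
                            persistence=persistence,
                            n_subjects=int(len(common)), n_excluded=int(n_excluded))


def incidence_by_tertile(base_tertiles: pd.Series, base_prediabetes: pd.Series,
                         follow_prediabetes: pd.Series,
                         base_diabetes: pd.Series | None = None) -> pd.DataFrame:
    """Prediabetes incidence at follow-up by baseline tertile.

    Restricted to subjects normoglycemic at baseline (prediabetes false and,
    if ``base_diabetes`` is given, diabetes false).  All inputs are indexed
    by subject id.  Returns a table with n, n_incident, incidence per tertile;
    an empty tertile yields NaN with a warning.
    """
    idx = base_tertiles.index.intersection(follow_prediabetes.index)
    ngt = ~base_prediabetes.loc[idx].astype(bool)
    if base_diabetes is not None:
        ngt &= ~base_diabetes.loc[idx].astype(bool)
    idx = idx[ngt]
    rows = []
    for t in TERTILES:
        members = idx[base_tertiles.loc[idx] == t]
        n = len(members)
        if n == 0:
            warnings.warn(f"no baseline-normoglycemic subjects in tertile {t}")
            rows.append({"tertile": t, "n": 0, "n_incident": 0, "incidence": np.nan})
            continue
        inc = follow_prediabetes.loc[members].astype(bool)
        rows.append({"tertile": t, "n": n, "n_incident": int(inc.sum()),
                     "incidence": float(inc.mean())})
    return pd.DataFrame(rows).set_index("tertile")


def loess_track(x, y, *, span: float = 0.6, n_grid: int = 50, grid=None):
    """Tricube-weighted local-linear smoother (lowess-style) on a grid.

    At each evaluation point the nearest ``ceil(span * n)`` observations get
    tricube weights scaled by the span radius and a weighted straight line is
    fit; the fitted value at the point is returned.  Local linear fits
    reproduce globally linear data exactly.

    Returns (grid, fitted) arrays over the observed x range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 10:
        raise ValueError("need at least 10 points to smooth")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    k = max(2, int(np.ceil(span * len(x))))
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        radius = np.partition(d, k - 1)[k - 1]
        if radius == 0:
            radius = np.finfo(float).tiny
        w = np.clip(1.0 - (d / radius) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = 0.0 if sxx == 0 else (w * (x - xm) * (y - ym)).sum() / sxx
        fitted[i] = ym + slope * (x0 - xm)
    return grid, fitted
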