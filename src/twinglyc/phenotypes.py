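"""Glycemic phenotype derivation from oral glucose tolerance test (OGTT) data.

Implements the homeostatic model assessment of insulin resistance (HOMA-IR)
and the American Diabetes Association glycemic status categories computed
from fasting plasma glucose (FPG, mmol/L) and 2-hour post-load glucose
(2hPG, mmol/L):

* diabetes: FPG >= 7.0 or 2hPG >= 11.1
* impaired fasting glucose (IFG): FPG in [5.6, 7.0) with 2hPG < 7.8
* impaired glucose tolerance (IGT): 2hPG in [7.8, 11.1) with FPG < 5.6
* combined elevation (IFG_IGT): both ranges at once
* normal glucose tolerance (NGT): neither

Prediabetes is IFG and/or IGT (including the combined category); diabetes is
not prediabetes.  The one-decimal printed ranges are implemented as
half-open intervals ([5.6, 7.0) and [7.8, 11.1)) so the categories partition
the (FPG, 2hPG) plane with no gap below the diabetes cut-offs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlycemicCategory",
    "GlycemicStatus",
    "OGTTRecord",
    "compute_homa_ir",
    "log_homa",
    "classify_glycemic",
    "add_phenotypes",
]

# cut-offs in mmol/L
FPG_IFG_LOW = 5.6
FPG_DIABETES = 7.0
PG2H_IGT_LOW = 7.8
PG2H_DIABETES = 11.1

HOMA_DENOMINATOR = 22.5


class GlycemicCategory(str, enum.Enum):
    NGT = "NGT"
    IFG = "IFG"
    IGT = "IGT"
    IFG_IGT = "IFG_IGT"
    DIABETES = "DIABETES"


# ordered severity used by the monotonicity property: normal < prediabetes < diabetes
SEVERITY = {
    GlycemicCategory.NGT: 0,
    GlycemicCategory.IFG: 1,
    GlycemicCategory.IGT: 1,
    GlycemicCategory.IFG_IGT: 1,
    GlycemicCategory.DIABETES: 2,
}

_PREDIABETES = {GlycemicCategory.IFG, GlycemicCategory.IGT, GlycemicCategory.IFG_IGT}


@dataclass(frozen=True)
class OGTTRecord:
    """One subject-visit's OGTT measurements.

    fpg and pg2h in mmol/L, fpi (fasting plasma insulin) in µU/mL.
    """

    fpg: float
    pg2h: float
    fpi: float = np.nan

    def __post_init__(self) -> None:
        for name in ("fpg", "pg2h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v!r} must be finite and non-negative")
        if np.isfinite(self.fpi) and self.fpi < 0:
            raise ValueError(f"fpi={self.fpi!r} must be non-negative")


@dataclass(frozen=True)
class GlycemicStatus:
    category: GlycemicCategory
    prediabetes: bool


def compute_homa_ir(fpi, fpg):
    """HOMA-IR = fasting insulin (µU/mL) x fasting glucose (mmol/L) / 22.5.

    Accepts scalars or arrays; negative inputs are rejected.
    """
    fpi = np.asarray(fpi, dtype=float)
    fpg = np.asarray(fpg, dtype=float)
    if np.any(fpi < 0) or np.any(fpg < 0):
        raise ValueError("insulin and glucose must be non-negative")
    out = fpi * fpg / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def log_homa(h):
    """Natural logarithm of HOMA-IR (used to normalize its skewed distribution)."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("log transform requires HOMA-IR > 0")
    out = np.log(h)
    return float(out) if out.ndim == 0 else out


def _classify_arrays(fpg: np.ndarray, pg2h: np.ndarray) -> np.ndarray:
    diabetes = (fpg >= FPG_DIABETES) | (pg2h >= PG2H_DIABETES)
    fpg_hi = fpg >= FPG_IFG_LOW
    pg_hi = pg2h >= PG2H_IGT_LOW
    return np.select(
        [diabetes, fpg_hi & pg_hi, fpg_hi, pg_hi],
        [GlycemicCategory.DIABETES.value, GlycemicCategory.IFG_IGT.value,
         GlycemicCategory.IFG.value, GlycemicCategory.IGT.value],
        default=GlycemicCategory.NGT.value,
    )


def classify_glycemic(rec: OGTTRecord | None = None, *, fpg=None, pg2h=None):
    """ADA glycemic status of one record, or vectorized over fpg/pg2h arrays.

    Returns a :class:`GlycemicStatus` for a single record, or a pair of
    (category string array, prediabetes bool array) for array inputs.
    """
    if rec is not None:
        fpg, pg2h = rec.fpg, rec.pg2h
    fpg = np.asarray(fpg, dtype=float)
    pg2h = np.asarray(pg2h, dtype=float)
    if np.any(~np.isfinite(fpg)) or np.any(~np.isfinite(pg2h)):
        raise ValueError("glucose values must be finite")
    if np.any(fpg < 0) or np.any(pg2h < 0):
        raise ValueError("glucose values must be non-negative")
    cats = _classify_arrays(np.atleast_1d(fpg), np.atleast_1d(pg2h))
    pred = np.isin(cats, [c.value for c in _PREDIABETES])
    if fpg.ndim == 0:
        cat = GlycemicCategory(cats[0])
        return GlycemicStatus(category=cat, prediabetes=bool(pred[0]))
    return cats, pred


def add_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Append homa_ir, log_homa, glycemic_category, prediabetes columns.

    Operates row-wise on a cohort table with fpg, pg2h, fpi columns; log_homa
    is NaN where HOMA-IR is zero (zero measured insulin).
    """
    out = df.copy()
    out["homa_ir"] = compute_homa_ir(out["fpi"].to_numpy(), out["fpg"].to_numpy())
    h = out["homa_ir"].to_numpy()
    lh = np.full_like(h, np.nan)
    pos = h > 0
    lh[pos] = np.log(h[pos])
    out["log_homa"] = lh
    cats, pred = classify_glycemic(fpg=out["fpg"].to_numpy(), pg2h=out["pg2h"].to_numpy())
    out["glycemic_category"] = cats
    out["prediabetes"] = pred
    return out
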