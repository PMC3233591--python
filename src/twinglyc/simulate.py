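"""Synthetic twin-cohort generator with known ACE and tracking structure.

Emulates a prospective cohort of same-sex MZ/DZ twin pairs examined at a
baseline visit (childhood/adolescence) and a follow-up visit ~6 years later,
with fasting glucose (FPG), 2-hour post-load glucose (2hPG) and fasting
insulin (FPI) measured at both visits plus the covariates used by the
downstream regression stage (age, Tanner stage, BMI, smoking, activity).

Each continuous trait is drawn, per pair, from a 4-variate normal over
(twin1, twin2) x (baseline, follow-up) whose correlation matrix is the
Kronecker product of a twin block (off-diagonal a2 + c2 for MZ, a2/2 + c2 for
DZ) and a visit block (off-diagonal ``tracking_r``); the cross-twin
cross-visit correlation is therefore the product of the two, the simplest
separable structure.  Binary liability traits are defined by thresholding a
standardized follow-up liability at the quantile implied by the configured
prevalence; a binary trait may be coupled to a continuous trait (thresholding
that trait's own liability) or carry an independent liability with its own
ACE parameters.

Covariates are generated independently of glucose except an optional linear
BMI effect on follow-up FPG (``bmi_effect_fpg``), which gives the regression
recovery tests a known target.

Default parameters mirror the cohort this generator emulates: 218/141 male
and 201/81 female MZ/DZ pairs, baseline ages uniform on 6-21 years with
follow-up 6 years later, trait means/SDs at the two visits, FPG heritability
near 0.43 with shared environment 0.19, and a follow-up impaired-fasting-
glucose prevalence of 28.2%.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TraitSpec", "BinaryTraitSpec", "SimulationConfig", "generate_cohort",
           "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "subject_id", "pair_id", "zygosity", "sex", "visit", "age", "tanner",
    "bmi", "smoking", "activity", "fpg", "pg2h", "fpi",
]

ACTIVITY_LEVELS = ("low", "moderate", "high", "NA")


@dataclass(frozen=True)
class TraitSpec:
    """ACE structure and per-visit moments of one continuous trait."""

    a2: float
    c2: float
    mean_baseline: float
    sd_baseline: float
    mean_followup: float
    sd_followup: float

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2

    def validate(self, name: str) -> None:
        if not (0 <= self.a2 <= 1 and 0 <= self.c2 <= 1 and self.a2 + self.c2 <= 1 + 1e-12):
            raise ValueError(f"trait {name}: (a2, c2) must lie on the unit simplex")
        if self.sd_baseline <= 0 or self.sd_followup <= 0:
            raise ValueError(f"trait {name}: standard deviations must be positive")


@dataclass(frozen=True)
class BinaryTraitSpec:
    """A thresholded liability trait observed at follow-up.

    If ``source_trait`` names a continuous trait, the binary outcome is that
    trait's standardized follow-up value exceeding the prevalence quantile
    (coupled liability); otherwise an independent latent liability with the
    given (a2, c2) is generated and thresholded.
    """

    prevalence: float
    source_trait: str | None = None
    a2: float = 0.5
    c2: float = 0.2

    def validate(self, name: str) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"binary trait {name}: prevalence must be in (0, 1)")
        if not (0 <= self.a2 and 0 <= self.c2 and self.a2 + self.c2 <= 1 + 1e-12):
            raise ValueError(f"binary trait {name}: (a2, c2) must lie on the unit simplex")


def _default_traits() -> dict[str, TraitSpec]:
    return {
        "fpg": TraitSpec(0.43, 0.19, 4.5, 0.5, 5.4, 0.4),
        "pg2h": TraitSpec(0.27, 0.33, 4.7, 0.85, 5.8, 1.35),
        "fpi": TraitSpec(0.57, 0.00, 7.3, 4.0, 9.3, 4.5),
    }


def _default_binary() -> dict[str, BinaryTraitSpec]:
    return {
        "ifg_liab": BinaryTraitSpec(prevalence=0.282, source_trait="fpg"),
        "igt_liab": BinaryTraitSpec(prevalence=0.075, source_trait="pg2h"),
    }


@dataclass
class SimulationConfig:
    """Full description of a synthetic twin cohort."""

    n_mz_pairs: int = 419
    n_dz_pairs: int = 222
    sex_ratio: float = 0.55          # proportion of male pairs
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    binary_traits: dict[str, BinaryTraitSpec] = field(default_factory=_default_binary)
    tracking_r: float = 0.4          # baseline -> follow-up within-subject correlation
    age_range: tuple[float, float] = (6.0, 21.0)
    followup_gap: float = 6.0        # years between visits
    bmi_mean: float = 15.7
    bmi_sd: float = 2.4
    bmi_pair_r: float = 0.5          # within-pair BMI correlation (not inferred from data)
    bmi_effect_fpg: float = 0.0      # mmol/L per kg/m^2 added to follow-up FPG
    smoking_p: float = 0.10
    activity_probs: tuple[float, float, float, float] = (0.31, 0.31, 0.24, 0.14)
    dropout_rate: float = 0.0        # completely-at-random follow-up dropout
    seed: int = 0

    def validate(self) -> None:
        if self.n_mz_pairs < 1 or self.n_dz_pairs < 1:
            raise ValueError("pair counts must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if not -1.0 <= self.tracking_r <= 1.0:
            raise ValueError("tracking_r must be in [-1, 1]")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if abs(sum(self.activity_probs) - 1.0) > 1e-9:
            raise ValueError("activity_probs must sum to 1")
        for name, t in self.traits.items():
            t.validate(name)
        for name, b in self.binary_traits.items():
            b.validate(name)
            if b.source_trait is not None and b.source_trait not in self.traits:
                raise ValueError(f"binary trait {name}: unknown source trait "
                                 f"{b.source_trait!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traits"] = {k: asdict(v) for k, v in self.traits.items()}
        d["binary_traits"] = {k: asdict(v) for k, v in self.binary_traits.items()}
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def pair_correlation_matrix(a2: float, c2: float, tracking_r: float,
                            zygosity: str) -> np.ndarray:
    """4x4 correlation over (twin1 base, twin1 follow, twin2 base, twin2 follow).

    Kronecker product of the twin block and the visit block; raises with a
    diagnostic naming the offending parameters if not positive definite.
    """
    rz = a2 + c2 if zygosity == "MZ" else 0.5 * a2 + c2
    twin = np.array([[1.0, rz], [rz, 1.0]])
    visit = np.array([[1.0, tracking_r], [tracking_r, 1.0]])
    corr = np.kron(twin, visit)
    if np.linalg.eigvalsh(corr).min() <= 1e-12:
        raise ValueError(
            "implied pair covariance is not positive definite for "
            f"(a2={a2}, c2={c2}, tracking_r={tracking_r}, zygosity={zygosity})"
        )
    return corr


def _sample_pair_liability(rng, n_pairs, a2, c2, tracking_r, zygosity):
    """(n_pairs, 4) standard-normal draws with the configured pair structure."""
    corr = pair_correlation_matrix(a2, c2, tracking_r, zygosity)
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n_pairs, 4)) @ chol.T


def _tanner_from_age(age: np.ndarray) -> np.ndarray:
    # coarse pubertal staging: ~1 stage per 2.5 years from age 8, clipped to 1-5
    return np.clip(((age - 8.0) / 2.5).astype(int) + 2, 1, 5)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a long-format twin cohort table; deterministic given the seed.

    Returns one row per subject per visit with the columns listed in
    ``COHORT_COLUMNS`` plus one 0/1 column per configured binary trait
    (populated on follow-up rows, NaN at baseline).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_pairs = config.n_mz_pairs + config.n_dz_pairs
    zygosity = np.array(["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs)
    sex = np.where(rng.random(n_pairs) < config.sex_ratio, "M", "F")

    lo, hi = config.age_range
    age_base = rng.uniform(lo, hi, size=n_pairs)       # twins share age
    age_follow = age_base + config.followup_gap

    # standardized liabilities per trait: dict -> (n_pairs, 4)
    liabilities: dict[str, np.ndarray] = {}
    mz = zygosity == "MZ"
    for name, spec in config.traits.items():
        z = np.empty((n_pairs, 4))
        z[mz] = _sample_pair_liability(rng, mz.sum(), spec.a2, spec.c2,
                                       config.tracking_r, "MZ")
        z[~mz] = _sample_pair_liability(rng, (~mz).sum(), spec.a2, spec.c2,
                                        config.tracking_r, "DZ")
        liabilities[name] = z

    # independent liabilities for uncoupled binary traits (single visit, 2 twins)
    binary_liab: dict[str, np.ndarray] = {}
    for name, bspec in config.binary_traits.items():
        if bspec.source_trait is None:
            z = np.empty((n_pairs, 2))
            for zyg, mask in (("MZ", mz), ("DZ", ~mz)):
                rz = bspec.a2 + bspec.c2 if zyg == "MZ" else 0.5 * bspec.a2 + bspec.c2
                cov = np.array([[1.0, rz], [rz, 1.0]])
                if np.linalg.eigvalsh(cov).min() <= 1e-12:
                    raise ValueError(
                        f"binary trait {name}: implied covariance not positive "
                        f"definite for (a2={bspec.a2}, c2={bspec.c2})")
                z[mask] = rng.standard_normal((mask.sum(), 2)) @ np.linalg.cholesky(cov).T
            binary_liab[name] = z
        else:
            # coupled: follow-up liability columns (1, 3) of the source trait
            binary_liab[name] = liabilities[bspec.source_trait][:, [1, 3]]

    # covariates
    bmi_cov = np.array([[1.0, config.bmi_pair_r], [config.bmi_pair_r, 1.0]])
    bmi_z = rng.standard_normal((n_pairs, 2)) @ np.linalg.cholesky(bmi_cov).T
    bmi_base = config.bmi_mean + config.bmi_sd * bmi_z
    bmi_follow = bmi_base + 3.8 + 0.5 * rng.standard_normal((n_pairs, 2))
    smoking = rng.random((n_pairs, 2)) < config.smoking_p
    activity = rng.choice(ACTIVITY_LEVELS, size=(n_pairs, 2), p=config.activity_probs)

    rows = []
    for t_idx in range(2):  # twin index within pair
        for visit, ages, bmis in (("baseline", age_base, bmi_base[:, t_idx]),
                                  ("followup", age_follow, bmi_follow[:, t_idx])):
            vi = 0 if visit == "baseline" else 1
            rec = pd.DataFrame({
                "subject_id": [f"P{p:05d}_{t_idx + 1}" for p in range(n_pairs)],
                "pair_id": [f"P{p:05d}" for p in range(n_pairs)],
                "zygosity": zygosity,
                "sex": sex,
                "visit": visit,
                "age": ages,
                "tanner": _tanner_from_age(ages),
                "bmi": bmis,
                "smoking": smoking[:, t_idx],
                "activity": activity[:, t_idx],
            })
            for name, spec in config.traits.items():
                z = liabilities[name][:, 2 * t_idx + vi]
                mean = spec.mean_baseline if vi == 0 else spec.mean_followup
                sd = spec.sd_baseline if vi == 0 else spec.sd_followup
                vals = mean + sd * z
                if name == "fpg" and vi == 1 and config.bmi_effect_fpg:
                    vals = vals + config.bmi_effect_fpg * (bmis - config.bmi_mean)
                if name == "fpi":
                    vals = np.clip(vals, 0.5, None)  # insulin cannot be negative
                rec[name] = vals
            for name, bspec in config.binary_traits.items():
                if vi == 0:
                    rec[name] = np.nan
                else:
                    thr = stats.norm.isf(bspec.prevalence)
                    rec[name] = (binary_liab[name][:, t_idx] > thr).astype(float)
            rows.append(rec)

    df = pd.concat(rows, ignore_index=True)
    if config.dropout_rate > 0:
        fu = df["visit"] == "followup"
        drop = rng.random(len(df)) < config.dropout_rate
        df = df[~(fu & drop)].reset_index(drop=True)
    df = df.sort_values(["pair_id", "subject_id", "visit"]).reset_index(drop=True)
    return df


def pairs_wide(df: pd.DataFrame, trait: str, visit: str = "followup") -> pd.DataFrame:
    """Pivot a cohort table to one row per pair: (pair_id, zygosity, sex, v1, v2).

    ``visit="both"`` stacks the baseline and follow-up measurements (two rows
    per pair), which halves the sampling noise of within-pair correlations
    for traits whose pair structure is the same at both visits.
    """
    visits = ("baseline", "followup") if visit == "both" else (visit,)
    frames = []
    for v in visits:
        sub = df[df["visit"] == v].copy()
        sub["member"] = sub["subject_id"].str[-1]
        wide = sub.pivot_table(index=["pair_id", "zygosity", "sex"], columns="member",
                               values=trait, aggfunc="first")
        wide = wide.dropna().reset_index()
        wide.columns = ["pair_id", "zygosity", "sex", "v1", "v2"]
        frames.append(wide)
    return pd.concat(frames, ignore_index=True)
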