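"""End-to-end orchestration: simulate -> derive -> track -> regress -> twin-fit.

Each stage is a pure function of (inputs, config, seed) and writes plain
CSV/TSV reports: a cohort characteristics table (means +/- SD and prevalence
counts by sex and visit), tertile transition matrices and prediabetes
incidence tables, a GEE regression table (per sex x exposure x outcome), and
a twin-model table (correlations and ACE components with 95% CIs per sex x
trait).  A JSON manifest records the config hash, seed, output paths and any
warnings, so a rerun with the same inputs reproduces the numeric tables
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import (ACEModel, LiabilityACEModel, fit_ace_continuous,
                  fit_ace_liability, twin_correlation)
from .gee import RegressionSpec, fit_clustered, sex_interaction_test
from .phenotypes import add_phenotypes
from .simulate import (BinaryTraitSpec, SimulationConfig, TraitSpec,
                       generate_cohort, pairs_wide)
from .tracking import assign_tertiles, incidence_by_tertile, transition_matrix

__all__ = ["load_config", "run_pipeline", "simulate_stage", "derive_stage",
           "summary_stage", "tracking_stage", "regression_stage", "twin_stage",
           "twin_stage_from_summary"]

TRACK_TRAITS = ("fpg", "pg2h", "homa_ir")
REG_OUTCOMES = (("fpg_fu", "gaussian"), ("pg2h_fu", "gaussian"),
                ("log_homa_fu", "gaussian"), ("prediabetes_fu", "binomial"))


def _simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d or {})
    if "traits" in d:
        d["traits"] = {k: TraitSpec(**v) for k, v in d["traits"].items()}
    if "binary_traits" in d:
        d["binary_traits"] = {k: BinaryTraitSpec(**v) for k, v in d["binary_traits"].items()}
    for key in ("age_range", "activity_probs"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON pipeline config; missing sections get defaults."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("cohort_csv", None)
    cfg.setdefault("simulation", {})
    cfg.setdefault("tracking", {})
    cfg.setdefault("regression", {})
    cfg.setdefault("twin", {})
    return cfg


def simulate_stage(cfg: dict, seed: int | None, outdir: Path) -> pd.DataFrame:
    if cfg.get("cohort_csv"):
        df = pd.read_csv(cfg["cohort_csv"])
        return df
    sim = _simulation_config_from_dict(cfg.get("simulation"))
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    df = generate_cohort(sim)
    df.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "simulation_config.json").write_text(
        json.dumps(sim.to_dict(), indent=2, sort_keys=True, default=float))
    return df


def derive_stage(cohort: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    derived = add_phenotypes(cohort)
    derived.to_csv(outdir / "cohort_derived.csv", index=False)
    return derived


def summary_stage(derived: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    """Cohort characteristics: means +/- SD and prevalence by sex and visit."""
    rows = []
    for (sex, visit), grp in derived.groupby(["sex", "visit"]):
        row = {"sex": sex, "visit": visit, "n": len(grp)}
        for col in ("age", "bmi", "fpg", "pg2h", "fpi", "homa_ir"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_sd"] = grp[col].std()
        for cat in ("IFG", "IGT"):
            row[f"n_{cat.lower()}"] = int((grp["glycemic_category"] == cat).sum())
        row["n_prediabetes"] = int(grp["prediabetes"].sum())
        row["prediabetes_pct"] = 100.0 * grp["prediabetes"].mean()
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["sex", "visit"]).reset_index(drop=True)
    out.round(4).to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return out


def _subject_wide(derived: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: baseline measurements + follow-up outcomes."""
    base = derived[derived["visit"] == "baseline"].set_index("subject_id")
    fu = derived[derived["visit"] == "followup"].set_index("subject_id")
    common = base.index.intersection(fu.index)
    base, fu = base.loc[common], fu.loc[common]
    wide = base[["pair_id", "zygosity", "sex", "age", "tanner", "bmi", "smoking",
                 "fpg", "pg2h", "homa_ir", "log_homa", "prediabetes",
                 "glycemic_category"]].copy()
    wide["activity"] = fu["activity"]  # activity is surveyed at follow-up
    for col in ("fpg", "pg2h", "log_homa", "prediabetes", "glycemic_category"):
        wide[f"{col}_fu"] = fu[col]
    wide["prediabetes_fu"] = wide["prediabetes_fu"].astype(float)
    return wide


def tracking_stage(derived: pd.DataFrame, cfg: dict, outdir: Path) -> dict:
    """Transition matrices, persistence, incidence, and the sex-tracking test."""
    width = float(cfg.get("age_bin_width", 2.0))
    wide = _subject_wide(derived)
    results = {"persistence": {}, "incidence": {}}
    for sex, grp in wide.groupby("sex"):
        for trait in cfg.get("traits", TRACK_TRAITS):
            fu_col = "log_homa_fu" if trait == "homa_ir" else f"{trait}_fu"
            base_vals = grp["log_homa"] if trait == "homa_ir" else grp[trait]
            base_t = assign_tertiles(base_vals, grp["sex"], grp["age"],
                                     age_bin_width=width)
            base_t.index = grp.index
            fu_t = assign_tertiles(grp[fu_col], grp["sex"], grp["age"] + 6.0,
                                   age_bin_width=width)
            fu_t.index = grp.index
            tm = transition_matrix(base_t, fu_t)
            tm.proportions.round(4).to_csv(
                outdir / f"transition_{sex}_{trait}.tsv", sep="\t")
            results["persistence"][(sex, trait)] = tm.persistence
            if trait in ("fpg", "pg2h"):
                inc = incidence_by_tertile(
                    base_t, grp["prediabetes"],
                    grp["prediabetes_fu"].astype(bool),
                    base_diabetes=(grp["glycemic_category"] == "DIABETES"))
                inc.round(4).to_csv(outdir / f"incidence_{sex}_{trait}.tsv", sep="\t")
                results["incidence"][(sex, trait)] = inc
    pers = pd.DataFrame(
        [{"sex": s, "trait": t, "persistence": v}
         for (s, t), v in results["persistence"].items()])
    pers.round(4).to_csv(outdir / "persistence.tsv", sep="\t", index=False)
    try:
        results["sex_tracking_p"] = sex_interaction_test(
            wide.reset_index(), baseline_col="fpg", outcome_col="fpg_fu")
    except ValueError:
        results["sex_tracking_p"] = np.nan
    return results


def regression_stage(derived: pd.DataFrame, cfg: dict, outdir: Path) -> pd.DataFrame:
    """GEE regressions of follow-up outcomes on baseline tertiles, by sex."""
    width = float(cfg.get("age_bin_width", 2.0))
    exposures = cfg.get("exposures", TRACK_TRAITS)
    wide = _subject_wide(derived)
    rows = []
    for sex, grp in wide.groupby("sex"):
        grp = grp.reset_index()
        for exposure in exposures:
            vals = grp["log_homa"] if exposure == "homa_ir" else grp[exposure]
            grp["tertile"] = assign_tertiles(vals, grp["sex"], grp["age"],
                                             age_bin_width=width).to_numpy()
            for outcome, family in REG_OUTCOMES:
                spec = RegressionSpec(outcome=outcome, family=family)
                try:
                    fit = fit_clustered(spec, grp)
                except (ValueError, RuntimeError) as err:
                    warnings.warn(f"regression {sex}/{exposure}->{outcome} failed: {err}")
                    continue
                for level, r in fit.summary_.iterrows():
                    rows.append({"sex": sex, "exposure": exposure, "outcome": outcome,
                                 "level": level, "scale": r["scale"],
                                 "estimate": r["estimate"], "robust_se": r["se"],
                                 "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                                 "p_trend": fit.trend_p_})
    out = pd.DataFrame(rows)
    out.round(6).to_csv(outdir / "regression.tsv", sep="\t", index=False)
    return out


def _ace_row(trait: str, sex: str, fit, r_mz: float, r_dz: float,
             n_mz: int, n_dz: int) -> dict:
    ci = fit.ci95_
    return {
        "sex": sex, "trait": trait, "r_mz": round(r_mz, 4), "r_dz": round(r_dz, 4),
        "n_mz_pairs": n_mz, "n_dz_pairs": n_dz,
        "a2": round(fit.a2_, 4), "a2_lo": round(ci["a2"][0], 4), "a2_hi": round(ci["a2"][1], 4),
        "c2": round(fit.c2_, 4), "c2_lo": round(ci["c2"][0], 4), "c2_hi": round(ci["c2"][1], 4),
        "e2": round(fit.e2_, 4), "e2_lo": round(ci["e2"][0], 4), "e2_hi": round(ci["e2"][1], 4),
        "model": "ACE",
    }


def twin_stage(derived: pd.DataFrame, cfg: dict, outdir: Path) -> pd.DataFrame:
    """Twin correlations and ACE fits on follow-up traits, stratified by sex."""
    rows = []
    for sex in sorted(derived["sex"].unique()):
        sub = derived[derived["sex"] == sex]
        for trait in ("fpg", "pg2h", "log_homa"):
            wide = pairs_wide(sub, trait, visit="followup")
            corr = twin_correlation(wide[["v1", "v2"]].to_numpy(),
                                    wide["zygosity"].to_numpy())
            fit = fit_ace_continuous(corr)
            rows.append(_ace_row(trait, sex, fit, corr.r_mz, corr.r_dz,
                                 corr.n_mz_pairs, corr.n_dz_pairs))
        for cat in ("IFG", "IGT"):
            sub2 = sub.copy()
            sub2["affected"] = (sub2["glycemic_category"] == cat).astype(float)
            wide = pairs_wide(sub2, "affected", visit="followup")
            model = LiabilityACEModel(
                concordance_type=cfg.get("concordance_type", "probandwise"))
            try:
                model.fit(wide[["v1", "v2"]].to_numpy(), wide["zygosity"].to_numpy())
            except (ValueError, RuntimeError) as err:
                warnings.warn(f"liability fit {sex}/{cat} failed: {err}")
                continue
            rows.append(_ace_row(cat, sex, model, model.r_mz_, model.r_dz_,
                                 model.corr_.n_mz_pairs, model.corr_.n_dz_pairs))
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "twin_models.tsv", sep="\t", index=False)
    return out


def twin_stage_from_summary(summary_tsv: str | Path, outdir: Path,
                            concordance_type: str = "probandwise") -> pd.DataFrame:
    """ACE fits from a summary TSV instead of raw pair data.

    Correlation rows need (trait, r_mz, r_dz, n_mz, n_dz); concordance rows
    need (trait, conc_mz, conc_dz, prevalence, n_mz, n_dz).  Sex column
    optional.
    """
    tab = pd.read_csv(summary_tsv, sep="\t")
    rows = []
    for _, r in tab.iterrows():
        sex = r.get("sex", "all")
        if "conc_mz" in tab.columns and np.isfinite(r.get("conc_mz", np.nan)):
            fit = fit_ace_liability(
                conc_mz=float(r["conc_mz"]), conc_dz=float(r["conc_dz"]),
                prevalence=float(r["prevalence"]), n_mz=int(r["n_mz"]),
                n_dz=int(r["n_dz"]), concordance_type=concordance_type)
            rows.append(_ace_row(r["trait"], sex, fit, fit.r_mz_, fit.r_dz_,
                                 int(r["n_mz"]), int(r["n_dz"])))
        else:
            fit = fit_ace_continuous(r_mz=float(r["r_mz"]), r_dz=float(r["r_dz"]),
                                     n_mz=int(r["n_mz"]), n_dz=int(r["n_dz"]))
            rows.append(_ace_row(r["trait"], sex, fit, float(r["r_mz"]),
                                 float(r["r_dz"]), int(r["n_mz"]), int(r["n_dz"])))
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "twin_models_summary.tsv", sep="\t", index=False)
    return out


def run_pipeline(config_path: str | Path, *, seed: int | None = None,
                 outdir: str | Path = "twinglyc_out") -> dict:
    """Execute every stage and write a run manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    caught: list[str] = []
    manifest = {"package_version": __version__, "seed": seed,
                "config_path": str(config_path), "outputs": [], "warnings": caught}

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        stage = "simulate"
        try:
            cohort = simulate_stage(cfg, seed, outdir)
            if not cfg.get("cohort_csv"):
                sim = _simulation_config_from_dict(cfg.get("simulation"))
                if seed is not None:
                    sim = dataclasses.replace(sim, seed=seed)
                manifest["config_hash"] = sim.digest()
            stage = "derive"
            derived = derive_stage(cohort, outdir)
            stage = "summary"
            summary_stage(derived, outdir)
            stage = "track"
            tracking_stage(derived, cfg.get("tracking", {}), outdir)
            stage = "regress"
            regression_stage(derived, cfg.get("regression", {}), outdir)
            stage = "twinfit"
            twin_cfg = cfg.get("twin", {})
            if twin_cfg.get("summary_tsv"):
                twin_stage_from_summary(
                    twin_cfg["summary_tsv"], outdir,
                    concordance_type=twin_cfg.get("concordance_type", "probandwise"))
            else:
                twin_stage(derived, twin_cfg, outdir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        caught.extend(str(w.message) for w in wlog)

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.is_file()
                                 and p.name != "manifest.json")
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
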