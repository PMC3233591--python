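# twinglyc

Twin-cohort analysis of blood glucose in children and adolescents: how well
do fasting and post-load glucose *track* from childhood into young adulthood,
how strongly does a high-normal glucose rank predict incident prediabetes,
and how much of the variation is genetic?

`twinglyc` packages the full analysis chain for a prospective same-sex twin
cohort examined with an oral glucose tolerance test (OGTT) at two visits
roughly six years apart:

* **Phenotype derivation** — HOMA-IR = FPI (µU/mL) × FPG (mmol/L) / 22.5 and
  the ADA glycemic categories (NGT / IFG / IGT / combined / diabetes, with a
  prediabetes flag) from fasting and 2-hour post-load glucose.
* **Tracking** — age- and sex-specific tertiles at each visit, 3×3
  baseline→follow-up transition matrices, a middle-or-top persistence
  statistic, prediabetes incidence by baseline tertile among subjects
  normoglycemic at baseline, and a tricube local-linear smoother for
  glucose-by-age tracking curves.
* **Clustered regression** — GEE with exchangeable working correlation and
  robust (sandwich) errors, twin pairs as clusters: follow-up outcomes on
  baseline tertiles adjusted for age, Tanner stage, BMI, smoking and
  physical activity, with ordinal trend tests and a baseline×sex
  tracking-difference test.
* **Heritability** — the classical twin ACE decomposition. For a standardized
  trait the expected within-pair correlation is a² + c² in monozygotic (MZ)
  pairs and ½a² + c² in dizygotic (DZ) pairs, where a² is additive-genetic,
  c² shared-environment and e² = 1 − a² − c² unique-environment variance.
  Components are estimated by maximizing the two-group Wishart likelihood
  under a², c² ≥ 0, with 95% profile-likelihood intervals truncated at the
  boundary. Binary traits (IFG, IGT) are handled on the liability scale: a
  latent standard-normal liability thresholded at the prevalence quantile,
  twin concordances converted to tetrachoric correlations by
  bivariate-normal root finding, then the same ACE fit.
* **Synthetic cohort generator** — same-sex MZ/DZ pairs with configurable
  ACE structure per trait, a baseline→follow-up tracking correlation,
  covariates, and thresholded binary liability traits, so that every stage
  of the pipeline is testable end to end with known truth.

Built for epidemiologists and quantitative geneticists who want these
standard twin-study computations as tested, composable Python instead of
one-off scripts. Estimators follow scikit-learn conventions
(`fit`, `get_params`, fitted attributes with trailing underscores).

## Worked example

Heritability of fasting plasma glucose in males from summary twin
correlations (r_MZ = 0.63 over 218 pairs, r_DZ = 0.42 over 141 pairs):

```python
>>> from twinglyc import fit_ace_continuous, fit_ace_liability
>>> fit = fit_ace_continuous(r_mz=0.63, r_dz=0.42, n_mz=218, n_dz=141)
>>> print(f"a2 {fit.a2_:.2f} {fit.ci95_['a2']}")
a2 0.42 (0.15, 0.68)
>>> print(f"c2 {fit.c2_:.2f}, e2 {fit.e2_:.2f}")
c2 0.21, e2 0.37
```

Additive genes explain ~42% of the variance in fasting glucose, shared
environment ~21%, and person-specific environment the remaining ~37%; the
profile interval (0.15–0.68) shows the genetic share is imprecise at these
pair counts but clearly non-zero.

Impaired fasting glucose as a thresholded liability (probandwise
concordances 66.7%/43.9% at 28.2% prevalence):

```python
>>> lf = fit_ace_liability(conc_mz=0.667, conc_dz=0.439, prevalence=0.282,
...                        n_mz=218, n_dz=141)
>>> print(f"r_mz {lf.r_mz_:.3f}, r_dz {lf.r_dz_:.3f}, a2 {lf.a2_:.2f}")
r_mz 0.764, r_dz 0.361, a2 0.76
```

The tetrachoric liability correlations (0.76 MZ vs 0.36 DZ) imply a strongly
genetic liability: a² = 0.76 with shared environment at the zero boundary.

End-to-end synthetic run from the command line:

```bash
cat > config.yaml <<EOF
simulation:
  n_mz_pairs: 419
  n_dz_pairs: 222
EOF
twinglyc all --config config.yaml --seed 7 --outdir run7
```

writes `cohort.csv`, a cohort summary, per-sex transition/incidence/
persistence tables, the GEE regression table, the twin-model table and a
JSON manifest; two runs with the same config and seed are byte-identical.

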