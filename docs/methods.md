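# Methods

## The twin variance-component model

For a phenotype standardized to unit variance within each zygosity group,
the classical twin design decomposes variance into additive-genetic (a²),
shared-environment (c²) and unique-environment (e²) proportions with
a² + c² + e² = 1. MZ co-twins share all additive-genetic and all shared
environmental influences; same-sex DZ co-twins share half the additive
effects on average. The expected 2×2 pair correlation matrices are therefore

    Σ_MZ = [[1, a²+c²], [a²+c², 1]],   Σ_DZ = [[1, ½a²+c²], [½a²+c², 1]].

Fitting is by maximum likelihood on the standardized scale: with S_g the
observed pair correlation matrix of group g (estimated by double-entry
Pearson, each pair entered in both orders) and n_g its pair count, the
objective is the two-group Wishart deviance

    F(a², c²) = Σ_g n_g [ ln|Σ_g| + tr(S_g Σ_g⁻¹) − ln|S_g| − 2 ],

minimized over a², c² ≥ 0, a² + c² ≤ 1. Because both matrices have fixed
unit diagonals and the model has exactly two free parameters, the interior
optimum reproduces the observed off-diagonals exactly and coincides with the
moment solution a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ; the likelihood
machinery matters at the boundary (r_DZ < ½r_MZ pins c² at 0, r_MZ < r_DZ
pins a² at 0) and for interval estimation. Fitting on summary correlations
is identical to fitting on the raw standardized pairs that produced them.

Optimization uses SLSQP on (a², c²) with bounds and the simplex constraint,
restarted from five points spread over the simplex — the deviance surface
can be nearly flat along a² + 2c² contours when the two group correlations
carry little independent information. Sub-models (AE, CE, E) fix omitted
components at zero; `compare_models` reports the deviance, AIC and the
likelihood-ratio test against ACE, using the 50:50 χ²₀/χ²₁ boundary mixture
for single-component tests because the null value lies on the boundary of
the parameter space.

### Profile-likelihood intervals

95% intervals are the set of component values whose profiled deviance (the
deviance minimized over the remaining free parameter at the fixed component
value) lies within χ²₁(0.95) = 3.84 of the minimum, found by bisection on
each side of the estimate and truncated to [0, 1]. A component estimated at
the boundary reports a lower limit of exactly 0.00 — the signature pattern
for variance components. When the profile never crosses the cut the interval
spans the admissible range and a warning is issued.

### Binary traits: the liability-threshold model

A binary trait (IFG, IGT) is modelled as a latent standard-normal liability
exceeding the threshold z = Φ⁻¹(1 − prevalence). Twin resemblance is
summarized by concordance — probandwise, P(co-twin affected | twin
affected) = P₁₁/K, or pairwise, P₁₁/(2K − P₁₁), with K the prevalence and
P₁₁ = P(both liabilities > z). The liability (tetrachoric) correlation is
recovered by root-finding the r whose implied concordance matches the
observed one; the orthant probability P₁₁ is evaluated by reducing the
double integral to ∫_z^∞ φ(x)Φ((rx − z)/√(1−r²)) dx and applying adaptive
quadrature, giving round-trip identity r → concordance → r to better than
1e-6 (scipy's bivariate-normal CDF serves as an independent cross-check in
the tests). The ACE fit then proceeds on the liability correlations exactly
as for a continuous trait, weighted by pair counts. Summary concordances
default to the probandwise reading; raw binary pair data may also be fit
directly, with prevalence taken from the observed margin unless supplied.

## Tracking and incidence

Tertiles are cut at the empirical 1/3 and 2/3 quantiles within (sex,
age-bin) strata; age bins default to 2-year widths (the stratification
granularity is not dictated by the data, so it is configurable), and strata
smaller than 3 subjects are merged into the nearest age bin of the same sex
with a warning. Labels are a function of the trait value, so tied values
never straddle a cut-point — relevant for glucose recorded at one-decimal
precision. Transition matrices cross-tabulate baseline against follow-up
tertiles over subjects seen at both visits; the persistence statistic
P(follow-up ∈ {T2,T3} | baseline ∈ {T2,T3}) has null value 2/3 under
independent re-ranking, and being rank-based is invariant to monotone
transforms of the trait. Prediabetes incidence by baseline tertile is
restricted to subjects normoglycemic at baseline. Tracking curves use a
hand-rolled tricube-weighted local-linear smoother with nearest-neighbour
span (default 0.6, 50-point grid — display smoothing, not inference); it
matches statsmodels' lowess (it=0) to machine precision on shared inputs.

## Clustered regression

Follow-up FPG, 2hPG, log HOMA-IR (gaussian) and prediabetes
(binomial-logit) are regressed on baseline tertile (T1 reference) adjusted
for age, Tanner stage (ordinal integer), smoking, BMI and physical activity
(categorical with an explicit "NA" level retained, preserving sample size).
Models are estimated with statsmodels GEE, exchangeable working correlation
— saturated for clusters of at most two — and robust sandwich errors. With
singleton clusters the gaussian fit reduces to OLS. Trend tests recode the
tertile 1/2/3 and Wald-test the ordinal coefficient; the sex difference in
tracking is a Wald test of the baseline×sex interaction on the follow-up
value, pair-clustered. HOMA-IR enters all models on the natural-log scale
(its distribution is right-skewed; natural rather than base-10 log because
the log-scale means in the 0.5–0.9 range correspond to raw means near
2.0–2.5).

## Glycemic classification

Cut-offs (mmol/L): diabetes at FPG ≥ 7.0 or 2hPG ≥ 11.1; IFG at FPG ∈
[5.6, 7.0) with 2hPG < 7.8; IGT at 2hPG ∈ [7.8, 11.1) with FPG < 5.6;
simultaneous elevation in both ranges is its own IFG_IGT category and counts
as prediabetes (IFG and IGT each exclude it; the "and/or" prediabetes
definition includes it — the classification of doubly-elevated subjects in
published count tables is ambiguous, so the combined category keeps the
choice explicit). The printed one-decimal ranges are implemented as
half-open intervals so the five categories partition the plane with no gap
below the diabetes cut-offs. Severity is ordered NGT < prediabetes <
diabetes and is monotone in either glucose value.

## The synthetic cohort generator

The generator emulates a same-sex twin cohort followed for six years:
defaults of 419 MZ and 222 DZ pairs (55% male), baseline ages uniform on
6–21 years, follow-up at baseline + 6. Each continuous trait is drawn per
pair from a 4-variate normal over (twin1, twin2) × (baseline, follow-up)
whose correlation matrix is the Kronecker product of the twin block
(off-diagonal a²+c² or ½a²+c²) and the visit block (off-diagonal
`tracking_r`); the cross-twin cross-visit correlation is therefore their
product — the simplest separable structure, chosen because nothing in the
study design pins it down. The matrix is checked for positive definiteness
before Cholesky sampling and rejected with a diagnostic naming the offending
(a², c², tracking_r) combination.

Default trait moments follow the cohort being emulated: FPG 4.5 ± 0.5 →
5.4 ± 0.4 mmol/L, 2hPG 4.7 ± 0.85 → 5.8 ± 1.35 mmol/L, FPI 7.3 ± 4.0 →
9.3 ± 4.5 µU/mL (one pooled set; the small sex differences in means are not
emulated). ACE defaults: FPG (0.43, 0.19), 2hPG (0.27, 0.33), FPI
(0.57, 0.00). `tracking_r` defaults to 0.4, which yields a middle-or-top
persistence of ~0.75 for bivariate-normal ranks, inside the 0.67–0.76 range
the emulated cohort reports. Binary liability traits threshold the
standardized follow-up liability at the prevalence quantile (defaults: IFG
28.2%, IGT 7.5%, both coupled to their continuous source trait; an
uncoupled trait draws an independent liability with its own ACE structure).
Covariates are independent of glucose except an optional linear BMI effect
on follow-up FPG that gives regression recovery tests a known target;
within-pair BMI correlation defaults to 0.5 (configurable, not inferred —
the within-pair structure of covariates is not documented for the emulated
cohort). Tanner stage is a coarse deterministic map of age. Gaussian insulin
values are floored at 0.5 µU/mL; with the default moments this touches a
negligible tail but slightly perturbs FPI pair correlations in extreme
configurations.

What the generator does **not** emulate: measurement error distinct from
unique environment, assortative mating or gene–environment interplay,
non-normal trait distributions (real insulin is right-skewed; here only the
derived HOMA-IR is log-handled), opposite-sex pairs, age trends in variance,
or informative dropout (only completely-at-random follow-up dropout is
available). Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to these violations.

## Problem sizes and numerical choices in the test suite

Recovery checks run at 20000 pairs per zygosity across 20 random simplex
points for continuous traits (tolerance ±0.03), with within-pair
correlations estimated from both visits' measurements — the generator draws
the same pair structure at each visit, and pooling visits roughly halves
the Monte-Carlo variance of the recovered components. The liability-scale
round trip runs at 50000 pairs per zygosity at (a², c²) = (0.5, 0.2) and
prevalence 0.3 with tolerance ±0.05: dichotomization discards most of the
liability information (the sampling sd of the recovered a² is ≈0.04 at
20000 pairs, whether the tetrachoric is computed from concordances or from
the full contingency table), hence the larger cohort and band. Null
calibrations use 200 replicate cohorts (persistence) and 500 replicates
(GEE trend p-values, KS uniformity at α = 0.01). ML fits are verified
against a 0.01-step brute-force scan of the (a², c²) simplex, and profile
interval endpoints against a 0.001-step profile-deviance scan (agreement
within 0.005). Optimizer tolerances: SLSQP ftol 1e-12, scalar profiles
xatol 1e-10, tetrachoric root-finding xtol 1e-12, orthant quadrature
epsabs/epsrel 1e-12.

## Known limitations

* The ACE fit operates on correlations of standardized data; means and raw
  variances are not modelled, so estimates can differ in the second decimal
  from full mean-and-covariance structural-equation fits on raw data.
* Tetrachoric correlations from very small concordances or prevalences sit
  near the −1/+1 boundary and propagate into boundary-heavy ACE fits; the
  package reports these honestly rather than smoothing them.
* GEE assumes missingness completely at random; no weighting is provided.
* The sex-difference-in-tracking test is one reasonable formalisation
  (baseline×sex interaction under pair-clustered GEE) of a comparison whose
  original form is unstated.
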