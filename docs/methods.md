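# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `proacs`.

## Composite scoring and the ACS

Composite grades are a fixed lookup, not a model. The grid is shipped as
data (`src/proacs/data/composite_grid.csv`, 215 rows: one per reachable
response tuple across the seven admissible attribute subsets) so corrected
or alternative grids are drop-in replacements. The shipped values are the
published PRO-CTCAE composite grading algorithm; they were verified
cell-by-cell against the ProAE `toxScores` reference implementation, whose
outputs are frozen in `tests/data/proae_toxscores_oracle.csv` and re-checked
by the test suite. Grid values are never derived at run time.

A term's composite is missing iff any constituent attribute response is
missing. The ACS is the arithmetic mean of a patient's non-missing
composites; by default it is only reported for fully observed rows
(`min_coverage=1.0`), matching an impute-then-analyze flow. A lower
`min_coverage` supports imputation-free use; the ACS under partial
missingness is then a per-patient complete-term mean. Binary yes/no
PRO-CTCAE items have no composite grade and are rejected at term
definition.

The external-criterion summary averages user-supplied subscale scores
(e.g. 13 QLQ-C30 scales, excluding global health/QoL and financial
impact) that must already be oriented so higher = worse. Scoring the
criterion instrument itself from item level is out of scope.

## Polychoric correlations

Two-step estimation: thresholds are set from the inverse-normal cumulative
marginals of each ordinal variable; then, per pair, the latent
bivariate-normal correlation maximizes the contingency-table likelihood
over (−0.999, 0.999) (bounded scalar minimization, tolerance 1e-8).
Bivariate-normal rectangle probabilities use the smooth single-integral
representation of the CDF with 48-point Gauss–Legendre quadrature, clipped
at 1e-12. Zero contingency cells receive a 0.5 continuity correction by
default (configurable off; the cross-implementation comparison in the
tests disables it because the reference implementation applies no
smoothing — with it off the two agree to <1e-4). The asymptotic variance
of each estimate is the inverse observed information of the profile
likelihood, from a central second difference at the maximum. Categories
never observed simply contribute no threshold (collapse), with a warning
below 4 interior thresholds. If the assembled matrix has an eigenvalue
below 1e-8 it is repaired by eigenvalue clipping and rescaling to unit
diagonal, and flagged.

## Dimensionality

The eigenvalue-ratio retention rule computes R_i = λ_i/λ_{i+1} for the
descending spectrum of a correlation matrix and retains the index
maximizing R_i (ties to the smaller index; denominators below 1e-10 are
undefined and skipped). The default eigen/PCA input is the Pearson matrix
of the numeric composite scores, with polychoric available by flag — the
Pearson choice makes the PC1/ACS comparison a least-assumption statement
about the observed scores. PC1 scores are standardized complete rows
projected on the first eigenvector, oriented so that PC1 correlates
positively with the row mean of the composites (a deterministic sign
convention across platforms).

## One-factor DWLS CFA

The model is fitted to the non-redundant lower triangle of the polychoric
matrix: minimize

F = Σ_{a<b} w_ab (r_ab − λ_a λ_b ψ − θ_ab)²

where θ_ab is nonzero only for explicitly freed residual pairs, and
w_ab = 1/γ_ab with γ_ab the asymptotic variance of √n(ρ̂_ab − ρ_ab)
(the n-scaled polychoric variance; on this scale (n−1)·F_min behaves as a
chi-square statistic when the model holds). Identification fixes the first
indicator's unstandardized loading to 1 with free factor variance ψ; the
standardized solution is l_a = λ_a √ψ. Optimization is L-BFGS-B with an
analytic gradient, initialized from the first eigenvector (three ψ
scalings as extra starts), relative tolerance 1e-12. Degrees of freedom:
p(p−1)/2 − p − (#freed pairs); for 8/16/17 indicators, 20/104/119.

Standardized |loadings| ≥ 1 (negative residual variance) raise a flagged
Heywood error; df = 0 yields a "just-identified" status with fit indices
suppressed. On a correlation matrix without asymptotic variances the same
routine runs as unweighted least squares (used for the closed-form triad
checks).

Fit indices: CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b, χ²−df, 0) with the
independence model (all correlations zero, same weights) as baseline;
TLI = ((χ²_b/df_b)−(χ²/df))/((χ²_b/df_b)−1); RMSEA =
√(max(χ²−df,0)/(df(n−1))) with a 90% CI from inverting the noncentral
chi-square CDF (bisection on the noncentrality); SRMR is the root mean
square of the off-diagonal residuals. The chi-square is the raw DWLS
statistic without a mean-and-variance adjustment; a robust correction is a
documented non-goal for this version, so printed χ² values are comparable
across this package's own runs rather than across software families.

Residual screening returns pairs with |r_obs − r_model| at or above a
threshold (default 0.20), largest first, to seed respecified models;
freeing residual covariances can only decrease χ² (nested models).

Factor scores use the regression method, scores = Z Σ⁻¹ l on standardized
complete rows with Σ the standardized model-implied matrix (including any
freed residual covariances), oriented positively with the ACS. McDonald's
ω = (Σl)²/((Σl)² + Σ(1−l²)); coefficient α is the classical formula on
complete composite rows. α is computed on the ordinal composite scale and
is therefore attenuated relative to ω from polychoric loadings; under
tau-equivalence it matches ω computed from Pearson-scale loadings.

## Latent profile analysis

Diagonal Gaussian mixtures fitted by EM; variances are shared across
classes by default (class-varying behind a flag), mixing proportions and
class means free. Free parameters: (k−1) + kp + p (shared) or + kp
(class-varying). Rows with missing cells contribute their marginal
likelihood over observed coordinates, which is exact for diagonal
covariance. Initialization is k-means++ seeding; the best of `starts`
random starts is kept (default 50 in the API, 10–20 in the bundled
analyses); convergence at relative log-likelihood change < 1e-6 or 500
iterations, with the per-iteration log-likelihood trace stored for
monotonicity checks. A class whose mixing proportion falls below 1/n
aborts that start; if all starts degenerate an error is raised.

Per-term variances are floored at 0.05 composite-units². Composite scores
have unit resolution, and without a floor the EM can lock a class onto an
exact discrete response pattern and diverge toward a zero-variance
optimum; the floor is well below any substantively meaningful within-class
variance.

Labels are canonicalized by ascending ACS of the class mean profile so
solutions are comparable across seeds. Relative entropy is
1 − Σ(−p log p)/(n log k) (not applicable at k=1). The selection table
reports log-likelihood, AIC, BIC, entropy, average posterior probability
range and class sizes, and flags the BIC-minimal row — the final choice of
k remains with the analyst, since interpretability and class sizes also
matter. The bootstrapped LRT simulates from the fitted (k−1)-class model
and reports the Monte Carlo p-value (1 + #{T_b ≥ T_obs})/(B + 1); runs
with more than 20% non-convergent replicates are flagged. The
Lo–Mendell–Rubin test is not implemented.

## Sequential term reduction

Starting from the full set, terms are removed one at a time (default:
ascending endorsement, the fraction of patients with composite > 0, ties
lexicographic; alternatively ascending standardized loading, or any
user-supplied order) down to 3 terms. Each step recomputes retention, PC1
variance share, ω, the DWLS fit (with optional residual respecification),
and the reduced-set ACS correlations with PC1, factor scores, the external
criterion, and the full-set ACS. Heywood and just-identified failures are
recorded as step markers, as such failures are expected near the bottom of
the trace, and do not abort it.

## Imputation

The pipeline's imputer is a deliberately simple round-robin conditional
imputer: initialize missing cells with the column mode, then cycle through
columns (least missing first) predicting each from all others with a
depth-6 classification tree, until no imputed cell changes or 10 cycles.
It is deterministic under its seed, keeps values in the observed category
range, and is clearly labeled in reports — it is not random-forest
imputation, and results under heavy missingness are method-dependent.
Columns with ≥60% missingness are refused.

## Synthetic-data generator

Per patient: latent class c_i ~ Categorical(π), burden factor
f_i ~ N(0,1); per term, s_ij = δ_j + μ_{c_i j} + λ_j f_i + ε_ij with
ε ~ N(0, 1−λ_j²), where δ_j is a per-term prevalence offset and μ a class
mean shift in latent (probit) units. Each attribute of a term observes
(s_ij + ν)/√(1+σ_ν²) with independent attribute noise ν (variance 0.1 by
default) — attributes are highly but not perfectly concordant, so
composite grading is exercised on non-degenerate combinations — and bins
it by attribute-specific ordered thresholds; the normalization keeps the
attribute latent unit-variance, so thresholds placed at N(0,1) quantiles
reproduce target category probabilities exactly. The external criterion is
criterion_loading·f + noise at unit variance. Missing-by-design masks are
Bernoulli per (patient, term).

Cohort presets `lung8` (n=183), `breast16` (n=260) and `headneck17`
(n=146) use term sets, attribute patterns and standardized loadings
representative of treated lung, breast and head/neck cohorts;
missing-by-design rates span 3–7%, 11–37% and 3–32% respectively when
enabled. Default thresholds place frequency cutpoints below severity below
interference (symptoms are reported before they are severe, and severe
before they interfere). Prevalence offsets are 1.2·(λ_j − mean λ), making
more salient terms also the more endorsed ones, as in real cohorts. The
default criterion loading is 0.90: with ordinal attenuation
(r(ACS, f) ≈ 0.86) this yields observed ACS–criterion correlations near
0.78–0.80, the regime a validated same-construct summary score occupies.

The `lung8` class structure (`with_classes=True`) mimics an observed
four-profile pattern: a large low-burden class, a small high-burden class,
and two mid-burden classes trading predominant symptoms. A separate
`wellsep_lpa_config` provides the well-separated regime for mixture
recovery studies: within-class loadings of 0.3 (latent profile models
assume local independence given class), thresholds spread so all class
means stay in the interior of the 0–3 scale, and exactly symmetric trading
classes (shortness of breath + cough vs decreased appetite + fatigue, all
severity+interference terms), so the two trading classes share their
expected ACS by construction while differing by 2.4 latent SD on the
traded terms.

What the generator does not emulate: demographic covariates,
treatment-arm structure, survey-phase administration schedules beyond
per-term Bernoulli masks, longitudinal dependence, and the non-Gaussian
within-class shapes of real composite distributions beyond what
thresholding induces. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative model, not
performance guarantees on any particular clinical dataset.

## Problem sizes in the bundled analyses

The test suite and the reproduction script use n=300–1000 cohorts,
200 replicates for retention rates, 50 replicates for mixture model
selection (6 class counts × 10 starts each), and 200 outer × 19 inner
replicates for bootstrap-LRT calibration — sizes at which the Monte Carlo
error of each reported rate is well inside the asserted margins.

## Known limitations

- No standard errors or z statistics for factor loadings; no robust
  (mean-variance adjusted) chi-square.
- Multi-factor, bifactor, formative and network models are out of scope.
- The BLRT refits with a reduced number of starts for speed; with highly
  multimodal likelihoods its p-value can be conservative.
- The imputer is a pragmatic stand-in, not a state-of-the-art method.
- Polychoric estimation is pairwise two-step; a full-ML or weighted
  multi-pair estimator is not provided.
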