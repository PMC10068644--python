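# Methods

This note records the models implemented in `glucometab`, the design of the
synthetic data every stage is validated on, and the numerical choices a
user or reviewer would want to audit. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Minimal-model kinetics

The glucose-disappearance model treats post-bolus glucose G(t) (mg/dL) as
cleared at a basal rate p1 (glucose effectiveness, S_G, per minute) plus a
remote insulin-action state X(t) that builds at rate p3 from the insulin
excursion above basal and decays at rate p2; insulin sensitivity is the
steady-state gain S_I = p3/p2, reported in x 10^-4 min^-1 per uU/mL so that
the disposition index DI = AIR x S_I lands on its conventional scale.
Insulin kinetics clear at rate n (per minute) with glucose-stimulated
secretion gamma (G - h)+ t above the threshold h. The secretion term is
clamped at zero for G <= h by default — the standard convention, since
negative secretion is unphysiological — with `clamp_secretion=False`
integrating the unclamped form.

Basal levels Gb and Ib are the means of the pre-injection (t <= 0) samples.
AIR is the mean incremental insulin above Ib over samples in [2, 8] min,
with sign retained. HOMA uses the classic single-formula indices
(HOMA-IR = G_mmol x I / 22.5; HOMA-B = 20 I / (G_mmol - 3.5), undefined and
logged when fasting glucose is at or below 3.5 mmol/L); the iterative
updated-HOMA computer model is deliberately out of scope.

### Fitting

Fitting is two-stage and decoupled, as in the MINMOD tradition: the glucose
model takes observed insulin as a fixed forcing input, and the
insulin-kinetics model takes observed glucose. Two numerical choices matter
and were validated by simulate-then-fit experiments:

* **Forcing interpolation.** The forcing input is interpolated with a
  shape-preserving monotone cubic (PCHIP) over the post-injection samples
  only. A piecewise-linear chord systematically overestimates a convexly
  decaying insulin curve and biased recovered (p2, p3) by several percent;
  interpolating across the injection instant from the pre-injection basal
  is worse, since the sample at t = 0 does not represent the immediate
  post-bolus insulin.
* **Optimization.** Sum of squared residuals over samples with
  t >= `fit_window_start` (default 8 min, the usual real-data convention
  for early mixing artifacts), minimized by Levenberg-Marquardt on
  log-parameters (positivity by construction), finite-difference step 1e-4
  (a smaller step drowns in integrator noise), integrator tolerance 1e-8,
  and 8 seeded multi-starts: with 5 starts roughly a fifth of noiseless
  parameter-grid fits ended in a distant local minimum, with 8 none did.
  A fit is flagged non-identifiable (S_I reported missing) when insulin
  never leaves basal, in which case only (p1, G0) are estimated from the
  pure exponential relaxation.

### Recovery study

The parameter-recovery experiments (test suite and acceptance script) use a
minute-sampled schedule (t = 1..180 plus four pre-injection samples) and fit
from t >= 2 min. The simulator produces no early mixing artifact, so the
8-minute exclusion would discard the most p1-informative samples for no
physical reason; at sparser schedules S_G sits on a flat p1-versus-(p2, p3)
likelihood ridge and its recovery error at 2% glucose noise roughly doubles.
On the stated protocol, noiseless recovery of (p1, p2, p3) is within 1%
across a 10-point seeded grid, and median recovery error at 2% glucose CV
(100 replicates) is well under 10% for both S_I and S_G.

## Synthetic cohorts

The generator emulates a family study of roughly 42 extended families and
572 genotyped-like individuals, with a second cohort of ~1,112 for the
comparison stage.

* **Pedigrees.** Each family has two founder couples; their children form
  the second generation, and one child of each couple is mated to produce
  grandchildren. This yields additive-relationship entries of 0.5
  (parent-offspring, full sibs) and 0.25 (grandparental, avuncular) and a
  positive-semidefinite relationship matrix; family sizes are drawn from a
  configurable range and can be nudged to hit an exact cohort total.
  Pedigree depth and size distribution are design choices — no real
  counterpart is published.
* **Physiology.** Age (42.3 +/- 13.7 y) and BMI (30.0 +/- 6.8 kg/m^2) are
  normal; S_I (1.64 +/- 1.17 x 1e-4), S_G (0.021 +/- 0.008 /min), AIR
  (1013 +/- 830), fasting insulin and the remaining kinetic parameters are
  log-normal with the stated means/SDs, so all are positive and
  right-skewed. A family-level normal component carries a configurable
  share (`family_icc`, default 0.30) of each log-scale variance, preserving
  the marginal moments at any intraclass correlation. Stored minimal-model
  parameters are internally consistent (p1 = S_G, p3 = S_I_raw x p2), the
  bolus raises glucose by ~190 mg/dL, and the first-phase insulin peak I0
  is sized so the 2-8 min incremental mean under clearance n reproduces the
  drawn AIR.
* **Trait panel.** The pipeline's default trait stage applies multiplicative
  log-normal measurement noise (CV 0.05) to the true S_I, S_G and AIR,
  takes DI as the product of the noisy AIR and S_I, and computes HOMA from
  the fasting values. A second mode (`trait_mode="fsigt_fit"`) simulates a
  full FSIGT per individual and estimates the panel by minimal-model
  fitting; it is exercised in tests and examples at small n. The default
  exists because fitting 571 ODE models per run adds minutes of compute
  without changing what the downstream statistics see: a noisy version of
  the same physiology.
* **Metabolome.** Metabolites live in sub-pathway blocks of 4-12 with a
  shared latent factor per block: z_j = sqrt(rho_b) f_b + sqrt(1-rho_b)
  eps_j, so the expected within-block correlation is rho_b (drawn from
  0.2-0.6 by default). A planted effect beta on a trait replaces z_j by
  beta T + sqrt(1-beta^2) z_j with T the standardized transformed trait, so
  beta is the latent metabolite-trait correlation. Abundance is
  exp(mu_j + sigma_j z_j) (mu in [-0.5, 0.5], sigma in [0.3, 1.0]): right-
  skewed, as untargeted panels are. Missingness censors the lowest
  quantiles per metabolite (detection-limit style); six metabolites exceed
  50% missingness by default and a designated individual carries 132
  planted +/- 4 SD outliers, so the QC stage reproduces the emulated
  counting (733 -> 727 metabolites, 572 -> 571 individuals) as an emergent
  result rather than a hard-coded one.
* **What it does not emulate.** Real metabolome correlation structure
  beyond single-block factors, batch/run-day artifacts (removed upstream in
  the emulated workflow), genotypes, assay chemistry, and any joint
  distribution beyond the stated moments. Passing tests certify the
  statistical machinery, not biological realism. The default planted truth
  is sparse (five metabolites per trait at |beta| = 0.3, plus one
  "glutamate-like" metabolite with a differential S_I effect of -0.35
  vs -0.12 between the cohorts); real metabolome-trait signal is denser
  and more collinear.

## Metabolite QC

Order: missingness filter (> 50% missing, strict) -> minimum imputation ->
unit-median rescaling -> +/- 4 SD outlier-individual screen (strictly more
than 100 flagged metabolites removes an individual) -> 1%/99% winsorization.
Quantiles are type-7 (linear interpolation between order statistics)
throughout. The outlier screen runs on rescaled, pre-winsorization values
and includes the individual under test in the mean/SD; it must precede
winsorization because no 4-SD outlier can survive 1%/99% capping. Two
properties worth knowing: capping 1%/99% tails never moves a median, and
interpolated quantiles are scale-equivariant, so rescaling and winsorization
in fact commute exactly — the fixed order is a convention, not a numerical
necessity; and winsorization is exactly idempotent only when (n-1)p is
integral (the quantile is an order statistic), otherwise a second pass can
nudge the capped values slightly.

## Mixed-model association

With relationship covariance K (family blocks of ones, or the additive
relationship matrix built by the recursive tabular method), the model
y = Xb + g + e, g ~ N(0, sigma_g^2 K), e ~ N(0, sigma_e^2 I) is estimated
by REML on the eigenbasis of K: rotating by the eigenvectors diagonalizes
the covariance to sigma_e^2 (delta S + I) with delta = sigma_g^2/sigma_e^2,
and the profiled REML criterion is optimized in log(delta) (bounded scalar
search, tolerance ~1e-10, the delta = 0 boundary checked explicitly so the
zero-variance case reduces exactly to OLS). The eigendecomposition is done
once per trait and reused across all metabolites, which is what makes a
727 x 6 scan take seconds. Metabolites are standardized (mean 0, SD 1)
within the analyzed samples; betas are therefore per-SD-of-metabolite on
the transformed-trait scale. Wald tests use the standard normal reference
(not a t with estimated denominator degrees of freedom; at n >= 500 the
difference is negligible). Nonpositive values under the log transform are
dropped and counted. Residualization subtracts fitted fixed effects and
BLUP-predicted random effects from the null (covariates-only) model.
Cross-checks in the test suite: ordinary least squares at zero family
variance (1e-6), statsmodels MixedLM on the family-intercept mode, an
independent recursive-kinship oracle for the relationship matrix, null
P-value uniformity and calibrated type-I error over 1000 null metabolites.

## Elastic net and stability selection

The single penalized objective below is the only selection algorithm
implemented; descriptions of elastic nets as "ridge first, then lasso on
the ridge coefficients" are a narrative account of how the combined penalty
behaves, not a separate procedure, and no second mode is provided.

The objective is the literal sum-of-squares form (no 1/n or 1/(2n) factor);
to transfer a penalty strength from mean-squared-error solvers use
lambda_here = 2 n a_meansq at the same l1_ratio — the test suite uses
exactly this mapping to cross-check against scikit-learn to 1e-8. Cyclic
coordinate descent with soft-thresholding, unpenalized intercept,
convergence when the largest coefficient change in a full sweep is below
1e-10, per-sweep objective monotonicity asserted, and an active-set
strategy (full sweep, then inner sweeps over the nonzero set) with warm
starts along a descending lambda path. The inner sweep is numba-compiled
when numba is importable, with an identical pure-python fallback.

The ridge weight comes from a log-spaced grid (25 points spanning
1e-4 lambda_max to lambda_max) maximizing adjusted R^2 with p = 1 + active
coefficients, ties to the larger lambda. One caveat is documented rather
than hidden: when p is comparable to n, the in-sample R^2 of a *selected*
model is inflated by selection, and the adjusted-R^2 criterion drifts
toward the saturated end of the path. The `max_active` option caps the
admissible active-set size; the pipeline passes n/8 so that per-draw models
stay sparse enough for the >20% stability rule to be informative. The
unrestricted criterion is preserved as the operation's default.

Stability selection: 200 bootstrap draws by default at desk scale (the
emulated workflow used 2000 — selection frequencies at 200 draws have a
binomial SE of ~3 percentage points, which does not move the >20% decision
for the effect sizes planted here); each draw trains on 90% of the sample,
drawn as whole families by default because observations correlate within
pedigrees (individual-level subsampling and classical with-replacement
resampling are flags); refit ordinary least squares on each draw's active
set (rank-deficient refits fall back to the penalized coefficients,
logged); selected set = nonzero in strictly more than 20% of draws;
model-average coefficients and 25/50/75% quantiles computed over all draws
including zeros. A known behavior on sparse synthetic truth: draws share
~80% of their rows, so a null metabolite that is correlated with the
response in this one sample recurs across draws and can cross the 20%
rule; planted true effects dominate the selection frequencies, but the
selected set is not guaranteed to be a subset of the Bonferroni-significant
set.

## Cross-cohort comparison

Z = (b1 - b2)/sqrt(SE1^2 + SE2^2) with a two-sided normal P, applied per
(metabolite, trait) after an inner join of the two association tables;
Bonferroni control at 0.05/M. The worked examples reproduce the published
two-ancestry glutamate comparisons from their printed per-cohort
coefficients to within the rounding of those inputs (the AIR row to three
digits; the others within 2-15% depending on how coarsely their inputs are
printed). Antisymmetry under cohort swap and invariance under common
rescaling of betas and SEs are exact and property-tested.

## Pipeline and reproducibility

Stages run in order simulate -> traits -> QC -> associate -> select ->
compare -> report; every intermediate is TSV (JSON twins for QC report,
truth and run log), floats at fixed "%.10g" precision, and all randomness
derives from one seed through `numpy.random.SeedSequence`, so a config+seed
pair reproduces the output directory byte for byte — asserted in the test
suite at full emulated scale (571 individuals, 733 metabolites, 200
bootstrap draws; about two minutes per run on one CPU). Report surfaces:
cohort characteristics (mean/SD/IQR), the most significant metabolite per
super-pathway per trait (exact-P ties break to the smaller metabolite id),
pairwise overlap counts of trait-significant sets, Spearman trait
correlations (pairwise-complete; equal to Pearson on ranks), the
cross-cohort comparison table, and adjusted-R^2 residual-variance-explained
summaries for the univariate-significant and the stability-selected sets.

## Known limitations

* S_G recovery at sparse sampling schedules is intrinsically imprecise
  (flat likelihood ridge); the package reports what the data support rather
  than regularizing the ridge away.
* The adjusted-R^2 grid criterion requires the `max_active` guard near
  p ~ n (above); a cross-validated criterion is deliberately out of scope.
* The >20% stability rule admits occasional in-sample-lucky nulls on sparse
  truth; interpret selection frequencies together with the model-averaged
  coefficients.
* HOMA is the classic formula, not the iterative updated model; kinship
  mode assumes a correctly specified pedigree with no inbreeding loops
  beyond what the tabular method handles.
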