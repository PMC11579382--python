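# Methods

This note documents the models, algorithms, defaults and deliberate
simplifications in `growthgwas`, in the order data flows through the
package.

## Synthetic cohorts (`growthgwas.simulate`)

The generator produces cohorts with the statistical structure the
framework assumes, so that every downstream stage has ground truth.

**Mean curve.** The default fixed-effect curve is a truncated-power cubic
spline in age with knots at 1, 8 and 12 years whose coefficients were
chosen once to mimic a typical European-ancestry childhood BMI curve:
BMI ≈ 13.5 kg/m² at two weeks, adiposity peak ≈ 17.7 kg/m² at 0.74 yr,
rebound ≈ 15.3 kg/m² at 5.0 yr, ≈ 21.6 kg/m² at 18 yr, infancy slope
≈ 0.53 log-BMI/yr. Girls get a small intercept shift (−0.02 log units).

**Random effects.** Naive independent priors on polynomial coefficients
produce exploding curves. Instead, subject deviations are defined as a
cubic through correlated Gaussian values at four anchor ages (0.04, 5, 11,
17 yr; SD 0.10 log units, AR-type correlation 0.7), and the implied
coefficient covariance `G = M⁻¹ Σ_d M⁻ᵀ` is used. This keeps each child's
deviation band near ±0.1 log-BMI at every age — about a 10% BMI spread,
realistic for cohort data.

**Visits and noise.** Fifteen scheduled visits from 2 weeks to 17 years
with Normal jitter (SD 0.08 yr), truncated to the age window; residual SD
σ = 0.035 log units; optional CAR(1) correlation φ (default 0). Weight is
back-derived as `exp(log BMI)·height²` from a monotone logistic stature
curve, so `weight/height²` reproduces the simulated BMI to machine
precision — height itself is never modelled, it only needs to exercise the
height QC rules.

**Genetics.** Dosages are Binomial(2, EAF) with EAF ~ U(0.05, 0.5). The
variant panel (positions, alleles, EAF, imputation INFO) is deterministic
given the panel size only, so cohorts simulated with different seeds share
a panel and can be harmonised and meta-analysed. Planted effects act
additively on named random-effect coefficients (dosage × effect added to
`b_i`), the generative model under which slope/AUC GWAS has known truth.

**Planted faults.** Same-day duplicates, kg→lb unit switches (×2.2046),
carried-forward height+weight, height drops (5 cm below the previous
visit's recorded height — relative to the child's own record, otherwise
natural growth masks the fault), and gross outliers (weight ×20, sized to
exceed the |z| > 25 extreme-value rule). At most one fault per record; a
ledger of every planted fault supports exact sensitivity scoring.

**Reproducibility.** Each subject draws from an RNG sub-stream keyed by
(seed, subject index): output is byte-identical across runs and a
subject's data does not change when the cohort is enlarged.

What the generator does *not* emulate: secular trends, relatedness/twins,
informative dropout, measurement devices differing by source, or
linkage disequilibrium between variants. Passing tests therefore
demonstrate correctness of the machinery under the assumed model, not
robustness to those real-data complications.

## Growth QC (`growthgwas.qc`)

A self-contained, deterministic version of the standard paediatric
cleaning taxonomy (the reference tooling does not publish its internal
parameters, so these are module decisions, stated here):

1. `missing_component` — absent or non-positive weight/height.
2. `same_day_duplicate` — same (child, age); first record in file order
   is kept, the rest flagged.
3. `carried_forward` — identical consecutive value of the same measure.
4. `unit_switch` — robust |z| > 3.5 against a sex-specific running median
   of log weight, where dividing (or multiplying) by 2.2046 brings the
   corrected |z| below 2. The z gate is 3.5 because the cross-sectional
   log-weight spread (~0.10–0.17) makes a kg↔lb shift (0.79 log units)
   only ~4.5–6 local SDs; the confirmation step carries the specificity
   (measured: 92% recall, no false unit-switch flags, overall QC false
   positives 2.4% at default settings).
5. `extreme_z` — robust |z| > 25 for weight or height.
6. `height_decrease` — drop > 3 cm between sequential heights.
7. `single_measure_pair_mismatch` — single-visit children whose weight
   and height z-scores disagree by > 5.
8. `moderate_outlier_ewma` — de-trended residual further than 3 robust
   SDs from the exponentially weighted moving average (half-life 0.5 yr in
   age) of the child's other residuals; records whose neighbours carry
   total weight < 0.2 (no visit within ~1.2 yr) are not judged.
9. `error_load` — more than half of a child's records flagged → all
   flagged.

Robust z-scores de-trend log values with a centred 31-record running
median within sex (record-count windows adapt to sampling density) and
scale by a local MAD floored at half the global MAD. Flags are recomputed
from data alone, so flagging is idempotent. `derive_analysis_set` drops
flagged records, restricts to the analysis window (default 2 weeks–18
years, inclusive; 16 years for short cohorts), optionally removes
multiple births, and derives `log_bmi = ln(weight/height²)`.

## Trajectory mixed models (`growthgwas.lmm`)

Design matrices use the truncated power basis: `[1, t, …, t^d]` plus
`(t−κ)₊^p` per knot, in that fixed column order. Random bases are
reductions of the fixed basis (lower polynomial degree and/or lower-degree
knot terms on shared knots). Categorical covariates (e.g. source) enter
the fixed effects as dummies against the first sorted level.

**Estimation.** The marginal likelihood factorises over subjects;
subjects with equal visit counts are stacked so each evaluation is a few
batched Cholesky factorisations. β and σ² are profiled out analytically;
the free parameters are the log-Cholesky factor of `G/σ²` (PSD by
construction) and logit φ. The optimisation is staged:

1. *Method-of-moments start*: covariance of per-subject
   ridge-regularised OLS coefficients, eigenvalue-floored to PSD.
2. *ECME iteration*: closed-form updates (GLS for β, conjugate E/M steps
   for G and σ²), monotone in the marginal likelihood; convergence when
   the log-likelihood changes by < 1e-8·(1+|ℓ|) (the attainable precision
   scales with |ℓ|), cap 500 iterations. With CAR(1), the data are
   whitened at the current φ, ECME runs on the whitened data, and φ is
   re-optimised on the profiled likelihood (bounded scalar search on
   [~0, 0.98]); the coordinate ascent stops when the profiled deviance
   changes by < 1e-4.
3. *Quasi-Newton polish*: L-BFGS-B on the profiled deviance with two
   finite-difference step sizes (1e-5 then 1e-7 relative — the coarse step
   is robust far from the optimum, the fine one recovers the last digits);
   single-parameter problems finish with a Brent solve. A pure
   quasi-Newton approach without the EM stage was tried first and
   systematically stalled in the flat, ill-conditioned log-Cholesky
   valley, hundreds of log-likelihood units short.

Final estimates (β̂, σ̂², SEs) are recomputed at the optimum via whitened
least squares (QR, not normal equations) so they do not pay the squared
condition number of the spline design. ML is the default so AIC/BIC are
comparable across fixed-effect structures; REML is available.

**Convergence bookkeeping.** `ok` / `warning` / `error` mirror grid-run
practice: warnings for iteration caps, variance components at the zero
boundary, φ at its ceiling, or near-singular fixed-effect information;
errors for failures — no exception escapes a grid. The EM log-likelihood
trace is kept on the fit (monotone up to ~1e-5 numerical wobble from the
guarded `G⁻¹`).

**Diagnostics.** AIC = −2ℓ + 2k, BIC = −2ℓ + k·ln(n_obs) with k = p +
q(q+1)/2 + 1 (+1 with CAR(1)); RMSE over conditional residuals; marginal
R² = var(Xβ̂)/(var(Xβ̂) + mean-trace(ZGZ') + σ²), conditional R² adds the
random-effect term to the numerator (variance-partition convention). ICC
is reported with the intercept-only formula `G₀₀/(G₀₀+σ²)` — an age-zero
simplification when slopes are random, chosen for a single-number summary.

## Model selection (`growthgwas.selection`)

The default grid crosses {cubic slope; linear splines (5.5, 11 yr); cubic
splines (2, 8, 12 yr a priori)} in the fixed effects with
reduced-complexity random bases and {independent, CAR(1)} residuals — 16
cells, fitted per sex, every cell recorded with its status. Ranking never
prefers a failed fit. `select_preferred` requires status `ok` in every
cohort × sex, then takes the smallest summed AIC (AIC differences below
1e-6 are treated as ties, broken by BIC then parameter count), and reports
better-AIC-but-ineligible specifications. Knot refinement refits the
chosen cubic-spline model over first knots {1, 1.5, 2} × second knots
{6, 7, 8} (third knot fixed at 12), and recommends the best-AIC
combination whose implied mean AP age is plausible (default window
0.5–1.0 yr, reflecting prior evidence of a population mean near nine
months). The grid's "visual inspection" step is replaced by that
automated plausibility constraint.

## Phenotype derivation (`growthgwas.phenotypes`)

Curves are predicted on a 0.01-yr grid (default 2 weeks–17 yr; shorter
for cohorts followed to 16). AP is the first interior local maximum
(strict discrete sign change, tolerance 1e-12, ties to the earliest age)
of log BMI with age in [0.25, 10]; AR the first interior minimum after the
AP in the same window; if either is absent or the AP does not precede the
AR, all four AP/AR values are missing — a boundary plateau never counts.
Slopes are two-point differences with endpoints evaluated exactly from
the model coefficients (grid-step independent); AUCs integrate the basis
analytically (`∫(t−κ)₊³ = (t−κ)₊⁴/4`), so AUC is additive over abutting
windows to machine precision. Windows falling outside the prediction
range come back missing for every child; other missingness is
per-phenotype. Outlier exclusion uses linear-interpolation (type-7)
quartiles with bounds Q1 − 2·IQR and Q3 + 2·IQR; a child outside bounds on
*any* phenotype is excluded from all downstream analyses. Summaries
include per-sex means/SDs, pairwise-complete Pearson correlations and
sex-adjusted z-score regressions of each phenotype on end-of-trajectory
BMI (adjusted R²).

## GWAS and meta-analysis (`growthgwas.assoc`)

Per-variant OLS of the phenotype on dosage + covariates via
Frisch–Waugh residualisation (one QR for the covariates, vectorised
per-variant statistics; identical to the full regression to ~1e-10).
Plain OLS stands in for mixed-model association tools deliberately:
relatedness modelling is out of scope. Monomorphic dosages are emitted
flagged, not dropped silently. P-values are two-sided t per cohort,
normal in the meta-analysis.

Pre-meta filters, each removal attributed to the first rule tripped:
monomorphic; multiallelic/indel; n < 20; MAC = 2·n·min(EAF, 1−EAF) ≤ 3;
|β| ≥ 10 or SE ≥ 10 (inclusive); INFO < 0.4. Harmonisation keys variants
by chrom:pos:sorted-alleles, aligns effect alleles to the first cohort
(flipping β and EAF on swaps), drops strand-ambiguous A/T and C/G variants
with |EAF − 0.5| < 0.08 everywhere, and flags (not drops) cross-cohort EAF
differences > 0.2 — the ambiguity window and difference threshold are
module defaults, as the upstream toolchain's values are unpublished. The
meta-analysis is standard IVW fixed effects with Cochran's Q (df = K−1),
I² = max(0, (Q−df)/Q)·100 and a per-cohort direction string. Post-meta:
variants present in < ⌈K/2⌉ cohorts or with MAF < 0.005 are dropped;
genome-wide hits (p < 5×10⁻⁸) are clumped by best-p per ±500 kb window —
distance-based only, as no LD structure exists in the simulations.

## Pipeline (`growthgwas.pipeline`, CLI)

Mixed models are fitted per sex; phenotype tables from the two fits are
concatenated and GWAS is sex-combined with a sex covariate. Every written
artifact carries a header with the config hash (excluding the output
directory) and seed; reruns are byte-identical. Stage failures raise a
typed error naming the stage, preserving earlier artifacts. The CLI is a
thin wrapper; the library is the interface.

## Problem sizes in the test suite

The suite exercises stated conditions at sizes chosen for a single-CPU
run: parameter recovery uses 20 replicates of 500-subject cohorts;
selection consistency 20 replicates of 60-subject cohorts (no-correlation
cells); GWAS calibration 10,000 null SNPs × 2,000 subjects; the end-to-end
check three 1,000-subject cohorts with one planted slope SNP (effect
0.006 log-BMI/yr per allele — detection power effectively 1 at combined
n = 3,000, well above 0.9). The acceptance script re-runs the same
computations at 10 replicates × 400 subjects and three 600-subject
cohorts.

## Known limitations

- ICC ignores random-slope variance (documented age-zero formula).
- The EWMA outlier rule abstains where visits are sparse; isolated gross
  errors at such visits survive to the extreme-z rule or not at all.
- CAR(1) coordinate ascent can declare `warning` on hard surfaces where a
  full Newton method might converge; grid ranking treats that
  conservatively (such cells are ineligible for preference).
- No LD, relatedness or imputation-uncertainty modelling anywhere; the
  INFO filter operates on supplied scores.
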