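# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization.  Each
genetic instrument j contributes an exposure association βX_j with standard
error σX_j (from one GWAS) and an outcome association βY_j with σY_j (from an
independent GWAS).  Under the instrumental-variable assumptions — relevance,
independence from confounders, and exclusion (no effect on the outcome except
through the exposure) — the per-SNP ratio βY_j/βX_j estimates a common causal
effect θ on the log odds-ratio scale for binary traits.

Estimators:

- **IVW** is the inverse-variance-weighted average of the ratios, identical
  to weighted least squares of βY on βX through the origin with weights
  σY⁻².  Cochran's Q = Σ wⱼ(βYⱼ − β̂βXⱼ)² is evaluated at the fixed-effect
  estimate and referred to χ²(J−1).
- **MR-Egger** adds an intercept, interpreted as average directional
  pleiotropy (valid under the InSIDE assumption: instrument strength
  independent of the direct effects).  Instruments are first oriented so
  βX_j ≥ 0 — without a fixed orientation the intercept is not identifiable.
  Slope and intercept p-values use Student t with J−2 df, the usual
  small-sample convention for this estimator.
- The **weighted median** is the 50% point of the ratio distribution under
  weights (βX_j/σY_j)² (normalized, positions cumsum(w) − w/2, linear
  interpolation).  It is consistent while more than half of the weight lies
  on valid instruments.  Its SE comes from a parametric bootstrap (default
  1,000 replicates, seed mandatory) redrawing βX and βY from normals.
- **MVMR** regresses βY on the matrix of exposure betas (exposure +
  mediators), weights σY⁻², no intercept, giving each trait's direct effect
  adjusted for the others.

SE conventions: IVW and MVMR default to *multiplicative random effects* —
the fixed-effect SE scaled by max(1, √(Q/df)) — so the SE never shrinks
below the fixed-effect value.  This matches the common practice of retaining
IVW as the primary estimator even when Q is significant.  MR-Egger applies
the same overdispersion floor.  MR-Egger and MVMR are solved through
statsmodels WLS; the test suite checks both against independent
normal-equation solves at 1e-10 relative tolerance.

## MR-PRESSO

The global statistic is the leave-one-out weighted residual sum of squares
RSS = Σⱼ wⱼ(βYⱼ − β̂₍₋ⱼ₎βXⱼ)².  Its null distribution is simulated K times by
drawing βX*_j ~ N(βX_j, σX_j) and βY*_j ~ N(β̂₍₋ⱼ₎βX_j, σY_j) and recomputing
the statistic (including the leave-one-out refits) on the simulated data.
p-values use the add-one rule (1 + #exceedances)/(K + 1), so they are never
zero.  Per-SNP outlier p-values compare each observed residual with its own
simulated distribution and are Bonferroni-multiplied by J, capped at 1.  The
distortion test compares the relative IVW change after removing the flagged
outliers with the change after removing equally many random SNPs; with no
outliers it is reported as missing ("NA").

Granularity: with K simulations the smallest attainable adjusted outlier
p-value is J/(K+1).  K defaults to 1,000 (adequate for the global test), but
outlier detection at α = 0.05 with J = 75 requires K > J/α; the pipeline
therefore defaults to K = 2,000 and the code warns when K is too small to
flag anything.  Given seed and inputs, results are bit-reproducible.

## The four-step ladder

Step 1 analyses the full instrument set after selection, clumping, palindrome
removal and harmonization.  Step 2 removes SNPs whose Bonferroni-adjusted
outlier p-value is below α.  Step 3 removes *every* SNP whose adjusted
p-value is below 1 — i.e. any SNP with a non-saturated exceedance fraction.
The "below 1" reading is a documented interpretation of an ambiguous
step-wise criterion (on the add-one scale almost every SNP has raw p < 1;
the adjusted-scale reading is the only one that removes an intermediate,
non-trivial set).  Step 4 removes the user-supplied confounder-associated
SNPs from step 3.  The sets are nested by construction and the ladder never
iterates past step 4; heterogeneity is considered addressed when the step-4
Q p-value is non-significant or the ladder is exhausted.

Multiple testing across the outcome panel (overall + three histological
subtypes) uses the Bonferroni threshold α/n = 0.05/4 = 0.0125, strict
inequality.

## Mediation

With β1 (exposure→mediator, univariable IVW), β2 (mediator→outcome), β3
(total effect, univariable IVW) and β3′ (direct effect, MVMR), the mediated
share is β1·β2/β3 in product mode and (β3−β3′)/β3 in difference mode.  β2
defaults to the mediator's MVMR-adjusted coefficient because the
product-of-coefficients decomposition requires the mediator's *direct*
effect on the outcome; a univariable β2 can be supplied explicitly.  Four
conditions are flagged: β1 significant, β3 significant, β2 significant, and
|β3′| < |β3|.  The proportion's SE comes from seeded normal draws of the
component estimates, since no closed form is exact for the ratio.  Negative
or >100% proportions are reported as computed with a warning flag, never
truncated.  MVMR instruments are the union of each trait's own significant,
clumped instruments (clumped per trait; the synthetic mediator-specific
instruments are LD-independent of the exposure blocks, so no cross-trait
clumping is required).

## Instrument processing conventions

- p-value selection, clump r² and the significance threshold all use strict
  inequality.
- Clump window: same chromosome and |Δpos| ≤ 10,000 kb; ties on p broken by
  position then snp_id for determinism.
- Palindrome window: eaf within 0.5 ± 0.08 (configurable) is treated as
  intermediate; palindromic SNPs with missing eaf are dropped conservatively.
  No strand inference is attempted anywhere — unresolvable records are
  dropped rather than corrected.
- Per-SNP explained variance uses the unit-variance-trait approximation
  R²_j = 2p_j(1−p_j)β_j²; it is the conventional summary-data choice and is
  isolated in one function if a different formula is preferred.
- p-values of exactly 0 on input are clamped to the smallest positive
  double; malformed rows are dropped with logged counts.

## Synthetic study conditions

The generator reproduces the *structure* of the motivating consortium data,
not any real genotypes: exposure GWAS n = 602,604; case-control outcome
n = 85,716 (case fraction 0.3414); mediator GWAS n = 607,291; J = 75
instruments.  Per-SNP instrument R² is drawn uniformly from
(3.5×10⁻⁴, 1.11×10⁻³), chosen so per-SNP F spans roughly 210–670 at the
exposure sample size — the strong-instrument regime of large biobank GWAS.
Effect alleles are oriented exposure-increasing (all true βX > 0), the usual
reporting convention, which also makes directional pleiotropy directional in
effect.  Sampling noise follows se = 1/√(2·maf(1−maf)·n); binary-trait
effects are generated directly on the log-OR scale (no liability-scale
individual-level simulation — adequate for testing summary-data methods and
fast).  Pleiotropy offsets are parameterised in units of the outcome SE so
their detectability is controlled explicitly.

Presets: `null` (θ = 0), `causal` (θ = ln 1.35), `pleiotropy` (40% invalid
instruments with a +0.7·σY directional offset — a design point where the
per-SNP ratio offset is comparable to the ratio noise, so IVW drifts by more
than twice its SE while the weighted-median contamination bias stays inside
two of its own SEs), `outlier` (one +10·σY outlier), `mediation`
(γ1 = ln 2.16, γ2 chosen so γ1γ2 = 0.35·θ_total with θ_total = ln 1.35 —
an exactly 35% mediated share — plus 40 mediator-specific instruments), and
`structural` (77 + 3 intermediate-frequency palindromes, allele-swapped
outcome records, LD decoy blocks inside and outside the clump window, eleven
confounder-linked SNPs).

What the generator does **not** emulate: realistic human LD maps, winner's
curse from in-sample instrument discovery, sample overlap between the two
GWAS, allele-frequency differences between cohorts, or liability-scale
effects.  Passing tests therefore demonstrate correctness of the estimators
and plumbing under the stated model, not robustness to those real-data
complications.

A separate noise-free fixture (`structured_count_study`) exercises the
four-step bookkeeping with planted residual z-scores of ±12 (three SNPs,
removed at step 2) and ±2.8 (four SNPs, removed at step 3) and eight listed
confounders, walking exactly 75 → 72 → 68 → 60; offsets are sign-balanced so
the clean SNPs' residuals stay near zero and the classification is stable
across analysis seeds.

## Problem sizes and numerics

Replication experiments use 500 replicates for calibration/recovery checks
(Monte-Carlo SE of a 5% rate ≈ 1 pt), 200 for the pleiotropy contrast and
100 seeds for outlier detection, with MR-PRESSO K = 1,000 (global
calibration) or 2,000 (outlier detection) — sizes at which every reported
rate is stable to well within its acceptance band.  All experiment
randomness derives from one integer seed via numpy `SeedSequence`.
Degenerate inputs are errors, not silent NaNs: bx = 0 in a Wald ratio,
empty instrument sets, rank-deficient MVMR designs, R² ≥ 1, and any ladder
step that would empty the SNP set.

## Known limitations

Conditional F statistics for MVMR are not computed; mode-based and
robust/penalized estimators, Steiger filtering, network mediation and
continuous-outcome power are out of scope.  The power formula is the
one-sided non-centrality approximation of the standard online calculator for
binary outcomes; at θ = 0 it returns α/2 rather than α (the lower rejection
tail is ignored by construction), except in the degenerate r² = 0 case which
returns α with a warning.
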