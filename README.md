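# mrmediate

Two-sample Mendelian randomization (MR) with mediation analysis, for
epidemiologists working from GWAS summary statistics.  The package covers the
full workflow of an exposure→outcome causal analysis with mediators on the
pathway — the motivating application is estimating the effect of
gastroesophageal reflux disease on lung cancer risk and how much of it is
mediated by smoking initiation and alcohol intake frequency, using
consortium-scale summary data.

## What it computes

Given per-SNP association tables (beta, SE, alleles, frequency, p, n) for an
exposure, an outcome and optional mediators:

- **Instrument processing** — genome-wide significance selection
  (p < 5×10⁻⁸, strict), greedy LD clumping (r² < 0.001 within 10,000 kb),
  removal of palindromic A/T–C/G variants at intermediate allele frequency,
  allele harmonization onto the exposure's effect allele, user-supplied
  confounder exclusion, and instrument strength
  F = ((n−k−1)/k)·R²/(1−R²) with R²ⱼ = 2pⱼ(1−pⱼ)βⱼ².
- **Causal estimators** — with exposure effects βX_j (SE σX_j) and outcome
  effects βY_j (SE σY_j):
  - IVW: β̂ = Σ wⱼβXⱼβYⱼ / Σ wⱼβXⱼ², wⱼ = σYⱼ⁻², multiplicative
    random-effects SE inflated by max(1, √(Q/(J−1)));
  - MR-Egger slope and intercept (directional-pleiotropy test);
  - weighted median (consistent when >50% of the weight is valid), with
    seeded parametric-bootstrap SE;
  - Cochran's Q, leave-one-out, funnel-plot data.
- **MR-PRESSO** — parametric-bootstrap global RSS test, Bonferroni-adjusted
  per-SNP outlier test, and distortion test; feeding a four-step
  re-estimation ladder (full set → minus significant outliers → minus every
  outlier-test signal → minus confounder-associated SNPs) with nested SNP
  sets.
- **Mediation** — multivariable MR (weighted regression of βY on several
  exposures' betas, no intercept) and two-step mediation: with β1
  (exposure→mediator), β2 (mediator→outcome, MVMR-adjusted by default),
  β3 (total) and β3′ (direct), the proportion mediated is β1·β2/β3
  (product mode) or (β3−β3′)/β3 (difference mode), with the four
  mediation conditions checked.
- **Power** — binary-outcome approximation
  power = Φ(|θ|·√(n·r²·K(1−K)) − z₁₋α/₂), adequate when > 0.8.
- **Synthetic studies** — a ground-truth generator emulating consortium-scale
  GWAS (exposure n = 602,604; outcome 29,266 cases / 56,450 controls;
  mediator n ≈ 607,291) with configurable pleiotropy, outliers, palindromes,
  allele swaps, LD decoy blocks and confounder subsets.

## Worked example

```python
import mrmediate as mr

study = mr.simulate_study(mr.preset_truth("causal", seed=7))   # true OR = 1.35
h = mr.prepare_instruments(study.exposure, study.outcome, study.ld)

est, q = mr.ivw(h)
egger, intercept, _ = mr.mr_egger(h)
wm = mr.weighted_median(h, seed=7)
pres = mr.mr_presso(h, K=2000, seed=7)
f = mr.f_statistics(h, n=602_604)
```

prints (via the objects' fields):

```
IVW      OR 1.36 (95% CI 1.32-1.40), p = 3.29e-99, n_snp = 75
Egger    OR 1.33, intercept +0.0009 (p = 0.790)
W-median OR 1.35 (95% CI 1.30-1.41), p = 4.55e-50
Cochran Q = 62.4 (df 74, p = 0.829); PRESSO global p = 0.846
F overall = 478; per-SNP F range 190-706
```

The IVW odds ratio recovers the simulated truth (1.35) within its CI; the
Egger intercept is indistinguishable from zero (no directional pleiotropy was
simulated), Q and the MR-PRESSO global test find no heterogeneity, and all
instruments are strong (F ≫ 10).

The same workflow is available from the shell:

```bash
mrmediate simulate --preset causal --seed 7 --out study/
mrmediate run --exposure study/exposure.tsv --outcome study/outcome.tsv \
    --ld-r2 study/ld_r2.tsv --ld-pos study/positions.tsv --out results.tsv
mrmediate power --n 85716 --case-fraction 0.3414 --r2 0.02 --odds-ratio 1.35
```

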