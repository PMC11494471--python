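# Methods

This note documents the generative model behind the synthetic cohort, the
estimators, the numerical conventions, and the design decisions that were
genuinely open — in enough detail that a user can judge what a passing test
suite does and does not demonstrate about real data.

## Generative model

### Genotypes

J biallelic SNPs as additive effect-allele dosages 0/1/2. Each gamete's
allele is a thresholded latent standard normal (threshold Φ⁻¹(maf)), so
marginals are exactly binomial(2, maf) — Hardy–Weinberg by construction.
Within an LD block the latents share an equicorrelated component
(`ld_block_corr`), across blocks they are independent. The resulting dosage
correlation is a monotone function of the latent correlation, not equal to
it; LD-dependent logic (clumping) uses empirical dosage r², so only the
ordering matters. Default: 60 unlinked SNPs, maf ~ U(0.1, 0.5) drawn
deterministically from the seed.

### Smoking

Initiation follows a liability-threshold model: liability = G·b_init +
0.3·risk_tolerance + 0.1·deprivation + N(0,1), thresholded at the empirical
(1 − 0.29213) quantile, so realized prevalence matches the target ever-smoker
share exactly up to rounding. The threshold is empirical rather than
closed-form so that arbitrary confounder mixtures never shift prevalence.

Among initiators, the composite smoking index (CSI) is drawn from
gamma(2.136, 0.5337) — moment-matched to the published smoker mean 1.14 and
sd 0.78 — plus a mean-centred genetic shift G·b_csi, clipped to
[0, min(cap, 3.4)]. Duration and years-since-cessation are drawn (60%
former smokers), and cigarettes/day is back-solved from the index formula

    csi = min(cap, ln(1 + cpd/2) · (1 − 0.5^(dur/τ)) · 0.5^(tsc/τ)),  τ = 18 y,

so `compute_csi` on the stored components reproduces the stored CSI exactly.
The exact functional form and half-life behind the published index are not
printed anywhere accessible, so this form — log-saturating heaviness,
saturating duration, exponential post-cessation decay with a configurable
half-life, capped at 4.0 — encodes the stated qualitative behaviour; τ and
the cap are configurable. Two consequences: (i) with cpd ≤ 60 the formula
cannot exceed ≈ 3.4, so the target CSI is clipped there (the gamma mass
above 3.4 is ~1.5%); (ii) the additive genetic shift plus the clip at 0
raises the realized smoker mean a few percent above 1.14 (the unit test
allows ±0.1). The gamma model itself is the calibration anchor.

### Costs

    cost = max(0, B + (θ_init − θ_csi·m̄)·init + θ_csi·csi
                  + confounder shifts + pleiotropic shifts)

where B is 0 with probability 0.45 and lognormal(6.0569, 1.1918) otherwise —
solved so the marginal distribution has mean £478 and median £87 — and m̄ is
the realized smoker CSI mean. The reparameterization makes the *config*
parameters the estimands: θ_init is the total causal effect of ever smoking
(including its effect through the index), θ_csi the effect per CSI unit. In
the naive parameterization θ_init·init + θ_csi·csi, the initiation-PRS IV
estimand would be θ_init + θ_csi·m̄ — neither configured number. Causal and
confounder effects are additive on the cost scale (an additive
structural-mean-model world), so 2SLS is exactly consistent for θ.

The floor at 0 is the one deliberate distortion: a never-smoker whose
confounder shift is very negative would be floored upward, biasing the
never-smoker mean. Covariate cost effects (risk tolerance +£30/SD,
deprivation +£20/SD, age +£2/yr, sex +£20) are sized so this is negligible
(measured estimand shift ≈ −£5 on θ_init at the oracle); large negative
user-configured effects revive it.

Directional pleiotropy assigns a constant direct effect (GBP/allele) to a
random `fraction_invalid` of the causal SNPs, sign-randomized when
`balanced`. Participation selection is
Bernoulli(logistic(α − γ₁·std(liability) − γ₂·std(cost))).

### Effect sizes are scaled up, on purpose

Per-SNP effects (0.11 liability SD/allele; 0.25 CSI units/allele) give
per-SNP variance explained ~0.2–0.4%, far above the real GWAS regime, so
that instruments are discoverable at p < 5×10⁻⁸ inside a 10,000-person
discovery half. This is the desk-scale design: the *structure* (split
discovery, ~5–13 instruments per half, first-stage F in the hundreds) mirrors
the target analysis; the absolute power regime does not. A subtle coupling
fixed the liability effect size: because CSI > 0 iff ever-smoker,
initiation SNPs have a real downstream CSI effect (ratio θ_init/m̄ ≈ £434,
not θ_csi), and if they pass the CSI scan's threshold they contaminate the
CSI instrument set — the within-model analogue of the heterogeneity the
sensitivity analyses exist to catch. At 0.11 the leakage noncentrality sits
far enough below the genome-wide threshold that contamination averages
<2 SNPs per 200-replicate study and the CSI IV estimand stays within
Monte-Carlo error of θ_csi; pushing the liability effects higher re-biases
the CSI model upward long before anything else breaks.

## Estimators and numerical conventions

* Per-SNP scans use Frisch–Waugh–Lovell partialling (exact per-SNP multiple
  OLS at O(nJ)); two-sided p from the normal approximation (n ≥ 10³ here;
  the t correction is negligible). Binary traits are scanned with the
  linear probability model by default (logistic optional), and PRS weights
  inherit that scale. Constant dosage columns are dropped with a warning.
* Clumping is greedy by ascending p with tie-break on SNP id, r² from
  in-sample dosage correlation (no reference panel); r² < 0.001 default.
* 2SLS standard errors: homoskedastic IV asymptotics by default (the cost
  noise is additive and homoskedastic by construction), HC1 optional for
  real data. First-stage F partials out covariates. Just-identified
  PRS-2SLS carries the usual finite-sample ratio bias: at 10,000 per half it
  measures ≈ −4% on θ_init, vanishing by n = 50,000 — visible in the
  recovery study's mean, covered by its bias budget.
* Wald-ratio SE is first-order (σ_Y/|β_X|) by default, second-order
  optional. IVW random effects multiply the fixed SE by max(1, √(Q/(J−1))).
  Q always uses df = J−1.
* MR-Egger orients exposure betas positive, weights by 1/σ²_Y, and reports
  t-based inference (df J−2) with the *estimated* multiplicative dispersion.
  The dispersion floor at 1 used by some packages makes the intercept test
  measurably conservative (type-I ≈ 0.03) at J = 15–30 and is available via
  `floor_dispersion=True`; the default keeps the pleiotropy test calibrated.
* Weighted median interpolates the inverse-variance-weighted order
  statistics at cumulative weight 0.5; the penalized variant multiplies
  weights by min(1, 20·P(χ²₁ > q_j)) with q_j the SNP's Q contribution.
  Penalization is aimed at isolated outliers: under *heavy* one-directional
  contamination (~40% of weight) the penalties are computed against the
  already-contaminated IVW centre and tilt the surviving weights upward, so
  the plain weighted median is the right robustness benchmark there.
* Mode estimator: weighted Gaussian KDE maximized on a 512-point grid,
  bandwidth φ·0.9·min(sd, mad/0.6745)·J^(−1/5) (sd fallback when the MAD
  degenerates). Median and mode SEs come from a seeded 1000-draw parametric
  bootstrap by default.
* Steiger converts scan statistics to correlations via r = t/√(t² + n − 2)
  (point-biserial for the binary trait) and compares Fisher z values; ties
  are kept with a warning.
* Multivariable MR is individual-level two-exposure 2SLS. Conditional
  instrument strength uses the regression-partialling form: exposure k is
  residualized on the instrument-predicted other exposures, the residual
  regressed on the instruments, F with numerator df J − (m − 1). Any
  conditional F < 10 sets the weak flag.
* Fixed-effect meta-analysis: w = 1/se², pooled se = (Σw)^(−1/2); a single
  estimate passes through with a warning.

## Pipeline

simulate → conventional OLS (age, sex, deprivation; deprivation is included
because the target table's footnotes list it even though the methods text
omits it — it is toggleable) → random half-split (no-overlap asserted) →
per-half GWAS of both exposures → select + clump → swapped-half PRS → 2SLS
per half → fixed-effect meta → per-SNP suite (discovery-half exposure betas
vs estimation-half cost betas) → Steiger, heaviness-SNP × ever/never
interaction, MVMR with risk tolerance. Risk-tolerance SNP effects default to
near-null (0.02 SD/allele): genome-wide hits essentially never occur, the
MVMR falls back to the top-5 scan SNPs, and its conditional F lands ≈ 1 —
reproducing the weak-instrument failure mode the analysis is known for.
Everything is driven by one seed; regenerated reports are byte-identical.

## Problem sizes used by the study-level checks

Cost calibration runs at the full cohort size (n = 300,045); parameter
recovery at n = 20,000 × 200 replicates (≈ 90 s); null calibration at 1,500
summary-level replicates; robustness at 200 replicates of 15 SNPs with a
fixed 60/40 valid/invalid weight split. Bootstrap draws are reduced to
100–250 inside replicate loops, where the bootstrap SEs are not the quantity
under test.

## What passing tests do not show

The generator draws unlinked (or block-equicorrelated) SNPs, Gaussian
confounders, additive homoskedastic cost noise and effect sizes far above
the real GWAS regime. Passing recovery and coverage therefore validates the
*estimators and the design logic*, not performance under realistic LD,
population structure, assortative mating, participation bias (unless
switched on), cost-coding artifacts, or sub-genome-wide instrument strength.
Known limitations: the CSI formula's reachable range caps near 3.4 at
realistic cigarettes/day; the cost floor distorts under large negative
configured effects; the penalized median misbehaves under majority-scale
directional contamination; conditional F equality with marginal F holds only
approximately in finite orthogonal designs.
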