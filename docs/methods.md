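# Methods

## The model

Two-sample MR treats genetic variants as instruments for an exposure X when
estimating its causal effect β on an outcome Y from two non-overlapping
GWAS. For instrument j the summary data are the estimated per-allele effects
β̂_Xj (SE σ_Xj) and β̂_Yj (SE σ_Yj). Under the three instrumental-variable
assumptions — relevance (the variant affects X), independence (no
confounding of the variant–outcome relation), and exclusion restriction (the
variant affects Y only through X) — each Wald ratio θ̂_j = β̂_Yj/β̂_Xj
estimates β. The estimators differ in how they combine the ratios and in
which violations of exclusion they tolerate:

- **IVW** is the inverse-variance weighted mean of the θ̂_j with first-order
  weights w_j = β̂²_Xj/σ²_Yj, algebraically identical to weighted least
  squares of β̂_Yj on β̂_Xj through the origin with weights 1/σ²_Yj. It is
  unbiased only when every instrument is valid.
- **MR-Egger** frees the intercept: β̂_Yj = α + β β̂_Xj + ε_j. Under InSIDE
  (pleiotropic effects independent of instrument strength) the slope remains
  consistent for β and the intercept estimates the average directional
  pleiotropy.
- **Weighted median** is consistent while valid instruments carry at least
  half the weight.
- **Mode-based estimators** (simple/weighted) are consistent while the
  largest cluster of ratios comes from valid instruments.

Estimates are reported on the log-odds scale and as odds ratios
OR = exp(β̂) with 95% bounds exp(β̂ ∓ 1.96·SE).

## Numerical and inferential conventions

Published applications of this workflow rarely state these choices, so the
package fixes them explicitly:

- **IVW variance**: multiplicative random-effects. The fixed-effect SE
  √(1/Σ β̂²_Xj/σ²_Yj) is scaled by max(1, √(Q/(J−1))) with Q the Cochran
  statistic, so under-dispersion never shrinks the SE. The fixed-effect SE is
  retained on the result object.
- **MR-Egger orientation**: each instrument is flipped so β̂_Xj ≥ 0 before
  the regression (orientation changes the meaning of the intercept).
  Coefficient SEs carry the same max(1, σ̂) overdispersion guard, with σ̂ the
  weighted residual SD; p-values use Student t with J−2 df.
- **Reference distributions**: standard normal for IVW, Wald, median and
  mode p-values; t(J−2) for Egger.
- **Bootstrap SEs** (median and mode): parametric bootstrap perturbing both
  β̂_Xj and β̂_Yj by their SEs, 1000 replicates by default, seeded, SD of the
  replicate estimates.
- **Mode bandwidth**: h = φ·0.9·min(sd(θ̂), 1.4826·MAD(θ̂))·J^(−1/5)
  (Silverman's rule with a MAD guard against outlier-inflated sd), density
  evaluated on a 512-point grid spanning [min θ̂ − 3h, max θ̂ + 3h]; tied
  grid maxima are averaged; φ defaults to 1 and is exposed everywhere.
- **Weighted median interpolation**: ratios sorted ascending, normalized
  weights w_(j), plotting positions p_j = Σ_{k≤j} w_(k) − w_(j)/2, estimate
  interpolated at p = 0.5.
- **Empirical p-values** (outlier test) use the add-one rule
  (1 + #{T* ≥ T})/(n_sim + 1), so they are never exactly 0.
- **p = 0 on input** is replaced by the smallest positive normal double with
  a warning, for downstream log/quantile safety.
- **Degenerate inputs**: a single instrument reduces IVW to the Wald ratio;
  β̂_Xj = 0 raises a degenerate-instrument error for the Wald ratio; all-equal
  ratios short-circuit the mode to that value; J below each method's minimum
  (2 for IVW/Q, 3 for Egger/median/mode/leave-one-out, 4 for the outlier
  test) raises an insufficient-instruments error, which the pipeline converts
  to an "insufficient instruments" pair status rather than a crash.

## Instrument selection

Filters and defaults: exposure p < 1×10⁻⁵ (strict inequality; boundary
dropped), MAF = min(eaf, 1−eaf) ≥ 0.01, single-SNP F = (β̂_X/σ_X)² ≥ 10
(the R²(N−2)/(1−R²) form is available when eaf and N are present), greedy LD
clumping at r² < 0.01 within 10,000 kb (ascending p; the index SNP removes
correlated neighbours). Order: p → MAF → clump → F; the per-record filters
commute, so only the clumping stage is order-sensitive, and it runs before
the F screen so that index-SNP choice is unaffected by strength filtering.
Records without allele frequency pass the MAF filter with a logged warning —
frequency is routinely absent from consortium exports and a hard failure
would gut real instrument sets. Clumping without an LD matrix degrades to a
no-op with a prominent warning: computing LD from a reference panel is out
of scope here, and callers supplying pre-clumped instruments (the common
case for consortium exports) lose nothing.

## Harmonization

Matching is by variant id only (rsID-keyed summary data). The outcome is
reconciled to the exposure effect allele through the four-case table (copy /
swap-and-negate / strand-flip / flip-and-swap); irreconcilable allele pairs
are excluded as `unmatched`, ids on one side only as `missing`, and
duplicate ids keep the smallest-p instance. Palindromic variants are
excluded unconditionally — no frequency-based rescue — which matches the
conservative practice of the studies this pipeline reproduces and keeps the
step deterministic. Harmonization is an involution: re-harmonizing an
aligned pair changes nothing (tested).

## Outlier test and iterative removal

The global statistic is RSS = Σ_j w_j (β̂_Yj − β̂_(−j) β̂_Xj)² with
w_j = 1/σ²_Yj and β̂_(−j) the leave-one-out IVW estimate. Its null
distribution is simulated: per replicate, β*_Yj ~ N(β̂_(−j) β̂_Xj, σ_Yj) and
β*_Xj ~ N(β̂_Xj, σ_Xj) (exposure resampling can be disabled), and the
statistic is recomputed on the simulated data, including the leave-one-out
estimates. Per-SNP outlier p-values come from each weighted squared
residual's simulated distribution, Bonferroni-adjusted by J. While the
global p is below 0.05 and some adjusted outlier p is below 0.05, the SNP
with the smallest outlier p is removed (one at a time, deterministic) and
everything is recomputed; the loop stops once the global test is
non-significant or fewer than 4 instruments would remain. After removal,
all estimates are recomputed on the survivors; both pre- and post-removal
results are retained, along with an optional distortion figure (relative
shift of the corrected IVW estimate) that is reported but drives no
decision. Note the Bonferroni floor: the smallest attainable adjusted
outlier p is J/(n_sim+1), so n_sim must exceed ~20·J for removal to be
possible at 0.05 (the default n_sim = 1000 is ample for J ≤ 50).

## Synthetic data generator

The generator emulates a pre-selected two-sample instrument set with known
truth; every realized per-SNP quantity (true effects, pleiotropy, masks) is
recorded for assertions.

- True exposure effects are |N(0, bx_sd²)| draws, resampled until
  β_Xj/σ_Xj clears the z-threshold of the p < 10⁻⁵ screen. The
  absolute value encodes the convention that the reported effect allele is
  the exposure-increasing allele; without it, post-orientation directional
  pleiotropy would average to zero and the Egger intercept would be
  unidentifiable in simulation. Defaults: J = 30, bx_sd = 0.1, σ_X = 0.005,
  σ_Y = 0.02 — strong instruments (typical F ≈ 400), chosen so that
  weak-instrument attenuation (≈ σ²_X/bx_sd² ≈ 0.25%) is negligible against
  Monte-Carlo error at the replicate counts used.
- Outcome: β_Yj = β·β_Xj + α_j, with α_j = 0 for valid SNPs and
  α_j ~ N(μ_α, σ_α²) for an `invalid_fraction` of SNPs; an optional
  ρ·β_Xj term breaks InSIDE on demand; planted outliers add ±k·σ_Yj
  (k = 10 by default, random sign). Observed betas add Gaussian noise;
  setting σ_X = σ_Y = 0 gives the exact noise-free limit (reported SEs are
  floored at 1e-8 so inverse-variance weights stay finite).
- Alleles are non-palindromic pairs except for a requested palindromic
  fraction; EAF is uniform on (0.05, 0.95); LD blocks, when requested, are
  placed within a 10 kb locus with 50 Mb between loci so block membership
  and the clumping window coincide. One integer seed drives a single
  `numpy` Generator; output is bitwise reproducible.

What the generator does **not** emulate: winner's curse (effects are
resampled, not selected post-hoc from noisy scans), realistic allele
frequency spectra or frequency-dependent effect sizes, LD beyond exchangeable
within-block r², sample overlap between the two GWAS, and binary-trait
non-collinearity of log-odds effects. Passing simulation checks therefore
demonstrate the estimators' statistical behaviour under the stated model,
not robustness to those real-data features.

## Validation conditions

The acceptance checks run at the following problem sizes, chosen to make
3-binomial-SE / 3-Monte-Carlo-SE bands decisive while keeping the whole
battery at a few seconds on one CPU: null calibration with J = 30 over 500
replicates (outlier-test n_sim = 500 there; 1000 elsewhere), recovery at
β = 0.5 with J = 50 over 500 replicates, outlier robustness with two planted
10σ outliers in J = 30 over 100 replicates.

One property deserves a note: the weighted median's consistency theorem is an
SE → 0 (growing sample size) statement, not a J → ∞ statement. At fixed SEs,
directional contamination of 30% of the weight leaves a bias of roughly
0.57 × the ratio-estimate SD that does not shrink as J grows, so "converges
with J" is tested in the form that is actually true: centred on the truth
under balanced (mean-zero) pleiotropy carrying ≤ 50% of weight at J = 200,
and several-fold less biased than IVW under directional contamination.

## Bundled reference tables

The five per-outcome result tables bundled under `tsmr/data/` are
transcriptions of a published microbiota → geriatric-syndromes MR study's
tables, used to exercise the reporting layer (counts of IVW-significant
pairs by direction: 5+2 frailty, 3+4 Parkinson's disease, 3+2 delirium,
9+2 insomnia, 9+2 depression; 41 total). Transcription notes: one IVW odds
ratio printed with a decimal comma ("1,144") is stored as 1.144, consistent
with the same study's running text; a handful of cells in the depression
table are visibly garbled in the source (CI bounds of "0.100", a swapped
SE pair) and are kept as printed but excluded from numeric checks, which use
only IVW OR and p columns; two genus-rank taxa are labelled "Class" in the
delirium table and the labels are kept as printed. The depression table's
directions are classified from the ORs themselves (its running text reverses
"reduced/increased risk" relative to its own ORs).

## Known limitations

- F-statistics use the single-SNP Wald approximation; no conditional or
  joint instrument-strength measures.
- No Steiger directionality filtering, multivariable MR, or reverse-direction
  analysis; no penalized/robust IVW variants.
- Clumping requires a user-supplied r² matrix; there is no reference-panel
  LD computation or proxy-SNP lookup.
- The outlier test's null simulation conditions on the observed instrument
  set; like the original formulation it is slightly conservative at small J.
- Odds-ratio output assumes the outcome GWAS effects are log-odds; continuous
  outcomes pass through unchanged but the OR columns are then exponentiated
  mean differences and should be read accordingly.
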