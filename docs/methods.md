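# Methods

## Scope and data model

`mrmediate` implements two-sample Mendelian randomization (MR) with a
two-step mediation extension, operating purely on GWAS summary
statistics.  A trait is a `SummaryTable` of per-SNP associations
(`snp, effect_allele, other_allele, beta, se, pvalue, eaf, n`), read and
written as delimited text (tab canonical, comma accepted).  Only
single-base biallelic SNPs are representable; indels and multiallelic
rows are rejected so that allele harmonization stays decidable.  Missing
`eaf`/`n` are `NA` (case-insensitive) or empty; any other unparsable
token is an error rather than a silent missing value, and a file is
either fully valid or the read fails with every offending row
enumerated.  p-values of exactly 0 are invalid (they cannot arise from a
correctly reported floating-point GWAS) and are never clamped on input.

## Instrument selection

1. **Association screen.** Keep SNPs with `p < threshold` (strict
   inequality).  Default `1e-5`, the customary relaxed threshold for
   microbiome-scale exposures with few genome-wide-significant hits.
2. **Weak-instrument screen.** Single-SNP F statistic `F = (β/se)²`,
   keep `F ≥ 10` (the conventional cutoff; the approximation ignores
   variance explained, adequate at GWAS sample sizes).
3. **LD clumping** (optional, requires a pairwise r² matrix): greedy
   p-ordered clumping — repeatedly keep the lowest-p remaining SNP
   (ties broken by lexicographic SNP id) and discard every SNP with
   `r² > r2_max` (default 0.001) to it.  Deterministic, and the kept set
   is an independent set by construction.  No genomic-window restriction
   is applied; the r² matrix is taken as authoritative for all pairs.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles are copied; swapped alleles negate the outcome beta and reflect
its frequency; alleles matching only after strand complement (A↔T, C↔G)
are complemented first.  Palindromic SNPs (A/T, C/G) cannot be resolved
from alleles alone: under the default `infer_by_eaf` policy they are
aligned by effect-allele-frequency concordance, but dropped when either
frequency is missing or lies within `eaf_window = 0.08` of 0.5
(frequency uninformative about strand — the window trades a few lost
SNPs against the risk of silent sign errors).  Under policy `drop` all
palindromic SNPs are excluded.  Every exclusion is logged with a reason;
harmonization is idempotent.

## Estimators

All methods consume the harmonized per-SNP effects (β_Xj, β_Yj, se_Yj).
The Wald ratio is β_Yj/β_Xj with first-order SE `se_Yj/|β_Xj|`; exposure
uncertainty is ignored, the standard two-sample simplification that
matches IVW's use of inverse outcome variance as weight.

* **IVW** — weighted least squares of β_Y on β_X through the origin,
  weights 1/se_Y².  Default `multiplicative_random`: SE inflated by
  `max(1, sqrt(Q/(J−1)))`, robust to overdispersion; `fixed` keeps the
  residual scale at 1.  The point estimate is identical under both and
  the multiplicative SE is never smaller.  A single instrument degrades
  to the Wald ratio with a logged notice.
* **MR-Egger** — the same regression with a free intercept after
  re-signing instruments so every β_X ≥ 0 (the orientation under which
  the intercept estimates average directional pleiotropy).  Slope and
  intercept p-values use the t reference with J−2 df and multiplicative
  residual scaling `max(1, Q/(J−2))` on the variance.
* **Weighted median** — order the Wald ratios, give each weight
  `se_ratio⁻²` (normalized), and linearly interpolate the ratio against
  the centered cumulative weight `s_j = Σ_{k≤j} w_k − w_j/2` at
  `s = 0.5`.
* **Simple / weighted mode** — Gaussian kernel density over the ratios
  (weights uniform or `se_ratio⁻²`), bandwidth
  `phi · 0.9 · min(sd, IQR/1.349) · J^(−1/5)` (modified Silverman,
  `phi = 1` by default), density evaluated on a 512-point uniform grid
  spanning the ratio range padded by 3 bandwidths, argmax with ties
  broken by the smallest grid index — deterministic and checkable
  against a brute-force oracle.  If the ratios are all identical the
  common value is returned; if the IQR degenerates to 0 with
  non-identical ratios the bandwidth falls back to the sample SD.

Median and mode SEs come from a parametric bootstrap (default 1000
resamples, seed mandatory) perturbing both exposure and outcome betas by
their reported SEs and recomputing the estimate; `n_boot = 0` skips the
bootstrap for point-estimate-only simulation studies.  p-values use the
normal reference except MR-Egger (t, J−2 df).  Odds ratios and CIs are
the reporting transform `exp(beta ∓ 1.959964·se)` at the 95% level.

Diagnostics: Cochran's Q around the IVW (df J−1) or Egger (df J−2) fit,
`I² = max(0, (Q−df)/Q)` floored at 0; the Egger intercept test shares
the Egger fit so the two are consistent by construction; single-SNP
Wald-ratio and leave-one-out IVW tables back per-SNP forest plots (CIs
on the effect scale, since those plots display signed effects).

## Two-step mediation

The three legs X→Y (total), X→M (a) and M→Y (b) are each estimated with
their own instrument selection from the leg's exposure table; the
composition uses each leg's IVW estimate by default (any battery method
can be substituted uniformly).  The indirect effect is `a·b` with
first-order delta SE `sqrt(a²se_b² + b²se_a²)`; the direct effect is
obtained by subtraction, `c′ = total − a·b` (difference method), so
`total = c′ + indirect` holds exactly.  All arithmetic is on the
log-odds/beta scale; odds ratios are a reporting transform only, and the
noncollapsibility of odds ratios is acknowledged but not corrected.  The
proportion mediated `indirect/total` is a signed fraction reported to
two decimals as a percentage; under inconsistent mediation (opposing
signs) it leaves [0, 1] and is flagged, never truncated.

**Exposure-instrument exclusion in the M→Y leg.**  A SNP that
instruments the exposure reaches the outcome through the direct path c′
as well as through the mediator, so using it in the mediator→outcome leg
estimates `total/a` rather than `b`.  The pipeline therefore excludes
SNPs associated with the exposure at the selection threshold from the
mediator leg (`exclude_exposure_associated = True`).  Without this the
product-of-coefficients decomposition is not identified from a single
shared instrument set.

A reverse leg (outcome as exposure) runs automatically as a
directionality check; with a weak or absent reverse signal it typically
finds no instruments and is reported as a failed leg with its per-stage
survival counts.

## Synthetic data

The generator emits three summary tables under the structural model with
known truth: per-SNP instrument effects `γ_j ~ N(0, gamma_scale²)` on X,
optional mediator-specific instruments `δ_j ~ N(0, delta_scale²)` (no
effect on X — what a real mediator GWAS contributes, and required for
the M→Y leg to be identified), and horizontal pleiotropy `α_j` on a
designated fraction of exposure instruments.  True marginal effects are
`γ_j` on X, `a·γ_j + δ_j` on M and `(c′+a·b)·γ_j + sign(γ_j)·α_j +
b·δ_j` on Y.  Pleiotropy is oriented to the exposure-increasing allele
of each instrument: with mean 0 (balanced) the orientation is
distributionally irrelevant, while a nonzero mean (directional) then
offsets every invalid instrument's Wald ratio in one shared direction —
the meaning of "directional" in ratio space, and the regime in which the
weighted median's 50%-validity robustness and the Egger intercept test
have power.  Observed effects add independent Gaussian noise with
`se = sqrt(var_trait/(2·maf·(1−maf)·n_trait))`; the three GWAS are
non-overlapping by construction (the two-sample assumption).  Reported
p-values are floored at 1e-300 to stay inside the valid (0, 1] range at
astronomical z-scores.

Defaults describe the motivating design: 11 exposure instruments, a
small quantitative exposure GWAS (n = 7,738), a large binary outcome
GWAS (n = 451,025), a mid-size immune-cell mediator GWAS (n = 3,757,
the scale of the standard immune-trait reference cohort), structural
coefficients from the published monocyte leg (a = ln 0.772,
b = ln 1.0003, c′ = −0.00092), minor-allele frequencies uniform on
[0.05, 0.5], and `gamma_scale = 0.1` (instrument effects of a few
percent of a trait SD, typical for pathway-abundance exposures).
Non-palindromic A/G alleles are assigned unless palindrome injection is
requested.  What the generator does **not** emulate: LD between SNPs
(clumping tests use hand-built r² fixtures), winner's curse, sample
overlap, population stratification.  A green recovery test therefore
establishes correctness of the estimators and plumbing under the stated
model, not robustness to those real-data complications.

## Statistical properties established by the test suite

* Exact-fit collapse: on data with β_Y = θβ_X exactly, all five methods
  return θ.
* Oracle equivalence on small instances: IVW equals the inverse-variance
  weighted average of Wald ratios, Egger the direct normal-equations
  solve, the weighted median the cumulative-weight interpolation, the
  modes a brute-force density-grid argmax.
* Recovery: mean IVW estimate over 200 replicates (J = 50, n = 50,000,
  θ = 0.1) within ±0.01; mean pipeline proportion mediated over 200
  replicates (J = 30 + 30, n = 10⁵, a = −0.25, b = 0.02, c′ = −0.12)
  within ±0.02 of the true 0.04.
* Type-I error: the fixed-effect IVW z-test rejects a true null in
  4–7% of 1,000 replicates at the 5% level; the multiplicative
  random-effects default, whose SE is only ever inflated, never rejects
  more often (it is mildly conservative, ≈4.2% asymptotically).
* Robustness: with 40% invalid instruments under directional pleiotropy
  (mean 0.05, sd 0.02 — pleiotropic ratio offsets several times the
  causal effect), the weighted median is closer to the truth than IVW in
  ≥90% of replicates, and the Egger intercept detects directional but
  not balanced pleiotropy.

## Known limitations

No MR-PRESSO outlier removal, Steiger filtering, SIMEX-adjusted Egger or
multivariable MR; one mediator per model; the proportion-mediated SE is
first-order only; LD matrices must be supplied, never computed; SNPs are
keyed by id only (no genomic coordinates or liftover).
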