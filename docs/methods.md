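# Methods

This note documents the statistical model behind `mrbidir`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Two-sample MR model and assumptions

A SNP is a valid instrument when it is (i) associated with the exposure,
(ii) independent of exposure–outcome confounders, and (iii) affects the
outcome only through the exposure.  Working from summary statistics, the
package treats the per-SNP pairs (γ̂ⱼ, σₓⱼ) and (Γ̂ⱼ, σᵧⱼ) as independent
normal estimates from non-overlapping samples.  Under a linear causal
effect θ and no horizontal pleiotropy, Γⱼ = θ·γⱼ; pleiotropy enters as a
per-SNP intercept αⱼ, and the estimator panel differs in what it assumes
about the αⱼ (IVW: all zero; Egger: constant mean, InSIDE; weighted
median: zero for instruments carrying ≥ 50 % of the weight; MR-PRESSO:
zero except for detectable outliers).

## Instrument selection

* p-value screen: strict `p < threshold`; defaults 5×10⁻⁸ for a
  quantitative exposure and 1×10⁻⁵ for the reverse (disease-as-exposure)
  direction, both configurable.  The strict comparison reads the
  genome-wide level as a significance level, the usual convention.
* LD clumping: greedy — rank by ascending p (ties broken by snp_id for
  reproducibility), keep the best unclaimed variant, remove every
  unclaimed same-chromosome variant within the window (default 1000 kb)
  whose r² with it exceeds the cutoff (default 0.001).  An in-window pair
  with no r² entry is *removed* by default (`missing_ld="correlated"`),
  a conservative distance-based reading; `"independent"` flips this and
  reduces clumping to known-LD pruning.  With an empty LD table the
  default therefore keeps one variant per window.
* Outcome-association exclusion: instruments with outcome p below a
  cutoff (default 5×10⁻⁸; "substantially associated with the outcome"
  has no canonical number) are removed as likely exclusion-restriction
  violations.  Instruments absent from the outcome file are *not*
  dropped here — the harmonization stage does that, so the drop reason
  is recorded exactly once.

## Harmonization

The exposure orientation is the reference; the outcome side is flipped.
Palindromic (A/T, C/G) variants cannot be strand-resolved from labels, so
the effect-allele frequency decides: both frequencies known, both outside
the ambiguity band (default |eaf − 0.5| ≥ 0.08, i.e. ambiguous in
[0.42, 0.58]) and on the same side of 0.5 → aligned; opposite sides →
outcome flipped; otherwise dropped rather than guessed.  The 0.08 margin
is the common practice value for frequency-based palindrome resolution;
it is configurable because no universal standard exists.  Harmonization
is idempotent on survivors and the whole pipeline is invariant to a
consistent relabelling of the outcome file's alleles.

## Estimators

* Ratio SEs: first-order delta method σᵧ/|γ̂| by default; the
  second-order form (adding Γ̂²σₓ²/γ̂⁴) is available.  With instrument
  z-scores above ~10 and modest causal ratios the two differ by well
  under 1 %, and the first-order form matches the convention of the
  widely used IVW implementations.
* IVW: fixed-effect for the main analysis; the random-effects option
  inflates the SE multiplicatively by max(1, √(Q/(n−1))).  The
  multiplicative (not additive) overdispersion form was chosen because
  it degrades gracefully to fixed-effect when Q ≤ n−1.
* Cochran's Q: Σwⱼ(β̂ⱼ − β̂ᵢᵥw)², upper-tail χ²(n−1).  This df/statistic
  convention is asserted by the tests; published tables sometimes pair a
  Q value with a p that matches no χ²(n−1) tail, so printed Q p-values
  from other software are not comparison targets.
* MR-Egger: pairs oriented to γ̂ ≥ 0 first (the slope is not invariant
  to per-instrument sign flips otherwise), weighted least squares with
  weights 1/σᵧ², residual scale max(1, √(RSS/(n−2))), t(n−2) inference.
* Medians: midpoint-convention interpolation of the ordered ratios at
  cumulative weight 0.5; with equal weights this reduces exactly to the
  sample median.  SEs by parametric bootstrap (default 1000 replicates,
  each ratio redrawn from Normal(β̂ⱼ, σⱼ), seed mandatory in the
  pipeline) — the established choice where no closed-form median SE
  exists.
* Confidence intervals use the normal quantile 1.959964 everywhere
  except inside Egger, which is t-based.

## MR-PRESSO

Observed statistic: RSS = Σⱼ wⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)² with θ̂₍₋ⱼ₎ the
leave-one-out IVW slope and wⱼ = 1/σᵧⱼ².  The null distribution redraws
all outcome effects from Normal(θ̂₍₋ⱼ₎γ̂ⱼ, σᵧⱼ) and recomputes the
leave-one-out slopes inside each simulated dataset.  Monte-Carlo
p-values use add-one smoothing, so the floor is 1/(n_sim+1) and a p of
exactly zero is impossible.  Per-instrument outlier p-values compare
each observed residual contribution with its simulated distribution and
are Bonferroni-corrected across instruments by default (flag to use raw
p): note n_sim must exceed n/α for an adjusted p to be able to reach α.
The outlier-adjusted estimate is fixed-effect IVW on the non-flagged
instruments — a delegation identity asserted by the tests.  The
distortion test compares the observed (raw − adjusted)/adjusted shift
with the distribution obtained by removing random subsets of non-outlier
instruments of the same size as the outlier set; the reference
implementation's exact resampling scheme is unpublished detail, so this
symmetric two-sided variant is this package's own choice.  The
distortion result is reported but never alters the primary estimate.

## Colocalization

Wakefield log-ABF per variant; hypothesis sums H0–H4 with per-variant
priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the canonical defaults of the coloc
literature) and prior effect SD 0.15 for quantitative, 0.2 for binary
(log-odds) traits.  All sums are accumulated in log space with
log-sum-exp — linear-scale ABFs overflow near |z| = 40.  At a single
shared variant the two-distinct-variants sum is empty and PP3 is exactly
zero.  Regions are intersected by snp_id and allele-aligned with the
harmonization rules; frequency-ambiguous palindromes are retained (the
ABF depends on z² only), while irreconcilable allele sets are dropped.
The implementation is verified against an exhaustive linear-scale
enumeration oracle for regions of up to five variants.

## Enrichment

One-sided upper-tail hypergeometric over-representation (enrichment
only, matching the GO-enrichment use case); gene-set members outside the
universe are intersected away before testing, the standard ORA
convention.  Benjamini–Hochberg adjustment is delegated to statsmodels'
`multipletests`.  SNP→gene mapping is an input, not computed: it
requires an external annotation database and is deliberately out of
scope.

## Synthetic data

The generator emulates the summary-statistic structure the MR model
assumes.  Per SNP: maf ~ Uniform(0.05, 0.5); analytic SEs
1/√(2·maf(1−maf)·n) for a per-SD quantitative trait, divided by
√(v(1−v)) (case fraction v, default 0.20) for a binary trait's log-odds
scale; true exposure effects from a truncated normal (σ = 0.1) with
|γⱼ| ≥ z_min·σₓⱼ so instruments are detectable — z_min defaults to 6
(comfortably past the genome-wide threshold z ≈ 5.45); the
strong-instrument scenarios in the tests use z_min = 10.  Default sample
sizes are 32 735 (exposure) and 384 838 (outcome), the sizes of the
femoral-neck BMD and OA GWAS that motivate the package.  Pleiotropy is
applied in the exposure-raising allele orientation (Γⱼ = θγⱼ +
sign(γⱼ)·αⱼ): a "directional" direct effect has a consistent sign
relative to the allele that raises the exposure, not relative to the
arbitrary effect-allele label — without this the random label signs
would cancel directional pleiotropy in ratio space and the Egger
intercept could not detect it.

What the generator does **not** emulate: LD between instruments (LD
blocks for clumping tests are synthetic, with a user-set within-block
r²), winner's-curse selection of instruments, sample overlap between
the two GWAS, MAF-dependent effect-size architecture, and non-normal
summary noise.  Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions, not robustness to those
real-data complications.

## Problem sizes and numerics

The statistical validation uses 500-seed recovery/coverage runs, a
1000-seed type-I grid, 100-seed MR-PRESSO and colocalization scenario
grids, and 1000 Monte-Carlo simulations per PRESSO call — sizes at
which the Monte-Carlo error is a small fraction of each assertion band
and a full run completes in seconds.  Ties in clumping are broken
lexicographically; p-values are floored at the smallest positive double
so they stay in (0, 1]; bootstrap and Monte-Carlo streams come from
`numpy.random.default_rng` seeded explicitly per call, with pipeline
sub-seeds spawned from the global seed via `SeedSequence` — no global
RNG state anywhere.

## Known limitations

Single-exposure, single-outcome MR only (no multivariable MR, no
mode-based estimators, no Steiger filtering); clumping consumes a
precomputed pairwise r² table and never computes LD from genotypes; no
genome-build liftover; colocalization assumes at most one causal
variant per trait per region (no conditional/SuSiE decomposition);
binary-trait SEs use the effective-sample-size approximation rather
than a full liability model.
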