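# mrbidir

Bi-directional two-sample Mendelian randomization (MR) for GWAS summary
statistics, built around the question of whether low bone mineral density
(BMD, the defining trait of osteoporosis) causally raises the risk of
osteoarthritis (OA) — and whether OA, in turn, affects BMD.  The package is
a general toolkit: any pair of traits with tab-delimited summary statistics
can be analysed.

It is aimed at genetic epidemiologists who work from published summary
data.  It covers instrument selection (genome-wide significance screen, LD
clumping, outcome-association exclusion), allele harmonization (strand
flips and frequency-resolved palindromic SNPs), a panel of causal
estimators with sensitivity analyses, MR-PRESSO outlier detection, Bayesian
colocalization of GWAS/eQTL signal pairs, gene-set over-representation
statistics, and synthetic-data generators with known ground truth so that
every stage is testable without downloading any real GWAS.

## The model

Each instrument SNP *j* carries an exposure association estimate
γ̂*ⱼ* (SE σ*ₓⱼ*) and an outcome association estimate Γ̂*ⱼ* (SE σ*ᵧⱼ*),
harmonized to a common effect allele.  The per-SNP Wald ratio is
β̂*ⱼ* = Γ̂*ⱼ*/γ̂*ⱼ* with first-order SE σ*ⱼ* = σ*ᵧⱼ*/|γ̂*ⱼ*|.  The primary
estimator is fixed-effect inverse-variance weighting,

> β̂ᵢᵥw = Σ*ⱼ* w*ⱼ* β̂*ⱼ* / Σ*ⱼ* w*ⱼ*,  w*ⱼ* = 1/σ*ⱼ*²,  SE = (Σ*ⱼ* w*ⱼ*)^(−1/2),

which is algebraically the slope of a zero-intercept weighted regression of
Γ̂ on γ̂.  Sensitivity analyses: simple and weighted medians (parametric
bootstrap SEs; the weighted median is consistent when instruments carrying
≥ 50 % of the weight are valid), MR-Egger regression (whose free intercept
estimates directional pleiotropy), Cochran's Q, leave-one-out estimates,
and MR-PRESSO (Monte-Carlo residual-sum-of-squares global, outlier and
distortion tests with an outlier-adjusted IVW).  Colocalization uses
Wakefield approximate Bayes factors, log ABF = ½log(1−r) + ½rz² with
r = W/(V+W), combined into posteriors PP0–PP4 for the five
shared-causal-variant hypotheses.

## Worked example

```python
from mrbidir import (SimulationParams, simulate_gwas_pair, harmonize_all,
                     ivw, mr_egger, weighted_median, cochran_q)

# 50 instruments, true causal effect 0.1, BMD-vs-OA-sized samples
params = SimulationParams(n_snps=50, theta=0.1, seed=7)
exposure, outcome, truth = simulate_gwas_pair(params)
instruments, report = harmonize_all(exposure, outcome)

est = ivw(instruments)
wm = weighted_median(instruments, n_boot=1000, seed=7)
egger = mr_egger(instruments)
q = cochran_q(instruments)
```

printing, for that seed:

```
IVW (fixed):      beta=0.098  95% CI (0.083, 0.112)  p=5.39e-39
Weighted median:  beta=0.106  95% CI (0.084, 0.128)
MR-Egger slope:   beta=0.119  intercept=-0.0030 (p=0.19)
Cochran's Q:      47.16 on 49 df (p=0.55)
```

The IVW estimate recovers the simulated causal effect of 0.1 (its CI covers
the truth), the weighted median agrees, the Egger intercept is consistent
with zero (no directional pleiotropy was simulated) and Q shows no excess
heterogeneity.  On the log-odds outcome scale a beta of 0.1 corresponds to
an odds ratio of about 1.11 per SD decrease of the exposure.

The same analysis runs from the shell:

```sh
mrbidir simulate --scenario causal --seed 7 --out-dir sim
mrbidir run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --seed 7 --out-dir out     # writes results.tsv/.json + reports
```

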