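"""Synthetic GWAS summary statistics with known ground truth.

Every pipeline stage is exercised on data generated here, so the
generators emulate the statistical structure a two-sample MR analysis
assumes: per-SNP exposure effects with standard errors driven by sample
size and allele frequency, outcome effects built as
``theta * gamma_j + alpha_j + noise`` with pleiotropy ``alpha_j`` drawn
under one of four scenarios (none, balanced, directional, gross
outliers), allele/strand perturbations for harmonization tests, LD-block
structure for clumping tests, and paired association regions for
colocalization tests.

Defaults mirror the BMD-on-OA setting: a quantitative exposure measured
in ~33k individuals (femoral-neck bone mineral density scale) and a
binary outcome from a ~385k-sample case-control GWAS (osteoarthritis
scale, case fraction 0.2).  Every generator is a pure function of its
parameters including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .colocalization import RegionAssociations
from .gwas_io import LDTable, SummaryStatSet, VariantAssociation

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "PerturbationTruth",
    "simulate_gwas_pair",
    "perturb_for_harmonization",
    "simulate_coloc_region",
    "simulate_clumping_input",
]

_TINY_P = float(np.finfo(float).tiny)

# non-palindromic allele pairs assigned round-robin to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one exposure/outcome GWAS pair.

    ``min_instrument_z`` truncates the true exposure effects away from
    zero so that each instrument's expected exposure z-statistic is at
    least that value (detectable instruments; 6 comfortably clears the
    genome-wide threshold z ≈ 5.45, 10 gives the strong-instrument
    regime).  ``outlier_shift`` is in units of the outcome SE.
    """

    n_snps: int = 50
    theta: float = 0.1
    n_exp: int = 32_735
    n_out: int = 384_838
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 10.0
    exposure_type: str = "quantitative"
    outcome_type: str = "binary"
    case_fraction: float = 0.2
    sigma_gamma: float = 0.1
    min_instrument_z: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated pair, one entry per SNP."""

    theta: float
    snp_ids: list[str]
    gamma: np.ndarray        # true exposure effects
    alpha: np.ndarray        # per-SNP pleiotropic effects on the outcome
    outlier_flags: np.ndarray
    maf: np.ndarray


def _se_quantitative(maf: np.ndarray, n: float) -> np.ndarray:
    """SE of a per-allele effect on a standardized quantitative trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    """Log-odds SE via the effective-sample-size approximation."""
    v = case_fraction
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * v * (1.0 - v))


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _TINY_P)


def _records(snp_ids, chroms, poss, alleles, eaf, beta, se, n) -> list[VariantAssociation]:
    p = _pvalues(beta, se)
    return [
        VariantAssociation(
            snp_id=snp_ids[j], chrom=chroms[j], pos=int(poss[j]),
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(p[j]), n=float(n))
        for j in range(len(snp_ids))
    ]


def simulate_gwas_pair(params: SimulationParams
                       ) -> tuple[SummaryStatSet, SummaryStatSet, SimulationTruth]:
    """Simulate one exposure GWAS, one outcome GWAS and their ground truth.

    For SNP j: maf_j ~ Uniform(maf_range); the true exposure effect
    gamma_j is drawn from Normal(0, sigma_gamma²) truncated so
    |gamma_j| >= min_instrument_z * se_exp_j, with a random sign; the
    observed effect is gamma_j plus sampling noise at the analytic SE.
    The true outcome effect is theta*gamma_j plus pleiotropy alpha_j
    (mode-dependent), observed with its own sampling noise.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_snps
    if params.min_instrument_z < 2:
        warnings.warn("min_instrument_z < 2: instruments may be undetectable",
                      stacklevel=2)

    maf = rng.uniform(params.maf_range[0], params.maf_range[1], size=n)
    se_exp = _se_quantitative(maf, params.n_exp) \
        if params.exposure_type == "quantitative" \
        else _se_binary(maf, params.n_exp, params.case_fraction)
    se_out = _se_quantitative(maf, params.n_out) \
        if params.outcome_type == "quantitative" \
        else _se_binary(maf, params.n_out, params.case_fraction)

    # truncated normal |gamma| >= bound, sign random
    bound = params.min_instrument_z * se_exp
    a = bound / params.sigma_gamma
    mag = stats.truncnorm.rvs(a, np.inf, scale=params.sigma_gamma,
                              size=n, random_state=rng)
    gamma = mag * rng.choice([-1.0, 1.0], size=n)

    alpha = np.zeros(n)
    outliers = np.zeros(n, dtype=bool)
    if params.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, params.pleiotropy_sd, size=n)
    elif params.pleiotropy_mode == "directional":
        alpha = rng.normal(params.pleiotropy_mean, params.pleiotropy_sd, size=n)
    elif params.pleiotropy_mode == "outlier":
        outliers = rng.random(n) < params.outlier_fraction
        alpha = np.where(outliers, params.outlier_shift * se_out, 0.0)

    # pleiotropy acts in the exposure-raising orientation: a "directional"
    # direct effect has a consistent sign relative to the allele that raises
    # the exposure, not relative to the arbitrary effect-allele label
    alpha = np.sign(gamma) * alpha
    beta_exp_hat = gamma + se_exp * rng.standard_normal(n)
    gamma_out = params.theta * gamma + alpha
    beta_out_hat = gamma_out + se_out * rng.standard_normal(n)

    snp_ids = [f"rs{j + 1:06d}" for j in range(n)]
    chroms = [str(j % 22 + 1) for j in range(n)]
    poss = [1_000_000 + (j // 22) * 2_000_000 for j in range(n)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n)]

    exposure = SummaryStatSet(
        "exposure", params.exposure_type,
        _records(snp_ids, chroms, poss, alleles, maf, beta_exp_hat, se_exp,
                 params.n_exp))
    outcome = SummaryStatSet(
        "outcome", params.outcome_type,
        _records(snp_ids, chroms, poss, alleles, maf, beta_out_hat, se_out,
                 params.n_out))
    truth = SimulationTruth(theta=params.theta, snp_ids=snp_ids, gamma=gamma,
                            alpha=alpha, outlier_flags=outliers, maf=maf)
    return exposure, outcome, truth


@dataclass
class PerturbationTruth:
    """Which perturbation was applied to each SNP and the harmonization
    action expected to undo it."""

    swapped: dict[str, bool] = field(default_factory=dict)
    complemented: dict[str, bool] = field(default_factory=dict)
    palindromic: dict[str, bool] = field(default_factory=dict)
    expected_action: dict[str, str] = field(default_factory=dict)


def _swap_alleles(v: VariantAssociation) -> VariantAssociation:
    return replace(v, effect_allele=v.other_allele, other_allele=v.effect_allele,
                   beta=-v.beta, eaf=None if v.eaf is None else 1.0 - v.eaf)


def _complement(v: VariantAssociation) -> VariantAssociation:
    return replace(v, effect_allele=_COMPLEMENT[v.effect_allele],
                   other_allele=_COMPLEMENT[v.other_allele])


def perturb_for_harmonization(exposure: SummaryStatSet, outcome: SummaryStatSet,
                              flip_fraction: float = 0.3,
                              palindrome_fraction: float = 0.0,
                              seed: int = 0,
                              palindrome_eaf: float | None = None
                              ) -> tuple[SummaryStatSet, SummaryStatSet,
                                         PerturbationTruth]:
    """Apply harmonization-testable perturbations to a simulated pair.

    A ``palindrome_fraction`` subset of SNPs is converted (on both sides)
    to an A/T variant whose strand must be resolved by frequency; the
    remaining SNPs have their *outcome* records allele-swapped and/or
    strand-complemented, each independently with probability
    ``flip_fraction``.  With ``palindrome_eaf`` set (e.g. 0.5) the
    converted palindromes get that frequency on both sides, which makes
    them deliberately unresolvable.  The truth records every perturbation
    and the harmonization action that should recover it.
    """
    if not (0.0 <= flip_fraction <= 1.0 and 0.0 <= palindrome_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = PerturbationTruth()
    new_exp, new_out = [], []
    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            new_exp.append(exp)
            continue
        make_palindrome = rng.random() < palindrome_fraction
        truth.palindromic[exp.snp_id] = make_palindrome
        if make_palindrome:
            if palindrome_eaf is not None:
                eaf_e = eaf_o = palindrome_eaf
            else:
                # resolvable: both frequencies on the same side, away from 0.5
                eaf_e = float(rng.uniform(0.10, 0.35))
                eaf_o = float(np.clip(eaf_e + rng.uniform(-0.03, 0.03), 0.05, 0.40))
            exp_p = replace(exp, effect_allele="A", other_allele="T", eaf=eaf_e)
            out_p = replace(out, effect_allele="A", other_allele="T", eaf=eaf_o)
            if rng.random() < 0.5:
                # present the outcome on the opposite strand: for an A/T
                # variant that is the same as swapping the labels
                out_p = replace(out_p, effect_allele="T", other_allele="A",
                                beta=-out_p.beta, eaf=1.0 - out_p.eaf)
            truth.swapped[exp.snp_id] = False
            truth.complemented[exp.snp_id] = False
            truth.expected_action[exp.snp_id] = (
                "dropped" if palindrome_eaf is not None
                and abs(palindrome_eaf - 0.5) < 0.08 else "palindrome_aligned")
            new_exp.append(exp_p)
            new_out.append(out_p)
            continue
        swap = rng.random() < flip_fraction
        comp = rng.random() < flip_fraction
        truth.swapped[exp.snp_id] = swap
        truth.complemented[exp.snp_id] = comp
        out_p = out
        if swap:
            out_p = _swap_alleles(out_p)
        if comp:
            out_p = _complement(out_p)
        truth.expected_action[exp.snp_id] = "flipped" if swap else "kept_as_is"
        new_exp.append(exp)
        new_out.append(out_p)
    return (exposure.replace_records(new_exp),
            outcome.replace_records(new_out), truth)


def simulate_coloc_region(q_variants: int, scenario: str = "shared",
                          z_scale: float = 8.0, seed: int = 0,
                          n_samples: int = 10_000
                          ) -> tuple[RegionAssociations, RegionAssociations, dict]:
    """Two association regions over shared variants with a known scenario.

    ``scenario``: ``"shared"`` plants one causal variant affecting both
    traits (the H4 configuration), ``"distinct"`` plants different causal
    variants for the two traits (H3; requires >= 2 variants), ``"null"``
    plants none (H0).  Non-causal variants carry standard-normal noise z.
    """
    if q_variants < 1:
        raise ValueError("q_variants must be >= 1")
    if scenario not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "distinct" and q_variants < 2:
        raise ValueError("distinct-causal scenario needs at least 2 variants")
    rng = np.random.default_rng(seed)

    maf = rng.uniform(0.1, 0.5, size=q_variants)
    se = _se_quantitative(maf, n_samples)
    z1 = rng.standard_normal(q_variants)
    z2 = rng.standard_normal(q_variants)
    causal1 = causal2 = None
    if scenario == "shared":
        causal1 = causal2 = int(rng.integers(q_variants))
        z1[causal1] += z_scale
        z2[causal2] += z_scale
    elif scenario == "distinct":
        causal1, causal2 = rng.choice(q_variants, size=2, replace=False)
        causal1, causal2 = int(causal1), int(causal2)
        z1[causal1] += z_scale
        z2[causal2] += z_scale

    snp_ids = [f"rs{j + 1:06d}" for j in range(q_variants)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(q_variants)]

    def _region(label, z):
        beta = z * se
        return RegionAssociations(
            trait_label=label,
            variants=_records(snp_ids, ["1"] * q_variants,
                              [1_000_000 + j * 1000 for j in range(q_variants)],
                              alleles, maf, beta, se, n_samples))

    truth = {"scenario": scenario, "causal1": causal1, "causal2": causal2,
             "z_scale": z_scale}
    return _region("trait1", z1), _region("trait2", z2), truth


def simulate_clumping_input(n_blocks: int = 5, snps_per_block: int = 4,
                            r2_within: float = 0.9, seed: int = 0
                            ) -> tuple[SummaryStatSet, LDTable, dict]:
    """Genome-wide-significant SNPs arranged in LD blocks, for clump tests.

    Each block is a cluster of ``snps_per_block`` SNPs within 100 kb that
    are mutually correlated at ``r2_within``; blocks are spaced 2 Mb apart
    (beyond the default clump window) and cross-block r² entries are
    omitted.  The truth names the expected index SNP of each block (lowest
    p, ties by snp_id).
    """
    rng = np.random.default_rng(seed)
    records = []
    ld = LDTable()
    expected = []
    sid = 0
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 2_000_000 + b * 2_000_000
        block_ids = []
        best = None
        for k in range(snps_per_block):
            sid += 1
            snp = f"rs{sid:06d}"
            block_ids.append(snp)
            maf = float(rng.uniform(0.1, 0.5))
            se = float(_se_quantitative(np.array([maf]), 30_000)[0])
            z = float(rng.uniform(6.0, 12.0))
            beta = z * se * (1 if rng.random() < 0.5 else -1)
            p = float(max(2.0 * stats.norm.sf(abs(z)), _TINY_P))
            records.append(VariantAssociation(
                snp_id=snp, chrom=chrom, pos=base + k * 25_000,
                effect_allele="A", other_allele="G", eaf=maf,
                beta=beta, se=se, pvalue=p, n=30_000))
            if best is None or (p, snp) < best:
                best = (p, snp)
        for i in range(len(block_ids)):
            for j in range(i + 1, len(block_ids)):
                ld.add(block_ids[i], block_ids[j], r2_within)
        expected.append(best[1])
    stats_set = SummaryStatSet("clump_input", "quantitative", records)
    return stats_set, ld, {"expected_index_snps": expected}
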