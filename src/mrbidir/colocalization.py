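"""Bayesian colocalization of two association signals in one region.

Given summary statistics for two traits (e.g. a GWAS and an eQTL study)
over a shared set of variants, computes Wakefield approximate Bayes
factors per variant and the posterior probabilities of the five standard
hypotheses:

* H0 — no association with either trait in the region;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, two distinct causal variants;
* H4 — both traits associated, one shared causal variant.

All hypothesis sums are accumulated in log space (ABFs overflow around
|z| > 40 otherwise).  Also provides the Bonferroni significance-threshold
helper used to screen gene–tissue pairs before colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .gwas_io import InputError, VariantAssociation
from .harmonization import HarmonizationConfig, harmonize_pair

__all__ = [
    "RegionAssociations",
    "ColocPriors",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_abf",
    "bonferroni_threshold",
]

#: canonical prior effect SDs (sqrt of Wakefield's W)
SD_PRIOR_QUANTITATIVE = 0.15
SD_PRIOR_BINARY = 0.20


@dataclass
class RegionAssociations:
    """One trait's associations across the variants of one region."""

    trait_label: str
    variants: list[VariantAssociation]
    trait_type: str = "quantitative"
    sd_prior: float | None = None

    def __post_init__(self):
        if len(self.variants) == 0:
            raise InputError(f"region for {self.trait_label!r} has no variants")
        chroms = {v.chrom for v in self.variants if v.chrom is not None}
        if len(chroms) > 1:
            raise InputError(f"region spans multiple chromosomes: {sorted(chroms)}")
        for v in self.variants:
            if v.se <= 0:
                raise InputError(f"non-positive se for {v.snp_id!r}")
        if self.sd_prior is None:
            self.sd_prior = (SD_PRIOR_BINARY if self.trait_type == "binary"
                             else SD_PRIOR_QUANTITATIVE)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def get(self, snp_id: str) -> VariantAssociation | None:
        for v in self.variants:
            if v.snp_id == snp_id:
                return v
        return None


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities: association with trait 1 only
    (``p1``), trait 2 only (``p2``), both (``p12``)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= self.p1 and self.p12 <= self.p2):
            raise ValueError("require 0 < p12 <= p1 and p12 <= p2")
        if self.p1 >= 1 or self.p2 >= 1:
            raise ValueError("priors must be < 1")

    def validate_for_region(self, q: int) -> None:
        if q * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError(
                f"priors too large for region of {q} variants: "
                f"Q*(p1+p2+p12) must be < 1")


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def to_dict(self) -> dict:
        return {"pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
                "pp3": self.pp3, "pp4": self.pp4, "n_variants": self.n_variants}


def wakefield_log_abf(beta: float, se: float, sd_prior: float) -> float:
    """Wakefield's log approximate Bayes factor for one variant.

    With z = beta/se, V = se², W = sd_prior² and shrinkage r = W/(V+W):
    log ABF = 0.5·log(1−r) + 0.5·r·z².
    """
    if se <= 0:
        raise InputError(f"se must be positive, got {se}")
    if sd_prior <= 0:
        raise InputError(f"sd_prior must be positive, got {sd_prior}")
    z = beta / se
    v = se * se
    w = sd_prior * sd_prior
    r = w / (v + w)
    return 0.5 * np.log1p(-r) + 0.5 * r * z * z


def _intersect_harmonized(region1: RegionAssociations,
                          region2: RegionAssociations
                          ) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Pair up shared variants, aligning region-2 alleles to region 1.

    Allele-irreconcilable or ambiguous-palindrome pairs are dropped (the
    ABF depends only on z², but a consistent orientation keeps reported
    effect directions meaningful).
    """
    config = HarmonizationConfig()
    v1_list, v2_list = [], []
    for v1 in region1.variants:
        v2 = region2.get(v1.snp_id)
        if v2 is None:
            continue
        inst = harmonize_pair(v1, v2, config)
        if not inst.kept:
            # frequency-ambiguous palindromes still carry z² information;
            # keep them unless the allele sets are truly irreconcilable
            if inst.drop_reason == "allele_mismatch":
                continue
        v1_list.append(v1)
        v2_list.append(v2)
    return v1_list, v2_list


def coloc_abf(region1: RegionAssociations, region2: RegionAssociations,
              priors: ColocPriors | None = None) -> ColocResult:
    """Posterior probabilities PP0–PP4 for one region's signal pair.

    Regions are intersected on shared snp_ids; the five hypothesis sums
    are computed in log space and normalized with log-sum-exp.
    """
    priors = priors or ColocPriors()
    v1, v2 = _intersect_harmonized(region1, region2)
    q = len(v1)
    if q == 0:
        raise InputError(
            f"no shared variants between regions "
            f"({len(region1.variants)} in {region1.trait_label!r}, "
            f"{len(region2.variants)} in {region2.trait_label!r})")
    priors.validate_for_region(q)

    l1 = np.array([wakefield_log_abf(v.beta, v.se, region1.sd_prior) for v in v1])
    l2 = np.array([wakefield_log_abf(v.beta, v.se, region2.sd_prior) for v in v2])

    lp1, lp2, lp12 = np.log(priors.p1), np.log(priors.p2), np.log(priors.p12)

    lh0 = 0.0
    lh1 = lp1 + logsumexp(l1)
    lh2 = lp2 + logsumexp(l2)
    lh4 = lp12 + logsumexp(l1 + l2)
    # H3: sum over i != j of ABF1_i * ABF2_j = (sum_i)(sum_j) - sum_diag
    s_all = logsumexp(l1) + logsumexp(l2)
    s_diag = logsumexp(l1 + l2)
    if s_diag >= s_all:  # Q == 1 (or numerically degenerate): empty i != j sum
        lh3 = -np.inf
    else:
        lh3 = lp1 + lp2 + s_all + np.log1p(-np.exp(s_diag - s_all))

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    return ColocResult(pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
                       pp3=float(pp[3]), pp4=float(pp[4]), n_variants=q)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha/n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests
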