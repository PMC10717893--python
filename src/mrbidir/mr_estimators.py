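"""Two-sample MR estimators and diagnostics.

Per-instrument Wald ratios (outcome effect over exposure effect) are
combined by inverse-variance weighting — fixed-effect for the main
analysis, multiplicative random-effect for subgroup use — and complemented
by MR-Egger regression (whose free intercept estimates directional
pleiotropy), simple and weighted median estimators with parametric
bootstrap standard errors, Cochran's Q heterogeneity, and leave-one-out
estimates.

Ratio-scale standard errors use the first-order delta method
``se_out / |beta_exp|`` by default; the second-order form adding the
exposure-noise term is available via ``second_order=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import InputError
from .harmonization import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "mr_egger",
    "simple_median",
    "weighted_median",
    "leave_one_out",
    "ratio_estimates",
]

#: normal quantile used for Wald-type 95% confidence intervals
Z_95 = 1.959964

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate: a cell-group of a Table-1-style report."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    label: str | None = None  # e.g. omitted snp_id for leave-one-out


@dataclass(frozen=True)
class HeterogeneityResult:
    q_statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    intercept_ci_low: float
    intercept_ci_high: float


def _kept(insts: Sequence[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    return [i for i in insts if i.kept]


def ratio_estimates(insts: Sequence[HarmonizedInstrument],
                    second_order: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their delta-method SEs."""
    kept = _kept(insts)
    bx = np.array([i.beta_exp for i in kept], dtype=float)
    by = np.array([i.beta_out for i in kept], dtype=float)
    sx = np.array([i.se_exp for i in kept], dtype=float)
    sy = np.array([i.se_out for i in kept], dtype=float)
    if np.any(bx == 0):
        bad = [i.snp_id for i, b in zip(kept, bx) if b == 0]
        raise InputError(f"zero exposure effect, Wald ratio undefined: {bad}")
    ratios = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return ratios, se


def _normal_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return max(p, _TINY_P)


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp."""
    ratios, ses = ratio_estimates([inst], second_order=second_order)
    beta, se = float(ratios[0]), float(ses[0])
    return MREstimate(
        method="wald_ratio", beta=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
        pvalue=_normal_p(beta / se), n_snps=1, label=inst.snp_id)


def ivw(insts: Sequence[HarmonizedInstrument], model: str = "fixed",
        second_order: bool = False) -> MREstimate:
    """Inverse-variance-weighted combination of the per-instrument ratios.

    ``model="fixed"`` gives the classical fixed-effect meta-analysis SE;
    ``model="random"`` inflates it multiplicatively by
    ``max(1, sqrt(Q / (n - 1)))`` to absorb overdispersion.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    kept = _kept(insts)
    n = len(kept)
    if n == 0:
        raise InputError("IVW requires at least one instrument")
    if model == "random" and n < 2:
        raise InputError("random-effects IVW requires at least two instruments")
    if n == 1:
        warnings.warn("single instrument: IVW reduces to the Wald ratio",
                      stacklevel=2)
        wr = wald_ratio(kept[0], second_order=second_order)
        return MREstimate(method="ivw_fixed", beta=wr.beta, se=wr.se,
                          ci_low=wr.ci_low, ci_high=wr.ci_high,
                          pvalue=wr.pvalue, n_snps=1)
    ratios, ses = ratio_estimates(kept, second_order=second_order)
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if model == "random":
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return MREstimate(
        method=f"ivw_{model}", beta=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
        pvalue=_normal_p(beta / se), n_snps=n)


def cochran_q(insts: Sequence[HarmonizedInstrument],
              second_order: bool = False) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of the per-instrument ratios around the
    fixed-effect IVW estimate; upper-tail chi-square(n−1) p-value."""
    kept = _kept(insts)
    n = len(kept)
    if n < 2:
        raise InputError("Cochran's Q requires at least two instruments")
    ratios, ses = ratio_estimates(kept, second_order=second_order)
    w = 1.0 / ses**2
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = n - 1
    return HeterogeneityResult(q_statistic=q, df=df,
                               pvalue=float(stats.chi2.sf(q, df)))


def mr_egger(insts: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: weighted least squares of the outcome effects on
    the exposure effects with a free intercept.

    Each pair is first oriented so the exposure effect is non-negative (the
    Egger slope is not invariant to per-instrument sign flips otherwise).
    Weights are 1/se_out²; standard errors carry the residual scale factor
    ``max(1, sqrt(RSS/(n−2)))`` and p-values use the t distribution with
    n−2 degrees of freedom.  A nonzero intercept estimates the average
    directional pleiotropic effect.
    """
    kept = _kept(insts)
    n = len(kept)
    if n < 3:
        raise InputError("MR-Egger requires at least three instruments")
    bx = np.array([i.beta_exp for i in kept], dtype=float)
    by = np.array([i.beta_out for i in kept], dtype=float)
    sy = np.array([i.se_out for i in kept], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    if np.allclose(x, x[0]):
        raise InputError("exposure effects are collinear; Egger fit undefined")
    w = 1.0 / sy**2

    # closed-form weighted least squares with intercept
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)

    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / (n - 2)))
    se_slope = float(np.sqrt(1.0 / sxx)) * scale
    se_int = float(np.sqrt(1.0 / sw + xbar**2 / sxx)) * scale

    df = n - 2
    tq = float(stats.t.ppf(0.975, df))
    p_slope = max(float(2.0 * stats.t.sf(abs(slope / se_slope), df)), _TINY_P)
    p_int = max(float(2.0 * stats.t.sf(abs(intercept / se_int), df)), _TINY_P)

    slope_est = MREstimate(
        method="egger_slope", beta=slope, se=se_slope,
        ci_low=slope - tq * se_slope, ci_high=slope + tq * se_slope,
        pvalue=p_slope, n_snps=n)
    return EggerResult(slope=slope_est, intercept=intercept,
                       intercept_se=se_int, intercept_pvalue=p_int,
                       intercept_ci_low=intercept - tq * se_int,
                       intercept_ci_high=intercept + tq * se_int)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by midpoint-convention linear interpolation.

    The j-th ordered ratio sits at cumulative-weight percentile
    ``S_j − w_j/2`` (S_j the inclusive cumulative sum of normalized
    weights); the estimate interpolates the ordered ratios at 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    perc = s - w / 2.0
    return float(np.interp(0.5, perc, r))


def _bootstrap_median(ratios: np.ndarray, ses: np.ndarray,
                      weights: np.ndarray | None, n_boot: int,
                      seed: int) -> float:
    """SD of the (weighted) median across parametric-bootstrap redraws of
    the ratio estimates (each redrawn from Normal(ratio_j, se_j))."""
    rng = np.random.default_rng(seed)
    draws = ratios[None, :] + ses[None, :] * rng.standard_normal((n_boot, len(ratios)))
    if weights is None:
        est = np.median(draws, axis=1)
    else:
        est = np.array([_weighted_median_point(row, weights) for row in draws])
    return float(np.std(est, ddof=1))


def _median_estimate(method: str, beta: float, se: float, n: int) -> MREstimate:
    if se > 0:
        p = _normal_p(beta / se)
    else:
        p = 1.0 if beta == 0 else _TINY_P
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
                      pvalue=p, n_snps=n)


def simple_median(insts: Sequence[HarmonizedInstrument], n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    """Median of the per-instrument ratios; parametric-bootstrap SE."""
    kept = _kept(insts)
    if len(kept) < 3:
        raise InputError("simple median requires at least three instruments")
    ratios, ses = ratio_estimates(kept)
    beta = float(np.median(ratios))
    se = _bootstrap_median(ratios, ses, None, n_boot, seed)
    return _median_estimate("simple_median", beta, se, len(kept))


def weighted_median(insts: Sequence[HarmonizedInstrument], n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Inverse-variance weighted median of the per-instrument ratios.

    Consistent when instruments carrying at least half of the weight are
    valid.  SE by parametric bootstrap, as for the simple median.
    """
    kept = _kept(insts)
    if len(kept) < 3:
        raise InputError("weighted median requires at least three instruments")
    ratios, ses = ratio_estimates(kept)
    weights = 1.0 / ses**2
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_median(ratios, ses, weights, n_boot, seed)
    return _median_estimate("weighted_median", beta, se, len(kept))


def leave_one_out(insts: Sequence[HarmonizedInstrument]) -> list[MREstimate]:
    """Fixed-effect IVW recomputed with each instrument omitted in turn;
    each estimate is labelled with the omitted snp_id."""
    kept = _kept(insts)
    if len(kept) < 3:
        raise InputError("leave-one-out requires at least three instruments")
    results = []
    for j, omitted in enumerate(kept):
        subset = kept[:j] + kept[j + 1:]
        est = ivw(subset, model="fixed")
        results.append(MREstimate(
            method="ivw_loo", beta=est.beta, se=est.se,
            ci_low=est.ci_low, ci_high=est.ci_high,
            pvalue=est.pvalue, n_snps=est.n_snps, label=omitted.snp_id))
    return results
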