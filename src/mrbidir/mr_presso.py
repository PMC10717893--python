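"""MR-PRESSO: pleiotropy residual sum and outlier test.

A Monte-Carlo test of horizontal pleiotropy built on leave-one-out IVW
slopes.  The observed global statistic is the weighted residual sum of
squares of each instrument's outcome effect around the prediction of the
model fitted without it; its null distribution comes from parametric
simulations that redraw all outcome effects from
``Normal(theta_loo_j * beta_exp_j, se_out_j)`` and recompute the statistic
(including the leave-one-out slopes) on each simulated dataset.  Per-
instrument outlier p-values compare each observed residual contribution
with its simulated distribution, Bonferroni-corrected across instruments;
the outlier-adjusted estimate is fixed-effect IVW on the surviving
instruments, and the distortion test compares the raw-vs-adjusted relative
difference with the distribution obtained by removing random same-sized
subsets of non-outlier instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_io import InputError
from .harmonization import HarmonizedInstrument
from .mr_estimators import MREstimate, ivw

__all__ = ["PressoResult", "presso_global", "presso_outlier_test"]


@dataclass
class PressoResult:
    rss_observed: float
    global_pvalue: float
    n_sim: int
    seed: int
    outliers: dict[str, float] = field(default_factory=dict)  # snp_id -> adj p
    outlier_pvalues_raw: dict[str, float] = field(default_factory=dict)
    adjusted_estimate: MREstimate | None = None
    distortion_pvalue: float | None = None
    distortion_observed: float | None = None

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_pvalue": self.global_pvalue,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outliers": dict(self.outliers),
            "outlier_pvalues_raw": dict(self.outlier_pvalues_raw),
            "adjusted_estimate": None if self.adjusted_estimate is None else {
                "method": self.adjusted_estimate.method,
                "beta": self.adjusted_estimate.beta,
                "se": self.adjusted_estimate.se,
                "ci_low": self.adjusted_estimate.ci_low,
                "ci_high": self.adjusted_estimate.ci_high,
                "pvalue": self.adjusted_estimate.pvalue,
                "n_snps": self.adjusted_estimate.n_snps,
            },
            "distortion_pvalue": self.distortion_pvalue,
            "distortion_observed": self.distortion_observed,
        }


def _arrays(insts: Sequence[HarmonizedInstrument]):
    kept = [i for i in insts if i.kept]
    x = np.array([i.beta_exp for i in kept], dtype=float)
    y = np.array([i.beta_out for i in kept], dtype=float)
    sy = np.array([i.se_out for i in kept], dtype=float)
    return kept, x, y, sy


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes (equivalently fixed IVW)."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def _rss_and_contrib(x, y, w):
    theta_loo = _loo_slopes(x, y, w)
    contrib = w * (y - theta_loo * x) ** 2
    return float(np.sum(contrib)), contrib


def _sim_contribs(x, sy, w, theta_loo_obs, n_sim, rng):
    """Simulated residual contributions, shape (n_sim, n).

    Outcome effects are redrawn around the observed leave-one-out
    predictions; LOO slopes are recomputed within each simulated dataset.
    """
    n = len(x)
    mu = theta_loo_obs * x
    ysim = mu[None, :] + sy[None, :] * rng.standard_normal((n_sim, n))
    sxx = np.sum(w * x * x)
    sxy_sim = ysim @ (w * x)  # (n_sim,)
    theta_sim = (sxy_sim[:, None] - (w * x)[None, :] * ysim) / (sxx - w * x * x)[None, :]
    return w[None, :] * (ysim - theta_sim * x[None, :]) ** 2


def presso_global(insts: Sequence[HarmonizedInstrument], n_sim: int = 1000,
                  seed: int = 0) -> PressoResult:
    """Global MR-PRESSO heterogeneity test.

    Monte-Carlo p uses add-one smoothing, so it is never below
    1/(n_sim + 1) and never exactly zero.
    """
    kept, x, y, sy = _arrays(insts)
    if len(kept) < 4:
        raise InputError("insufficient instruments for MR-PRESSO (need >= 4)")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    w = 1.0 / sy**2
    rss_obs, _ = _rss_and_contrib(x, y, w)
    theta_loo = _loo_slopes(x, y, w)
    rng = np.random.default_rng(seed)
    sim = _sim_contribs(x, sy, w, theta_loo, n_sim, rng)
    rss_sim = np.sum(sim, axis=1)
    p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return PressoResult(rss_observed=rss_obs, global_pvalue=p,
                        n_sim=n_sim, seed=seed)


def presso_outlier_test(insts: Sequence[HarmonizedInstrument],
                        n_sim: int = 1000, seed: int = 0,
                        alpha: float = 0.05, force: bool = False,
                        use_raw_p: bool = False) -> PressoResult:
    """Per-instrument outlier test with outlier-adjusted IVW and distortion p.

    Runs the global test first; unless ``force`` is set, a non-significant
    global p (>= ``alpha``) returns the global result with no outlier
    search.  Outlier flagging uses Bonferroni-adjusted per-instrument
    Monte-Carlo p-values by default (``use_raw_p=True`` flags on the raw
    ones).  All Monte-Carlo streams are determined by ``seed``.
    """
    kept, x, y, sy = _arrays(insts)
    n = len(kept)
    if n < 4:
        raise InputError("insufficient instruments for MR-PRESSO (need >= 4)")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    w = 1.0 / sy**2
    rss_obs, contrib_obs = _rss_and_contrib(x, y, w)
    theta_loo = _loo_slopes(x, y, w)

    rng = np.random.default_rng(seed)
    sim = _sim_contribs(x, sy, w, theta_loo, n_sim, rng)
    rss_sim = np.sum(sim, axis=1)
    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    result = PressoResult(rss_observed=rss_obs, global_pvalue=global_p,
                          n_sim=n_sim, seed=seed)
    if global_p >= alpha and not force:
        return result

    raw_p = (1.0 + np.sum(sim >= contrib_obs[None, :], axis=0)) / (n_sim + 1.0)
    adj_p = np.minimum(1.0, raw_p * n)
    result.outlier_pvalues_raw = {k.snp_id: float(p) for k, p in zip(kept, raw_p)}
    flag_p = raw_p if use_raw_p else adj_p
    flagged = flag_p < alpha
    result.outliers = {k.snp_id: float(a) for k, a, f in zip(kept, adj_p, flagged) if f}
    if not np.any(flagged):
        return result
    if np.all(flagged):
        raise InputError("no instruments survive outlier removal")

    survivors = [k for k, f in zip(kept, flagged) if not f]
    adjusted = ivw(survivors, model="fixed")
    result.adjusted_estimate = adjusted

    # distortion test: compare the observed raw-vs-adjusted relative shift
    # with the shifts obtained by removing random same-sized subsets of the
    # non-outlier instruments
    raw_est = ivw(kept, model="fixed")
    if adjusted.beta != 0:
        d_obs = (raw_est.beta - adjusted.beta) / abs(adjusted.beta)
        n_out = int(np.sum(flagged))
        surv_idx = np.flatnonzero(~flagged)
        if len(surv_idx) > n_out:
            d_sim = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(surv_idx, size=n_out, replace=False)
                keep_mask = np.ones(n, dtype=bool)
                keep_mask[drop] = False
                xs, ys, ws = x[keep_mask], y[keep_mask], w[keep_mask]
                theta_s = np.sum(ws * xs * ys) / np.sum(ws * xs * xs)
                d_sim[s] = (theta_s - adjusted.beta) / abs(adjusted.beta)
            dp = (1.0 + float(np.sum(np.abs(d_sim) >= abs(d_obs)))) / (n_sim + 1.0)
            result.distortion_observed = float(d_obs)
            result.distortion_pvalue = dp
    return result
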