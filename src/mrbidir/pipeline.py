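"""Orchestration of the bi-directional MR analysis.

One *direction* runs p-value screen → LD clumping → outcome-association
exclusion → harmonization → the estimator panel (simple median, weighted
median, fixed-effect IVW, MR-Egger with intercept, Cochran's Q,
leave-one-out, MR-PRESSO) for a single exposure/outcome pair.  The
bi-directional driver runs the forward grid (each BMD-style exposure
against each OA-style outcome) and the reverse grid with its own,
typically looser, instrument p-threshold, isolating per-pair failures.
Everything emitted is a deterministic function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import mr_estimators as me
from .gwas_io import (InputError, LDTable, SummaryStatSet, write_results_table)
from .harmonization import HarmonizationConfig, harmonize_all
from .instrument_selection import (SelectionConfig, exclude_outcome_associated,
                                   filter_by_pvalue, ld_clump)
from .mr_presso import presso_outlier_test

__all__ = ["DirectionConfig", "run_mr_direction", "run_bidirectional",
           "METHOD_ORDER"]

logger = logging.getLogger("mrbidir")

#: Table-1 row ordering of the method panel
METHOD_ORDER = ("simple_median", "weighted_median", "ivw", "mr_egger")

ALL_METHODS = frozenset(METHOD_ORDER)


@dataclass(frozen=True)
class DirectionConfig:
    """Configuration of one analysis direction."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    methods: tuple[str, ...] = METHOD_ORDER
    ivw_model: str = "fixed"
    n_boot: int = 1000
    presso_nsim: int = 1000
    presso_alpha: float = 0.05
    run_presso: bool = True
    exclude_snps: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.methods) - ALL_METHODS
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _estimate_dict(est: me.MREstimate) -> dict:
    d = dataclasses.asdict(est)
    return d


def run_mr_direction(exposure: SummaryStatSet, outcome: SummaryStatSet,
                     ld: LDTable | None = None,
                     config: DirectionConfig | None = None) -> dict:
    """Run the full selection/harmonization/estimation chain for one pair.

    Returns a JSON-serializable report: per-stage selection counts,
    harmonization actions, the requested method estimates in Table-1
    order, heterogeneity, Egger intercept, leave-one-out table and
    MR-PRESSO block.  With fewer than three usable instruments the
    estimator panel degrades gracefully: IVW is still reported from one
    or two instruments and every skipped method carries an explicit note.
    """
    config = config or DirectionConfig()
    ld = ld or LDTable()
    report: dict = {
        "exposure": exposure.trait_label,
        "outcome": outcome.trait_label,
        "config": {
            "p_threshold": config.selection.p_threshold,
            "clump_r2": config.selection.clump_r2,
            "clump_window_kb": config.selection.clump_window_kb,
            "outcome_exclusion_p": config.selection.outcome_exclusion_p,
            "missing_ld": config.selection.missing_ld,
            "ivw_model": config.ivw_model,
            "n_boot": config.n_boot,
            "seed": config.seed,
        },
        "estimates": [],
        "skipped": [],
        "error": None,
    }

    # manual exclusions (e.g. instruments known to be heterogeneous)
    if config.exclude_snps:
        keep = [r for r in exposure if r.snp_id not in set(config.exclude_snps)]
        exposure = exposure.replace_records(keep)
        report["manually_excluded"] = list(config.exclude_snps)

    n_input = len(exposure)
    screened = filter_by_pvalue(exposure, config.selection.p_threshold)
    logger.info("p-filter: %d -> %d", n_input, len(screened))
    if len(screened) == 0:
        report["selection"] = {"n_input": n_input, "n_post_p_filter": 0}
        report["error"] = "no genome-wide-significant instruments"
        return report

    clumped, clump_report = ld_clump(screened, ld, config.selection)
    excluded, excl_report = exclude_outcome_associated(
        clumped, outcome, config.selection.outcome_exclusion_p)
    report["selection"] = {
        "n_input": n_input,
        "n_post_p_filter": len(screened),
        "n_post_clump": len(clumped),
        "n_post_outcome_exclusion": len(excluded),
        "drop_reasons": {**clump_report.drop_reasons, **excl_report.drop_reasons},
    }
    if len(excluded) == 0:
        report["error"] = "no instruments after outcome-association exclusion"
        return report

    try:
        harmonized, harm_report = harmonize_all(excluded, outcome,
                                                config.harmonization)
    except InputError as exc:
        report["harmonization"] = {"error": str(exc)}
        report["error"] = str(exc)
        return report
    report["harmonization"] = harm_report.to_dict()
    usable = [h for h in harmonized if h.kept]
    n_usable = len(usable)
    report["n_usable_instruments"] = n_usable

    seed_seq = np.random.SeedSequence(config.seed)
    boot_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(3)]

    estimates = []
    for method in METHOD_ORDER:
        if method not in config.methods:
            continue
        try:
            if method == "simple_median":
                estimates.append(_estimate_dict(
                    me.simple_median(usable, config.n_boot, boot_seeds[0])))
            elif method == "weighted_median":
                estimates.append(_estimate_dict(
                    me.weighted_median(usable, config.n_boot, boot_seeds[1])))
            elif method == "ivw":
                estimates.append(_estimate_dict(me.ivw(usable, config.ivw_model)))
            elif method == "mr_egger":
                egger = me.mr_egger(usable)
                estimates.append(_estimate_dict(egger.slope))
                report["egger_intercept"] = {
                    "intercept": egger.intercept,
                    "se": egger.intercept_se,
                    "pvalue": egger.intercept_pvalue,
                    "ci_low": egger.intercept_ci_low,
                    "ci_high": egger.intercept_ci_high,
                }
        except InputError as exc:
            report["skipped"].append({"method": method, "reason": str(exc)})
    report["estimates"] = estimates

    try:
        het = me.cochran_q(usable)
        report["heterogeneity"] = {"q": het.q_statistic, "df": het.df,
                                   "pvalue": het.pvalue}
    except InputError as exc:
        report["skipped"].append({"method": "cochran_q", "reason": str(exc)})

    try:
        loo = me.leave_one_out(usable)
        report["leave_one_out"] = [
            {"omitted": e.label, "beta": e.beta, "se": e.se, "pvalue": e.pvalue}
            for e in loo]
    except InputError as exc:
        report["skipped"].append({"method": "leave_one_out", "reason": str(exc)})

    if config.run_presso:
        try:
            presso = presso_outlier_test(
                usable, n_sim=config.presso_nsim, seed=boot_seeds[2],
                alpha=config.presso_alpha)
            report["presso"] = presso.to_dict()
        except InputError as exc:
            report["skipped"].append({"method": "mr_presso", "reason": str(exc)})

    return report


def run_bidirectional(forward_pairs: Sequence[tuple[SummaryStatSet, SummaryStatSet]],
                      reverse_pairs: Sequence[tuple[SummaryStatSet, SummaryStatSet]],
                      ld: LDTable | None = None,
                      forward_config: DirectionConfig | None = None,
                      reverse_config: DirectionConfig | None = None) -> dict:
    """Run forward and reverse grids; one failing pair never aborts the grid.

    The default reverse selection threshold is the suggestive 1e-5 (binary
    disease exposures rarely yield enough genome-wide-significant
    instruments); both directions otherwise share defaults.
    """
    forward_config = forward_config or DirectionConfig()
    if reverse_config is None:
        reverse_config = dataclasses.replace(
            forward_config,
            selection=dataclasses.replace(forward_config.selection,
                                          p_threshold=1e-5))
    out: dict = {"forward": [], "reverse": []}
    for direction, pairs, cfg in (("forward", forward_pairs, forward_config),
                                  ("reverse", reverse_pairs, reverse_config)):
        for exposure, outcome in pairs:
            try:
                block = run_mr_direction(exposure, outcome, ld, cfg)
            except Exception as exc:  # isolate pair-level failures
                block = {"exposure": exposure.trait_label,
                         "outcome": outcome.trait_label,
                         "error": f"{type(exc).__name__}: {exc}"}
            out[direction].append(block)
    return out


def direction_result_rows(report: dict) -> list[dict]:
    """Flatten a direction report into Table-1-shaped result rows."""
    rows = []
    het = report.get("heterogeneity") or {}
    egger_int = report.get("egger_intercept") or {}
    for est in report.get("estimates", []):
        rows.append({
            "exposure": report["exposure"],
            "outcome": report["outcome"],
            "n_ivs": est["n_snps"],
            "method": est["method"],
            "beta": est["beta"],
            "ci_low": est["ci_low"],
            "ci_high": est["ci_high"],
            "pvalue": est["pvalue"],
            "cochran_q": het.get("q"),
            "q_pvalue": het.get("pvalue"),
            "egger_intercept": egger_int.get("intercept"),
            "intercept_pvalue": egger_int.get("pvalue"),
        })
    return rows


def write_direction_outputs(report: dict, out_dir: str | Path) -> None:
    """Write results.tsv/.json plus the selection/harmonization/LOO/PRESSO
    side files for one direction report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = direction_result_rows(report)
    if rows:
        write_results_table(rows, out_dir / "results.tsv")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
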