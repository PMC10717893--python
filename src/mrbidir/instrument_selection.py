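"""Selection of independent genome-wide-significant instruments.

Three stages, mirroring standard two-sample MR practice: a strict p-value
screen at the genome-wide significance level, greedy LD clumping (keep the
most significant variant in each window, discard in-window variants
correlated with it), and exclusion of instruments that are themselves
strongly associated with the outcome.  Every drop is recorded with a reason
so the stage-by-stage instrument counts are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .gwas_io import InputError, LDTable, SummaryStatSet

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "filter_by_pvalue",
    "ld_clump",
    "exclude_outcome_associated",
]

GENOME_WIDE_P = 5e-8
#: suggestive threshold used when genome-wide-significant instruments are too
#: few, as in the reverse (OA-as-exposure) direction
SUGGESTIVE_P = 1e-5


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection stages.

    ``missing_ld`` controls in-window variant pairs with no r² entry:
    ``"correlated"`` (default) removes them — a conservative reading of
    distance-based pruning — while ``"independent"`` keeps them.
    """

    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_window_kb: float = 1000.0
    outcome_exclusion_p: float = GENOME_WIDE_P
    missing_ld: str = "correlated"

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if not (0.0 < self.outcome_exclusion_p < 1.0):
            raise ValueError("outcome_exclusion_p must be in (0, 1)")
        if self.missing_ld not in ("correlated", "independent"):
            raise ValueError("missing_ld must be 'correlated' or 'independent'")


@dataclass
class SelectionReport:
    """Per-stage instrument counts and per-SNP drop reasons."""

    n_input: int = 0
    n_post_p_filter: int | None = None
    n_post_clump: int | None = None
    n_post_outcome_exclusion: int | None = None
    drop_reasons: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "SelectionReport") -> "SelectionReport":
        merged = SelectionReport(
            n_input=self.n_input,
            n_post_p_filter=other.n_post_p_filter
            if other.n_post_p_filter is not None else self.n_post_p_filter,
            n_post_clump=other.n_post_clump
            if other.n_post_clump is not None else self.n_post_clump,
            n_post_outcome_exclusion=other.n_post_outcome_exclusion
            if other.n_post_outcome_exclusion is not None
            else self.n_post_outcome_exclusion,
        )
        merged.drop_reasons = {**self.drop_reasons, **other.drop_reasons}
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_post_p_filter": self.n_post_p_filter,
            "n_post_clump": self.n_post_clump,
            "n_post_outcome_exclusion": self.n_post_outcome_exclusion,
            "drop_reasons": dict(self.drop_reasons),
        }


def filter_by_pvalue(stats: SummaryStatSet, threshold: float) -> SummaryStatSet:
    """Keep records with ``pvalue < threshold`` (strict), preserving order.

    An empty survivor set is returned with a warning rather than raised;
    downstream stages that need instruments raise on it.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = [rec for rec in stats if rec.pvalue < threshold]
    if not kept:
        warnings.warn(
            f"no variants of {stats.trait_label!r} pass p < {threshold:g}",
            stacklevel=2)
    return stats.replace_records(kept)


def ld_clump(stats: SummaryStatSet, ld: LDTable,
             config: SelectionConfig) -> tuple[SummaryStatSet, SelectionReport]:
    """Greedy LD clumping.

    Rank variants by ascending p-value (ties broken by snp_id); repeatedly
    retain the best-ranked unclaimed variant (the index) and remove every
    unclaimed variant on the same chromosome within ``clump_window_kb``
    whose r² with the index exceeds ``clump_r2``.  An in-window pair with no
    r² entry is removed under the default ``missing_ld="correlated"``
    policy and kept under ``"independent"``.  The retained set is returned
    in genomic order.
    """
    for rec in stats:
        if rec.chrom is None or rec.pos is None:
            raise InputError(f"variant {rec.snp_id!r} lacks chrom/pos, cannot clump")

    report = SelectionReport(n_input=len(stats))
    window_bp = config.clump_window_kb * 1000.0

    ranked = sorted(stats, key=lambda r: (r.pvalue, r.snp_id))
    unclaimed = {rec.snp_id for rec in ranked}
    retained: list = []

    for index in ranked:
        if index.snp_id not in unclaimed:
            continue
        unclaimed.discard(index.snp_id)
        retained.append(index)
        for other in ranked:
            if other.snp_id not in unclaimed or other.chrom != index.chrom:
                continue
            if abs(other.pos - index.pos) > window_bp:
                continue
            r2 = ld.lookup(index.snp_id, other.snp_id)
            if r2 is None:
                correlated = config.missing_ld == "correlated"
            else:
                correlated = r2 > config.clump_r2
            if correlated:
                unclaimed.discard(other.snp_id)
                report.drop_reasons[other.snp_id] = f"clumped_with:{index.snp_id}"

    retained.sort(key=lambda r: (r.chrom, r.pos, r.snp_id))
    report.n_post_clump = len(retained)
    return stats.replace_records(retained), report


def exclude_outcome_associated(instruments: SummaryStatSet,
                               outcome: SummaryStatSet,
                               threshold: float
                               ) -> tuple[SummaryStatSet, SelectionReport]:
    """Remove instruments substantially associated with the outcome.

    An instrument whose outcome-GWAS p-value is below ``threshold`` is
    dropped (it plausibly acts on the outcome directly, violating the
    exclusion restriction).  Instruments absent from the outcome set are
    retained here; the harmonization stage is responsible for dropping
    them.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    report = SelectionReport(n_input=len(instruments))
    kept = []
    for rec in instruments:
        out = outcome.get(rec.snp_id)
        if out is not None and out.pvalue < threshold:
            report.drop_reasons[rec.snp_id] = "outcome_associated"
            continue
        kept.append(rec)
    report.n_post_outcome_exclusion = len(kept)
    return instruments.replace_records(kept), report
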