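"""Allele harmonization of exposure/outcome summary-statistic pairs.

Two-sample MR requires the exposure and outcome effect sizes of each
instrument to refer to the same effect allele on the same strand.  The
exposure orientation is the reference; the outcome side is flipped where
necessary.  Four cases arise for a shared variant:

* alleles identical → kept as-is;
* alleles swapped → outcome beta sign-flipped, eaf mirrored;
* alleles match only after strand complement (A↔T, C↔G) → complement, then
  one of the two cases above;
* palindromic variant (A/T or C/G pair) → allele labels cannot distinguish
  strands, so the effect-allele frequency decides: if both frequencies are
  known, both are away from 0.5 and they sit on the same side, the pair is
  already aligned; opposite sides means the outcome refers to the
  complementary allele and is flipped; a frequency near 0.5 (or missing)
  makes the variant unresolvable and it is dropped.

Instruments absent from the outcome set are dropped with reason
``missing_in_outcome``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .gwas_io import InputError, SummaryStatSet, VariantAssociation

__all__ = [
    "HarmonizationConfig",
    "HarmonizedInstrument",
    "HarmonizationReport",
    "harmonize_pair",
    "harmonize_all",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = ("kept_as_is", "flipped", "palindrome_aligned", "dropped")


@dataclass(frozen=True)
class HarmonizationConfig:
    """``palindrome_eaf_margin`` is the distance from 0.5 below which a
    palindromic variant's frequency is considered ambiguous; the default
    0.08 makes frequencies in [0.42, 0.58] ambiguous."""

    palindrome_eaf_margin: float = 0.08

    def __post_init__(self):
        if not (0.0 < self.palindrome_eaf_margin < 0.5):
            raise ValueError("palindrome_eaf_margin must be in (0, 0.5)")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome pair on a common effect-allele orientation."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action: str = "kept_as_is"
    drop_reason: str = ""
    pvalue_exp: float | None = None
    pvalue_out: float | None = None
    effect_allele: str | None = None
    other_allele: str | None = None

    @property
    def kept(self) -> bool:
        return self.action != "dropped"


@dataclass
class HarmonizationReport:
    action_counts: dict[str, int] = field(default_factory=dict)
    drop_reasons: dict[str, str] = field(default_factory=dict)

    def record(self, inst: HarmonizedInstrument) -> None:
        self.action_counts[inst.action] = self.action_counts.get(inst.action, 0) + 1
        if inst.action == "dropped":
            self.drop_reasons[inst.snp_id] = inst.drop_reason

    def to_dict(self) -> dict:
        return {"action_counts": dict(self.action_counts),
                "drop_reasons": dict(self.drop_reasons)}


def _complement_variant(v: VariantAssociation) -> VariantAssociation:
    return replace(v,
                   effect_allele=_COMPLEMENT[v.effect_allele],
                   other_allele=_COMPLEMENT[v.other_allele])


def _flip_variant(v: VariantAssociation) -> VariantAssociation:
    """Swap the allele labels so the former other-allele is the effect
    allele, negating beta and mirroring the frequency."""
    return replace(v,
                   effect_allele=v.other_allele,
                   other_allele=v.effect_allele,
                   beta=-v.beta,
                   eaf=None if v.eaf is None else 1.0 - v.eaf)


def _build(exp: VariantAssociation, out: VariantAssociation, action: str,
           drop_reason: str = "") -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=out.beta, se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=out.eaf,
        action=action, drop_reason=drop_reason,
        pvalue_exp=exp.pvalue, pvalue_out=out.pvalue,
        effect_allele=exp.effect_allele, other_allele=exp.other_allele)


def harmonize_pair(exp: VariantAssociation, out: VariantAssociation,
                   config: HarmonizationConfig | None = None
                   ) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair (same snp_id required)."""
    config = config or HarmonizationConfig()
    if exp.snp_id != out.snp_id:
        raise InputError(f"snp_id mismatch: {exp.snp_id!r} vs {out.snp_id!r}")

    if exp.is_palindromic():
        if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
            return _build(exp, out, "dropped", "allele_mismatch")
        return _resolve_palindrome(exp, out, config)

    # non-palindromic: direct match, swapped, or strand-complemented versions
    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return _build(exp, out, "kept_as_is")
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return _build(exp, _flip_variant(out), "flipped")
    comp = _complement_variant(out)
    if (comp.effect_allele, comp.other_allele) == (exp.effect_allele, exp.other_allele):
        return _build(exp, comp, "kept_as_is")
    if (comp.effect_allele, comp.other_allele) == (exp.other_allele, exp.effect_allele):
        return _build(exp, _flip_variant(comp), "flipped")
    return _build(exp, out, "dropped", "allele_mismatch")


def _resolve_palindrome(exp: VariantAssociation, out: VariantAssociation,
                        config: HarmonizationConfig) -> HarmonizedInstrument:
    margin = config.palindrome_eaf_margin
    if exp.eaf is None or out.eaf is None:
        return _build(exp, out, "dropped", "palindrome_ambiguous")
    if abs(exp.eaf - 0.5) < margin or abs(out.eaf - 0.5) < margin:
        return _build(exp, out, "dropped", "palindrome_ambiguous")
    same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
    if same_side:
        return _build(exp, out, "palindrome_aligned")
    # opposite sides: the outcome effect allele is the complement of the
    # exposure effect allele, so flip the outcome
    flipped = replace(out, beta=-out.beta, eaf=1.0 - out.eaf)
    return _build(exp, flipped, "palindrome_aligned")


def harmonize_all(instruments: SummaryStatSet, outcome: SummaryStatSet,
                  config: HarmonizationConfig | None = None
                  ) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Harmonize every instrument against the outcome set.

    Returns all instruments (kept and dropped, input order preserved) plus a
    report of action counts and drop reasons.  Raises if no instrument
    survives.
    """
    config = config or HarmonizationConfig()
    if len(instruments) == 0:
        raise InputError("no instruments to harmonize")
    report = HarmonizationReport()
    results: list[HarmonizedInstrument] = []
    for exp in instruments:
        out = outcome.get(exp.snp_id)
        if out is None:
            inst = _build(exp, exp, "dropped", "missing_in_outcome")
            # outcome fields are meaningless for a missing pair; zero them
            inst = replace(inst, beta_out=float("nan"), se_out=float("nan"),
                           eaf_out=None, pvalue_out=None)
        else:
            inst = harmonize_pair(exp, out, config)
        report.record(inst)
        results.append(inst)
    if not any(r.kept for r in results):
        raise InputError("no usable instruments after harmonization")
    return results, report
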