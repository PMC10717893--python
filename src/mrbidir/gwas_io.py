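"""Reading, validation and serialisation of GWAS summary statistics.

This module defines the variant-level data model shared by every pipeline
stage: a :class:`VariantAssociation` is one variant's summary-level
association with one trait (effect size, standard error, p-value and allele
metadata), a :class:`SummaryStatSet` is an ordered, snp-id-unique collection
of them for one trait, and an :class:`LDTable` holds pairwise r² values used
by LD clumping.

Input files are plain tab-delimited text with a header row; column names are
remapped through a user-supplied ``column_map`` so that arbitrary published
schemas can be read without editing the file.  Records that violate the data
model (non-positive SE, out-of-range p-value or frequency, identical
alleles, duplicate ids) are dropped and counted in a :class:`ParseReport`
with a machine-readable reason code; a p-value materially inconsistent with
its (beta, se) pair is flagged by default and only dropped under strict
parsing, because published summary files are frequently rounded.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "InputError",
    "VariantAssociation",
    "SummaryStatSet",
    "LDTable",
    "ParseReport",
    "read_summary_stats",
    "read_ld_table",
    "write_results_table",
    "RESULT_COLUMNS",
]

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: required logical fields in a summary-statistics column map
REQUIRED_FIELDS = ("snp", "effect_allele", "other_allele", "beta", "se", "pvalue")
#: optional logical fields
OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")

#: canonical column order of the Table-1-shaped results report
RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "n_ivs",
    "method",
    "beta",
    "ci_low",
    "ci_high",
    "pvalue",
    "cochran_q",
    "q_pvalue",
    "egger_intercept",
    "intercept_pvalue",
]

# relative tolerance for the p vs (beta, se) consistency cross-check
P_CONSISTENCY_RTOL = 0.10


class ConfigurationError(ValueError):
    """A column map or configuration value is unusable."""


class InputError(ValueError):
    """An input file is malformed or empty."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-level association with one trait.

    ``beta`` is in SD units for quantitative traits and log-odds for binary
    traits; ``pos`` is 1-based; ``chrom`` is a string so non-numeric
    chromosomes ("X") are representable.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    flags: tuple[str, ...] = ()

    def validation_errors(self) -> list[str]:
        """Reason codes for hard invariant violations (empty if valid)."""
        errors: list[str] = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            errors.append("invalid_allele")
        elif self.effect_allele == self.other_allele:
            errors.append("identical_alleles")
        if not (math.isfinite(self.se) and self.se > 0):
            errors.append("invalid_se")
        if not (math.isfinite(self.beta)):
            errors.append("invalid_beta")
        if not (math.isfinite(self.pvalue) and 0 < self.pvalue <= 1):
            errors.append("invalid_pvalue")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            errors.append("invalid_eaf")
        if self.n is not None and self.n < 1:
            errors.append("invalid_n")
        return errors

    def p_is_consistent(self, rtol: float = P_CONSISTENCY_RTOL) -> bool:
        """Check the reported p against the two-sided normal p of beta/se.

        Agreement within ``rtol`` relative difference (on the larger of the
        two p-values) counts as consistent.  Only meaningful when the record
        passes the hard invariants.
        """
        if self.se <= 0 or not math.isfinite(self.beta):
            return True
        z = abs(self.beta) / self.se
        expected = 2.0 * stats.norm.sf(z)
        denom = max(expected, self.pvalue)
        if denom == 0:
            return True
        return abs(self.pvalue - expected) <= rtol * denom

    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class ParseReport:
    """Bookkeeping of a summary-statistics parse."""

    n_input: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    flagged: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def drop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.dropped:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "drop_counts": self.drop_counts(),
            "dropped": [list(t) for t in self.dropped],
            "flagged": [list(t) for t in self.flagged],
        }


_CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]


class SummaryStatSet:
    """Ordered collection of :class:`VariantAssociation`, unique by snp_id."""

    def __init__(self, trait_label: str, trait_type: str,
                 records: Iterable[VariantAssociation]):
        if trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'quantitative' or 'binary', got {trait_type!r}")
        self.trait_label = trait_label
        self.trait_type = trait_type
        self._records: list[VariantAssociation] = list(records)
        seen: set[str] = set()
        for rec in self._records:
            if rec.snp_id in seen:
                raise InputError(f"duplicate snp_id {rec.snp_id!r} in {trait_label!r}")
            seen.add(rec.snp_id)
        self._index = {rec.snp_id: rec for rec in self._records}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index.get(snp_id)

    @property
    def records(self) -> list[VariantAssociation]:
        return list(self._records)

    @property
    def snp_ids(self) -> list[str]:
        return [rec.snp_id for rec in self._records]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatSet":
        """Subset preserving the order of this set (not of ``snp_ids``)."""
        wanted = set(snp_ids)
        return SummaryStatSet(
            self.trait_label, self.trait_type,
            [rec for rec in self._records if rec.snp_id in wanted])

    def replace_records(self, records: Iterable[VariantAssociation]) -> "SummaryStatSet":
        return SummaryStatSet(self.trait_label, self.trait_type, records)

    # -- tabular views -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self._records:
            rows.append({
                "snp_id": rec.snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": rec.eaf,
                "beta": rec.beta,
                "se": rec.se,
                "pvalue": rec.pvalue,
                "n": rec.n,
            })
        return pd.DataFrame(rows, columns=_CANONICAL_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


IDENTITY_COLUMN_MAP: dict[str, str] = {
    "snp": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}


def read_summary_stats(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       trait_label: str = "",
                       trait_type: str = "quantitative",
                       strict: bool = False) -> tuple[SummaryStatSet, ParseReport]:
    """Read and validate a tab-delimited summary-statistics file.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    column_map:
        Mapping of logical field name (``snp``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pvalue``; optionally ``chrom``,
        ``pos``, ``eaf``, ``n``) to the column name in the file.  Defaults to
        the canonical names this package itself writes.
    strict:
        If true, records whose p-value disagrees with the two-sided normal
        p of beta/se by more than 10% are dropped instead of flagged.

    Returns
    -------
    (SummaryStatSet, ParseReport)
        Validated records (allele strings upper-cased, order preserved) and
        the per-record drop/flag bookkeeping.
    """
    column_map = dict(column_map) if column_map else dict(IDENTITY_COLUMN_MAP)
    path = Path(path)

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty") from None
    if df.empty:
        raise InputError(f"{path}: file has a header but no records")

    for logical in REQUIRED_FIELDS:
        if logical not in column_map:
            raise ConfigurationError(f"column map is missing required field {logical!r}")
        if column_map[logical] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {column_map[logical]!r} "
                f"(field {logical!r}) not found; have {list(df.columns)}")

    def col(logical: str) -> pd.Series | None:
        name = column_map.get(logical)
        if name is None or name not in df.columns:
            return None
        return df[name]

    report = ParseReport(n_input=len(df))
    records: list[VariantAssociation] = []
    seen: set[str] = set()

    snp_s = col("snp")
    ea_s, oa_s = col("effect_allele"), col("other_allele")
    beta_s, se_s, p_s = col("beta"), col("se"), col("pvalue")
    chrom_s, pos_s, eaf_s, n_s = col("chrom"), col("pos"), col("eaf"), col("n")

    def _float(series, i) -> float | None:
        if series is None:
            return None
        raw = series.iloc[i]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", "NA", "NaN", "nan", "."):
            return None
        try:
            return float(raw)
        except ValueError:
            return math.nan

    for i in range(len(df)):
        snp_id = str(snp_s.iloc[i]).strip()
        beta = _float(beta_s, i)
        se = _float(se_s, i)
        pvalue = _float(p_s, i)
        if beta is None or se is None or pvalue is None:
            report.dropped.append((snp_id, "missing_required_value"))
            continue
        pos_v = _float(pos_s, i)
        n_v = _float(n_s, i)
        rec = VariantAssociation(
            snp_id=snp_id,
            effect_allele=str(ea_s.iloc[i]).strip().upper(),
            other_allele=str(oa_s.iloc[i]).strip().upper(),
            beta=beta,
            se=se,
            pvalue=pvalue,
            chrom=(str(chrom_s.iloc[i]).strip() if chrom_s is not None
                   and not pd.isna(chrom_s.iloc[i]) else None),
            pos=int(pos_v) if pos_v is not None and math.isfinite(pos_v) else None,
            eaf=_float(eaf_s, i),
            n=n_v,
        )
        errors = rec.validation_errors()
        if errors:
            report.dropped.append((snp_id, errors[0]))
            continue
        if rec.snp_id in seen:
            report.dropped.append((snp_id, "duplicate_snp_id"))
            continue
        if not rec.p_is_consistent():
            if strict:
                report.dropped.append((snp_id, "p_beta_se_inconsistent"))
                continue
            report.flagged.append((snp_id, "p_beta_se_inconsistent"))
            rec = dataclasses.replace(rec, flags=rec.flags + ("p_beta_se_inconsistent",))
        seen.add(rec.snp_id)
        records.append(rec)

    report.n_kept = len(records)
    return SummaryStatSet(trait_label, trait_type, records), report


class LDTable:
    """Symmetric pairwise r² lookup; r²(x, x) = 1 implicitly."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r² for ({a}, {b}) out of [0, 1]: {r2}")
        key = self._key(a, b)
        existing = self._entries.get(key)
        if existing is not None and existing != r2:
            raise InputError(
                f"conflicting r² for pair ({key[0]}, {key[1]}): {existing} vs {r2}")
        self._entries[key] = r2

    def lookup(self, a: str, b: str) -> float | None:
        """Known r² for the pair, 1.0 for a pair with itself, else None."""
        if a == b:
            return 1.0
        return self._entries.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_a\tsnp_b\tr2\n")
            for (a, b), r2 in sorted(self._entries.items()):
                fh.write(f"{a}\t{b}\t{r2!r}\n")


def read_ld_table(path: str | Path) -> LDTable:
    """Read a 3-column (snp_a, snp_b, r2) tab-delimited LD table.

    A first line whose third field is not numeric is treated as a header.
    Malformed numeric fields and out-of-range r² raise :class:`InputError`
    with the offending line number; a duplicate pair with a different r² is
    an error naming the pair.
    """
    table = LDTable()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, raw = (p.strip() for p in parts)
            try:
                r2 = float(raw)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise InputError(f"{path}:{lineno}: malformed r² value {raw!r}") from None
            if not (0.0 <= r2 <= 1.0):
                raise InputError(f"{path}:{lineno}: r² out of [0, 1]: {r2}")
            try:
                table.add(a, b, r2)
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
    return table


def _estimate_row(est, exposure: str, outcome: str,
                  heterogeneity=None, egger=None) -> dict:
    row = {
        "exposure": exposure,
        "outcome": outcome,
        "n_ivs": est.n_snps,
        "method": est.method,
        "beta": est.beta,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "cochran_q": None,
        "q_pvalue": None,
        "egger_intercept": None,
        "intercept_pvalue": None,
    }
    if heterogeneity is not None:
        row["cochran_q"] = heterogeneity.q_statistic
        row["q_pvalue"] = heterogeneity.pvalue
    if egger is not None:
        row["egger_intercept"] = egger.intercept
        row["intercept_pvalue"] = egger.intercept_pvalue
    return row


def write_results_table(rows: Sequence[Mapping], path: str | Path) -> pd.DataFrame:
    """Write the Table-1-shaped per-method results as TSV plus a JSON twin.

    ``rows`` are mappings with the :data:`RESULT_COLUMNS` keys (missing keys
    become NA).  The JSON twin is written next to the TSV with a ``.json``
    suffix.  Returns the DataFrame that was written.
    """
    if len(rows) == 0:
        raise InputError("no estimates to write")
    path = Path(path)
    df = pd.DataFrame([{c: row.get(c) for c in RESULT_COLUMNS} for row in rows],
                      columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")

    def _jsonable(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    payload = [{c: _jsonable(row.get(c)) for c in RESULT_COLUMNS} for row in rows]
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
    return df
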