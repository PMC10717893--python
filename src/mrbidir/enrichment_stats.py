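"""Gene-set over-representation statistics.

Upper-tail hypergeometric test of a hit list against each gene set (the
classical one-sided ORA used by GO-enrichment tools), with Benjamini–
Hochberg adjustment across sets.  SNP-to-gene mapping and the gene sets
themselves are caller-supplied inputs; gene sets are read from GMT-format
text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gwas_io import InputError

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_enrichment",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if len(self.members) == 0:
            raise InputError(f"gene set {self.set_id!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    overlap: int
    set_size: int
    hits_size: int
    universe_size: int
    pvalue: float
    adjusted_pvalue: float | None = None


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT text (set_id <tab> description <tab> genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(set_id=parts[0], name=parts[1],
                                members=frozenset(g for g in parts[2:] if g)))
    return sets


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def hypergeom_enrichment(hits: Iterable[str], sets: Sequence[GeneSet],
                         universe: Iterable[str]) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of ``hits`` in each set.

    Every hit must belong to the universe (an unknown hit gene is an
    error naming it); set members outside the universe are silently
    dropped before testing.  p = P(X >= overlap) for a hypergeometric
    draw of ``len(hits)`` genes from the universe with ``set_size``
    successes.  Results carry BH-adjusted p-values and are sorted by
    ascending raw p.
    """
    universe_set = set(universe)
    hit_set = set(hits)
    unknown = hit_set - universe_set
    if unknown:
        raise InputError(f"hit gene(s) absent from universe: {sorted(unknown)}")

    m = len(universe_set)
    n_hits = len(hit_set)
    results = []
    for gs in sets:
        members = gs.members & universe_set
        k = len(members & hit_set)
        set_size = len(members)
        # P(X >= k): sf is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, m, set_size, n_hits)) if set_size else 1.0
        results.append(EnrichmentResult(
            set_id=gs.set_id, name=gs.name, overlap=k, set_size=set_size,
            hits_size=n_hits, universe_size=m, pvalue=min(p, 1.0)))

    adjusted = benjamini_hochberg([r.pvalue for r in results])
    results = [EnrichmentResult(
        set_id=r.set_id, name=r.name, overlap=r.overlap, set_size=r.set_size,
        hits_size=r.hits_size, universe_size=r.universe_size,
        pvalue=r.pvalue, adjusted_pvalue=float(a))
        for r, a in zip(results, adjusted)]
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    return results
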