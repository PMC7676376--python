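"""Gene-set over-representation analysis with BH-FDR and pathway sharing.

Enrichment of an unranked query gene list against a GMT collection is
scored with the hypergeometric right tail (the classic over-representation
test), adjusted across the collection by Benjamini-Hochberg.  The shared
pathway matrix counts, for each gene pair, how many significant sets
contain both genes (the diagonal counts sets per single gene) — the basis
of the pathway-sharing heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError
from .relations import canonical_symbol

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "enrich",
    "results_table",
    "shared_pathway_matrix",
    "distinct_overlap_genes",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        canon = frozenset(canonical_symbol(str(g)) for g in self.members)
        object.__setattr__(self, "members", canon)
        if not self.members:
            raise FormatError(f"gene set {self.set_id!r} has no members")


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    set_size: int
    overlap_genes: list[str]  # sorted for deterministic output
    raw_p: float
    fdr_p: float = float("nan")
    significant: bool = False


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, `set_id TAB description TAB genes...`.

    Duplicate member symbols (after canonicalization) are collapsed.  A
    non-empty line with fewer than three fields is a format error.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 tab-separated fields")
            members = frozenset(
                canonical_symbol(g) for g in fields[2:] if g.strip()
            )
            sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def enrich(
    query: set[str],
    collection: Sequence[GeneSet],
    universe_size: int | None = None,
    q_threshold: float = 0.005,
) -> list[EnrichmentResult]:
    """Over-representation of a query list against every set of a collection.

    raw_p is the hypergeometric right tail P(overlap >= observed) for a
    universe of `universe_size` genes (default: the number of distinct genes
    in the collection).  BH adjustment runs across all sets; results with
    fdr_p < q_threshold are flagged significant.  Output is sorted by fdr_p
    ascending, ties broken by set_id.
    """
    if not query:
        raise ValueError("query gene set is empty")
    query = {canonical_symbol(g) for g in query}
    all_members: set[str] = set().union(*(s.members for s in collection)) if collection else set()
    if universe_size is None:
        universe_size = len(all_members)
    if universe_size < len(query | all_members):
        raise ValueError(
            f"universe_size {universe_size} smaller than |query ∪ members| = "
            f"{len(query | all_members)}"
        )
    results = []
    for s in collection:
        overlap = sorted(query & s.members)
        raw_p = float(
            stats.hypergeom.sf(
                len(overlap) - 1, universe_size, len(s.members), len(query)
            )
        )
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                name=s.name,
                set_size=len(s.members),
                overlap_genes=overlap,
                raw_p=min(1.0, raw_p),
            )
        )
    if results:
        _, fdr, _, _ = multipletests([r.raw_p for r in results], method="fdr_bh")
        for r, q in zip(results, fdr):
            r.fdr_p = float(q)
            r.significant = bool(q < q_threshold)
    return sorted(results, key=lambda r: (r.fdr_p, r.set_id))


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Report table: one row per set with semicolon-joined overlapping genes."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "set_id": r.set_id,
                "set_size": r.set_size,
                "overlap": len(r.overlap_genes),
                "overlap_genes": ";".join(r.overlap_genes),
                "raw_p": r.raw_p,
                "fdr_p": r.fdr_p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "name", "set_id", "set_size", "overlap",
            "overlap_genes", "raw_p", "fdr_p", "significant",
        ],
    )


def shared_pathway_matrix(
    results: Sequence[EnrichmentResult], genes: Sequence[str]
) -> pd.DataFrame:
    """Symmetric gene x gene count of significant sets shared by each pair.

    Cell (i, j), i != j, counts the sets whose overlap genes contain both
    gene i and gene j; the diagonal counts the sets containing the single
    gene.
    """
    genes = [canonical_symbol(g) for g in genes]
    idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(genes)), dtype=int)
    for r in results:
        present = sorted(
            {idx[c] for c in (canonical_symbol(g) for g in r.overlap_genes) if c in idx}
        )
        for i in present:
            for j in present:
                mat[i, j] += 1
    return pd.DataFrame(mat, index=genes, columns=genes)


def distinct_overlap_genes(results: Sequence[EnrichmentResult]) -> int:
    """Number of distinct genes appearing in the overlap of the given rows."""
    if not results:
        raise ValueError("need at least one enrichment result")
    union: set[str] = set()
    for r in results:
        union |= set(r.overlap_genes)
    return len(union)
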