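"""Literature disease-gene relation tables and gene-list overlap analysis.

A relation record is one literature-mined edge (disease, gene, polarity,
number of supporting references).  Reliability filtering keeps relations
with at least `min_refs` supporting references and, optionally, a specific
polarity (positive or negative regulation).  The overlap between two
diseases' gene sets is scored with a right-tail Fisher's exact test, i.e.
the hypergeometric tail probability of seeing at least the observed number
of shared genes when drawing from a common gene universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import FormatError

__all__ = [
    "POLARITIES",
    "RelationRecord",
    "OverlapResult",
    "canonical_symbol",
    "read_relation_table",
    "write_relation_table",
    "filter_relations",
    "gene_sets",
    "overlap_analysis",
]

POLARITIES = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class RelationRecord:
    """One literature edge: disease regulates/associates-with gene."""

    disease: str
    gene: str
    polarity: str  # "positive" | "negative" | "unknown"
    ref_count: int

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError("relation record with empty gene symbol")
        if self.polarity not in POLARITIES:
            raise FormatError(f"unknown polarity {self.polarity!r} for gene {self.gene!r}")
        if self.ref_count < 1:
            raise FormatError(f"ref_count must be >= 1 (gene {self.gene!r})")


@dataclass(frozen=True)
class OverlapResult:
    """Two-set overlap summary with Fisher right-tail significance."""

    n_a: int
    n_b: int
    n_overlap: int
    pct_of_a: float  # 100 * |A∩B| / |A|
    fisher_p: float  # right tail: P(overlap >= observed)
    odds_ratio: float
    universe_size: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def canonical_symbol(gene: str) -> str:
    """Canonical gene symbol: trimmed and upper-cased."""
    return gene.strip().upper()


def read_relation_table(path: str | Path) -> list[RelationRecord]:
    """Read a relation TSV (disease, gene, polarity, ref_count).

    Raises FormatError naming the row for an unknown polarity string.
    """
    df = pd.read_csv(path, sep="\t", dtype={"disease": str, "gene": str, "polarity": str})
    required = ["disease", "gene", "polarity", "ref_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing relation columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.polarity not in POLARITIES:
            raise FormatError(f"{path} line {i}: unknown polarity {row.polarity!r}")
        records.append(
            RelationRecord(
                disease=row.disease,
                gene=canonical_symbol(row.gene),
                polarity=row.polarity,
                ref_count=int(row.ref_count),
            )
        )
    return records


def write_relation_table(records: list[RelationRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def filter_relations(
    records: list[RelationRecord],
    min_refs: int = 3,
    require_polarity: bool = True,
) -> list[RelationRecord]:
    """Reliability filter: >= min_refs supporting references and, when
    require_polarity, a specific polarity (positive or negative).

    Input order is preserved.
    """
    if min_refs < 1:
        raise ValueError("min_refs must be >= 1")
    kept = []
    for r in records:
        if r.ref_count < min_refs:
            continue
        if require_polarity and r.polarity not in ("positive", "negative"):
            continue
        kept.append(r)
    return kept


def gene_sets(
    records_a: list[RelationRecord], records_b: list[RelationRecord]
) -> tuple[set[str], set[str], set[str], set[str]]:
    """Distinct canonical gene sets of two diseases, their intersection, and
    the A-minus-B difference (the disease-A-specific genes)."""
    set_a = {canonical_symbol(r.gene) for r in records_a}
    set_b = {canonical_symbol(r.gene) for r in records_b}
    return set_a, set_b, set_a & set_b, set_a - set_b


def overlap_analysis(
    set_a: set[str], set_b: set[str], universe_size: int
) -> OverlapResult:
    """Score the overlap of two gene sets against a hypergeometric null.

    fisher_p is the right-tail probability of at least the observed overlap
    when |A| genes and |B| genes are drawn from a universe of universe_size.
    The odds ratio comes from the 2x2 in/out-of-A by in/out-of-B table, with
    a 0.5 Haldane correction only when some cell is zero.
    """
    n_a, n_b = len(set_a), len(set_b)
    n_overlap = len(set_a & set_b)
    n_union = len(set_a | set_b)
    if universe_size < n_union:
        raise ValueError(
            f"universe_size {universe_size} smaller than |A ∪ B| = {n_union}"
        )
    fisher_p = float(stats.hypergeom.sf(n_overlap - 1, universe_size, n_a, n_b))
    n11 = n_overlap
    n12 = n_a - n_overlap
    n21 = n_b - n_overlap
    n22 = universe_size - n_union
    cells = [n11, n12, n21, n22]
    if 0 in cells:
        cells = [c + 0.5 for c in cells]
    odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    pct_of_a = 100.0 * n_overlap / n_a if n_a else 0.0
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_overlap,
        pct_of_a=pct_of_a,
        fisher_p=min(1.0, fisher_p),
        odds_ratio=float(odds_ratio),
        universe_size=universe_size,
    )
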