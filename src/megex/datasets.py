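"""Loaders for the small reference tables packaged with the library."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .enrichment import EnrichmentResult
from .expression import StudyRegistry

__all__ = ["thyroid_registry", "top_go_terms", "network_genes"]


def _data_path(name: str):
    return resources.files("megex.data").joinpath(name)


def thyroid_registry() -> StudyRegistry:
    """The 16-study thyroid-cancer case/control registry (GEO accessions,
    sample counts, study region and study age in years)."""
    with resources.as_file(_data_path("thyroid_registry.tsv")) as p:
        return StudyRegistry.from_tsv(p)


def top_go_terms() -> list[EnrichmentResult]:
    """The ten top-ranked GO terms enriched by the regulatory-network genes,
    as reported enrichment rows (set id, size, overlapping entities, FDR p)."""
    with resources.as_file(_data_path("top10_go_terms.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        EnrichmentResult(
            set_id=row.set_id,
            name=row.name_,
            set_size=int(row.set_size),
            overlap_genes=row.overlap_genes.split(";"),
            raw_p=float("nan"),
            fdr_p=float(row.fdr_p),
            significant=True,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def network_genes() -> list[str]:
    """The 14 genes of the obesity-to-thyroid-cancer regulatory network:
    the five expression hits plus their nine network partners."""
    text = _data_path("network_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
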