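"""Study expression matrices, phenotype tables and the study registry.

Files are plain tab-separated text: a series-matrix-style expression table
(`gene_id` first header field, one column per sample), a phenotype table
(sample_id, group in {case, control}) and a registry table with one row of
study-level metadata per study.  Inputs are assumed pre-normalized, on the
linear (anti-logged) scale unless flagged otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDataset",
    "StudyRegistry",
    "read_expression_matrix",
    "write_study",
    "select_datasets",
    "registry_totals",
]

REGISTRY_COLUMNS = [
    "study_id", "n_case", "n_control", "country", "study_age",
    "organism", "data_type", "design",
]

FLOAT_FMT = "%.10g"  # deterministic serialization for byte-identical reruns


@dataclass
class StudyDataset:
    """One study's expression data and metadata.

    matrix holds non-negative linear-scale values, genes as rows and samples
    as columns; groups is the per-sample case/control label aligned with the
    matrix columns.
    """

    study_id: str
    matrix: pd.DataFrame
    groups: list[str]
    country: str = ""
    study_age: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.groups) != self.matrix.shape[1]:
            raise FormatError(
                f"study {self.study_id!r}: {len(self.groups)} group labels for "
                f"{self.matrix.shape[1]} matrix columns"
            )
        bad = set(self.groups) - {"case", "control"}
        if bad:
            raise FormatError(f"study {self.study_id!r}: unknown group labels {bad}")
        if self.n_case < 1 or self.n_control < 1:
            raise FormatError(
                f"study {self.study_id!r}: needs at least one case and one control"
            )
        if not self.matrix.index.is_unique:
            raise FormatError(f"study {self.study_id!r}: duplicate gene ids")
        if (self.matrix.to_numpy() < 0).any():
            raise FormatError(f"study {self.study_id!r}: negative expression values")
        self.matrix.index.name = "gene_id"

    @property
    def n_case(self) -> int:
        return sum(g == "case" for g in self.groups)

    @property
    def n_control(self) -> int:
        return sum(g == "control" for g in self.groups)


@dataclass
class StudyRegistry:
    """Ordered table of study-level metadata (one row per study)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REGISTRY_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in REGISTRY_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"registry missing columns: {missing}")
        if not self.table["study_id"].is_unique:
            raise FormatError("registry study ids are not unique")
        if (self.table[["n_case", "n_control"]].to_numpy() < 0).any():
            raise FormatError("registry sample counts must be >= 0")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyRegistry":
        table = pd.read_csv(path, sep="\t", dtype={"study_id": str, "country": str})
        return cls(table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def row(self, study_id: str) -> pd.Series:
        hit = self.table[self.table["study_id"] == study_id]
        if hit.empty:
            raise KeyError(study_id)
        return hit.iloc[0]


def read_expression_matrix(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    study_id: str = "",
    country: str = "",
    study_age: float = float("nan"),
    collapse: str = "mean",
    is_log2: bool = False,
) -> StudyDataset:
    """Read an expression matrix and its phenotype table into a StudyDataset.

    Duplicate gene rows are collapsed (arithmetic mean on the linear scale by
    default; "max" keeps the per-sample maximum).  Gene rows containing a
    missing cell are dropped with a warning — a gene with missing data is
    treated as absent from the study.  Sample ids in the matrix header must
    match the phenotype table exactly.
    """
    if collapse not in ("mean", "max"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in mat.columns:
        coerced = pd.to_numeric(mat[col], errors="coerce")
        bad = coerced.isna() & mat[col].notna()
        if bad.any():
            gene = mat.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {matrix_path}"
            )
        mat[col] = coerced.astype(float)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if list(pheno.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(
            f"phenotype table {phenotype_path} must start with sample_id, group"
        )
    matrix_ids = list(mat.columns)
    pheno_ids = list(pheno["sample_id"])
    if set(matrix_ids) != set(pheno_ids) or len(pheno_ids) != len(set(pheno_ids)):
        only_m = sorted(set(matrix_ids) - set(pheno_ids))
        only_p = sorted(set(pheno_ids) - set(matrix_ids))
        raise FormatError(
            f"sample mismatch between {matrix_path} and {phenotype_path}: "
            f"matrix-only={only_m}, phenotype-only={only_p}"
        )
    group_of = dict(zip(pheno["sample_id"], pheno["group"]))
    groups = [group_of[s] for s in matrix_ids]

    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        dropped = sorted(set(mat.index[incomplete]))
        logger.warning(
            "%s: dropping %d gene(s) with missing cells: %s...",
            matrix_path, len(dropped), dropped[:5],
        )
        mat = mat.loc[~incomplete]
    if not mat.index.is_unique:
        grouped = mat.groupby(level=0, sort=False)
        mat = grouped.mean() if collapse == "mean" else grouped.max()
    if is_log2:
        mat = 2.0**mat
    return StudyDataset(
        study_id=study_id or Path(matrix_path).stem,
        matrix=mat,
        groups=groups,
        country=country,
        study_age=study_age,
    )


def write_study(
    study: StudyDataset, matrix_path: str | Path, phenotype_path: str | Path
) -> None:
    """Serialize a StudyDataset to matrix + phenotype TSVs.

    Floats are written with a fixed repr-faithful format so identical data
    always produces identical bytes.
    """
    mat = study.matrix.copy()
    mat.index.name = "gene_id"
    mat.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame(
        {"sample_id": list(study.matrix.columns), "group": study.groups}
    ).to_csv(phenotype_path, sep="\t", index=False)


def select_datasets(registry: StudyRegistry, min_n: int = 10) -> StudyRegistry:
    """Apply the four dataset-selection criteria.

    Keeps studies that are (1) Homo sapiens, (2) RNA expression data,
    (3) total sample size n_case + n_control >= min_n, and (4) a case vs
    healthy-control design.
    """
    t = registry.table
    keep = (
        (t["organism"] == "Homo sapiens")
        & (t["data_type"] == "RNA expression")
        & (t["n_case"] + t["n_control"] >= min_n)
        & (t["design"] == "case_control")
    )
    return StudyRegistry(t.loc[keep].copy())


def registry_totals(registry: StudyRegistry) -> tuple[int, int]:
    """(total cases, total controls) summed over the registry."""
    if len(registry) == 0:
        return 0, 0
    t = registry.table
    return int(t["n_case"].sum()), int(t["n_control"].sum())
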