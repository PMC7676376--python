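"""Synthetic multi-study expression collections with known ground truth.

The generative model mirrors the assumptions of the mega-analysis it feeds:
log2 expression of gene g in study s is Normal(baseline_g + delta_gs * case,
sigma2) and is emitted anti-logged (linear scale); the realized study effect
delta_gs = true_lfc_g + Normal(0, tau2) is the true log2 fold change plus an
additive between-study heterogeneity draw (the standard random-effects
generative model), optionally shifted by a per-country moderator effect.
Platform coverage is Bernoulli per gene per study, so a gene can be absent
from some studies' matrices, as happens across array platforms.

Defaults reproduce the reference 16-study thyroid-cancer collection layout:
its per-study case/control counts, countries and study ages.

Everything is driven by a single integer seed; per-study generators are
spawned from (seed, study_index), so a study can be regenerated in isolation
and a collection is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import thyroid_registry
from .errors import ConfigError
from .expression import REGISTRY_COLUMNS, StudyDataset, StudyRegistry, write_study
from .relations import RelationRecord

__all__ = [
    "MegaSimConfig",
    "SimTruth",
    "generate_study",
    "generate_collection",
    "generate_relation_tables",
    "generate_gmt_sets",
    "write_collection",
    "collection_registry",
]


def _table1_defaults() -> pd.DataFrame:
    return thyroid_registry().table


@dataclass
class MegaSimConfig:
    """Parameters of the synthetic multi-study collection.

    n_case / n_control may be single counts (every study identical) or
    per-study lists.  true_lfc and baseline_log2 may be scalars or per-gene
    arrays.  tau2 is the between-study variance of the true LFC (log2^2
    units); sigma2 the within-sample log2-expression noise variance.
    country_effects adds a per-country shift (log2 units) to every gene's
    realized study effect, for moderator-analysis simulations.
    """

    seed: int
    n_studies: int = 16
    n_case: int | Sequence[int] | None = None
    n_control: int | Sequence[int] | None = None
    n_genes: int = 2000
    true_lfc: float | Sequence[float] = 0.0
    tau2: float = 0.0
    sigma2: float = 0.5
    baseline_log2: float | Sequence[float] = 8.0
    coverage_prob: float = 1.0
    countries: Sequence[str] | None = None
    study_ages: Sequence[float] | None = None
    country_effects: dict[str, float] = dc_field(default_factory=dict)
    # convenience: plant the first n_planted genes at planted_lfc (applied
    # only when true_lfc is given as a scalar)
    n_planted: int = 0
    planted_lfc: float = -1.8

    def __post_init__(self) -> None:
        if self.seed is None or int(self.seed) != self.seed:
            raise ConfigError("seed: an integer seed is mandatory")
        self.seed = int(self.seed)
        if self.n_studies < 2:
            raise ConfigError("n_studies: must be >= 2")
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        if self.tau2 < 0:
            raise ConfigError("tau2: must be >= 0")
        if self.sigma2 <= 0:
            raise ConfigError("sigma2: must be > 0")
        if not 0 < self.coverage_prob <= 1:
            raise ConfigError("coverage_prob: must be in (0, 1]")
        defaults = _table1_defaults() if (
            self.n_case is None or self.n_control is None
            or self.countries is None or self.study_ages is None
        ) else None
        if defaults is not None and self.n_studies > len(defaults) and (
            self.n_case is None or self.n_control is None
        ):
            raise ConfigError(
                "n_case/n_control: explicit counts required when n_studies "
                f"exceeds the {len(defaults)} reference studies"
            )
        if self.n_case is None:
            self.n_case = list(defaults["n_case"][: self.n_studies])
        if self.n_control is None:
            self.n_control = list(defaults["n_control"][: self.n_studies])
        self.n_case = self._per_study("n_case", self.n_case)
        self.n_control = self._per_study("n_control", self.n_control)
        if min(self.n_case) < 1 or min(self.n_control) < 1:
            raise ConfigError("n_case/n_control: all counts must be >= 1")
        if self.countries is None:
            if defaults is not None and self.n_studies <= len(defaults):
                self.countries = list(defaults["country"][: self.n_studies])
            else:  # round-robin over the reference label list
                labels = list(dict.fromkeys(_table1_defaults()["country"]))
                self.countries = [
                    labels[i % len(labels)] for i in range(self.n_studies)
                ]
        if len(self.countries) != self.n_studies:
            raise ConfigError("countries: need one label per study")
        if self.study_ages is None:
            if defaults is not None and self.n_studies <= len(defaults):
                self.study_ages = [float(a) for a in defaults["study_age"][: self.n_studies]]
            else:
                self.study_ages = [float(5 + i % 10) for i in range(self.n_studies)]
        if len(self.study_ages) != self.n_studies:
            raise ConfigError("study_ages: need one value per study")
        if self.n_planted < 0 or self.n_planted > self.n_genes:
            raise ConfigError("n_planted: must be in [0, n_genes]")
        scalar_lfc = np.isscalar(self.true_lfc)
        self.true_lfc = self._per_gene("true_lfc", self.true_lfc)
        if self.n_planted:
            if not scalar_lfc:
                raise ConfigError("n_planted: needs a scalar true_lfc baseline")
            self.true_lfc[: self.n_planted] = float(self.planted_lfc)
        self.baseline_log2 = self._per_gene("baseline_log2", self.baseline_log2)

    def _per_study(self, name: str, value) -> list[int]:
        if np.isscalar(value):
            return [int(value)] * self.n_studies
        value = [int(v) for v in value]
        if len(value) != self.n_studies:
            raise ConfigError(f"{name}: need one count per study, got {len(value)}")
        return value

    def _per_gene(self, name: str, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_genes, float(arr))
        if arr.shape != (self.n_genes,):
            raise ConfigError(f"{name}: need a scalar or one value per gene")
        if not np.all(np.isfinite(arr)):
            raise ConfigError(f"{name}: values must be finite")
        return arr

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def study_ids(self) -> list[str]:
        return [f"SIM{i + 1:02d}" for i in range(self.n_studies)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MegaSimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "MegaSimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("seed: an integer seed is mandatory")
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth of one generated collection.

    study_effects holds the realized per-study effect (true LFC plus the
    heterogeneity draw plus any country shift); membership flags which genes
    were emitted in which study's matrix.
    """

    true_lfc: pd.Series  # per gene
    study_effects: pd.DataFrame  # genes x studies
    membership: pd.DataFrame  # genes x studies, bool

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {
                "true_lfc": self.true_lfc,
                "effect": self.study_effects,
                "member": self.membership.astype(int),
            },
            axis=1,
        )
        out.columns = [
            "true_lfc" if a == "true_lfc" else f"{a}:{b}" for a, b in out.columns
        ]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _study_parts(config: MegaSimConfig, study_index: int):
    """One study's dataset plus its truth slices (realized effects, membership)."""
    if not 0 <= study_index < config.n_studies:
        raise ConfigError(
            f"study_index: {study_index} out of range for {config.n_studies} studies"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(study_index)])
    )
    country = config.countries[study_index]
    delta = config.true_lfc + rng.normal(0.0, np.sqrt(config.tau2), config.n_genes)
    delta = delta + config.country_effects.get(country, 0.0)
    member = rng.random(config.n_genes) < config.coverage_prob
    n_case = config.n_case[study_index]
    n_ctrl = config.n_control[study_index]
    n = n_case + n_ctrl
    is_case = np.zeros(n)
    is_case[:n_case] = 1.0
    log2expr = (
        config.baseline_log2[:, None]
        + delta[:, None] * is_case[None, :]
        + rng.normal(0.0, np.sqrt(config.sigma2), (config.n_genes, n))
    )
    sid = config.study_ids[study_index]
    samples = [f"{sid}_case_{j + 1:03d}" for j in range(n_case)] + [
        f"{sid}_ctrl_{j + 1:03d}" for j in range(n_ctrl)
    ]
    matrix = pd.DataFrame(
        np.exp2(log2expr[member]),
        index=pd.Index(np.array(config.genes)[member], name="gene_id"),
        columns=samples,
    )
    study = StudyDataset(
        study_id=sid,
        matrix=matrix,
        groups=["case"] * n_case + ["control"] * n_ctrl,
        country=country,
        study_age=config.study_ages[study_index],
    )
    return study, delta, member


def generate_study(config: MegaSimConfig, study_index: int) -> StudyDataset:
    """Generate one study of the collection (reproducible in isolation)."""
    return _study_parts(config, study_index)[0]


def generate_collection(
    config: MegaSimConfig,
) -> tuple[list[StudyDataset], SimTruth]:
    """Generate the full collection and its ground truth."""
    studies, deltas, members = [], [], []
    for i in range(config.n_studies):
        study, delta, member = _study_parts(config, i)
        studies.append(study)
        deltas.append(delta)
        members.append(member)
    genes = pd.Index(config.genes, name="gene_id")
    truth = SimTruth(
        true_lfc=pd.Series(config.true_lfc, index=genes, name="true_lfc"),
        study_effects=pd.DataFrame(
            np.column_stack(deltas), index=genes, columns=config.study_ids
        ),
        membership=pd.DataFrame(
            np.column_stack(members), index=genes, columns=config.study_ids
        ),
    )
    return studies, truth


def collection_registry(config: MegaSimConfig) -> StudyRegistry:
    """Registry rows describing the simulated studies."""
    table = pd.DataFrame(
        {
            "study_id": config.study_ids,
            "n_case": config.n_case,
            "n_control": config.n_control,
            "country": list(config.countries),
            "study_age": list(config.study_ages),
            "organism": "Homo sapiens",
            "data_type": "RNA expression",
            "design": "case_control",
        },
        columns=REGISTRY_COLUMNS,
    )
    return StudyRegistry(table)


def write_collection(
    studies: Sequence[StudyDataset],
    truth: SimTruth,
    registry: StudyRegistry,
    outdir: str | Path,
) -> None:
    """Serialize a collection (matrices, phenotypes, registry, truth) as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for study in studies:
        write_study(
            study,
            outdir / f"{study.study_id}_matrix.tsv",
            outdir / f"{study.study_id}_phenotype.tsv",
        )
    registry.to_tsv(outdir / "registry.tsv")
    truth.to_tsv(outdir / "truth.tsv")


def generate_relation_tables(
    n_universe: int,
    n_disease_a: int,
    n_disease_b: int,
    n_overlap: int,
    seed: int,
    fail_fraction: float = 0.2,
    disease_a: str = "obesity",
    disease_b: str = "thyroid carcinoma",
) -> tuple[list[RelationRecord], list[RelationRecord]]:
    """Two synthetic disease-gene relation tables with a known overlap.

    After reliability filtering (>= 3 references, specific polarity) the two
    tables' gene sets have exactly n_disease_a and n_disease_b genes sharing
    exactly n_overlap; an extra `fail_fraction` of rows per table carries
    too few references or an unknown polarity and is removed by the filter.
    """
    if n_overlap > min(n_disease_a, n_disease_b):
        raise ValueError("n_overlap exceeds a disease set size")
    if n_disease_a + n_disease_b - n_overlap > n_universe:
        raise ValueError("universe too small for the requested set sizes")
    if not 0 <= fail_fraction < 1:
        raise ValueError("fail_fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 977]))
    universe = np.array([f"G{i + 1:06d}" for i in range(n_universe)])
    n_union = n_disease_a + n_disease_b - n_overlap
    chosen = rng.choice(universe, size=n_union, replace=False)
    shared = chosen[:n_overlap]
    a_only = chosen[n_overlap:n_disease_a]
    b_only = chosen[n_disease_a:]

    def passing_rows(disease: str, genes: np.ndarray) -> list[RelationRecord]:
        pols = rng.choice(["positive", "negative"], size=genes.size)
        refs = rng.integers(3, 20, size=genes.size)
        return [
            RelationRecord(disease, g, p, int(r))
            for g, p, r in zip(genes, pols, refs)
        ]

    def failing_rows(disease: str, n_pass: int) -> list[RelationRecord]:
        n_fail = int(round(fail_fraction / (1 - fail_fraction) * n_pass))
        genes = rng.choice(universe, size=n_fail, replace=True)
        rows = []
        for g in genes:
            if rng.random() < 0.5:  # too few supporting references
                rows.append(
                    RelationRecord(
                        disease, g,
                        str(rng.choice(["positive", "negative"])),
                        int(rng.integers(1, 3)),
                    )
                )
            else:  # no specific polarity
                rows.append(
                    RelationRecord(disease, g, "unknown", int(rng.integers(3, 20)))
                )
        return rows

    table_a = passing_rows(disease_a, np.concatenate([shared, a_only]))
    table_b = passing_rows(disease_b, np.concatenate([shared, b_only]))
    table_a += failing_rows(disease_a, len(table_a))
    table_b += failing_rows(disease_b, len(table_b))
    return table_a, table_b


def generate_gmt_sets(
    genes: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int,
    planted: Sequence[str] = (),
):
    """Random gene sets over a gene universe, for exercising enrichment.

    The first set additionally contains every `planted` gene, giving a known
    enriched set when the planted genes are the query.
    """
    from .enrichment import GeneSet

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4211]))
    genes = np.asarray(genes)
    sets = []
    for i in range(n_sets):
        members = set(rng.choice(genes, size=min(set_size, genes.size), replace=False))
        if i == 0:
            members |= set(planted)
        sets.append(
            GeneSet(
                set_id=f"SET{i + 1:04d}",
                name=f"synthetic set {i + 1}",
                members=frozenset(members),
            )
        )
    return sets
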