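"""Domain containers, TSV/GMT readers and writers, dataset eligibility
filtering, and multiple-testing adjustment shared by every pipeline stage.

The unit of integration is a *dataset*: one case-versus-control differential
expression comparison summarized per gene as a log2 fold change, its standard
error, a two-sided P value, and a normalized mean expression level.  A study
corpus is a :class:`StudyCollection` — aligned dataset summaries plus their
metadata (disorder label, neurological phenotypes, sample-type and
model-system class, case/control counts).

All tables are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments; empty fields and ``NA`` denote missing values.  Gene
identifiers are opaque strings (no ID-mapping layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PHENOTYPES = frozenset(
    {
        "intellectual disability",
        "hypotonia",
        "global developmental delay",
        "microcephaly",
        "gait ataxia",
        "autism/autistic behavior",
        "seizure",
        "scoliosis",
    }
)

SAMPLE_TYPES = frozenset({"immune", "neural", "other"})
MODEL_SYSTEMS = frozenset({"in vitro", "non-in vitro"})

SUMMARY_COLUMNS = ("gene_id", "log2fc", "se", "p", "mean_expr")

_NA_VALUES = ("", "NA")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class DuplicateIDError(ValueError):
    """Duplicate identifiers where uniqueness is required."""


@dataclass(frozen=True)
class GeneStats:
    """Per-gene differential-expression summary from one dataset."""

    gene_id: str
    log2fc: float
    se: float
    p: float
    mean_expr: float

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"P value out of [0,1] for {self.gene_id}: {self.p}")
        if np.isfinite(self.p) and np.isfinite(self.se) and self.se <= 0:
            raise ValueError(f"non-positive SE for {self.gene_id}: {self.se}")
        if np.isfinite(self.mean_expr) and self.mean_expr < 0:
            raise ValueError(f"negative mean expression for {self.gene_id}")


class DatasetSummary:
    """One dataset's per-gene statistics, backed by a DataFrame.

    The table is indexed by ``gene_id`` with float columns ``log2fc``, ``se``,
    ``p``, ``mean_expr``.  Missing statistics are NaN — genes with missing
    entries stay in the table so downstream denominators can count what was
    actually measured.
    """

    def __init__(self, dataset_id: str, table: pd.DataFrame):
        if table.index.has_duplicates:
            dups = sorted(table.index[table.index.duplicated()].unique())
            raise DuplicateIDError(
                f"duplicate gene_id in dataset {dataset_id}: {', '.join(map(str, dups))}"
            )
        if len(table) < 2:
            raise ValueError(f"dataset {dataset_id} has fewer than 2 genes")
        missing = [c for c in ("log2fc", "se", "p", "mean_expr") if c not in table.columns]
        if missing:
            raise FormatError(f"dataset {dataset_id} missing columns: {missing}")
        p = table["p"].to_numpy(float)
        bad = np.isfinite(p) & ((p < 0) | (p > 1))
        if bad.any():
            raise ValueError(
                f"dataset {dataset_id}: P values outside [0,1] for "
                f"{list(table.index[bad][:5])}"
            )
        self.dataset_id = str(dataset_id)
        self.table = table[["log2fc", "se", "p", "mean_expr"]].astype(float)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def __getitem__(self, gene_id: str) -> GeneStats:
        row = self.table.loc[gene_id]
        return GeneStats(gene_id, row["log2fc"], row["se"], row["p"], row["mean_expr"])

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __repr__(self) -> str:  # pragma: no cover
        return f"DatasetSummary({self.dataset_id!r}, n_genes={len(self)})"


@dataclass
class Stratum:
    label: str
    n_cases: int
    n_controls: int


@dataclass
class DatasetMetadata:
    """Curation metadata for one dataset."""

    dataset_id: str
    disorder: str
    phenotypes: frozenset = frozenset()
    sample_type: str = "other"
    model_system: str = "non-in vitro"
    n_cases: int = 0
    n_controls: int = 0
    has_case_control_design: bool = True
    strata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotypes = frozenset(self.phenotypes)
        unknown = self.phenotypes - PHENOTYPES
        if unknown:
            raise ValueError(
                f"unknown phenotype labels for {self.dataset_id}: {sorted(unknown)}"
            )
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.model_system not in MODEL_SYSTEMS:
            raise ValueError(f"unknown model_system {self.model_system!r}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("negative case/control counts")


@dataclass
class StudyCollection:
    """Aligned dataset summaries + metadata + the union gene universe."""

    datasets: list
    metadata: list
    gene_universe: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ds_ids = [d.dataset_id for d in self.datasets]
        md_ids = [m.dataset_id for m in self.metadata]
        if ds_ids != md_ids:
            raise ValueError(
                "datasets and metadata must align one-to-one by dataset_id"
            )
        if len(set(ds_ids)) != len(ds_ids):
            raise DuplicateIDError("duplicate dataset_ids in collection")
        if not self.gene_universe:
            universe: set = set()
            for d in self.datasets:
                universe.update(d.gene_ids)
            self.gene_universe = sorted(universe)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def dataset_ids(self) -> list:
        return [d.dataset_id for d in self.datasets]

    def metadata_by_id(self) -> Mapping[str, DatasetMetadata]:
        return {m.dataset_id: m for m in self.metadata}

    def median_expression(self) -> pd.Series:
        """Per-gene median of mean expression across datasets measuring it."""
        frames = [d.table["mean_expr"] for d in self.datasets]
        wide = pd.concat(frames, axis=1, keys=self.dataset_ids)
        return wide.median(axis=1).reindex(self.gene_universe)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological-process terms)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_id} is empty")
            self.sets[set_id] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> frozenset:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_summary_table(path, dataset_id: str) -> DatasetSummary:
    """Read one per-dataset differential-expression summary TSV.

    Requires header columns gene_id, log2fc, se, p, mean_expr.  Rows with
    missing p or se are kept as missing (NaN), never silently dropped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=list(_NA_VALUES),
        keep_default_na=False,
        dtype={"gene_id": str},
    )
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df.set_index("gene_id")
    n_missing = int(df[["p", "se"]].isna().any(axis=1).sum())
    logger.info(
        "read %d rows (%d with missing p/se) for dataset %s from %s",
        len(df), n_missing, dataset_id, path,
    )
    return DatasetSummary(dataset_id, df)


def write_summary_table(dataset: DatasetSummary, path) -> None:
    """Write a summary TSV readable by :func:`read_summary_table`.

    Floats are written at 12 significant digits (the round-trip contract).
    """
    df = dataset.table.reset_index()
    if "index" in df.columns:
        df = df.rename(columns={"index": "gene_id"})
    df.columns = list(SUMMARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (set_id TAB description TAB gene...)."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (set_id, description, genes), got {len(fields)}"
                )
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene list")
            if set_id in sets:
                raise DuplicateIDError(f"{path}: duplicate set_id {set_id!r}")
            sets[set_id] = frozenset(genes)
            descriptions[set_id] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, genes in collection.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *sorted(genes)]) + "\n")


def read_gene_list(path) -> list:
    """One gene_id per line; '#' comments and blank lines ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


def _parse_strata(text: str) -> list:
    """Decode 'label:cases:controls;...' stratification strings."""
    strata = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise FormatError(f"bad stratum encoding: {chunk!r}")
        strata.append(Stratum(parts[0], int(parts[1]), int(parts[2])))
    return strata


def read_metadata_table(path) -> list:
    """Read dataset metadata TSV.

    Columns: dataset_id, disorder, phenotypes (semicolon-separated),
    sample_type, model_system, n_cases, n_controls, design, strata (optional).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=list(_NA_VALUES),
        keep_default_na=False, dtype=str,
    )
    required = [
        "dataset_id", "disorder", "phenotypes", "sample_type",
        "model_system", "n_cases", "n_controls", "design",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        phen = row["phenotypes"]
        phenotypes = frozenset(
            p.strip() for p in str(phen).split(";") if p.strip()
        ) if isinstance(phen, str) and phen else frozenset()
        strata_txt = row.get("strata")
        strata = _parse_strata(strata_txt) if isinstance(strata_txt, str) and strata_txt else []
        out.append(
            DatasetMetadata(
                dataset_id=row["dataset_id"],
                disorder=row["disorder"],
                phenotypes=phenotypes,
                sample_type=row["sample_type"],
                model_system=row["model_system"],
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
                has_case_control_design=str(row["design"]).strip().lower()
                in {"case-control", "true", "1", "yes"},
                strata=strata,
            )
        )
    ids = [m.dataset_id for m in out]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIDError(f"{path}: duplicate dataset_id: {', '.join(dups)}")
    return out


def write_metadata_table(metadata: Sequence[DatasetMetadata], path) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "dataset_id": m.dataset_id,
                "disorder": m.disorder,
                "phenotypes": ";".join(sorted(m.phenotypes)),
                "sample_type": m.sample_type,
                "model_system": m.model_system,
                "n_cases": m.n_cases,
                "n_controls": m.n_controls,
                "design": "case-control" if m.has_case_control_design else "none",
                "strata": ";".join(
                    f"{s.label}:{s.n_cases}:{s.n_controls}" for s in m.strata
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_collection(fixture_dir) -> StudyCollection:
    """Load a fixture directory: metadata.tsv + one <dataset_id>.tsv each."""
    fixture_dir = Path(fixture_dir)
    metadata = read_metadata_table(fixture_dir / "metadata.tsv")
    datasets = [
        read_summary_table(fixture_dir / f"{m.dataset_id}.tsv", m.dataset_id)
        for m in metadata
    ]
    return StudyCollection(datasets, metadata)


# ---------------------------------------------------------------------------
# eligibility filtering


@dataclass(frozen=True)
class AnalysisUnit:
    """One statistical comparison: a whole dataset or a single stratum."""

    dataset_id: str
    stratum: str | None = None

    @property
    def unit_id(self) -> str:
        return self.dataset_id if self.stratum is None else f"{self.dataset_id}::{self.stratum}"


def filter_eligible_datasets(
    metadata: Sequence[DatasetMetadata],
    min_cases: int = 3,
    min_controls: int = 3,
):
    """Apply the corpus curation rules and resolve stratification.

    A dataset is excluded when it lacks a case-control design or has fewer
    than ``min_cases`` cases / ``min_controls`` controls.  A retained dataset
    with strata becomes one analysis unit per stratum only when *every*
    stratum has at least ``min_cases`` cases and ``min_controls`` controls;
    otherwise it is kept as a single unstratified unit.

    Returns (units, report): units is a list of :class:`AnalysisUnit`;
    report maps each excluded dataset_id to its first failing rule.
    """
    if not metadata:
        raise ValueError("metadata is empty")
    units: list = []
    report: dict = {}
    for m in metadata:
        if not m.has_case_control_design:
            report[m.dataset_id] = "no case-control design"
            continue
        if m.n_cases < min_cases:
            report[m.dataset_id] = f"fewer than {min_cases} cases"
            continue
        if m.n_controls < min_controls:
            report[m.dataset_id] = f"fewer than {min_controls} controls"
            continue
        if m.strata and all(
            s.n_cases >= min_cases and s.n_controls >= min_controls for s in m.strata
        ):
            units.extend(AnalysisUnit(m.dataset_id, s.label) for s in m.strata)
        else:
            units.append(AnalysisUnit(m.dataset_id))
    return units, report


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues: Iterable[float], family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Missing values (NaN) propagate as NaN and do not count toward the number
    of tests m.  Input order is preserved.  ``family`` is an optional label
    naming the adjustment family; it is carried by callers into output
    tables, not used here.
    """
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                   dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("P values must lie in [0,1]")
    out = np.full_like(p, np.nan)
    if finite.sum() > 0:
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out
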