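"""Synthetic study corpora with the statistical structure the pipeline
assumes, plus planted effects for parameter-recovery testing.

The generator emulates the *output* of a per-dataset Wald differential
expression analysis (one log2 fold change, standard error and two-sided P
value per gene), not the count data behind it: every downstream stage
consumes only these summary statistics, so a Normal sampling model for the
observed effect is the minimal sufficient emulation.

Model, per dataset d and gene g:

* a gene is globally "active" with probability ``frac_true_effects`` and
  then carries a base effect b_g ~ Normal(0, effect_sd**2) shared across all
  datasets;
* designated gene groups get extra per-dataset activation — imprinted genes
  have their per-dataset non-null probability raised to
  ``min(1, frac_true_effects * imprinted_boost)``, phenotype-linked sets
  likewise (``phenotype_boost``) but only in datasets whose disorder carries
  the phenotype — with an effect drawn afresh per dataset;
* sample-type gene sets carry a block-level effect shared by all datasets of
  that sample type (this is what makes datasets cluster by tissue);
* ``disorder_gene_effects`` adds a fixed log2FC to named genes in every
  dataset of a disorder;
* any gene with a nonzero systematic effect also receives a between-dataset
  deviation Normal(0, tau**2); exactly-null genes stay exactly null, so a
  null configuration yields uniform P values;
* observed log2fc = delta + Normal(0, se**2) with se drawn from a scaled
  square-root-inverse-chi-square (shrinking with total sample size), and
  p = two-sided Normal tail of log2fc/se.

One global seed; per-dataset substreams use fixed spawn keys, so adding
datasets never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    DatasetMetadata,
    DatasetSummary,
    StudyCollection,
    write_metadata_table,
    write_summary_table,
)
import pandas as pd

DEFAULT_PHENOTYPE_MAP: dict = {
    # representative phenotype annotations for the four most common disorders
    "RTT": frozenset(
        {"intellectual disability", "seizure", "microcephaly", "gait ataxia",
         "hypotonia", "global developmental delay", "scoliosis"}
    ),
    "DMD": frozenset({"intellectual disability", "scoliosis", "global developmental delay"}),
    "FXS": frozenset({"intellectual disability", "autism/autistic behavior",
                      "seizure", "hypotonia"}),
    "DS": frozenset({"intellectual disability", "hypotonia",
                     "global developmental delay", "seizure"}),
    "other": frozenset(),
}


@dataclass(frozen=True)
class SEShape:
    """Scaled square-root-inverse-chi-square SE distribution.

    se = scale / sqrt(n_cases + n_controls) * sqrt(df / X), X ~ chi2(df).
    """

    df: float = 8.0
    scale: float = 2.0


@dataclass
class SimulationConfig:
    """Conditions of a synthetic corpus.

    Defaults mirror the integrated corpus the pipeline targets: 151 datasets
    of ~20k genes, mostly 3-4 cases and controls each, with the four most
    common disorders making up just under half the corpus.
    """

    n_genes: int = 20_000
    n_datasets: int = 151
    n_cases: int | Sequence[int] = 4
    n_controls: int | Sequence[int] = 4
    disorder_labels: Sequence[str] | None = None
    phenotype_map: Mapping[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MAP)
    )
    sample_types: Sequence[str] | None = None
    model_systems: Sequence[str] | None = None
    frac_true_effects: float = 0.1
    effect_sd: float = 0.5
    tau: float = 0.15
    se_shape: SEShape = field(default_factory=SEShape)
    imprinted_ids: Sequence[str] = ()
    imprinted_boost: float = 1.0
    phenotype_gene_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    phenotype_boost: float = 1.0
    phenotype_shift: float = 0.0
    sample_type_gene_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    disorder_gene_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_expr: tuple = (4.0, 2.0)  # lognormal (meanlog, sdlog) of mean_expr
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_true_effects <= 1.0:
            raise ValueError("frac_true_effects must lie in [0,1]")
        if self.imprinted_boost < 1 or self.phenotype_boost < 1:
            raise ValueError("boost multipliers must be >= 1")
        if min(self.effect_sd, self.tau, self.baseline_expr[1]) < 0:
            raise ValueError("effect_sd, tau and baseline scale must be >= 0")
        if self.n_genes < 2 or self.n_datasets < 1:
            raise ValueError("need n_genes >= 2 and n_datasets >= 1")


def default_disorder_labels(n_datasets: int) -> list:
    """RTT/DMD/FXS/DS for ~43% of datasets, the rest pooled as 'other'."""
    n_major = int(round(0.43 * n_datasets))
    majors = ["RTT", "DMD", "FXS", "DS"]
    labels = [majors[i % 4] for i in range(n_major)]
    labels += ["other"] * (n_datasets - n_major)
    return labels


def _per_dataset(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value)
    if arr.ndim == 0:
        arr = np.full(n, arr)
    if len(arr) != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return arr


def _extra_activation_prob(base: float, boost: float) -> float:
    """Probability of extra activation lifting P(non-null) to min(1, base*boost)."""
    target = min(1.0, base * boost)
    if base >= 1.0:
        return 0.0
    return (target - base) / (1.0 - base)


def simulate_collection(config: SimulationConfig) -> StudyCollection:
    """Draw a :class:`StudyCollection` under ``config`` (deterministic in seed)."""
    cfg = config
    genes = np.array([f"G{i:06d}" for i in range(cfg.n_genes)])
    gene_index = pd.Index(genes, name="gene_id")
    gene_pos = {g: i for i, g in enumerate(genes)}

    imprinted = list(cfg.imprinted_ids)
    unknown = [g for g in imprinted if g not in gene_pos]
    if unknown:
        raise ValueError(
            f"imprinted_ids not in the gene universe: {unknown[:5]}"
        )
    imprinted_idx = np.array([gene_pos[g] for g in imprinted], dtype=int)

    disorders = (
        list(cfg.disorder_labels)
        if cfg.disorder_labels is not None
        else default_disorder_labels(cfg.n_datasets)
    )
    if len(disorders) != cfg.n_datasets:
        raise ValueError("disorder_labels length must equal n_datasets")
    sample_types = (
        list(cfg.sample_types)
        if cfg.sample_types is not None
        else [["immune", "neural", "other"][i % 3] for i in range(cfg.n_datasets)]
    )
    model_systems = (
        list(cfg.model_systems)
        if cfg.model_systems is not None
        else [["in vitro", "non-in vitro"][i % 2] for i in range(cfg.n_datasets)]
    )
    n_cases = _per_dataset(cfg.n_cases, cfg.n_datasets, "n_cases").astype(int)
    n_controls = _per_dataset(cfg.n_controls, cfg.n_datasets, "n_controls").astype(int)
    if (n_cases < 3).any() or (n_controls < 3).any():
        raise ValueError("per-dataset n_cases/n_controls must be >= 3")

    # gene-level stream: expression, global activity, base effects
    rng_g = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    meanlog, sdlog = cfg.baseline_expr
    mean_expr = rng_g.lognormal(meanlog, sdlog, size=cfg.n_genes)
    active = rng_g.random(cfg.n_genes) < cfg.frac_true_effects
    base_effect = rng_g.normal(0.0, cfg.effect_sd, size=cfg.n_genes)
    shared = np.where(active, base_effect, 0.0)

    # block-level effects shared within a sample type
    block_effects: dict = {}
    for k, st in enumerate(sorted(cfg.sample_type_gene_sets)):
        rng_b = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(2, k))
        )
        idx = np.array(
            [gene_pos[g] for g in cfg.sample_type_gene_sets[st] if g in gene_pos],
            dtype=int,
        )
        block_effects[st] = (idx, rng_b.normal(0.0, cfg.effect_sd, size=len(idx)))

    p_extra_imp = _extra_activation_prob(cfg.frac_true_effects, cfg.imprinted_boost)
    phen_sets = {
        ph: np.array([gene_pos[g] for g in gs if g in gene_pos], dtype=int)
        for ph, gs in sorted(cfg.phenotype_gene_sets.items())
    }
    p_extra_ph = _extra_activation_prob(cfg.frac_true_effects, cfg.phenotype_boost)
    # fixed-magnitude shifts for phenotype-linked genes: sign drawn once per
    # (phenotype, gene) so the direction is consistent across datasets
    phen_signs: dict = {}
    if cfg.phenotype_shift > 0:
        rng_ph = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3,)))
        for ph in sorted(phen_sets):
            idx = phen_sets[ph]
            phen_signs[ph] = rng_ph.choice([-1.0, 1.0], size=len(idx))

    datasets = []
    metadata = []
    for d in range(cfg.n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, d)))
        n_tot = n_cases[d] + n_controls[d]
        chi2 = rng.chisquare(cfg.se_shape.df, size=cfg.n_genes)
        se = cfg.se_shape.scale / np.sqrt(n_tot) * np.sqrt(cfg.se_shape.df / chi2)

        delta = shared.copy()
        # imprinted genes: extra per-dataset activation
        if len(imprinted_idx) and p_extra_imp > 0:
            mask = ~active[imprinted_idx]
            extra = rng.random(len(imprinted_idx)) < p_extra_imp
            sel = imprinted_idx[mask & extra]
            delta[sel] += rng.normal(0.0, cfg.effect_sd, size=len(sel))
        # phenotype-linked sets in carrying datasets
        carried = cfg.phenotype_map.get(disorders[d], frozenset())
        for ph, idx in phen_sets.items():
            if ph not in carried or not len(idx):
                continue
            if p_extra_ph > 0:
                mask = ~active[idx]
                extra = rng.random(len(idx)) < p_extra_ph
                sel = idx[mask & extra]
                delta[sel] += rng.normal(0.0, cfg.effect_sd, size=len(sel))
            if cfg.phenotype_shift > 0:
                delta[idx] += phen_signs[ph] * cfg.phenotype_shift
        # sample-type block structure
        if sample_types[d] in block_effects:
            idx, eff = block_effects[sample_types[d]]
            delta[idx] += eff
        # disorder-planted fixed effects
        for g, mu in cfg.disorder_gene_effects.get(disorders[d], {}).items():
            delta[gene_pos[g]] += float(mu)

        nonnull = delta != 0.0
        if cfg.tau > 0 and nonnull.any():
            delta[nonnull] += rng.normal(0.0, cfg.tau, size=int(nonnull.sum()))

        obs = delta + rng.normal(0.0, 1.0, size=cfg.n_genes) * se
        p = 2.0 * stats.norm.sf(np.abs(obs / se))

        table = pd.DataFrame(
            {"log2fc": obs, "se": se, "p": p, "mean_expr": mean_expr},
            index=gene_index,
        )
        ds_id = f"DS{d:03d}"
        datasets.append(DatasetSummary(ds_id, table))
        metadata.append(
            DatasetMetadata(
                dataset_id=ds_id,
                disorder=disorders[d],
                phenotypes=cfg.phenotype_map.get(disorders[d], frozenset()),
                sample_type=sample_types[d],
                model_system=model_systems[d],
                n_cases=int(n_cases[d]),
                n_controls=int(n_controls[d]),
                has_case_control_design=True,
            )
        )
    return StudyCollection(datasets, metadata, gene_universe=list(genes))


def write_fixture(collection: StudyCollection, out_dir) -> list:
    """Write one summary TSV per dataset plus metadata.tsv; returns paths."""
    if not collection.datasets:
        raise ValueError("cannot write an empty collection")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in collection.datasets:
        path = out_dir / f"{ds.dataset_id}.tsv"
        write_summary_table(ds, path)
        paths.append(path)
    meta_path = out_dir / "metadata.tsv"
    write_metadata_table(collection.metadata, meta_path)
    paths.append(meta_path)
    return paths
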