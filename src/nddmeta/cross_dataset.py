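"""Corpus-level summaries and association tests.

Four questions, asked across the whole corpus of datasets:

* which gene sets are significantly enriched in the most datasets
  (common-alteration ranking, with Ward-D2 clustering of their signed
  -log10 P profiles for display);
* which genes are differentially expressed in the largest fraction of
  datasets;
* which gene sets show significant enrichment with a *consistent direction*
  (sign of the enrichment score) across one disorder's datasets;
* which term profiles or genes associate with a neurological phenotype —
  Mann-Whitney U on per-dataset signed/unsigned -log10 P values, and
  per-gene Fisher tests of DE frequency in phenotype-carrying versus
  non-carrying datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .core_io import StudyCollection, bh_adjust
from .imprinted import _de_flags, _log2_or_ci

logger = logging.getLogger(__name__)


def _as_frame(results) -> pd.DataFrame:
    """Normalize per-dataset GSEA results (GseaResults or DataFrame)."""
    if isinstance(results, pd.DataFrame):
        return results
    return results.to_frame()


@dataclass
class TermProfile:
    """One gene set's enrichment across all datasets."""

    set_id: str
    signed_logp: dict           # dataset_id -> signed -log10 P
    significant: dict           # dataset_id -> bool
    significant_count: int = 0

    def __post_init__(self) -> None:
        self.significant_count = int(sum(self.significant.values()))

    @property
    def mean_abs_signed_logp(self) -> float:
        vals = [abs(v) for v in self.signed_logp.values()]
        return float(np.mean(vals)) if vals else 0.0


def count_significant(results_by_dataset, use_fdr: bool = True,
                      alpha: float = 0.05) -> list:
    """Rank terms by the number of datasets where they reach significance.

    ``results_by_dataset``: dataset_id -> per-dataset GSEA results.  The
    significance flag uses the FDR-adjusted P (or nominal when
    ``use_fdr=False``).  Ties in count break by mean |signed -log10 P|
    descending, then set_id.
    """
    frames = {ds: _as_frame(res) for ds, res in results_by_dataset.items()}
    pcol = "p_adj" if use_fdr else "p"
    profiles: dict = {}
    for ds, df in frames.items():
        for row in df.itertuples(index=False):
            prof = profiles.setdefault(
                row.set_id, TermProfile(row.set_id, {}, {})
            )
            prof.signed_logp[ds] = row.signed_logp
            prof.significant[ds] = bool(getattr(row, pcol) < alpha)
    out = []
    for prof in profiles.values():
        if not prof.signed_logp:
            logger.warning("term %s never evaluated; excluded", prof.set_id)
            continue
        prof.significant_count = int(sum(prof.significant.values()))
        out.append(prof)
    out.sort(key=lambda p: (-p.significant_count, -p.mean_abs_signed_logp, p.set_id))
    return out


def term_profile_matrix(profiles, dataset_ids) -> pd.DataFrame:
    """Terms x datasets matrix of signed -log10 P (missing imputed as 0)."""
    mat = pd.DataFrame(
        0.0, index=[p.set_id for p in profiles], columns=list(dataset_ids)
    )
    for p in profiles:
        for ds, v in p.signed_logp.items():
            if ds in mat.columns:
                mat.loc[p.set_id, ds] = v
    return mat


def cluster_term_profiles(matrix: pd.DataFrame):
    """Ward-D2 / Euclidean hierarchical clustering of term profiles.

    Returns (leaf-ordered term ids, scipy linkage matrix).  Rows are sorted
    by set_id before linkage so exact ties merge deterministically.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 term profiles to cluster")
    matrix = matrix.sort_index(kind="mergesort")
    Z = linkage(matrix.to_numpy(dtype=float), method="ward")
    order = leaves_list(Z)
    return [matrix.index[i] for i in order], Z


@dataclass
class AssociationResult:
    """One unit's (term or gene) association with a binary dataset label."""

    unit_id: str
    n_a: int
    n_b: int
    statistic: float
    p: float
    p_adj: float = float("nan")
    method: str = ""
    table: tuple | None = None
    log2_or: float | None = None


def mwu_association(values, labels, unit_id: str = "") -> AssociationResult:
    """Two-sided Mann-Whitney U of ``values`` split by boolean ``labels``.

    Exact null enumeration when the total n is at most 12 and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  The branch used is recorded in ``method``.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have equal length")
    a, b = v[lab], v[~lab]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(v)) < len(v)
    if len(v) <= 12 and not ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal-approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return AssociationResult(
        unit_id=unit_id, n_a=len(a), n_b=len(b),
        statistic=float(res.statistic), p=float(res.pvalue), method=method,
    )


def mwu_association_table(values_by_unit, labels,
                          family: str = "mwu") -> pd.DataFrame:
    """Per-unit Mann-Whitney tests + BH adjustment across units."""
    rows = [mwu_association(vals, labels, unit_id=uid)
            for uid, vals in values_by_unit.items()]
    df = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in rows],
            "n_a": [r.n_a for r in rows],
            "n_b": [r.n_b for r in rows],
            "U": [r.statistic for r in rows],
            "p": [r.p for r in rows],
            "method": [r.method for r in rows],
        }
    ).set_index("unit_id")
    df[f"p_adj_{family}"] = bh_adjust(df["p"].to_numpy(), family=family)
    return df.sort_values("p", kind="mergesort")


def gene_de_frequency(collection: StudyCollection,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene count and fraction of datasets calling it DE (p < alpha)."""
    n_de: dict = {}
    n_meas: dict = {}
    for ds in collection.datasets:
        de = _de_flags(ds, alpha, "any")
        for g, flag in de.items():
            n_meas[g] = n_meas.get(g, 0) + 1
            if flag:
                n_de[g] = n_de.get(g, 0) + 1
    genes = sorted(n_meas)
    df = pd.DataFrame(
        {
            "n_de": [n_de.get(g, 0) for g in genes],
            "n_measured": [n_meas[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df["fraction"] = df["n_de"] / df["n_measured"]
    return df.sort_values(["n_de", "gene_id"], ascending=[False, True],
                          kind="mergesort")


def consistent_direction_rank(results_by_dataset,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Rank terms by significant datasets sharing one enrichment direction.

    Per term: count datasets with nominal GSEA P < alpha split by the sign
    of the enrichment score; the score is the larger count and the reported
    direction is that majority side ('ambiguous' on an exact tie).  Ties in
    score break by total significant count, then set_id.
    """
    if not results_by_dataset:
        raise ValueError("need at least 1 dataset")
    counts: dict = {}
    for ds, res in results_by_dataset.items():
        df = _as_frame(res)
        for row in df.itertuples(index=False):
            up, down = counts.setdefault(row.set_id, [0, 0])
            if row.p < alpha:
                if row.es > 0:
                    up += 1
                elif row.es < 0:
                    down += 1
            counts[row.set_id] = [up, down]
    rows = []
    for set_id, (up, down) in counts.items():
        score = max(up, down)
        direction = ("up" if up > down else "down" if down > up
                     else "ambiguous" if score > 0 else "none")
        rows.append((set_id, up, down, score, up + down, direction))
    df = pd.DataFrame(
        rows, columns=["set_id", "n_up", "n_down", "score", "n_significant",
                       "direction"],
    ).set_index("set_id")
    return df.sort_values(
        ["score", "n_significant", "set_id"], ascending=[False, False, True],
        kind="mergesort",
    )


@lru_cache(maxsize=100_000)
def _fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def phenotype_gene_fisher(collection: StudyCollection, phenotype: str,
                          alpha: float = 0.05,
                          direction: str = "any") -> pd.DataFrame:
    """Per-gene Fisher test of DE odds in phenotype-linked datasets.

    For each gene, the 2x2 table counts (DE, not-DE) x (phenotype,
    no-phenotype) over the datasets measuring the gene.  The log2 OR uses
    the Haldane +0.5 correction when any cell is zero.  P values are
    BH-adjusted across genes.
    """
    carrying = [phenotype in m.phenotypes for m in collection.metadata]
    if not any(carrying):
        raise ValueError(f"phenotype {phenotype!r} absent from all metadata")
    if all(carrying):
        raise ValueError(f"every dataset carries phenotype {phenotype!r}")
    genes = pd.Index(collection.gene_universe, name="gene_id")
    row_of = {g: i for i, g in enumerate(genes)}
    n_ds = len(collection.datasets)
    de = np.zeros((len(genes), n_ds), dtype=bool)
    meas = np.zeros_like(de)
    for j, ds in enumerate(collection.datasets):
        flags = _de_flags(ds, alpha, direction)
        rows = np.fromiter((row_of[g] for g in flags.index), dtype=int,
                           count=len(flags))
        meas[rows, j] = True
        de[rows, j] = flags.to_numpy()
    ph = np.asarray(carrying, dtype=bool)
    a = (de[:, ph] & meas[:, ph]).sum(axis=1)
    b = (~de[:, ph] & meas[:, ph]).sum(axis=1)
    c = (de[:, ~ph] & meas[:, ~ph]).sum(axis=1)
    d = (~de[:, ~ph] & meas[:, ~ph]).sum(axis=1)
    keep = (a + b > 0) & (c + d > 0)
    rows = []
    for g, ai, bi, ci, di in zip(genes[keep], a[keep], b[keep], c[keep], d[keep]):
        p = _fisher_2x2(int(ai), int(bi), int(ci), int(di))
        log2_or, lo, hi = _log2_or_ci(int(ai), int(bi), int(ci), int(di))
        rows.append((g, ai, bi, ci, di, log2_or, lo, hi, p))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "de_ph", "notde_ph", "de_noph", "notde_noph",
                 "log2_or", "ci_low", "ci_high", "p"],
    ).set_index("gene_id")
    df[f"p_adj_phenotype-{phenotype}"] = bh_adjust(
        df["p"].to_numpy(), family=f"phenotype-{phenotype}"
    )
    return df.sort_values(["p", "gene_id"], kind="mergesort")


def phenotype_term_association(results_by_dataset, metadata, phenotype: str,
                               signed: bool = True) -> pd.DataFrame:
    """Mann-Whitney association of term enrichment with a phenotype.

    Dependent variable: per-dataset signed (or unsigned) -log10 GSEA P of
    each term; groups: datasets whose disorder carries the phenotype versus
    those that do not.  BH adjustment across terms.
    """
    ph_of = {m.dataset_id: phenotype in m.phenotypes for m in metadata}
    if not any(ph_of.values()):
        raise ValueError(f"phenotype {phenotype!r} absent from all metadata")
    per_term: dict = {}
    labels_per_term: dict = {}
    for ds, res in results_by_dataset.items():
        df = _as_frame(res)
        for row in df.itertuples(index=False):
            v = row.signed_logp if signed else abs(row.signed_logp)
            per_term.setdefault(row.set_id, []).append(v)
            labels_per_term.setdefault(row.set_id, []).append(ph_of[ds])
    rows = []
    for set_id in sorted(per_term):
        vals = np.asarray(per_term[set_id])
        labs = np.asarray(labels_per_term[set_id], dtype=bool)
        if labs.all() or not labs.any():
            continue
        r = mwu_association(vals, labs, unit_id=set_id)
        rows.append(r)
    df = pd.DataFrame(
        {
            "set_id": [r.unit_id for r in rows],
            "n_phenotype": [r.n_a for r in rows],
            "n_other": [r.n_b for r in rows],
            "U": [r.statistic for r in rows],
            "p": [r.p for r in rows],
            "method": [r.method for r in rows],
        }
    ).set_index("set_id")
    fam = f"phenotype-term-{phenotype}-{'signed' if signed else 'unsigned'}"
    df[f"p_adj_{fam}"] = bh_adjust(df["p"].to_numpy(), family=fam)
    return df.sort_values("p", kind="mergesort")
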