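"""Preranked gene-set enrichment per dataset, the signed -log10 P statistic,
and ontology-term clustering by Resnik semantic similarity.

Genes are ranked by log2 fold change (decreasing) and each gene set is
scored with the weighted Kolmogorov-Smirnov running-sum enrichment score:
walking down the ranked list, a member gene ("hit") at rank j adds
|score_j|**q / N_R (N_R normalizing the hit weights), a non-member
("miss") subtracts 1/(N - n_hits); the ES is the running-sum value of
maximal absolute deviation from zero, carrying its sign.  Significance
comes from a gene-label permutation null: random same-size sets drawn from
the ranked universe, with a one-sided +1-smoothed Monte-Carlo P value in
the direction of the observed sign.  Per dataset, the P value and the ES
sign combine into the signed -log10 P value used by all cross-dataset
stages.

Redundant ontology terms are grouped by Resnik similarity — the information
content, -ln(n_t / N), of the most informative common ancestor, normalized
to [0, 1] by the corpus-maximal IC — with complete-linkage clustering cut
so that within-cluster similarity stays above the threshold; the cluster
representative is the term significant (FDR-adjusted P < 0.05) in the most
datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import DatasetSummary, GeneSetCollection, bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankedList:
    """Genes sorted by ranking score (log2FC), decreasing.

    Exact score ties are broken by a seed-deterministic shuffle; the seed is
    recorded so the ordering is reproducible.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    tie_break_seed: int

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(dataset: DatasetSummary, seed: int = 0) -> RankedList:
    """Rank a dataset's genes by log2fc, decreasing, with seeded tie-breaks."""
    tab = dataset.table
    finite = np.isfinite(tab["log2fc"].to_numpy())
    if finite.sum() < 2:
        raise ValueError(
            f"dataset {dataset.dataset_id}: fewer than 2 genes with finite log2fc"
        )
    genes = tab.index.to_numpy()[finite]
    scores = tab["log2fc"].to_numpy()[finite]
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(scores))
    order = np.lexsort((jitter, -scores))  # score desc, ties by shuffle
    return RankedList(genes[order], scores[order], tie_break_seed=seed)


# ---------------------------------------------------------------------------
# enrichment score


def gsea_es(ranked: RankedList, gene_set, weight_exponent: float = 1.0) -> float:
    """Weighted running-sum enrichment score of one gene set."""
    members = set(gene_set)
    hit = np.isin(ranked.gene_ids, list(members))
    n_hits = int(hit.sum())
    N = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hits == N:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.scores) ** weight_exponent
    n_r = w[hit].sum()
    if n_r == 0:
        # all member scores exactly zero: fall back to unweighted hits
        incr = hit / n_hits
    else:
        incr = np.where(hit, w / n_r, 0.0)
    decr = np.where(hit, 0.0, 1.0 / (N - n_hits))
    running = np.cumsum(incr - decr)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_from_positions(pos_sorted: np.ndarray, weights: np.ndarray,
                       N: int) -> np.ndarray:
    """Enrichment scores from sorted hit positions (vectorized over rows).

    ``pos_sorted``: (B, m) sorted 0-based ranks of the hits; ``weights``:
    length-N rank weights |score|**q.  Exploits that the running sum attains
    its maximum immediately after a hit and its minimum immediately before a
    hit (or at the end, where it returns to 0).
    """
    B, m = pos_sorted.shape
    u = 1.0 / (N - m)
    wh = weights[pos_sorted]                       # (B, m) hit weights
    totals = wh.sum(axis=1, keepdims=True)
    C = np.cumsum(wh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Cn = np.where(totals > 0, C / totals, np.cumsum(np.ones_like(wh), axis=1) / m)
    misses_before = pos_sorted - np.arange(m)      # misses preceding hit k
    post = Cn - misses_before * u                  # value just after hit k
    pre = np.concatenate([np.zeros((B, 1)), Cn[:, :-1]], axis=1) - misses_before * u
    max_dev = post.max(axis=1)
    min_dev = np.minimum(pre.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def _sample_positions(rng: np.random.Generator, n_perm: int, m: int,
                      N: int) -> np.ndarray:
    """(n_perm, m) sorted positions, each row an m-subset of range(N).

    Rejection sampling on integer draws (exact: conditioning iid draws on
    distinctness is uniform over subsets), falling back to per-row
    ``rng.choice`` when collisions would be too frequent.
    """
    if m * (m - 1) > 2 * N:  # expected >1 collision per row
        out = np.empty((n_perm, m), dtype=np.int64)
        for b in range(n_perm):
            out[b] = rng.choice(N, size=m, replace=False)
        out.sort(axis=1)
        return out
    x = np.sort(rng.integers(0, N, size=(n_perm, m)), axis=1)
    bad = (np.diff(x, axis=1) == 0).any(axis=1)
    while bad.any():
        x[bad] = np.sort(rng.integers(0, N, size=(int(bad.sum()), m)), axis=1)
        bad = (np.diff(x, axis=1) == 0).any(axis=1)
    return x


# ---------------------------------------------------------------------------
# signed -log10 P


def signed_log10_p(p: float, es: float) -> float:
    """-log10(P) carrying the sign of the enrichment score.

    p = 1 maps to 0 regardless of es; an exactly zero es with p < 1 yields 0
    with a warning (the direction is genuinely undefined).
    """
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        raise ValueError(f"P value out of range: {p}")
    if p == 0.0:
        raise ValueError(
            "P value of exactly 0: use the permutation floor 1/(n_perm+1)"
        )
    if p == 1.0:
        return 0.0
    if es == 0.0:
        warnings.warn("zero enrichment score with p < 1: signed -log10 P set to 0")
        return 0.0
    return float(-np.log10(p) * np.sign(es))


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set scored in one dataset."""

    set_id: str
    es: float
    p: float
    p_adj: float
    signed_logp: float
    n_hits: int


class GseaResults(list):
    """List of :class:`EnrichmentResult` plus a skipped-set report."""

    def __init__(self, results, skipped=None):
        super().__init__(results)
        self.skipped: dict = dict(skipped or {})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_id": r.set_id, "es": r.es, "p": r.p,
                    "p_adj": r.p_adj, "signed_logp": r.signed_logp,
                    "n_hits": r.n_hits,
                }
                for r in self
            ]
        )


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResults:
    """Score every gene set against one ranked list.

    Null enrichment scores come from ``n_perm`` random same-size gene-label
    sets per set; the one-sided P in the observed direction is +1-smoothed
    (never exactly zero), then BH-adjusted across sets.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    N = len(ranked)
    weights = np.abs(ranked.scores) ** weight_exponent
    pos_of = {g: i for i, g in enumerate(ranked.gene_ids)}
    rng = np.random.default_rng(seed)

    rows = []
    skipped: dict = {}
    for set_id, genes in sets.items():
        positions = np.array(sorted(pos_of[g] for g in genes if g in pos_of))
        m = len(positions)
        if m == 0:
            skipped[set_id] = "no member gene in the ranked list"
            logger.warning("set %s skipped: %s", set_id, skipped[set_id])
            continue
        if m >= N:
            skipped[set_id] = "set covers the entire ranked universe"
            logger.warning("set %s skipped: %s", set_id, skipped[set_id])
            continue
        es_obs = float(_es_from_positions(positions[None, :], weights, N)[0])
        null = _es_from_positions(
            _sample_positions(rng, n_perm, m, N), weights, N
        )
        if es_obs > 0:
            same = null > 0
            extreme = same & (null >= es_obs)
        elif es_obs < 0:
            same = null < 0
            extreme = same & (null <= es_obs)
        else:
            same = np.zeros_like(null, dtype=bool)
            extreme = same
        p = (1 + int(extreme.sum())) / (1 + int(same.sum()))
        rows.append((set_id, es_obs, p, m))

    padj = bh_adjust([r[2] for r in rows], family="gsea-terms")
    results = [
        EnrichmentResult(
            set_id=set_id, es=es, p=p, p_adj=float(pa),
            signed_logp=signed_log10_p(p, es), n_hits=m,
        )
        for (set_id, es, p, m), pa in zip(rows, padj)
    ]
    return GseaResults(results, skipped)


# ---------------------------------------------------------------------------
# ontology + Resnik similarity


class OntologyDAG:
    """Ontology terms with child->parent edges and gene annotations.

    Annotation counts follow the true-path rule: a gene annotated to a term
    counts for all the term's ancestors.
    """

    def __init__(self, edges, annotations):
        g = nx.DiGraph()
        g.add_edges_from(edges)  # child -> parent
        for t in annotations:
            g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology edges contain a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have a unique root, found {sorted(roots)}")
        self.root = roots[0]
        for n in g.nodes:
            if n != self.root and not nx.has_path(g, n, self.root):
                raise ValueError(f"term {n} cannot reach the root")
        self.graph = g
        self.annotations = {t: frozenset(gs) for t, gs in annotations.items()}
        self._closure: dict = {}
        # accumulate annotated genes bottom-up (children before parents)
        for t in nx.topological_sort(g):
            acc = set(self.annotations.get(t, ()))
            for child in g.predecessors(t):
                acc |= self._closure[child]
            self._closure[t] = frozenset(acc)
        n_root = len(self._closure[self.root])
        if n_root == 0:
            raise ValueError("no gene annotated anywhere in the ontology")
        self._n_root = n_root
        self._ic = {
            t: -np.log(len(c) / n_root)
            for t, c in self._closure.items() if len(c) > 0
        }
        self._max_ic = max(self._ic.values())

    @classmethod
    def from_files(cls, edge_tsv, annotation_gmt) -> "OntologyDAG":
        """Edge-list TSV (columns child, parent) + annotation GMT."""
        from .core_io import read_gmt

        df = pd.read_csv(edge_tsv, sep="\t", comment="#", dtype=str)
        if not {"child", "parent"}.issubset(df.columns):
            raise ValueError(f"{edge_tsv}: need columns 'child' and 'parent'")
        gmt = read_gmt(annotation_gmt)
        return cls(list(df[["child", "parent"]].itertuples(index=False, name=None)),
                   dict(gmt.sets))

    def ic(self, term: str) -> float:
        if term not in self.graph:
            raise KeyError(f"term not in ontology: {term}")
        return self._ic.get(term, np.inf)

    def ancestors_incl(self, term: str) -> set:
        if term not in self.graph:
            raise KeyError(f"term not in ontology: {term}")
        return nx.descendants(self.graph, term) | {term}

    def annotated_closure(self, term: str) -> frozenset:
        if term not in self.graph:
            raise KeyError(f"term not in ontology: {term}")
        return self._closure[term]

    def term_gene_sets(self, min_genes: int = 1) -> GeneSetCollection:
        """Closure annotation sets as a GeneSetCollection (for GSEA input)."""
        return GeneSetCollection(
            {t: set(c) for t, c in self._closure.items() if len(c) >= min_genes}
        )


def resnik_similarity(dag: OntologyDAG, term_a: str, term_b: str) -> float:
    """Normalized Resnik similarity: IC of the most informative common
    ancestor divided by the corpus-maximal IC, clipped to [0, 1]."""
    anc = dag.ancestors_incl(term_a) & dag.ancestors_incl(term_b)
    ics = [dag._ic[t] for t in anc if t in dag._ic]
    raw = max(ics) if ics else 0.0
    if dag._max_ic <= 0:
        return 0.0
    return float(np.clip(raw / dag._max_ic, 0.0, 1.0))


def resnik_matrix(dag: OntologyDAG, terms) -> pd.DataFrame:
    terms = list(terms)
    n = len(terms)
    ancestors = {t: dag.ancestors_incl(t) for t in terms}
    S = np.eye(n)
    for i in range(n):
        S[i, i] = resnik_similarity(dag, terms[i], terms[i])
        for j in range(i + 1, n):
            anc = ancestors[terms[i]] & ancestors[terms[j]]
            ics = [dag._ic[t] for t in anc if t in dag._ic]
            raw = max(ics) if ics else 0.0
            S[i, j] = S[j, i] = float(np.clip(raw / dag._max_ic, 0.0, 1.0))
    return pd.DataFrame(S, index=terms, columns=terms)


# ---------------------------------------------------------------------------
# term clustering


@dataclass
class TermCluster:
    members: list
    representative: str
    significance_counts: dict = field(default_factory=dict)


def cluster_terms(sim: pd.DataFrame, threshold: float = 0.85,
                  significance_counts=None) -> list:
    """Group terms by complete-linkage clustering on 1 - similarity.

    The dendrogram is cut at height 1 - threshold, so each cluster's least
    similar pair still sits near the threshold.  The representative term of
    a cluster has the maximal significance count (datasets with FDR-adjusted
    P < 0.05); ties go to the lexicographically smallest term id.
    """
    terms = list(sim.index)
    counts = dict(significance_counts or {})
    S = sim.to_numpy(dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if len(terms) == 1:
        labels = np.array([1])
    else:
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = sorted(t for t, l in zip(terms, labels) if l == lab)
        rep = min(members, key=lambda t: (-counts.get(t, 0), t))
        clusters.append(
            TermCluster(members, rep, {t: counts.get(t, 0) for t in members})
        )
    return clusters
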