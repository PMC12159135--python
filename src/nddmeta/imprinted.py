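"""Per-dataset Fisher enrichment of a designated gene set among
differentially expressed genes, and the corpus-level permutation test
against expression-matched random sets.

The question: are imprinted genes (or any designated set) differentially
expressed more often than the rest of the transcriptome — beyond what their
expression levels alone would predict?  Per dataset, a 2x2 table of
(in-set vs out-of-set) x (DE vs not-DE, DE meaning nominal P < alpha,
optionally restricted to one direction of log2FC) gives a log2 odds ratio
and Fisher exact P.  Corpus-wide, the statistic is the number of datasets
with log2 OR > 0; its null distribution comes from random gene sets matched
to the target's size and median-expression quartile composition, so that
expression-level confounding (highly expressed genes are easier to call DE)
is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DatasetSummary, StudyCollection

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 enrichment of a gene set among DE genes in one dataset.

    Table cells: (in-set & DE, in-set & not-DE, out-set & DE, out-set & not-DE).
    The log2 OR uses the raw cells unless any cell is zero, in which case the
    Haldane-Anscombe +0.5 correction is applied to every cell (point estimate
    and Wald CI alike).
    """

    dataset_id: str
    table: tuple
    log2_or: float
    ci_low: float
    ci_high: float
    p: float

    @property
    def n_measured(self) -> int:
        return int(sum(self.table))


def _log2_or_ci(a: int, b: int, c: int, d: int):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log2_or = np.log2(a * d / (b * c))
    se_ln = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = Z975 * se_ln / np.log(2)
    return float(log2_or), float(log2_or - half), float(log2_or + half)


def _de_flags(dataset: DatasetSummary, alpha: float, direction: str) -> pd.Series:
    """Boolean DE flag per measured gene (NaN p = not measured -> dropped)."""
    tab = dataset.table
    measured = tab["p"].notna()
    de = tab.loc[measured, "p"] < alpha
    if direction == "up":
        de &= tab.loc[measured, "log2fc"] > 0
    elif direction == "down":
        de &= tab.loc[measured, "log2fc"] < 0
    elif direction != "any":
        raise ValueError(f"direction must be any/up/down, got {direction!r}")
    return de


def fisher_enrichment(
    dataset: DatasetSummary,
    gene_set,
    alpha: float = 0.05,
    direction: str = "any",
) -> OddsRatioResult:
    """Fisher exact enrichment of ``gene_set`` among the dataset's DE genes."""
    de = _de_flags(dataset, alpha, direction)
    in_set = de.index.isin(list(gene_set))
    if not in_set.any():
        raise ValueError(
            f"gene set disjoint from the measured genes of {dataset.dataset_id}"
        )
    if in_set.all():
        raise ValueError(
            f"gene set covers every measured gene of {dataset.dataset_id} "
            f"(out-of-set margin empty)"
        )
    de_arr = de.to_numpy()
    a = int((in_set & de_arr).sum())
    b = int((in_set & ~de_arr).sum())
    c = int((~in_set & de_arr).sum())
    d = int((~in_set & ~de_arr).sum())
    if a + c == 0 or b + d == 0:
        raise ValueError(
            f"degenerate DE margin in {dataset.dataset_id}: "
            f"{'no' if a + c == 0 else 'only'} DE genes"
        )
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    log2_or, lo, hi = _log2_or_ci(a, b, c, d)
    return OddsRatioResult(dataset.dataset_id, (a, b, c, d), log2_or, lo, hi, float(p))


# ---------------------------------------------------------------------------
# expression-matched null sets


def quartile_bins(median_expr: pd.Series) -> pd.Series:
    """Assign each gene to one of 4 equal-size rank bins of median expression.

    Bin sizes differ by at most one; remainder genes go to the lower bins.
    Ties in median expression are broken by gene id (deterministic).
    """
    s = median_expr.dropna()
    order = sorted(s.index, key=lambda g: (s[g], g))
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels = np.repeat(np.arange(4), sizes)
    return pd.Series(labels, index=pd.Index(order, name="gene_id"), name="quartile")


def expression_matched_sets(
    median_expr: pd.Series,
    target,
    n_perm: int,
    seed: int = 0,
) -> list:
    """Random gene sets matching the target's per-quartile composition.

    ``median_expr``: per-gene median expression across datasets (the
    universe).  Each of the ``n_perm`` sets has exactly the target's count
    in every expression quartile, sampled without replacement.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    target = list(target)
    missing = [g for g in target if g not in median_expr.index]
    if missing:
        raise ValueError(f"target genes absent from universe: {missing[:5]}")
    bins = quartile_bins(median_expr)
    unranked = [g for g in target if g not in bins.index]
    if unranked:
        raise ValueError(
            f"target genes lack an expression rank (missing median "
            f"expression): {unranked[:5]}"
        )
    target_bins = bins.loc[target]
    rng = np.random.default_rng(seed)
    per_q_pool = {q: bins.index[bins == q].to_numpy() for q in range(4)}
    per_q_need = {q: int((target_bins == q).sum()) for q in range(4)}
    for q in range(4):
        if per_q_need[q] > len(per_q_pool[q]):
            raise ValueError(
                f"quartile {q + 1} exhausted: need {per_q_need[q]}, "
                f"have {len(per_q_pool[q])}"
            )
    out = []
    for _ in range(n_perm):
        chosen: list = []
        for q in range(4):
            if per_q_need[q]:
                chosen.extend(
                    rng.choice(per_q_pool[q], size=per_q_need[q], replace=False)
                )
        out.append(frozenset(chosen))
    return out


# ---------------------------------------------------------------------------
# corpus permutation test


@dataclass
class PermutationReport:
    """Corpus-level expression-matched permutation test result."""

    observed_stat: int            # datasets with log2 OR > 0
    null_stats: np.ndarray
    n_perm: int
    p_perm: float
    matched_set_size: int
    n_datasets: int
    subgroup: str | None = None
    per_dataset: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_perm <= 1.0:
            raise ValueError("p_perm must lie in (0,1]")


def _positive_or_count(de_mat: np.ndarray, measured: np.ndarray,
                       member_rows: np.ndarray) -> int:
    """Datasets where the member genes' DE odds ratio exceeds 1.

    ``de_mat``/``measured``: genes x datasets booleans; ``member_rows``:
    row indices of the set.  Uses raw cells; ties (OR exactly 1) and any
    zero cell fall back to Haldane-corrected cells, matching the sign of
    :func:`fisher_enrichment`'s log2 OR.
    """
    in_meas = measured[member_rows]
    a = (de_mat[member_rows] & in_meas).sum(axis=0).astype(float)
    n_in = in_meas.sum(axis=0).astype(float)
    b = n_in - a
    tot_de = (de_mat & measured).sum(axis=0).astype(float)
    tot = measured.sum(axis=0).astype(float)
    c = tot_de - a
    d = (tot - n_in) - c
    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    a = np.where(zero, a + 0.5, a)
    b = np.where(zero, b + 0.5, b)
    c = np.where(zero, c + 0.5, c)
    d = np.where(zero, d + 0.5, d)
    return int((a * d > b * c).sum())


def permutation_test(
    collection: StudyCollection,
    target,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "any",
    by_model_system: bool = True,
) -> dict:
    """Expression-matched permutation test of preferential DE of a gene set.

    Observed statistic: number of datasets whose Fisher log2 OR for the
    target set is positive.  Null: the same count for each of ``n_perm``
    random sets matched to the target's expression-quartile histogram.
    P value: (1 + #{null >= observed}) / (n_perm + 1), never exactly zero.

    Returns {"all": PermutationReport, ...} with per-model-system subgroup
    reports when ``by_model_system`` (subgroups with < 2 datasets skipped).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(collection.datasets) < 2:
        raise ValueError("need at least 2 datasets")
    universe = list(collection.gene_universe)
    row_of = {g: i for i, g in enumerate(universe)}
    n_ds = len(collection.datasets)
    de_mat = np.zeros((len(universe), n_ds), dtype=bool)
    measured = np.zeros_like(de_mat)
    for j, ds in enumerate(collection.datasets):
        de = _de_flags(ds, alpha, direction)
        rows = np.fromiter((row_of[g] for g in de.index), dtype=int, count=len(de))
        measured[rows, j] = True
        de_mat[rows, j] = de.to_numpy()

    median_expr = collection.median_expression()
    matched = expression_matched_sets(median_expr, target, n_perm, seed=seed)
    target_rows = np.array(sorted(row_of[g] for g in target))
    null_rows = [np.array(sorted(row_of[g] for g in s)) for s in matched]

    per_dataset = [
        fisher_enrichment(ds, set(target), alpha=alpha, direction=direction)
        for ds in collection.datasets
    ]

    def report(cols: np.ndarray, subgroup: str | None) -> PermutationReport:
        dm, mm = de_mat[:, cols], measured[:, cols]
        obs = _positive_or_count(dm, mm, target_rows)
        null = np.array(
            [_positive_or_count(dm, mm, rows) for rows in null_rows]
        )
        p = (1 + int((null >= obs).sum())) / (n_perm + 1)
        return PermutationReport(
            observed_stat=obs, null_stats=null, n_perm=n_perm, p_perm=p,
            matched_set_size=len(target_rows), n_datasets=len(cols),
            subgroup=subgroup,
            per_dataset=[per_dataset[int(c)] for c in cols],
        )

    out = {"all": report(np.arange(n_ds), None)}
    if by_model_system:
        systems = [m.model_system for m in collection.metadata]
        for sub in sorted(set(systems)):
            cols = np.array([j for j, s in enumerate(systems) if s == sub])
            if len(cols) >= 2:
                out[sub] = report(cols, sub)
    return out
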