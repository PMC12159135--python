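"""Dataset ordination: Spearman similarity of per-gene P values, the
1 - S distance transform, and principal coordinate analysis.

Two datasets are similar when they rank the same genes as significant:
S[i,j] is the Spearman correlation of their P-value vectors on the genes
both measure, and D = 1 - S.  Classical (Gower) scaling double-centers the
element-wise *squared* distances before eigendecomposition; literal
centering of D itself is available behind a flag for comparison.  D is not
Euclidean-embeddable in general, so negative eigenvalues are reported but
excluded from coordinates and variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SimilarityMatrix:
    ids: list
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.shape != (len(self.ids), len(self.ids)):
            raise ValueError("S must be square and match ids")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-12):
            raise ValueError("diagonal of S must be 1")
        self.S = S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)


@dataclass
class PCoAResult:
    ids: list
    eigenvalues: np.ndarray       # all eigenvalues, non-increasing
    coordinates: np.ndarray       # n x k, retained (positive) axes only
    variance_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pvalue_similarity(collection) -> SimilarityMatrix:
    """Pairwise Spearman correlation of P values on each pair's common genes.

    Uses average ranks for ties.  When every dataset measures the identical
    gene list with no missing P values the whole matrix is computed in one
    rank-transform + correlation product; otherwise pairs are handled on
    their pairwise-complete gene intersections.
    """
    ids = collection.dataset_ids
    n = len(ids)
    pvecs = [ds.table["p"] for ds in collection.datasets]

    same_index = all(pvecs[0].index.equals(v.index) for v in pvecs[1:])
    complete = same_index and not any(v.isna().any() for v in pvecs)
    if complete and n >= 2:
        mat = np.vstack([stats.rankdata(v.to_numpy()) for v in pvecs])
        sds = mat.std(axis=1)
        flat = np.where(sds == 0)[0]
        if len(flat):
            raise ValueError(
                f"constant P vector (Spearman undefined) in dataset(s): "
                f"{[ids[i] for i in flat]}"
            )
        S = np.corrcoef(mat)
        np.fill_diagonal(S, 1.0)
        S = (S + S.T) / 2.0
        return SimilarityMatrix(ids, S)

    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pvecs[i].dropna(), pvecs[j].dropna()
            common = a.index.intersection(b.index)
            if len(common) < 3:
                raise ValueError(
                    f"datasets {ids[i]} and {ids[j]} share fewer than 3 genes"
                )
            x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
            for vec, which in ((x, ids[i]), (y, ids[j])):
                if np.ptp(vec) == 0:
                    raise ValueError(
                        f"constant P vector on the intersection of "
                        f"{ids[i]} and {ids[j]}: dataset {which}"
                    )
            rho = stats.spearmanr(x, y).statistic
            S[i, j] = S[j, i] = rho
    return SimilarityMatrix(ids, S)


def similarity_to_distance(sim: SimilarityMatrix) -> np.ndarray:
    """D = 1 - S: zero diagonal, range [0, 2]."""
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return D


def pcoa(D: np.ndarray, n_axes: int | None = None, ids=None,
         center_squared: bool = True) -> PCoAResult:
    """Classical scaling of a distance matrix.

    B = -1/2 * J (D o D) J with J the centering projector (the Gower
    convention); ``center_squared=False`` instead double-centers D itself.
    Axes with eigenvalue <= 1e-10 * max eigenvalue are dropped; coordinates
    are eigenvectors scaled by sqrt(eigenvalue), each axis oriented so its
    largest-magnitude loading is positive.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if (D < 0).any():
        raise ValueError("D must be nonnegative")
    if ids is None:
        ids = [str(i) for i in range(n)]

    J = np.eye(n) - np.ones((n, n)) / n
    M = D * D if center_squared else D
    B = -0.5 * J @ M @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if eigvals.size and eigvals[0] > 0:
        keep = eigvals > 1e-10 * eigvals[0]
    else:
        keep = np.zeros_like(eigvals, dtype=bool)
    pos_vals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(pos_vals)
    # deterministic sign: largest-|loading| coordinate positive per axis
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pos_vals = pos_vals[:n_axes]
    total_pos = eigvals[eigvals > 0].sum()
    var_exp = pos_vals / total_pos if total_pos > 0 else np.zeros_like(pos_vals)
    return PCoAResult(list(ids), eigvals, coords, var_exp)
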