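"""Cell-line and drug similarity matrices, their weighted combination, and
k-nearest-neighbor adjacency graphs.

Five cell-line similarities enter the model: Pearson correlation on
selected expression features, Pearson on selected CNV features, Jaccard on
selected binary mutation features, Pearson on IC50 response rows, and a
binary same-tissue indicator.  They are combined entrywise as a weighted
mean with nonnegative weights (lambda, gamma, phi, psi, rho); drugs use
Jaccard similarity on 881-bit substructure fingerprints.  The k-NN
adjacency of a similarity matrix keeps, per row, the similarities of the k
most similar other entities (ties broken by higher similarity, then
lexicographic id) and zeroes the rest; it is not symmetric in general.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix must be square over ids")
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)


@dataclass
class NeighborGraph:
    ids: list[str]
    W: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if (np.diag(self.W) != 0).any():
            raise ValueError("neighbor graph diagonal must be zero")
        if ((self.W != 0).sum(axis=1) > self.k).any():
            raise ValueError("row has more than k neighbors")


def pearson_similarity(X: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Pearson correlation between entity rows.  Entities with a
    constant profile get similarity 0 to all others and 1 to themselves."""
    if X.shape[0] < 2:
        raise ValueError("need at least 2 entities")
    if X.isna().any().any():
        raise ValueError("similarity input must be fully observed")
    values = X.to_numpy(dtype=float)
    std = values.std(axis=1)
    constant = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(values)
    if constant.any():
        logger.info("pearson_similarity: %d constant rows set to 0", constant.sum())
        S[constant, :] = 0.0
        S[:, constant] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(X.index), S)


def jaccard_similarity(X: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Jaccard similarity |intersection| / |union| between binary
    entity rows.  Two all-zero vectors are identical: similarity 1 (logged)."""
    values = X.to_numpy(dtype=float)
    if not np.isin(values[~np.isnan(values)], (0.0, 1.0)).all():
        raise ValueError("jaccard input must be binary")
    if np.isnan(values).any():
        raise ValueError("similarity input must be fully observed")
    B = values.astype(bool)
    inter = (B[:, None, :] & B[None, :, :]).sum(axis=2).astype(float)
    union = (B[:, None, :] | B[None, :, :]).sum(axis=2).astype(float)
    both_empty = union == 0
    if both_empty.any():
        logger.info("jaccard_similarity: %d all-zero pairs set to 1 by convention",
                    int(both_empty.sum()))
    S = np.where(both_empty, 1.0, inter / np.where(union == 0, 1.0, union))
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(X.index), S)


def tissue_similarity(labels: pd.Series) -> SimilarityMatrix:
    """1 where two cell lines share a tissue label, else 0."""
    if labels.isna().any():
        raise ValueError("every cell line must carry a tissue label")
    values = labels.to_numpy()
    S = (values[:, None] == values[None, :]).astype(float)
    return SimilarityMatrix(list(labels.index), S)


def combine_similarities(s_exp: SimilarityMatrix, s_cnv: SimilarityMatrix,
                         s_mut: SimilarityMatrix, s_ic50: SimilarityMatrix,
                         s_tissue: SimilarityMatrix,
                         weights: Sequence[float] = (2, 2, 2, 5, 2)) -> SimilarityMatrix:
    """Entrywise weighted mean of the five cell-line similarities.  The
    weight order is (lambda, gamma, phi, psi, rho) for (expression, CNV,
    mutation, IC50, tissue); invariant to rescaling all weights."""
    mats = (s_exp, s_cnv, s_mut, s_ic50, s_tissue)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (5,) or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("need 5 nonnegative weights with positive sum")
    ids = mats[0].ids
    if any(m.ids != ids for m in mats):
        raise ValueError("similarity matrices must share the same id order")
    S = sum(w * m.S for w, m in zip(weights, mats)) / weights.sum()
    return SimilarityMatrix(list(ids), S)


def combine_rows(rows: Sequence[np.ndarray],
                 weights: Sequence[float] = (2, 2, 2, 5, 2)) -> np.ndarray:
    """The same weighted mean for a single new cell line's similarity rows."""
    weights = np.asarray(weights, dtype=float)
    return sum(w * np.asarray(r, dtype=float) for w, r in zip(weights, rows)) / weights.sum()


def knn_adjacency(S: SimilarityMatrix, k: int) -> NeighborGraph:
    """Keep each row's k most similar other entities (their similarity
    values), zero elsewhere.  Ties: higher similarity first, then
    lexicographic id."""
    n = len(S.ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    W = np.zeros_like(S.S)
    for i in range(n):
        cand = [j for j in range(n) if j != i]
        cand.sort(key=lambda j: (-S.S[i, j], S.ids[j]))
        top = cand[:k]
        W[i, top] = S.S[i, top]
    return NeighborGraph(list(S.ids), W, k)


def top_k_neighbors(sim_row: np.ndarray, ids: Sequence[str], k: int) -> list[int]:
    """Indices of the k most similar training entities to a new entity,
    with the same tie-break as :func:`knn_adjacency`."""
    order = sorted(range(len(ids)), key=lambda j: (-sim_row[j], ids[j]))
    return order[:k]


def pearson_to_rows(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson correlation of one new profile against each row of M
    (constant profiles correlate 0, as in :func:`pearson_similarity`)."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())
    Mc = M - M.mean(axis=1, keepdims=True)
    Ms = np.sqrt((Mc ** 2).sum(axis=1))
    denom = xs * Ms
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ xc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def jaccard_to_rows(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Jaccard similarity of one new binary profile against each row of M."""
    xb = np.asarray(x, dtype=float).astype(bool)
    Mb = np.asarray(M, dtype=float).astype(bool)
    inter = (Mb & xb).sum(axis=1).astype(float)
    union = (Mb | xb).sum(axis=1).astype(float)
    return np.where(union == 0, 1.0, inter / np.where(union == 0, 1.0, union))


def tissue_to_rows(label, train_labels: pd.Series) -> np.ndarray:
    return (train_labels.to_numpy() == label).astype(float)


def collinearity_report(named: dict[str, SimilarityMatrix]) -> pd.DataFrame:
    """Diagnostic: Pearson correlation of upper-triangle entries for every
    pair of similarity matrices (a low value supports linear combination)."""
    names = list(named)
    n = len(next(iter(named.values())).ids)
    iu = np.triu_indices(n, k=1)
    rows = []
    for a, b in combinations(names, 2):
        x, y = named[a].S[iu], named[b].S[iu]
        if x.std() == 0 or y.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append((a, b, r))
    return pd.DataFrame(rows, columns=["matrix_a", "matrix_b", "pearson_r"])
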