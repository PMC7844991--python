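"""Cell-line filtering, k-NN imputation of omics/response values, and
median-based binarization of IC50 into sensitive/resistant labels.

Distances between cell lines are squared Euclidean distances on the (fully
observed) gene-expression profile.  Two neighbor weighting modes exist for
real-valued imputation:

``as-printed``
    weight of neighbor i is ``d_i / sum(d)`` — the published formula, which
    gives *larger* weight to *farther* neighbors.
``inverse``
    conventional inverse-distance weights ``(1/d_i) / sum(1/d)``.

Both modes coincide when all k distances are equal; the package default is
``as-printed`` for fidelity to the published formula (see docs/methods.md).
Binary (mutation) imputation is a strict majority vote among the k nearest
neighbors: a tie yields 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WeightMode = Literal["as-printed", "inverse"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Entities x features values with an explicit missingness mask.

    ``values`` entries under a True mask are ignored; binary matrices hold
    only {0, 1} where observed.
    """

    entity_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.entity_ids) != n or len(self.feature_ids) != p:
            raise ValueError("id lengths do not match value matrix shape")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.entity_ids)) != n or len(set(self.feature_ids)) != p:
            raise ValueError("entity/feature ids must be unique")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(list(df.index), list(df.columns), np.nan_to_num(values), mask)

    def to_dataframe(self) -> pd.DataFrame:
        values = self.values.copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=self.entity_ids, columns=self.feature_ids)

    def subset_entities(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        idx = [pos[i] for i in ids]
        return FeatureMatrix(list(ids), list(self.feature_ids),
                             self.values[idx], self.missing_mask[idx])

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        idx = [pos[i] for i in ids]
        return FeatureMatrix(list(self.entity_ids), list(ids),
                             self.values[:, idx], self.missing_mask[:, idx])

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-entity fraction of missing features."""
        return self.missing_mask.mean(axis=1)


@dataclass
class ResponseMatrix:
    """IC50 response matrix (cell lines x drugs) with optional binary labels.

    ``labels`` is float with NaN where undefined; 1 marks sensitive (IC50
    strictly below that drug's median), 0 resistant.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    ic50: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray | None = None
    medians: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.ic50 = np.asarray(self.ic50, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.ic50.shape != (len(self.cell_ids), len(self.drug_ids)):
            raise ValueError("ic50 shape does not match ids")
        if self.missing_mask.shape != self.ic50.shape:
            raise ValueError("mask shape mismatch")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(list(df.index), list(df.columns), np.nan_to_num(values), mask)

    def to_dataframe(self) -> pd.DataFrame:
        values = self.ic50.copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=self.cell_ids, columns=self.drug_ids)

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(list(self.cell_ids), list(self.drug_ids),
                             self.ic50, self.missing_mask)

    def subset_cells(self, ids: Sequence[str]) -> "ResponseMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[i] for i in ids]
        labels = None if self.labels is None else self.labels[idx]
        return ResponseMatrix(list(ids), list(self.drug_ids), self.ic50[idx],
                              self.missing_mask[idx], labels, self.medians)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_cell_lines(matrices: Sequence[FeatureMatrix],
                      max_missing_frac: float = 0.5) -> list[str]:
    """Retain entities whose missing fraction is <= ``max_missing_frac`` in
    every matrix; an entity missing more than half its features in any one
    omics layer is dropped.  Order of the first matrix is preserved."""
    if not matrices:
        raise ValueError("need at least one matrix")
    universe = list(matrices[0].entity_ids)
    if any(set(m.entity_ids) != set(universe) for m in matrices):
        raise ValueError("matrices must share the same entity universe")
    dropped: set[str] = set()
    for m in matrices:
        frac = dict(zip(m.entity_ids, m.missing_fraction))
        dropped.update(e for e in universe if frac[e] > max_missing_frac)
    retained = [e for e in universe if e not in dropped]
    if not retained:
        raise ValueError("no cell lines retained after missingness filtering")
    if dropped:
        logger.info("filter_cell_lines: dropped %d of %d entities",
                    len(dropped), len(universe))
    return retained


# ---------------------------------------------------------------------------
# distances / neighbors
# ---------------------------------------------------------------------------

def euclidean_distance(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Squared Euclidean distance ||x_i - x_j||^2 between two profiles."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("profile length mismatch")
    d = x_i - x_j
    return float(d @ d)


def _neighbor_ranking(expression: FeatureMatrix) -> list[list[int]]:
    """For each entity, all other entities ordered by increasing squared
    distance on expression, ties broken by entity-id lexicographic order."""
    if expression.missing_mask.any():
        raise ValueError("expression must be fully observed")
    X = expression.values
    sq = (X ** 2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, np.inf)
    D = np.maximum(D, 0.0)
    np.fill_diagonal(D, np.inf)
    ids = expression.entity_ids
    order = []
    for i in range(len(ids)):
        cand = [j for j in range(len(ids)) if j != i]
        cand.sort(key=lambda j: (D[i, j], ids[j]))
        order.append(cand)
    return order


def _neighbor_weights(distances: np.ndarray, mode: WeightMode) -> np.ndarray:
    distances = np.asarray(distances, dtype=float)
    if np.allclose(distances, 0.0):
        # duplicate profiles: uniform weights avoid 0/0
        return np.full(distances.shape, 1.0 / len(distances))
    if mode == "as-printed":
        return distances / distances.sum()
    if mode == "inverse":
        with np.errstate(divide="ignore"):
            inv = 1.0 / distances
        if np.isinf(inv).any():  # exact duplicates among the k: all mass there
            w = np.isinf(inv).astype(float)
            return w / w.sum()
        return inv / inv.sum()
    raise ValueError(f"unknown weighting mode: {mode}")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_real(target: FeatureMatrix, expression: FeatureMatrix, k: int = 5,
                weighting: WeightMode = "as-printed") -> FeatureMatrix:
    """Impute missing real-valued entries (IC50 or CNV) from the k nearest
    cell lines in expression space.  Observed entries are never modified."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if target.entity_ids != expression.entity_ids:
        raise ValueError("target and expression entity ids must align")
    ranking = _neighbor_ranking(expression)
    X = expression.values
    values = target.values.copy()
    mask = target.missing_mask.copy()
    for i in range(len(target.entity_ids)):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        neigh = ranking[i][:k]
        for j in cols:
            usable = [c for c in neigh if not target.missing_mask[c, j]]
            if not usable:
                # fall back to nearest observed neighbors beyond the first k
                usable = [c for c in ranking[i] if not target.missing_mask[c, j]][:k]
            if not usable:
                raise ValueError(
                    f"feature {target.feature_ids[j]!r}: no observed neighbor "
                    f"for entity {target.entity_ids[i]!r}")
            dist = np.array([euclidean_distance(X[i], X[c]) for c in usable])
            w = _neighbor_weights(dist, weighting)
            values[i, j] = float(w @ target.values[usable, j])
            mask[i, j] = False
    return FeatureMatrix(list(target.entity_ids), list(target.feature_ids), values, mask)


def impute_binary(target: FeatureMatrix, expression: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """Impute missing binary (mutation) entries by strict majority among the
    k nearest neighbors: 1 iff #ones > #zeros, else 0 (ties -> 0)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if target.entity_ids != expression.entity_ids:
        raise ValueError("target and expression entity ids must align")
    observed = target.values[~target.missing_mask]
    if not np.isin(observed, (0.0, 1.0)).all():
        raise ValueError("target matrix is not binary where observed")
    ranking = _neighbor_ranking(expression)
    values = target.values.copy()
    mask = target.missing_mask.copy()
    for i in range(len(target.entity_ids)):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        neigh = ranking[i][:k]
        for j in cols:
            usable = [c for c in neigh if not target.missing_mask[c, j]]
            if not usable:
                usable = [c for c in ranking[i] if not target.missing_mask[c, j]][:k]
            if not usable:
                raise ValueError(
                    f"feature {target.feature_ids[j]!r}: no observed neighbor "
                    f"for entity {target.entity_ids[i]!r}")
            ones = sum(target.values[c, j] for c in usable)
            zeros = len(usable) - ones
            values[i, j] = 1.0 if ones > zeros else 0.0
            mask[i, j] = False
    return FeatureMatrix(list(target.entity_ids), list(target.feature_ids), values, mask)


def _impute_against(new_values: np.ndarray, new_mask: np.ndarray,
                    train: FeatureMatrix, expr_new: np.ndarray,
                    expr_train: np.ndarray, train_ids: Sequence[str], k: int,
                    weighting: WeightMode, binary: bool) -> np.ndarray:
    """Impute held-out entities' missing entries from their k nearest
    *training* neighbors in expression space (no information flows between
    held-out entities)."""
    if train.missing_mask.any():
        raise ValueError("training matrix must be fully observed (impute first)")
    values = new_values.copy()
    for i in range(values.shape[0]):
        cols = np.flatnonzero(new_mask[i])
        if cols.size == 0:
            continue
        dist = ((expr_train - expr_new[i]) ** 2).sum(axis=1)
        order = sorted(range(len(train_ids)), key=lambda j: (dist[j], train_ids[j]))
        neigh = order[:k]
        if binary:
            ones = train.values[neigh].sum(axis=0)
            values[i, cols] = (ones[cols] > len(neigh) - ones[cols]).astype(float)
        else:
            w = _neighbor_weights(dist[neigh], weighting)
            values[i, cols] = (w @ train.values[neigh])[cols]
    return values


def impute_new_real(new: FeatureMatrix, train: FeatureMatrix,
                    expr_new: np.ndarray, expr_train: np.ndarray, k: int = 5,
                    weighting: WeightMode = "as-printed") -> FeatureMatrix:
    values = _impute_against(new.values, new.missing_mask, train, expr_new,
                             expr_train, train.entity_ids, k, weighting, False)
    return FeatureMatrix(list(new.entity_ids), list(new.feature_ids), values,
                         np.zeros_like(new.missing_mask))


def impute_new_binary(new: FeatureMatrix, train: FeatureMatrix,
                      expr_new: np.ndarray, expr_train: np.ndarray,
                      k: int = 5) -> FeatureMatrix:
    values = _impute_against(new.values, new.missing_mask, train, expr_new,
                             expr_train, train.entity_ids, k, "as-printed", True)
    return FeatureMatrix(list(new.entity_ids), list(new.feature_ids), values,
                         np.zeros_like(new.missing_mask))


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def binarize_response(resp: ResponseMatrix,
                      medians: np.ndarray | None = None) -> ResponseMatrix:
    """Label each (cell line, drug) pair sensitive (1) iff its IC50 is
    strictly below the drug's median IC50 across cell lines, else resistant
    (0).  Pass precomputed ``medians`` to label new cell lines against
    training medians.  Per-drug medians are stored on the result for audit."""
    if resp.missing_mask.any():
        raise ValueError("binarize_response expects fully observed IC50 (impute first)")
    if medians is None:
        if resp.ic50.shape[0] < 2:
            raise ValueError("need at least 2 observed values per drug for a median")
        medians = np.median(resp.ic50, axis=0)
    medians = np.asarray(medians, dtype=float)
    labels = (resp.ic50 < medians[None, :]).astype(float)
    return ResponseMatrix(list(resp.cell_ids), list(resp.drug_ids), resp.ic50,
                          resp.missing_mask, labels, medians)
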