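"""Neighborhood-regularized logistic matrix factorization.

The probability that cell line i is sensitive to drug j is modeled as
sigma(u_i . v_j + beta^c_i + beta^d_j) with latent factors U (n x L),
V (m x L) and per-entity biases.  Training minimizes the weighted logistic
loss

    sum_ij w_ij [ (1 + r q_ij - q_ij) log(1 + exp(z_ij)) - r q_ij z_ij ]
    + 1/2 tr[U^T (lambda_c I + alpha H^c) U]
    + 1/2 tr[V^T (lambda_d I + beta H^d) V]

where q_ij are the 0/1 sensitivity labels, w_ij an optional observation
mask, and H^c, H^d graph Laplacians of the k-NN cell-line / drug similarity
graphs (H = (E + E~) - (A + A^T) with E, E~ the row/column-sum diagonals of
the adjacency A); the Laplacian terms pull neighbors' latent vectors
together.  Optimization is full-batch AdaGrad from a seeded small-Gaussian
start; the objective trajectory is recorded and must not increase overall.

Cold start: a held-out cell line's IC50 similarity row is estimated by a
decision-tree classifier on the other similarity layers (10 equal-width
bins over [-1, 1], midpoint decoding), the combined similarity row is
assembled, and the new latent vector and bias are the similarity-weighted
mean of its k nearest training neighbors'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

from .similarity import NeighborGraph, top_k_neighbors

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LmfHyperParams:
    """Hyperparameters of the factorization (defaults follow the published
    GDSC-tuned values; L is data-dependent)."""

    L: int = 95
    r: float = 1.0
    lambda_c: float = 0.5
    lambda_d: float = 0.5
    alpha: float = 0.5
    beta: float = 0.1
    k: int = 20
    sim_weights: tuple[float, float, float, float, float] = (2, 2, 2, 5, 2)
    threshold: float = 0.4
    n_iter: int = 1000
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (self.r, self.lambda_c, self.lambda_d, self.alpha, self.beta,
                  self.k, self.n_iter, self.learning_rate, *self.sim_weights)
        if any(x < 0 for x in nonneg):
            raise ValueError("hyperparameters must be nonnegative")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class LmfModel:
    U: np.ndarray
    V: np.ndarray
    beta_c: np.ndarray
    beta_d: np.ndarray
    hyper: LmfHyperParams
    cell_ids: list[str] = field(default_factory=list)
    drug_ids: list[str] = field(default_factory=list)
    objective_trajectory: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.U.shape[1]

    def logits(self) -> np.ndarray:
        return self.U @ self.V.T + self.beta_c[:, None] + self.beta_d[None, :]


def laplacian(graph: NeighborGraph) -> np.ndarray:
    """H = (E + E~) - (A + A^T): the Laplacian of the symmetrized k-NN
    graph; symmetric and positive semidefinite for nonnegative weights."""
    A = graph.W
    E = np.diag(A.sum(axis=1))
    E_t = np.diag(A.sum(axis=0))
    return (E + E_t) - (A + A.T)


# ---------------------------------------------------------------------------
# objective and gradients
# ---------------------------------------------------------------------------

def _log1pexp(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def objective(U: np.ndarray, V: np.ndarray, beta_c: np.ndarray,
              beta_d: np.ndarray, Q: np.ndarray, H_c: np.ndarray,
              H_d: np.ndarray, hyper: LmfHyperParams,
              mask: np.ndarray | None = None) -> float:
    """The regularized logistic loss (numerically stable log(1+exp))."""
    n, m = Q.shape
    if U.shape[0] != n or V.shape[0] != m:
        raise ValueError("factor dimensions do not match the label matrix")
    Z = U @ V.T + beta_c[:, None] + beta_d[None, :]
    r = hyper.r
    term = (1.0 + r * Q - Q) * _log1pexp(Z) - r * Q * Z
    if mask is not None:
        term = term * mask
    reg_u = 0.5 * np.trace(U.T @ (hyper.lambda_c * np.eye(n) + hyper.alpha * H_c) @ U)
    reg_v = 0.5 * np.trace(V.T @ (hyper.lambda_d * np.eye(m) + hyper.beta * H_d) @ V)
    return float(term.sum() + reg_u + reg_v)


def gradients(U, V, beta_c, beta_d, Q, H_c, H_d, hyper: LmfHyperParams,
              mask: np.ndarray | None = None):
    """Analytic gradients of :func:`objective` w.r.t. U, V and the biases."""
    r = hyper.r
    Z = U @ V.T + beta_c[:, None] + beta_d[None, :]
    dZ = (1.0 + r * Q - Q) * expit(Z) - r * Q
    if mask is not None:
        dZ = dZ * mask
    n, m = Q.shape
    gU = dZ @ V + (hyper.lambda_c * np.eye(n) + hyper.alpha * H_c) @ U
    gV = dZ.T @ U + (hyper.lambda_d * np.eye(m) + hyper.beta * H_d) @ V
    return gU, gV, dZ.sum(axis=1), dZ.sum(axis=0)


def train(Q: np.ndarray, H_c: np.ndarray, H_d: np.ndarray,
          hyper: LmfHyperParams, mask: np.ndarray | None = None,
          cell_ids: Sequence[str] | None = None,
          drug_ids: Sequence[str] | None = None) -> LmfModel:
    """Fit the factorization by full-batch AdaGrad.

    Observed labels must be 0/1 (use ``mask`` to down-weight held-out
    entries to zero).  Raises on a non-finite objective; the recorded final
    objective is never above the initial one.
    """
    Q = np.asarray(Q, dtype=float)
    obs = Q if mask is None else Q[np.asarray(mask, dtype=bool)]
    if not np.isin(obs, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1 where observed")
    n, m = Q.shape
    L = hyper.L
    if L > min(n, m):
        logger.info("train: L=%d exceeds min(n, m)=%d; using %d",
                    L, min(n, m), min(n, m))
        L = min(n, m)
    rng = np.random.default_rng(hyper.seed)
    U = rng.normal(0.0, 1.0 / np.sqrt(L), size=(n, L))
    V = rng.normal(0.0, 1.0 / np.sqrt(L), size=(m, L))
    beta_c = np.zeros(n)
    beta_d = np.zeros(m)
    hist = [objective(U, V, beta_c, beta_d, Q, H_c, H_d, hyper, mask)]
    acc = [np.zeros_like(U), np.zeros_like(V), np.zeros_like(beta_c),
           np.zeros_like(beta_d)]
    eps = 1e-8
    params = [U, V, beta_c, beta_d]
    for _ in range(hyper.n_iter):
        grads = gradients(*params, Q, H_c, H_d, hyper, mask)
        for q, g, a in zip(params, grads, acc):
            a += g ** 2
            q -= hyper.learning_rate * g / (np.sqrt(a) + eps)
        val = objective(*params, Q, H_c, H_d, hyper, mask)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"objective diverged at iteration {len(hist)}: {val}")
        hist.append(val)
    if hist[-1] > hist[0]:
        logger.warning("train: final objective above initial (%.4f > %.4f)",
                       hist[-1], hist[0])
    U, V, beta_c, beta_d = params
    return LmfModel(U, V, beta_c, beta_d, hyper,
                    list(cell_ids or []), list(drug_ids or []),
                    np.asarray(hist))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_prob(model: LmfModel, i: int, j: int) -> float:
    """P(sensitive) for the (cell line i, drug j) pair (stable sigmoid)."""
    z = model.U[i] @ model.V[j] + model.beta_c[i] + model.beta_d[j]
    return float(expit(z))


def predict_matrix(model: LmfModel) -> np.ndarray:
    return expit(model.logits())


def classify(prob: float | np.ndarray, threshold: float = 0.4) -> np.ndarray:
    """Label 1 iff probability strictly exceeds the threshold."""
    return (np.asarray(prob) > threshold).astype(int)


# ---------------------------------------------------------------------------
# serialization (plain-text container: TSV factors + JSON hyperparameters)
# ---------------------------------------------------------------------------

def save_model(model: LmfModel, outdir) -> None:
    import dataclasses
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = model.cell_ids or [str(i) for i in range(model.U.shape[0])]
    drugs = model.drug_ids or [str(j) for j in range(model.V.shape[0])]
    cols = [f"L{l}" for l in range(model.L)]
    pd.DataFrame(model.U, index=cells, columns=cols).to_csv(outdir / "U.tsv", sep="\t")
    pd.DataFrame(model.V, index=drugs, columns=cols).to_csv(outdir / "V.tsv", sep="\t")
    pd.DataFrame({"beta_c": model.beta_c}, index=cells).to_csv(outdir / "beta_c.tsv", sep="\t")
    pd.DataFrame({"beta_d": model.beta_d}, index=drugs).to_csv(outdir / "beta_d.tsv", sep="\t")
    meta = {"hyper": dataclasses.asdict(model.hyper)}
    if model.objective_trajectory is not None:
        meta["objective_trajectory"] = [float(x) for x in model.objective_trajectory]
    with open(outdir / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(indir) -> LmfModel:
    import json
    from pathlib import Path

    import pandas as pd

    indir = Path(indir)
    U = pd.read_csv(indir / "U.tsv", sep="\t", index_col=0)
    V = pd.read_csv(indir / "V.tsv", sep="\t", index_col=0)
    bc = pd.read_csv(indir / "beta_c.tsv", sep="\t", index_col=0)["beta_c"]
    bd = pd.read_csv(indir / "beta_d.tsv", sep="\t", index_col=0)["beta_d"]
    with open(indir / "model.json") as fh:
        meta = json.load(fh)
    hyper_d = meta["hyper"]
    hyper_d["sim_weights"] = tuple(hyper_d["sim_weights"])
    traj = meta.get("objective_trajectory")
    return LmfModel(U.to_numpy(), V.to_numpy(), bc.to_numpy(), bd.to_numpy(),
                    LmfHyperParams(**hyper_d), list(U.index), list(V.index),
                    None if traj is None else np.asarray(traj))


# ---------------------------------------------------------------------------
# cold start
# ---------------------------------------------------------------------------

N_IC50_BINS = 10


class SimIc50Estimator:
    """Decision tree predicting a pair's IC50-similarity bin from its other
    similarity layers.

    Features of a (cell line, cell line) pair: its expression, CNV,
    mutation and tissue similarities.  The target is the pair's IC50
    Pearson similarity discretized into 10 equal-width bins over [-1, 1];
    predictions decode to bin midpoints.
    """

    def __init__(self, max_depth: int = 6, seed: int = 0) -> None:
        self.tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        self.edges = np.linspace(-1.0, 1.0, N_IC50_BINS + 1)
        self.midpoints = (self.edges[:-1] + self.edges[1:]) / 2.0
        self.fitted = False

    def _bin(self, values: np.ndarray) -> np.ndarray:
        idx = np.digitize(np.clip(values, -1.0, 1.0), self.edges[1:-1])
        return idx

    def fit(self, pair_features: np.ndarray, sim_ic50: np.ndarray) -> "SimIc50Estimator":
        self.tree.fit(np.asarray(pair_features, dtype=float),
                      self._bin(np.asarray(sim_ic50, dtype=float)))
        self.fitted = True
        return self

    def predict(self, pair_features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("SimIc50Estimator is not fitted")
        bins = self.tree.predict(np.asarray(pair_features, dtype=float))
        return self.midpoints[bins]


def pair_feature_table(sim_layers: Sequence[np.ndarray]) -> np.ndarray:
    """Stack the upper-triangle entries of (exp, cnv, mut, tissue)
    similarity matrices into a pairs x 4 feature table."""
    n = sim_layers[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return np.column_stack([S[iu] for S in sim_layers])


def fit_sim_ic50_estimator(sim_exp: np.ndarray, sim_cnv: np.ndarray,
                           sim_mut: np.ndarray, sim_tissue: np.ndarray,
                           sim_ic50: np.ndarray, max_depth: int = 6,
                           seed: int = 0) -> SimIc50Estimator:
    feats = pair_feature_table((sim_exp, sim_cnv, sim_mut, sim_tissue))
    iu = np.triu_indices(sim_ic50.shape[0], k=1)
    return SimIc50Estimator(max_depth, seed).fit(feats, sim_ic50[iu])


def estimate_sim_ic50_new(new_sim_rows: Sequence[np.ndarray],
                          estimator: SimIc50Estimator) -> np.ndarray:
    """Estimated IC50-similarity row of a new cell line to every training
    cell line, from its (exp, cnv, mut, tissue) similarity rows."""
    feats = np.column_stack([np.asarray(r, dtype=float) for r in new_sim_rows])
    return estimator.predict(feats)


def infer_new_cell_line(sim_cl_row: np.ndarray, model: LmfModel, k: int,
                        weighted: bool = True) -> tuple[np.ndarray, float, np.ndarray]:
    """Latent vector, bias and per-drug sensitivity probabilities of a
    held-out cell line.

    Neighbors are the k training cell lines most similar in the combined
    row; the latent vector and bias are their similarity-weighted mean
    (plain mean with ``weighted=False``, or as fallback when no neighbor
    similarity is positive).
    """
    sim_cl_row = np.asarray(sim_cl_row, dtype=float)
    ids = model.cell_ids or [str(i) for i in range(model.U.shape[0])]
    neigh = top_k_neighbors(sim_cl_row, ids, k)
    w = np.clip(sim_cl_row[neigh], 0.0, None)
    if not weighted or w.sum() <= 0:
        if weighted and w.sum() <= 0:
            logger.info("infer_new_cell_line: no positive neighbor similarity; "
                        "using unweighted mean")
        w = np.ones(len(neigh))
    w = w / w.sum()
    u_new = w @ model.U[neigh]
    beta_new = float(w @ model.beta_c[neigh])
    probs = expit(u_new @ model.V.T + beta_new + model.beta_d)
    return u_new, beta_new, probs
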