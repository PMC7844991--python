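"""Two-stage feature screening for expression and CNV panels.

Stage 1 is an unsupervised single-hidden-layer autoencoder (tanh encoder,
linear decoder) trained to reconstruct the standardized feature matrix.
Features are scored by the L2 norm of their input-to-hidden weight row and
the top ``keep_fraction`` survive — a feature the encoder ignores cannot
influence the hidden representation.

Stage 2 is a Boruta shadow-feature confirmation: each iteration appends a
per-column permuted copy of every undecided feature, fits a random-forest
classifier on sensitive/resistant labels, computes per-feature importance
Z-scores (mean / sd of per-tree impurity importances), and registers a
"hit" for features beating the best shadow score.  A two-sided binomial
test on accumulated hits confirms clear winners and rejects clear losers;
features still undecided after ``max_iter`` iterations remain tentative
(treated as not selected downstream, logged).

Labels are per (cell line, drug) while features are per cell line, so the
procedure runs either once per drug with the confirmed sets unioned
(default) or once on stacked cell-line copies with per-drug labels
("pooled").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

BorutaMode = Literal["per-drug-union", "pooled"]


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderSpec:
    """Architecture and training settings of the screening autoencoder."""

    hidden_units: int = 100
    epochs: int = 500
    learning_rate: float = 0.01
    weight_decay: float = 1e-3   # shrinks unused encoder rows toward zero so
                                 # the weight-norm readout ranks features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


def train_autoencoder(X: np.ndarray, spec: AutoencoderSpec) -> tuple[np.ndarray, float]:
    """Train x -> tanh(x W + b) -> x_hat on the standardized matrix X with
    full-batch Adam, minimizing mean squared reconstruction error.

    Returns the p x h encoder weight matrix and the final reconstruction
    error (mean squared, over all entries).  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("autoencoder input must be finite")
    n, p = X.shape
    h = spec.hidden_units
    rng = np.random.default_rng(spec.seed)
    # Glorot-style scales
    W1 = rng.normal(0.0, math.sqrt(2.0 / (p + h)), size=(p, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, math.sqrt(2.0 / (p + h)), size=(h, p))
    b2 = np.zeros(p)
    params = [W1, b1, W2, b2]
    m = [np.zeros_like(q) for q in params]
    v = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    err = float("nan")
    for step in range(1, spec.epochs + 1):
        H = np.tanh(X @ W1 + b1)
        Xhat = H @ W2 + b2
        R = Xhat - X
        err = float((R ** 2).mean())
        G2 = 2.0 * R / R.size
        gW2 = H.T @ G2
        gb2 = G2.sum(axis=0)
        GH = (G2 @ W2.T) * (1.0 - H ** 2)
        gW1 = X.T @ GH + spec.weight_decay * W1
        gb1 = GH.sum(axis=0)
        gW2 = gW2 + spec.weight_decay * W2
        for q, g, mq, vq in zip(params, [gW1, gb1, gW2, gb2], m, v):
            mq *= beta1
            mq += (1 - beta1) * g
            vq *= beta2
            vq += (1 - beta2) * g ** 2
            mhat = mq / (1 - beta1 ** step)
            vhat = vq / (1 - beta2 ** step)
            q -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
    H = np.tanh(X @ W1 + b1)
    err = float(((H @ W2 + b2 - X) ** 2).mean())
    return W1, err


def score_and_screen(encoder_weights: np.ndarray, feature_ids: list[str],
                     keep_fraction: float = 0.5) -> list[str]:
    """Rank features by the L2 norm of their encoder weight row and keep the
    top ``ceil(keep_fraction * p)`` (ties broken by feature id)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    W = np.asarray(encoder_weights, dtype=float)
    if W.shape[0] != len(feature_ids):
        raise ValueError("weight rows must match feature ids")
    scores = np.linalg.norm(W, axis=1)
    n_keep = math.ceil(keep_fraction * len(feature_ids))
    order = sorted(range(len(feature_ids)),
                   key=lambda j: (-scores[j], feature_ids[j]))
    kept = sorted(order[:n_keep], key=lambda j: feature_ids[j])
    return [feature_ids[j] for j in kept]


def screen_features(X: pd.DataFrame, spec: AutoencoderSpec | None = None,
                    keep_fraction: float = 0.5) -> list[str]:
    """Standardize, train the autoencoder, and return the screened ids."""
    spec = spec or AutoencoderSpec()
    values = X.to_numpy(dtype=float)
    mu = values.mean(axis=0)
    sd = np.maximum(values.std(axis=0), 1e-9)
    W, _ = train_autoencoder((values - mu) / sd, spec)
    return score_and_screen(W, list(X.columns), keep_fraction)


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    importance_history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        sets = [set(self.confirmed), set(self.rejected), set(self.tentative)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("confirmed/rejected/tentative must be disjoint")


MIN_SHADOW = 5  # keep the shadow-maximum competitive when few features remain


def make_shadow(X: np.ndarray, rng: np.random.Generator,
                min_columns: int = 1) -> np.ndarray:
    """Per-column permuted copies of X (the shadow features); columns are
    recycled if X has fewer than ``min_columns``."""
    src = X
    while src.shape[1] < min_columns:
        src = np.hstack([src, X])
    shadow = src.copy()
    for j in range(shadow.shape[1]):
        rng.shuffle(shadow[:, j])
    return shadow


def _importance_z(rf: RandomForestClassifier) -> np.ndarray:
    imp = np.array([t.feature_importances_ for t in rf.estimators_])
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0)
    return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)


SUBSAMPLE = 0.75  # per-round row subsample: decorrelates chance associations
                  # across rounds so the binomial hit model holds on fixed data


def _boruta_single(X: np.ndarray, y: np.ndarray, feature_ids: list[str],
                   max_iter: int, alpha: float, rng: np.random.Generator,
                   n_trees: int) -> BorutaResult:
    n, p = X.shape
    status = np.zeros(p, dtype=int)       # 0 tentative, 1 confirmed, -1 rejected
    hits = np.zeros(p, dtype=int)
    history = []
    n_rounds = 0
    for it in range(1, max_iter + 1):
        undecided = np.flatnonzero(status == 0)
        if undecided.size == 0:
            break
        live = np.flatnonzero(status >= 0)   # confirmed features stay in the forest
        rows = rng.choice(n, size=max(10, int(SUBSAMPLE * n)), replace=False) \
            if n > 13 else np.arange(n)
        X_live = X[np.ix_(rows, live)]
        shadow = make_shadow(X_live, rng, MIN_SHADOW)
        X_ext = np.hstack([X_live, shadow])
        rf = RandomForestClassifier(n_estimators=n_trees, n_jobs=1,
                                    random_state=int(rng.integers(2 ** 31)))
        rf.fit(X_ext, y[rows])
        z = _importance_z(rf)
        z_real = z[: live.size]
        z_shadow_max = z[live.size:].max() if live.size else 0.0
        live_pos = {f: i for i, f in enumerate(live)}
        hit_now = np.zeros(p, dtype=bool)
        for f in undecided:
            hit_now[f] = z_real[live_pos[f]] > z_shadow_max
        hits[hit_now] += 1
        n_rounds = it
        for f in undecided:
            history.append((it, feature_ids[f], float(z_real[live_pos[f]]),
                            float(z_shadow_max), int(hits[f])))
        # two-sided binomial test on accumulated hits vs Binomial(it, 1/2),
        # Bonferroni-corrected over the p features on both sides so
        # pure-noise panels confirm nothing and rejection keeps the shadow
        # pool competitive while features are still in play
        for f in undecided:
            pval = stats.binomtest(int(hits[f]), it, 0.5).pvalue
            if pval < alpha / p:
                status[f] = 1 if hits[f] > it / 2 else -1
    confirmed = [feature_ids[f] for f in np.flatnonzero(status == 1)]
    rejected = [feature_ids[f] for f in np.flatnonzero(status == -1)]
    tentative = [feature_ids[f] for f in np.flatnonzero(status == 0)]
    if tentative:
        logger.info("boruta: %d features tentative after %d iterations "
                    "(treated as not selected)", len(tentative), n_rounds)
    hist = pd.DataFrame(history, columns=["iteration", "feature", "z",
                                          "z_shadow_max", "hits"])
    return BorutaResult(confirmed, rejected, tentative, hist)


def boruta_select(X: pd.DataFrame, labels: pd.DataFrame,
                  mode: BorutaMode = "per-drug-union", max_iter: int = 20,
                  alpha: float = 0.05, seed: int = 0,
                  n_trees: int = 500) -> BorutaResult:
    """Boruta confirmation of cell-line features against sensitive/resistant
    labels.

    ``X`` is cell lines x features, ``labels`` cell lines x drugs in {0, 1}.
    In ``per-drug-union`` mode the procedure runs independently per drug and
    the confirmed sets are unioned (a feature confirmed anywhere is kept);
    ``pooled`` mode stacks one copy of the cell lines per drug with that
    drug's labels and runs once.  Drugs whose labels are single-class are
    skipped with a warning.
    """
    if not set(X.index) >= set(labels.index):
        raise ValueError("label rows must be covered by feature rows")
    Xv = X.loc[labels.index].to_numpy(dtype=float)
    ids = list(X.columns)
    rng = np.random.default_rng(seed)

    usable_drugs = []
    for d in labels.columns:
        y = labels[d].to_numpy()
        if np.unique(y).size < 2:
            logger.warning("boruta_select: drug %s has single-class labels; skipped", d)
            continue
        usable_drugs.append(d)
    if not usable_drugs:
        raise ValueError("no drug with two-class labels")

    if mode == "pooled":
        Xs = np.vstack([Xv] * len(usable_drugs))
        ys = np.concatenate([labels[d].to_numpy(dtype=int) for d in usable_drugs])
        return _boruta_single(Xs, ys, ids, max_iter, alpha, rng, n_trees)
    if mode != "per-drug-union":
        raise ValueError(f"unknown mode: {mode}")

    confirmed: set[str] = set()
    ever_tentative: set[str] = set()
    histories = []
    for d in usable_drugs:
        res = _boruta_single(Xv, labels[d].to_numpy(dtype=int), ids,
                             max_iter, alpha, rng, n_trees)
        confirmed.update(res.confirmed)
        ever_tentative.update(res.tentative)
        if not res.importance_history.empty:
            histories.append(res.importance_history.assign(drug=d))
    tentative = sorted(ever_tentative - confirmed)
    rejected = sorted(set(ids) - confirmed - set(tentative))
    hist = pd.concat(histories, ignore_index=True) if histories else pd.DataFrame()
    return BorutaResult(sorted(confirmed), rejected, tentative, hist)
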