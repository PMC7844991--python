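"""Classification metrics, rank-based AUC, and the repeated tenfold
cross-validation harness with unseen-cell-line (cold-start) evaluation.

Folds split *cell lines*, never pairs: a test cell line contributes nothing
to feature selection, similarity construction or factorization training in
its fold — its predictions flow entirely through the cold-start path
(estimated IC50-similarity row -> combined similarity row -> neighbor-
averaged latent vector).  Metrics are computed over all test (cell line,
drug) pairs pooled; AUC excludes drugs whose test labels are single-class
in a fold (logged).  A per-drug breakdown is also emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import lmf as _lmf
from . import mutsig as _mutsig
from . import preprocess as _pre
from . import screening as _screen
from . import similarity as _sim
from .config import PipelineConfig
from .synthetic import SyntheticPanel

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "f1", "mcc")


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, recall, precision, specificity, F1 and MCC.  A metric with
    a zero denominator is reported as 0 and flagged so fold averages stay
    defined."""
    if c.total == 0:
        raise ValueError("no evaluated pairs")
    flags: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    out = {
        "accuracy": safe(tp + tn, c.total, "accuracy"),
        "recall": safe(tp, tp + fn, "recall"),
        "precision": safe(tp, tp + fp, "precision"),
        "specificity": safe(tn, tn + fp, "specificity"),
        "f1": safe(2 * tp, 2 * tp + fp + fn, "f1"),
        "mcc": safe(tp * tn - fp * fn,
                    math.sqrt(float(tp + fp) * (tp + fn) * (fp + tn) * (fn + tn)),
                    "mcc"),
    }
    out["zero_denominator_flags"] = tuple(flags)
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-based Mann-Whitney statistic;
    tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CvPlan:
    n_folds: int
    n_repeats: int
    seed: int
    assignments: list[np.ndarray] = field(default_factory=list)  # per repeat

    def folds(self, repeat: int) -> list[np.ndarray]:
        a = self.assignments[repeat]
        return [np.flatnonzero(a == f) for f in range(self.n_folds)]


def make_cv_plan(cell_ids: list[str], n_folds: int = 10, n_repeats: int = 30,
                 seed: int = 0) -> CvPlan:
    """Random fold assignments per repeat; fold sizes differ by at most 1."""
    n = len(cell_ids)
    if n < n_folds:
        raise ValueError("need at least n_folds cell lines")
    rng = np.random.default_rng(seed)
    assignments = []
    base = np.arange(n) % n_folds
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        a = np.empty(n, dtype=int)
        a[perm] = base
        assignments.append(a)
    return CvPlan(n_folds, n_repeats, seed, assignments)


# ---------------------------------------------------------------------------
# fitted pipeline (training side of one fold, or of the full panel)
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    train_ids: list[str]
    expr_features: list[str]
    cnv_features: list[str]
    mut_features: list[str]
    expr_train: pd.DataFrame
    cnv_train: pd.DataFrame
    mut_train: pd.DataFrame
    labels: pd.DataFrame
    medians: np.ndarray
    tissue_train: pd.Series
    sims: dict
    model: _lmf.LmfModel
    sim_ic50_estimator: _lmf.SimIc50Estimator
    config: PipelineConfig
    hmm: _mutsig.HmmModel | None = None
    mmm: _mutsig.MmmModel | None = None
    activities: pd.DataFrame | None = None


def _load_signature_profiles(config: PipelineConfig) -> np.ndarray | None:
    if config.signature_profiles is None:
        return None
    from . import io as sio
    prof = sio.read_matrix_tsv(config.signature_profiles)
    E = prof.to_numpy(dtype=float).T          # columns = signatures -> rows
    return E / E.sum(axis=1, keepdims=True)


def fit_pipeline(panel: SyntheticPanel, train_ids: list[str],
                 config: PipelineConfig) -> FittedPipeline:
    """Run preprocessing, both feature-selection arms, similarity
    integration and factorization training on the training cell lines."""
    expr = panel.expression.loc[train_ids]
    expr_fm = _pre.FeatureMatrix.from_dataframe(expr)

    cnv_fm = _pre.impute_real(_pre.FeatureMatrix.from_dataframe(panel.cnv.loc[train_ids]),
                              expr_fm, k=config.impute_k,
                              weighting=config.impute_weighting)
    mut_fm = _pre.impute_binary(_pre.FeatureMatrix.from_dataframe(panel.mutation.loc[train_ids]),
                                expr_fm, k=config.impute_k)
    ic50_fm = _pre.impute_real(_pre.FeatureMatrix.from_dataframe(panel.ic50.loc[train_ids]),
                               expr_fm, k=config.impute_k,
                               weighting=config.impute_weighting)
    resp = _pre.binarize_response(
        _pre.ResponseMatrix(list(train_ids), list(panel.ic50.columns),
                            ic50_fm.values, ic50_fm.missing_mask))
    labels = pd.DataFrame(resp.labels, index=train_ids, columns=panel.ic50.columns)

    # --- screening (autoencoder + Boruta) on expression and CNV -----------
    spec = config.autoencoder_spec()
    cnv_df = cnv_fm.to_dataframe()

    def screen_arm(X: pd.DataFrame, name: str) -> list[str]:
        screened = _screen.screen_features(X, spec, config.keep_fraction)
        res = _screen.boruta_select(X[screened], labels, mode=config.boruta_mode,
                                    max_iter=config.boruta_max_iter,
                                    alpha=config.boruta_alpha, seed=config.seed,
                                    n_trees=config.boruta_trees)
        if res.confirmed:
            return res.confirmed
        logger.warning("no %s feature confirmed by Boruta; falling back to the "
                       "autoencoder screen", name)
        return screened

    expr_sel = screen_arm(expr, "expression")
    cnv_sel = screen_arm(cnv_df, "CNV")

    # --- mutational-signature arm -----------------------------------------
    hmm = mmm = None
    activities = None
    mut_df = mut_fm.to_dataframe()
    mut_sel = list(mut_df.columns)
    if panel.maf is not None:
        maf_train = panel.maf[panel.maf["sample"].isin(train_ids)]
        partitions = _mutsig.partition_samples(maf_train, config.close_threshold_bp)
        close_runs = [r for p in partitions.values() for r in p.close_runs()]
        iso_list = [p.isolated_categories() for p in partitions.values()]
        isolated = (np.concatenate(iso_list) if iso_list else np.empty(0, dtype=int))
        if not close_runs or isolated.size == 0:
            raise ValueError("mutation table lacks close runs or isolated "
                             "mutations; cannot fit the signature models")
        fixed_E = _load_signature_profiles(config)
        t = fixed_E.shape[0] if fixed_E is not None else config.n_signatures
        hmm = _mutsig.fit_hmm(close_runs, t, fixed_E=fixed_E,
                              n_restarts=config.hmm_restarts,
                              max_iter=config.hmm_max_iter, tol=config.hmm_tol,
                              seed=config.seed)
        mmm = _mutsig.fit_mmm(isolated, t, fixed_E=fixed_E, seed=config.seed)
        activities = _mutsig.activity_matrix(partitions, hmm, mmm,
                                             normalized=config.normalized_activities)
        selected, _table = _mutsig.select_genes(expr, activities,
                                                rho_threshold=config.rho_threshold,
                                                use_abs=config.rho_use_abs)
        selected = [g for g in selected if g in mut_df.columns]
        if selected:
            mut_sel = selected
        else:
            logger.warning("signature arm selected no genes; using all "
                           "mutation features")

    # --- similarities ------------------------------------------------------
    ic50_df = ic50_fm.to_dataframe()
    if config.ic50_log:
        ic50_df = np.sign(ic50_df) * np.log1p(ic50_df.abs())
    s_exp = _sim.pearson_similarity(expr[expr_sel])
    s_cnv = _sim.pearson_similarity(cnv_df[cnv_sel])
    s_mut = _sim.jaccard_similarity(mut_df[mut_sel])
    s_ic50 = _sim.pearson_similarity(ic50_df)
    s_tissue = _sim.tissue_similarity(panel.tissue.loc[train_ids])
    sim_cl = _sim.combine_similarities(s_exp, s_cnv, s_mut, s_ic50, s_tissue,
                                       config.sim_weights)
    s_drug = _sim.jaccard_similarity(panel.fingerprints)

    n, m = len(train_ids), panel.fingerprints.shape[0]
    k_cell = min(config.k, n - 1)
    k_drug = min(config.k, m - 1)
    H_c = _lmf.laplacian(_sim.knn_adjacency(sim_cl, k_cell))
    H_d = _lmf.laplacian(_sim.knn_adjacency(s_drug, k_drug))

    model = _lmf.train(labels.to_numpy(), H_c, H_d, config.lmf_hyper(),
                       cell_ids=list(train_ids),
                       drug_ids=list(panel.ic50.columns))
    estimator = _lmf.fit_sim_ic50_estimator(
        s_exp.S, s_cnv.S, s_mut.S, s_tissue.S, s_ic50.S,
        max_depth=config.tree_max_depth, seed=config.seed)

    return FittedPipeline(
        train_ids=list(train_ids), expr_features=expr_sel,
        cnv_features=cnv_sel, mut_features=mut_sel,
        expr_train=expr, cnv_train=cnv_df, mut_train=mut_df, labels=labels,
        medians=resp.medians, tissue_train=panel.tissue.loc[train_ids],
        sims={"exp": s_exp, "cnv": s_cnv, "mut": s_mut, "ic50": s_ic50,
              "tissue": s_tissue, "cl": sim_cl, "drug": s_drug},
        model=model, sim_ic50_estimator=estimator, config=config,
        hmm=hmm, mmm=mmm, activities=activities)


def predict_new_cell_lines(fitted: FittedPipeline, panel: SyntheticPanel,
                           test_ids: list[str]) -> pd.DataFrame:
    """Cold-start sensitivity probabilities for held-out cell lines
    (rows) across all drugs (columns)."""
    cfg = fitted.config
    train_ids = fitted.train_ids
    expr_train_all = fitted.expr_train.to_numpy()
    expr_new_all = panel.expression.loc[test_ids].to_numpy()

    cnv_new = _pre.impute_new_real(
        _pre.FeatureMatrix.from_dataframe(panel.cnv.loc[test_ids]),
        _pre.FeatureMatrix.from_dataframe(fitted.cnv_train),
        expr_new_all, expr_train_all, k=cfg.impute_k,
        weighting=cfg.impute_weighting).to_dataframe()
    mut_new = _pre.impute_new_binary(
        _pre.FeatureMatrix.from_dataframe(panel.mutation.loc[test_ids]),
        _pre.FeatureMatrix.from_dataframe(fitted.mut_train),
        expr_new_all, expr_train_all, k=cfg.impute_k).to_dataframe()

    expr_sel_train = fitted.expr_train[fitted.expr_features].to_numpy()
    cnv_sel_train = fitted.cnv_train[fitted.cnv_features].to_numpy()
    mut_sel_train = fitted.mut_train[fitted.mut_features].to_numpy()

    rows = {}
    for cid in test_ids:
        r_exp = _sim.pearson_to_rows(
            panel.expression.loc[cid, fitted.expr_features].to_numpy(), expr_sel_train)
        r_cnv = _sim.pearson_to_rows(
            cnv_new.loc[cid, fitted.cnv_features].to_numpy(), cnv_sel_train)
        r_mut = _sim.jaccard_to_rows(
            mut_new.loc[cid, fitted.mut_features].to_numpy(), mut_sel_train)
        r_tissue = _sim.tissue_to_rows(panel.tissue.loc[cid], fitted.tissue_train)
        r_ic50 = _lmf.estimate_sim_ic50_new((r_exp, r_cnv, r_mut, r_tissue),
                                            fitted.sim_ic50_estimator)
        r_cl = _sim.combine_rows((r_exp, r_cnv, r_mut, r_ic50, r_tissue),
                                 cfg.sim_weights)
        k_cell = min(cfg.k, len(train_ids))
        _u, _b, probs = _lmf.infer_new_cell_line(r_cl, fitted.model, k_cell,
                                                 weighted=cfg.cold_start_weighted)
        rows[cid] = probs
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(panel.ic50.columns))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_metrics(probs: pd.DataFrame, truth_labels: pd.DataFrame,
                  threshold: float) -> dict:
    """Pooled metrics over observed test pairs; AUC over pairs of drugs
    with two-class test labels."""
    mask = truth_labels.notna()
    y_true = truth_labels.to_numpy()[mask.to_numpy()]
    y_prob = probs.to_numpy()[mask.to_numpy()]
    y_pred = _lmf.classify(y_prob, threshold)
    out = metrics(confusion_counts(y_true.astype(int), y_pred))
    auc_scores, auc_labels = [], []
    for d in truth_labels.columns:
        col = truth_labels[d].dropna()
        if col.nunique() < 2:
            logger.info("fold AUC: drug %s single-class in test; excluded", d)
            continue
        auc_scores.append(probs.loc[col.index, d].to_numpy())
        auc_labels.append(col.to_numpy())
    if auc_scores:
        out["auc"] = auc(np.concatenate(auc_scores),
                         np.concatenate(auc_labels).astype(int))
    else:
        out["auc"] = float("nan")
    return out


def per_drug_report(probs: pd.DataFrame, truth_labels: pd.DataFrame,
                    ic50: pd.DataFrame) -> pd.DataFrame:
    """Per-drug breakdown: AUC where defined, and the Pearson correlation
    between predicted probability and the observed response score."""
    rows = []
    for d in truth_labels.columns:
        col = truth_labels[d].dropna()
        d_auc = float("nan")
        if col.nunique() == 2:
            d_auc = auc(probs.loc[col.index, d].to_numpy(), col.to_numpy().astype(int))
        obs = ic50[d].dropna()
        common = obs.index.intersection(probs.index)
        r = float("nan")
        if len(common) >= 3 and obs.loc[common].std() > 0:
            p = probs.loc[common, d]
            if p.std() > 0:
                r = float(np.corrcoef(p, -obs.loc[common])[0, 1])
        rows.append((d, d_auc, r))
    return pd.DataFrame(rows, columns=["drug", "auc", "pearson_prob_vs_sensitivity"])


def cross_validate(panel: SyntheticPanel, config: PipelineConfig,
                   plan: CvPlan | None = None) -> tuple[pd.DataFrame, dict]:
    """Repeated tenfold cross-validation over cell lines with cold-start
    test prediction.  Returns the per-(repeat, fold) metric table and the
    mean over folds and repeats."""
    cell_ids = panel.cell_ids
    if plan is None:
        plan = make_cv_plan(cell_ids, config.n_folds, config.n_repeats, config.seed)
    records = []
    for rep in range(plan.n_repeats):
        for fold_idx, test_pos in enumerate(plan.folds(rep)):
            test_ids = [cell_ids[i] for i in test_pos]
            train_ids = [c for c in cell_ids if c not in set(test_ids)]
            assert not set(train_ids) & set(test_ids)
            fitted = fit_pipeline(panel, train_ids, config)
            probs = predict_new_cell_lines(fitted, panel, test_ids)
            # ground-truth labels from *observed* test IC50 vs training medians
            ic50_test = panel.ic50.loc[test_ids]
            truth = (ic50_test < fitted.medians).astype(float).where(ic50_test.notna())
            fm = _fold_metrics(probs, truth, config.threshold)
            fm.pop("zero_denominator_flags", None)
            records.append({"repeat": rep, "fold": fold_idx, **fm})
    table = pd.DataFrame(records)
    mean = {k: float(table[k].mean()) for k in table.columns
            if k not in ("repeat", "fold")}
    return table, mean
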