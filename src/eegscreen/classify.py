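"""Nested leave-one-out classification and univariate ROC thresholding.

For every LOOCV split the *entire* screening stack - propensity model,
matching, weighted per-feature regressions, Bonferroni ranking - is re-run
on the training participants only; the top-K features feed a greedy forward
selection over L2-penalized (ridge) logistic models whose regularization
strength is grid-searched by inner stratified cross-validation on ROC-AUC,
with the minority class upweighted inversely to prevalence. The selected
model predicts the single held-out participant, so no test-sample
information reaches feature selection or model fitting.

The ridge logistic solver is a small Newton/IRLS optimizer (penalty
excludes the intercept); scikit-learn only provides the stratified fold
iterator here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .inference import run_inference
from .matching import compute_match_weights, fit_propensity, ipw_weights, optimal_full_match

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ridge logistic regression (L2 penalty, intercept unpenalized)
# ---------------------------------------------------------------------------

@dataclass
class RidgeLogisticModel:
    intercept: float
    coef: np.ndarray
    mean: np.ndarray | None = None  # standardization, when fitted standardized
    scale: np.ndarray | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mean is not None:
            X = (X - self.mean) / self.scale
        return self.intercept + X @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.decision(X), -35, 35)))


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Balanced weights: each class contributes equally to the loss."""
    n = y.size
    w = np.empty(n)
    for cls in (0, 1):
        n_cls = (y == cls).sum()
        if n_cls == 0:
            raise ValueError("both classes required")
        w[y == cls] = n / (2.0 * n_cls)
    return w


def ridge_logistic_fit(X: np.ndarray, y: np.ndarray, alpha: float,
                       class_weight: str | None = "balanced",
                       standardize: bool = False,
                       max_iter: int = 100, tol: float = 1e-10) -> RidgeLogisticModel:
    """Fit sum_i w_i logloss + (alpha/2)||coef||^2 by damped Newton.

    ``class_weight='balanced'`` upweights the minority class inversely to
    prevalence. With ``standardize`` the features are scaled to training
    mean 0 / SD 1 first (constant columns are left unscaled and end up with
    zero coefficients).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        X = (X - mean) / scale
    n, d = X.shape
    w = _class_weights(y.astype(int)) if class_weight == "balanced" else np.ones(n)
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(d + 1)
    pen = np.full(d + 1, alpha)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (w * (p - y)) + pen * beta
        H = (Z * (w * p * (1 - p))[:, None]).T @ Z + np.diag(pen)
        H[0, 0] += 1e-10  # keep the intercept row invertible in degenerate cases
        step = np.linalg.solve(H, grad)
        beta -= step
        if np.abs(step).max() < tol:
            break
    return RidgeLogisticModel(float(beta[0]), beta[1:], mean, scale)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(labels, scores) -> float:
    """Mann-Whitney ROC-AUC: P(random positive outranks random negative),
    ties counting one half."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def prc_auc(labels, scores) -> float:
    """Precision-recall AUC by trapezoidal integration over recall.

    The no-skill reference for this curve is the positive prevalence.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("PRC-AUC undefined with a single class")
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    # evaluate at distinct thresholds only (tie-safe)
    distinct = np.r_[np.flatnonzero(np.diff(s[order])), y.size - 1]
    tp = np.cumsum(ys)[distinct]
    fp = (distinct + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall = np.r_[0.0, recall]
    precision = np.r_[1.0 if precision.size == 0 else precision[0], precision]
    return float(np.trapezoid(precision, recall))


def bootstrap_ci(labels, scores, metric, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Stratified percentile 95% bootstrap interval for a ranking metric."""
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, pos.size, replace=True),
                    rng.choice(neg, neg.size, replace=True)]
        vals[b] = metric(y[idx], s[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def confusion_and_pv(labels, probabilities, threshold: float = 0.5):
    """Confusion matrix at ``prob > threshold`` plus PPV and NPV.

    Returns ``(matrix, ppv, npv)`` with matrix rows = true class (0, 1) and
    columns = predicted class; undefined predictive values are NaN.
    """
    y = np.asarray(labels, dtype=int)
    pred = (np.asarray(probabilities, dtype=float) > threshold).astype(int)
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    tp = int(((y == 1) & (pred == 1)).sum())
    matrix = np.array([[tn, fp], [fn, tp]])
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return matrix, float(ppv), float(npv)


# ---------------------------------------------------------------------------
# nested feature selection
# ---------------------------------------------------------------------------

def rank_features_nested(features: pd.DataFrame, meta: pd.DataFrame,
                         cfg: PipelineConfig, k: int | None = None) -> list[str]:
    """Re-run matching + screening within a training split; return the top-K
    feature names by Bonferroni-adjusted p (ties by name)."""
    k = k or cfg.classify.top_k
    groups = meta["group"]
    try:
        pm = fit_propensity(meta, cfg.covariates)
        if cfg.matching_method == "ipw":
            weights = ipw_weights(pm.scores, groups.loc[pm.scores.index])
        else:
            mr = optimal_full_match(pm.scores, groups.loc[pm.scores.index])
            weights = compute_match_weights(mr, groups.loc[pm.scores.index])
    except ValueError as exc:
        # tiny training splits can separate perfectly; fall back to an
        # unweighted screen rather than losing the split
        logger.warning("nested ranking: %s; using uniform weights", exc)
        weights = pd.Series(1.0, index=meta.index)
    table = run_inference(features, meta, weights, cfg)
    usable = table[table["p"].notna()]
    if len(usable) < k:
        logger.info("nested ranking: only %d usable features for K=%d", len(usable), k)
    return usable["feature"].head(k).tolist()


def _grid_search_auc(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig,
                     seed: int) -> tuple[float, float]:
    """Inner stratified CV over the alpha grid; returns (best AUC, best alpha)."""
    n_splits = min(cfg.classify.inner_folds, int((y == 1).sum()), int((y == 0).sum()))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_auc, best_alpha = -np.inf, cfg.classify.alpha_grid[0]
    for alpha in cfg.classify.alpha_grid:
        oof = np.empty(y.size)
        ok = True
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                ok = False
                break
            model = ridge_logistic_fit(X[tr], y[tr], alpha, standardize=True)
            oof[te] = model.predict_proba(X[te])
        if not ok:
            continue
        auc = roc_auc(y, oof)
        if auc > best_auc:
            best_auc, best_alpha = auc, alpha
    return best_auc, best_alpha


def forward_select(X: pd.DataFrame, y: np.ndarray, candidates: list[str],
                   cfg: PipelineConfig, seed: int = 0) -> list[str]:
    """Greedy forward selection maximizing inner-CV ROC-AUC.

    The first feature is always kept (non-empty guarantee); later additions
    must improve the criterion by more than ``forward_tol``. Deterministic
    given the seed: candidates are scanned in their given order and ties
    keep the earlier candidate.
    """
    if not candidates:
        raise ValueError("no candidate features")
    selected: list[str] = []
    best_auc = -np.inf
    remaining = list(candidates)
    yv = np.asarray(y, dtype=float)
    while remaining:
        step_best, step_feat = -np.inf, None
        for feat in remaining:
            cols = selected + [feat]
            auc, _ = _grid_search_auc(X[cols].to_numpy(float), yv, cfg, seed)
            if auc > step_best:
                step_best, step_feat = auc, feat
        if not selected or step_best > best_auc + cfg.classify.forward_tol:
            selected.append(step_feat)
            remaining.remove(step_feat)
            best_auc = step_best
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    predictions: pd.DataFrame  # participant_id, prob, label, selected_features
    metrics: dict = field(default_factory=dict)


def _prepare_split_features(train: pd.DataFrame, test: pd.Series,
                            candidates: list[str], max_missing_frac: float):
    """Drop over-missing candidates; impute the rest with training medians."""
    keep = [c for c in candidates
            if train[c].isna().mean() <= max_missing_frac]
    med = train[keep].median()
    Xtr = train[keep].fillna(med)
    Xte = test[keep].fillna(med)
    return keep, Xtr, Xte


def loocv_classify(features: pd.DataFrame, meta: pd.DataFrame,
                   cfg: PipelineConfig | None = None,
                   mode: str = "eeg") -> CVResult:
    """Leave-one-out CV with the screening stack nested in every split.

    ``mode='eeg'`` ranks features by the nested inference step and forward-
    selects among the top K; ``mode='baseline'`` uses only age and sex as
    features, bypassing selection. Returns one out-of-fold probability per
    participant plus ROC-AUC / PRC-AUC with bootstrap CIs, the confusion
    matrix at the configured threshold, PPV and NPV.
    """
    cfg = cfg or PipelineConfig()
    ids = list(meta.index)
    if len(ids) < 10:
        raise ValueError("LOOCV requires at least 10 participants")
    y_all = meta["group"].astype(int)
    if y_all.nunique() < 2:
        raise ValueError("both classes required")
    base_seed = cfg.stage_seed(f"loocv-{mode}")
    records = []
    for i, pid in enumerate(ids):
        train_ids = [p for p in ids if p != pid]
        tr_meta = meta.loc[train_ids]
        y_tr = y_all.loc[train_ids].to_numpy()
        fold_seed = (base_seed + i) % (2**31)
        if len(np.unique(y_tr)) < 2:
            prob = float(y_tr.mean())
            logger.warning("split %s lost a class; predicting prevalence", pid)
            records.append({"participant_id": pid, "fold": i, "prob": prob,
                            "label": int(y_all.loc[pid]), "selected_features": ""})
            continue
        if mode == "baseline":
            from .matching import design_matrix
            Xfull = design_matrix(meta, ("age_months", "sex"))
            med = Xfull.loc[train_ids].median()
            Xtr = Xfull.loc[train_ids].fillna(med)
            Xte = Xfull.loc[[pid]].fillna(med)
            selected = list(Xtr.columns)
            _, best_alpha = _grid_search_auc(Xtr.to_numpy(float), y_tr.astype(float),
                                            cfg, fold_seed)
            model = ridge_logistic_fit(Xtr.to_numpy(float), y_tr.astype(float),
                                       best_alpha, standardize=True)
            prob = float(model.predict_proba(Xte.to_numpy(float))[0])
        else:
            tr_feats = features.loc[train_ids]
            topk = rank_features_nested(tr_feats, tr_meta, cfg)
            keep, Xtr, Xte_row = _prepare_split_features(
                tr_feats, features.loc[pid], topk, cfg.classify.max_missing_frac)
            if not keep:
                prob = float(y_tr.mean())
                logger.warning("split %s: no usable candidates; predicting prevalence", pid)
                records.append({"participant_id": pid, "fold": i, "prob": prob,
                                "label": int(y_all.loc[pid]), "selected_features": ""})
                continue
            selected = forward_select(Xtr, y_tr, keep, cfg, fold_seed)
            _, best_alpha = _grid_search_auc(Xtr[selected].to_numpy(float),
                                            y_tr.astype(float), cfg, fold_seed)
            model = ridge_logistic_fit(Xtr[selected].to_numpy(float),
                                       y_tr.astype(float), best_alpha,
                                       standardize=True)
            prob = float(model.predict_proba(
                Xte_row[selected].to_numpy(float).reshape(1, -1))[0])
        records.append({"participant_id": pid, "fold": i, "prob": prob,
                        "label": int(y_all.loc[pid]),
                        "selected_features": "|".join(selected)})
    preds = pd.DataFrame(records)
    metrics = compute_cv_metrics(preds, cfg)
    return CVResult(preds, metrics)


def compute_cv_metrics(preds: pd.DataFrame, cfg: PipelineConfig | None = None) -> dict:
    """Aggregate LOOCV out-of-fold predictions into the reported metrics."""
    cfg = cfg or PipelineConfig()
    y = preds["label"].to_numpy(int)
    p = preds["prob"].to_numpy(float)
    boot_seed = cfg.stage_seed("bootstrap")
    roc = roc_auc(y, p)
    prc = prc_auc(y, p)
    roc_lo, roc_hi = bootstrap_ci(y, p, roc_auc, cfg.classify.bootstrap_reps, boot_seed)
    prc_lo, prc_hi = bootstrap_ci(y, p, prc_auc, cfg.classify.bootstrap_reps, boot_seed)
    matrix, ppv, npv = confusion_and_pv(y, p, cfg.classify.threshold)
    return {
        "n": int(y.size),
        "roc_auc": {"point": roc, "lo": roc_lo, "hi": roc_hi},
        "prc_auc": {"point": prc, "lo": prc_lo, "hi": prc_hi},
        "confusion": matrix.tolist(),
        "ppv": ppv,
        "npv": npv,
        "threshold": cfg.classify.threshold,
    }


# ---------------------------------------------------------------------------
# univariate ROC thresholding
# ---------------------------------------------------------------------------

@dataclass
class UnivariateCut:
    feature: str
    stratum: str
    threshold: float
    direction: str  # ">" : positive iff value > threshold; "<" likewise
    sensitivity: float
    specificity: float


def univariate_threshold(values, labels, feature: str = "",
                         stratum: str = "") -> UnivariateCut:
    """Optimal single-feature cutoff: the ROC point closest to the top-left.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; both orientations are scanned and the better one reported. Ties
    prefer the lower threshold, then the ``>`` direction.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    ok = ~np.isnan(v)
    v, y = v[ok], y[ok]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes required within the stratum")
    uniq = np.unique(v)
    if uniq.size < 2:
        cands = np.array([uniq[0]])
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best = None
    for direction in (">", "<"):
        for thr in cands:
            pred = v > thr if direction == ">" else v < thr
            sens = (pred & (y == 1)).sum() / n_pos
            spec = (~pred & (y == 0)).sum() / n_neg
            dist = float(np.hypot(1 - sens, 1 - spec))
            key = (dist, 0 if direction == ">" else 1, thr)
            if best is None or key < best[0]:
                best = (key, thr, direction, sens, spec)
    _, thr, direction, sens, spec = best
    return UnivariateCut(feature, stratum, float(thr), direction,
                         float(sens), float(spec))


def univariate_cut_table(features: pd.DataFrame, meta: pd.DataFrame,
                         feature_names: list[str]) -> pd.DataFrame:
    """Per-sex univariate cutoffs for each listed feature."""
    rows = []
    for feat in feature_names:
        for sex in ("male", "female"):
            sel = meta.index[meta["sex"] == sex]
            sel = sel.intersection(features.index)
            if len(sel) == 0:
                continue
            y = meta.loc[sel, "group"].astype(int)
            try:
                cut = univariate_threshold(features.loc[sel, feat], y, feat, sex)
            except ValueError:
                continue
            rows.append({"feature": feat, "sex": sex, "threshold": cut.threshold,
                         "direction": cut.direction, "sensitivity": cut.sensitivity,
                         "specificity": cut.specificity})
    return pd.DataFrame(rows, columns=["feature", "sex", "threshold", "direction",
                                       "sensitivity", "specificity"])
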