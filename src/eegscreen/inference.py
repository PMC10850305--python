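"""Per-feature weighted outcome regressions with Bonferroni screening.

Each EEG feature is regressed (after a feature-type-specific transform) on
the case/control exposure plus demographic covariates, using the matching or
IPW weights, with heteroskedasticity-robust (HC0 sandwich) standard errors.
Only participants non-missing for a feature enter its regression - weights
are renormalized within that subset - so the per-feature case/control counts
vary with channel missingness. The family-wise screen is Bonferroni over
the number of features attempted.

With heavy matching weights the effective number of controls can be far
below the nominal count, and a normal reference for the robust z statistic
is badly anticonservative exactly in the Bonferroni-relevant tail. The
exposure test therefore uses a t reference with Satterthwaite degrees of
freedom computed from the sandwich quadratic form (the Bell-McCaffrey
small-sample adjustment); the df depends only on the design and weights, so
it is computed once per missingness pattern.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .matching import design_matrix

logger = logging.getLogger(__name__)

INFERENCE_COLUMNS = ["feature", "transform", "coefficient", "std_error",
                     "n_case", "n_control", "p", "p_adjusted", "significant"]


def choose_transform(values: np.ndarray) -> str:
    """Pick the variance-stabilizing transform from the observed range.

    Logit for unit-interval features (relative power, coherence; exact 0/1
    boundary values are nudged at transform time), log for strictly positive
    unbounded features (SD, sample entropy), identity otherwise (means,
    skewness, kurtosis, binary flags).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return "identity"
    in_unit = (v >= 0).all() and (v <= 1).all()
    if in_unit and not np.isin(v, (0.0, 1.0)).all():
        return "logit"
    if (v > 0).all():
        return "log"
    return "identity"


def transform_values(values: np.ndarray, kind: str, eps: float = 1e-6) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if kind == "log":
        return np.log(v)
    if kind == "logit":
        v = np.clip(v, eps, 1.0 - eps)
        return np.log(v) - np.log1p(-v)
    return v


def _wls_sandwich(X: np.ndarray, Y: np.ndarray, w: np.ndarray,
                  leverage_correct: bool = True):
    """Weighted least squares of every column of Y on X with sandwich errors.

    The variance estimator is the HC3 (jackknife-style leverage-corrected)
    sandwich by default - the small-sample form that stays calibrated when
    matching weights concentrate the effective sample - or HC0 with
    ``leverage_correct=False``. Returns (coefficients, robust SEs), each of
    shape (p, m) for the m outcome columns.
    """
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    bread = np.linalg.pinv(XtWX)
    B = bread @ (Xw.T @ Y)  # p x m
    E = Y - X @ B  # n x m residuals
    WE = w[:, None] * E
    if leverage_correct:
        h = np.einsum("ip,pq,iq->i", X, bread, Xw)  # weighted leverages
        WE = WE / np.clip(1.0 - h, 1e-8, None)[:, None]
    meat = np.einsum("ip,iq,im->pqm", X, X, WE**2)
    V = np.einsum("ab,bcm,cd->adm", bread, meat, bread)
    se = np.sqrt(np.maximum(np.einsum("aam->am", V), 0.0))
    return B, se


def _satterthwaite_df(X: np.ndarray, w: np.ndarray, col: int = 1) -> float:
    """Bell-McCaffrey degrees of freedom for the sandwich test of X[:, col].

    Under a homoskedastic reference the HC3 variance of the contrast is a
    quadratic form e' M e; matching its first two moments to a chi-square
    gives df = (tr M)^2 / tr(M^2). Depends only on the design and weights.
    """
    n = X.shape[0]
    Xw = X * w[:, None]
    bread = np.linalg.pinv(X.T @ Xw)
    h = np.einsum("ip,pq,iq->i", X, bread, Xw)
    d = (X @ bread[:, col]) * w / np.clip(1.0 - h, 1e-8, None)
    K = np.eye(n) - X @ (bread @ Xw.T)
    A = d[:, None] * K
    tr_m = float((A * A).sum())
    g = A @ A.T
    tr_m2 = float((g * g).sum())
    if tr_m2 <= 0:
        return float(n - X.shape[1])
    return tr_m**2 / tr_m2


def weighted_feature_regression(y: np.ndarray, exposure: np.ndarray,
                                covariates: np.ndarray | None,
                                weights: np.ndarray):
    """One weighted regression: returns (coefficient, robust SE, p) for the
    exposure term. With equal weights this reduces to ordinary least squares
    with heteroskedasticity-robust errors.
    """
    from scipy.stats import t as t_dist
    n = y.shape[0]
    cols = [np.ones(n), np.asarray(exposure, float)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    w = np.asarray(weights, float)
    B, se = _wls_sandwich(X, y.reshape(-1, 1), w)
    coef, s = float(B[1, 0]), float(se[1, 0])
    df = _satterthwaite_df(X, w)
    p = 2.0 * t_dist.sf(abs(coef) / s, df) if s > 0 else (0.0 if coef != 0 else 1.0)
    return coef, s, float(p)


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Family-wise adjustment p_adj = min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def run_inference(features: pd.DataFrame, meta: pd.DataFrame, weights: pd.Series,
                  cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Screen every feature with a weighted covariate-adjusted regression.

    Participants enter a feature's regression iff the feature and all
    covariates are non-missing and their weight is positive; group weights
    are renormalized to the subset's group sizes. The Bonferroni multiplier
    is the number of features attempted (the full column count). Rows come
    back sorted by adjusted p, ties broken by feature name.
    """
    from scipy.stats import t as t_dist
    cfg = cfg or PipelineConfig()
    common = features.index.intersection(meta.index).intersection(weights.index)
    feats = features.loc[common]
    md = meta.loc[common]
    w_all = weights.loc[common].to_numpy(float)
    cov = design_matrix(md, cfg.covariates)
    cov_ok = cov.notna().all(axis=1).to_numpy() & (w_all > 0)
    group = md["group"].to_numpy(int)

    m_features = features.shape[1]
    values = feats.to_numpy(float)
    names = list(feats.columns)

    # transform per feature (decided on the analyzed values)
    kinds = [choose_transform(values[:, j]) for j in range(len(names))]
    Y = np.empty_like(values)
    for j, kind in enumerate(kinds):
        Y[:, j] = transform_values(values[:, j], kind, cfg.logit_eps)

    present = ~np.isnan(values) & cov_ok[:, None]
    rows: list[dict] = []
    # group features sharing a missingness pattern: one vectorized WLS each
    patterns: dict[bytes, list[int]] = {}
    for j in range(len(names)):
        patterns.setdefault(present[:, j].tobytes(), []).append(j)

    covX = cov.to_numpy(float)
    for key, js in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        g = group[mask]
        n_case, n_control = int((g == 1).sum()), int((g == 0).sum())
        if n_case < 2 or n_control < 2:
            for j in js:
                logger.info("inference: skipped %s (insufficient group sizes)", names[j])
                rows.append({"feature": names[j], "transform": kinds[j],
                             "coefficient": np.nan, "std_error": np.nan,
                             "n_case": n_case, "n_control": n_control,
                             "p": np.nan, "p_adjusted": np.nan, "significant": False})
            continue
        w = w_all[mask].copy()
        for gv, n_g in ((1, n_case), (0, n_control)):  # renormalize within subset
            s = w[g == gv].sum()
            if s > 0:
                w[g == gv] *= n_g / s
        X = np.column_stack([np.ones(mask.sum()), g.astype(float), covX[mask]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            for j in js:
                logger.info("inference: skipped %s (rank-deficient design)", names[j])
                rows.append({"feature": names[j], "transform": kinds[j],
                             "coefficient": np.nan, "std_error": np.nan,
                             "n_case": n_case, "n_control": n_control,
                             "p": np.nan, "p_adjusted": np.nan, "significant": False})
            continue
        B, SE = _wls_sandwich(X, Y[np.ix_(mask, js)], w)
        coefs, ses = B[1], SE[1]
        df = _satterthwaite_df(X, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = 2.0 * t_dist.sf(np.abs(coefs) / ses, df)
        for idx, j in enumerate(js):
            rows.append({"feature": names[j], "transform": kinds[j],
                         "coefficient": float(coefs[idx]),
                         "std_error": float(ses[idx]),
                         "n_case": n_case, "n_control": n_control,
                         "p": float(pvals[idx]), "p_adjusted": np.nan,
                         "significant": False})

    table = pd.DataFrame(rows, columns=INFERENCE_COLUMNS)
    table["p_adjusted"] = bonferroni_adjust(table["p"].to_numpy(), m_features)
    table["significant"] = table["p_adjusted"] < cfg.alpha_level
    table = table.sort_values(["p_adjusted", "feature"],
                              na_position="last").reset_index(drop=True)
    return table
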