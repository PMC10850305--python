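"""Propensity scores, optimal full matching, analysis weights, balance.

Optimal full matching partitions cases and controls into matched sets (one
case with k controls, or k cases with one control) minimizing the total
within-set case-control distance on the logit of the propensity score. A
full match is exactly a minimum-weight edge cover of the bipartite
case-control graph whose components are stars, so the solver here uses the
classical exact reduction of minimum-weight edge cover to an assignment
problem on reduced costs (each unit's cheapest partner is subtracted; a
minimum-weight partial matching of the reduced costs is found with the
Hungarian algorithm; uncovered units then attach to their cheapest
partner). Deterministic tie-breaking follows participant-id order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class PropensityModel:
    covariates: tuple[str, ...]
    params: pd.Series
    scores: pd.Series  # index: participant_id, strictly inside (0, 1)
    dropped: list[str]  # participants without complete covariates


@dataclass
class MatchResult:
    """Matched-set partition: list of (case_ids, control_ids) per set."""

    sets: list[tuple[list[str], list[str]]]
    set_id: pd.Series  # participant -> set index (NaN if unmatched)
    unmatched: list[str]

    @property
    def total_distance(self) -> float:
        return self._total_distance

    _total_distance: float = 0.0


def design_matrix(meta: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Numeric covariate design: sex coded male=1/female=0, others as-is."""
    cols = {}
    for c in covariates:
        if c == "sex":
            cols["sex"] = (meta["sex"] == "male").astype(float)
        else:
            cols[c] = pd.to_numeric(meta[c], errors="coerce")
    return pd.DataFrame(cols, index=meta.index)


def fit_propensity(meta: pd.DataFrame, covariates: tuple[str, ...] = ("age_months", "sex"),
                   eps: float = 1e-9) -> PropensityModel:
    """Maximum-likelihood logistic regression of group on covariates.

    Participants with missing covariates are dropped (logged). Perfect
    separation raises with advice to reduce the covariate set.
    """
    X = design_matrix(meta, covariates)
    ok = X.notna().all(axis=1)
    dropped = list(meta.index[~ok])
    if dropped:
        logger.info("propensity: dropped %d participants with missing covariates", len(dropped))
    Xc = sm.add_constant(X[ok], has_constant="add")
    y = meta.loc[ok, "group"].astype(float)
    if y.nunique() < 2:
        raise ValueError("both groups required to fit a propensity model")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(
            "propensity model failed (possible perfect separation); "
            "consider reducing the covariate set"
        ) from exc
    scores = res.predict(Xc).clip(eps, 1 - eps)
    scores.name = "propensity"
    return PropensityModel(tuple(covariates), res.params, scores, dropped)


# ---------------------------------------------------------------------------
# optimal full match
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def optimal_full_match(scores: pd.Series, groups: pd.Series,
                       max_load_factor: float | None = 2.0) -> MatchResult:
    """Optimal full matching on |logit(e_i) - logit(e_j)| distances.

    ``max_load_factor`` restricts the matched-set structure: no unit may
    anchor more than ``ceil(factor * group-size ratio)`` partners. Without
    a restriction, near-tied scores (the usual case once covariates are
    balanced) let a single control absorb dozens of cases, collapsing the
    effective sample size of the weighted analysis - the same reason the
    standard full-matching tools expose set-size restrictions. Overloaded
    anchors shed their worst-fitting partners to the nearest under-loaded
    alternative. ``None`` disables the restriction, giving the exact
    unrestricted optimum.
    """
    common = scores.index.intersection(groups.index)
    scores = scores.loc[common]
    groups = groups.loc[common]
    case_ids = sorted(scores.index[groups == 1])
    ctrl_ids = sorted(scores.index[groups == 0])
    if not case_ids or not ctrl_ids:
        raise ValueError("full matching requires both groups non-empty")
    lc = _logit(scores.loc[case_ids].to_numpy(float))
    lk = _logit(scores.loc[ctrl_ids].to_numpy(float))
    D = np.abs(lc[:, None] - lk[None, :])
    edges = _min_weight_edge_cover(D)
    if max_load_factor is not None:
        edges = _rebalance_loads(edges, D, max_load_factor)

    # connected components of the star forest -> matched sets
    case_sets: dict[int, set] = {}
    ctrl_sets: dict[int, set] = {}
    parent: dict[tuple, tuple] = {}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, j in edges:
        for node in (("c", i), ("k", j)):
            parent.setdefault(node, node)
        ri, rj = find(("c", i)), find(("k", j))
        if ri != rj:
            parent[ri] = rj
    comp: dict[tuple, tuple[set, set]] = {}
    for i, j in edges:
        root = find(("c", i))
        cs, ks = comp.setdefault(root, (set(), set()))
        cs.add(i)
        ks.add(j)

    sets = []
    total = 0.0
    for cs, ks in comp.values():
        if min(len(cs), len(ks)) != 1:  # star-forest guarantee
            raise AssertionError("full match produced a non-star component")
        sets.append((sorted(case_ids[i] for i in cs), sorted(ctrl_ids[j] for j in ks)))
    sets.sort(key=lambda s: (s[0], s[1]))
    for i, j in edges:
        total += D[i, j]

    set_id = pd.Series(np.nan, index=list(scores.index), dtype=float)
    for s_idx, (cs, ks) in enumerate(sets):
        for pid in cs + ks:
            set_id[pid] = s_idx
    mr = MatchResult(sets, set_id, unmatched=[])
    mr._total_distance = float(total)
    return mr


def _min_weight_edge_cover(D: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-weight bipartite edge cover (every vertex covered >= once)."""
    nc, nk = D.shape
    mi = D.min(axis=1)
    mj = D.min(axis=0)
    R = D - mi[:, None] - mj[None, :]
    # minimum-weight *partial* matching of R via padded assignment: dummy
    # columns/rows let any unit stay unmatched at zero reduced cost
    big = float(np.abs(R).sum() + 1.0)
    A = np.zeros((nc + nk, nk + nc))
    A[:nc, :nk] = R
    A[:nc, nk:] = big
    A[nc:, :nk] = big
    np.fill_diagonal(A[:nc, nk:], 0.0)
    np.fill_diagonal(A[nc:, :nk], 0.0)
    rows, cols = linear_sum_assignment(A)
    matched = [(int(r), int(c)) for r, c in zip(rows, cols) if r < nc and c < nk]
    edges = set(matched)
    deg_c = np.zeros(nc, int)
    deg_k = np.zeros(nk, int)
    for i, j in edges:
        deg_c[i] += 1
        deg_k[j] += 1
    def _attach(dist_row, degrees):
        # cheapest partner; exact-distance ties spread by current load so
        # degenerate scores (e.g. a single binary covariate) do not pile
        # every unit onto one partner
        best = dist_row.min()
        tied = np.flatnonzero(dist_row <= best + 1e-12)
        return int(tied[np.argmin(degrees[tied])])

    for i in range(nc):
        if deg_c[i] == 0:
            j = _attach(D[i], deg_k)
            edges.add((i, j))
            deg_c[i] += 1
            deg_k[j] += 1
    for j in range(nk):
        if deg_k[j] == 0:
            i = _attach(D[:, j], deg_c)
            edges.add((i, j))
            deg_c[i] += 1
            deg_k[j] += 1
    # prune any edge whose endpoints are both shared (possible only at ties)
    changed = True
    while changed:
        changed = False
        for i, j in sorted(edges, key=lambda e: -D[e[0], e[1]]):
            if deg_c[i] > 1 and deg_k[j] > 1:
                edges.remove((i, j))
                deg_c[i] -= 1
                deg_k[j] -= 1
                changed = True
    return sorted(edges)


def _rebalance_loads(edges: set[tuple[int, int]], D: np.ndarray,
                     factor: float) -> set[tuple[int, int]]:
    """Enforce the set-size restriction on a star-forest edge cover.

    A case anchored by >cap controls (or a control by >cap cases) moves its
    worst-fitting leaves to the nearest alternative anchor with spare
    capacity whose own partners are all leaves (so the result stays a star
    forest). Each move adds the smallest available distance increment.
    """
    nc, nk = D.shape
    cap_k = max(1, int(np.ceil(factor * nc / nk)))  # cases per control
    cap_c = max(1, int(np.ceil(factor * nk / nc)))  # controls per case
    edges = set(edges)
    deg_c = np.zeros(nc, int)
    deg_k = np.zeros(nk, int)
    for i, j in edges:
        deg_c[i] += 1
        deg_k[j] += 1

    def star_safe_controls():
        # controls whose attached cases are all leaves (degree 1)
        bad = {j for i, j in edges if deg_c[i] > 1}
        return [j for j in range(nk) if j not in bad]

    def star_safe_cases():
        bad = {i for i, j in edges if deg_k[j] > 1}
        return [i for i in range(nc) if i not in bad]

    moved = True
    while moved:
        moved = False
        for j in np.argsort(-deg_k):
            while deg_k[j] > cap_k:
                leaves = sorted(i for i, jj in edges if jj == j and deg_c[i] == 1)
                targets = [t for t in star_safe_controls()
                           if t != j and deg_k[t] < cap_k]
                if not leaves or not targets:
                    break
                i, t = min(((i, t) for i in leaves for t in targets),
                           key=lambda e: (D[e[0], e[1]], e))
                edges.remove((i, int(j)))
                edges.add((i, t))
                deg_k[j] -= 1
                deg_k[t] += 1
                moved = True
        for i in np.argsort(-deg_c):
            while deg_c[i] > cap_c:
                leaves = sorted(j for ii, j in edges if ii == i and deg_k[j] == 1)
                targets = [t for t in star_safe_cases()
                           if t != i and deg_c[t] < cap_c]
                if not leaves or not targets:
                    break
                j, t = min(((j, t) for j in leaves for t in targets),
                           key=lambda e: (D[e[1], e[0]], e))
                edges.remove((int(i), j))
                edges.add((t, j))
                deg_c[i] -= 1
                deg_c[t] += 1
                moved = True
    return edges


def compute_match_weights(mr: MatchResult, groups: pd.Series) -> pd.Series:
    """Per-participant analysis weights from a full match.

    Cases weigh 1. A control in a set with T cases and C controls gets a raw
    weight T/C, then control weights are rescaled to sum to the number of
    matched controls. Unmatched participants get weight 0.
    """
    w = pd.Series(0.0, index=groups.index)
    raw_ctrl = {}
    for cs, ks in mr.sets:
        for pid in cs:
            w[pid] = 1.0
        for pid in ks:
            raw_ctrl[pid] = len(cs) / len(ks)
    if raw_ctrl:
        scale = len(raw_ctrl) / sum(raw_ctrl.values())
        for pid, rw in raw_ctrl.items():
            w[pid] = rw * scale
    return w


def ipw_weights(scores: pd.Series, groups: pd.Series, stabilized: bool = True,
                trim: tuple[float, float] = (0.01, 0.99)) -> pd.Series:
    """Inverse-probability-of-treatment weights (ATE form).

    Cases get 1/e, controls 1/(1-e); stabilization multiplies by the group
    prevalence, and scores are symmetrically trimmed to ``trim`` first.
    """
    common = scores.index.intersection(groups.index)
    e = scores.loc[common].clip(*trim)
    g = groups.loc[common]
    prev = float(g.mean())
    w = pd.Series(np.where(g == 1, 1.0 / e, 1.0 / (1.0 - e)), index=common)
    if stabilized:
        w *= np.where(g == 1, prev, 1.0 - prev)
    return w


def balance_table(meta: pd.DataFrame, weights: pd.Series,
                  covariates: tuple[str, ...] = ("age_months", "sex")) -> pd.DataFrame:
    """Standardized mean differences before and after weighting.

    SMD = (weighted case mean - weighted control mean) / pooled unweighted
    SD, with the pooled SD taken as sqrt of the mean of the two group
    variances. Covariates with zero pooled SD are flagged NaN.
    """
    meta = meta.loc[weights.index]
    X = design_matrix(meta, covariates)
    g = meta["group"].to_numpy()
    rows = []
    for c in covariates:
        x = X[c].to_numpy(float)
        ok = ~np.isnan(x)
        xc, xk = x[ok & (g == 1)], x[ok & (g == 0)]
        pooled = np.sqrt((xc.var(ddof=1) + xk.var(ddof=1)) / 2.0)
        wc = weights.to_numpy()[ok & (g == 1)]
        wk = weights.to_numpy()[ok & (g == 0)]
        if pooled == 0 or not np.isfinite(pooled):
            rows.append({"covariate": c, "smd_pre": np.nan, "smd_post": np.nan})
            continue
        pre = (xc.mean() - xk.mean()) / pooled
        post = (np.average(xc, weights=wc) - np.average(xk, weights=wk)) / pooled \
            if wc.sum() > 0 and wk.sum() > 0 else np.nan
        rows.append({"covariate": c, "smd_pre": pre, "smd_post": post})
    return pd.DataFrame(rows)
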