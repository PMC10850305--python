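"""Propensity model, optimal full matching (vs brute force), weights, balance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegscreen.matching import (MatchResult, balance_table,
                                compute_match_weights, fit_propensity,
                                ipw_weights, optimal_full_match)
from eegscreen.synth import SynthConfig, generate_demographics
from eegscreen.types import meta_to_frame


def _meta_frame(groups, ages=None, sexes=None):
    n = len(groups)
    return pd.DataFrame({
        "group": groups,
        "age_months": ages if ages is not None else np.full(n, 36.0),
        "sex": sexes if sexes is not None else ["male"] * n,
    }, index=[f"p{i:03d}" for i in range(n)])


def brute_force_full_match(scores, groups):
    """Oracle: enumerate every full matching (partition into 1:k / k:1 sets
    via all bipartite edge covers that are star forests) and return the
    minimum total distance."""
    logit = lambda p: np.log(p / (1 - p))
    cases = [i for i, g in enumerate(groups) if g == 1]
    ctrls = [i for i, g in enumerate(groups) if g == 0]
    best = np.inf
    edges = list(itertools.product(cases, ctrls))
    for mask in range(1, 1 << len(edges)):
        chosen = [e for b, e in enumerate(edges) if mask >> b & 1]
        cov_c = {e[0] for e in chosen}
        cov_k = {e[1] for e in chosen}
        if cov_c != set(cases) or cov_k != set(ctrls):
            continue
        # star forest: no edge may have both endpoints shared
        deg_c = {c: sum(e[0] == c for e in chosen) for c in cases}
        deg_k = {k: sum(e[1] == k for e in chosen) for k in ctrls}
        if any(deg_c[a] > 1 and deg_k[b] > 1 for a, b in chosen):
            continue
        total = sum(abs(logit(scores[a]) - logit(scores[b])) for a, b in chosen)
        best = min(best, total)
    return best


class TestPropensity:
    def test_null_covariates_give_prevalence(self):
        rng = np.random.default_rng(0)
        meta = _meta_frame([1] * 60 + [0] * 20, ages=rng.normal(36, 10, 80),
                           sexes=rng.choice(["male", "female"], 80).tolist())
        pm = fit_propensity(meta)
        assert np.allclose(pm.scores, 0.75, atol=0.15)

    def test_balanced_binary_covariate_zero_coefficient(self):
        meta = _meta_frame([1, 1, 0, 0], sexes=["male", "female"] * 2,
                           ages=[30.0] * 4)
        pm = fit_propensity(meta, covariates=("sex",))
        assert abs(pm.params["sex"]) < 1e-4

    def test_confounded_cohort_separates_scores(self):
        cfg = SynthConfig(n_case=300, n_control=100, seed=3)
        meta = meta_to_frame(generate_demographics(cfg))
        pm = fit_propensity(meta)
        g = meta.loc[pm.scores.index, "group"]
        assert pm.scores[g == 1].mean() > pm.scores[g == 0].mean()

    def test_missing_covariates_dropped(self):
        meta = _meta_frame([1, 0, 1, 0, 1, 0],
                           ages=[30, 28, np.nan, 40, 35, 33],
                           sexes=["male", "male", "female", "female",
                                  "male", "female"])
        pm = fit_propensity(meta)
        assert pm.dropped == ["p002"]
        assert len(pm.scores) == 5

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_propensity(_meta_frame([1, 1, 1]))


class TestOptimalFullMatch:
    def _match(self, scores, groups):
        ids = [f"p{i:03d}" for i in range(len(scores))]
        s = pd.Series(scores, index=ids)
        g = pd.Series(groups, index=ids)
        return optimal_full_match(s, g)

    def test_single_pair(self):
        mr = self._match([0.6, 0.4], [1, 0])
        assert mr.sets == [(["p000"], ["p001"])]
        logit = lambda p: np.log(p / (1 - p))
        assert mr.total_distance == pytest.approx(abs(logit(0.6) - logit(0.4)))

    def test_spec_instance_matches_enumeration(self):
        scores = [0.8, 0.6, 0.7, 0.2, 0.1]
        groups = [1, 1, 0, 0, 0]
        mr = self._match(scores, groups)
        assert mr.total_distance == pytest.approx(
            brute_force_full_match(scores, groups))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_instances(self, seed):
        """Exact optimality on every random instance of <= 6 units."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        n_case = int(rng.integers(1, n))
        groups = [1] * n_case + [0] * (n - n_case)
        scores = rng.uniform(0.05, 0.95, n).tolist()
        mr = self._match(scores, groups)
        assert mr.total_distance == pytest.approx(
            brute_force_full_match(scores, groups), abs=1e-9)

    def test_all_sets_are_stars(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(0.1, 0.9, 40)
        groups = [1] * 30 + [0] * 10
        mr = self._match(scores.tolist(), groups)
        matched = set()
        for cs, ks in mr.sets:
            assert min(len(cs), len(ks)) == 1
            matched.update(cs + ks)
        assert len(matched) == 40  # full matching covers everyone

    def test_beats_greedy_nearest_neighbor(self):
        """Optimal total distance never exceeds a greedy full matching."""
        logit = lambda p: np.log(p / (1 - p))
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(4, 13))
            n_case = int(rng.integers(1, n))
            groups = np.array([1] * n_case + [0] * (n - n_case))
            scores = rng.uniform(0.05, 0.95, n)
            mr = self._match(scores.tolist(), groups.tolist())
            # greedy: attach every unit to its nearest cross-group unit
            lo = logit(scores)
            cases, ctrls = np.where(groups == 1)[0], np.where(groups == 0)[0]
            D = np.abs(lo[cases][:, None] - lo[ctrls][None, :])
            greedy = set()
            for i in range(len(cases)):
                greedy.add((i, int(np.argmin(D[i]))))
            for j in range(len(ctrls)):
                greedy.add((int(np.argmin(D[:, j])), j))
            greedy_total = sum(D[i, j] for i, j in greedy)
            assert mr.total_distance <= greedy_total + 1e-9

    def test_identical_scores_deterministic(self):
        mr1 = self._match([0.5] * 5, [1, 1, 0, 0, 0])
        mr2 = self._match([0.5] * 5, [1, 1, 0, 0, 0])
        assert mr1.sets == mr2.sets
        assert mr1.total_distance == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            self._match([0.5, 0.6], [1, 1])


class TestWeights:
    def test_one_to_one_sets_weight_one(self):
        mr = MatchResult(sets=[(["a"], ["b"]), (["c"], ["d"])],
                         set_id=pd.Series([0, 0, 1, 1], index=list("abcd")),
                         unmatched=[])
        groups = pd.Series([1, 0, 1, 0], index=list("abcd"))
        w = compute_match_weights(mr, groups)
        assert np.allclose(w, 1.0)

    def test_mixed_sets_rescaled(self):
        """1 case : 2 controls plus a 1:1 set -> control weights
        {0.5, 0.5, 1} rescaled by 3/2 -> {0.75, 0.75, 1.5}."""
        mr = MatchResult(sets=[(["c1"], ["k1", "k2"]), (["c2"], ["k3"])],
                         set_id=pd.Series([0, 0, 0, 1, 1],
                                          index=["c1", "k1", "k2", "c2", "k3"]),
                         unmatched=[])
        groups = pd.Series([1, 0, 0, 1, 0],
                           index=["c1", "k1", "k2", "c2", "k3"])
        w = compute_match_weights(mr, groups)
        assert w["c1"] == w["c2"] == 1.0
        assert w["k1"] == pytest.approx(0.75)
        assert w["k2"] == pytest.approx(0.75)
        assert w["k3"] == pytest.approx(1.5)
        assert w[groups == 0].sum() == pytest.approx(3.0)

    def test_weights_nonnegative_and_sum_preserved(self):
        rng = np.random.default_rng(1)
        ids = [f"p{i:03d}" for i in range(30)]
        scores = pd.Series(rng.uniform(0.2, 0.9, 30), index=ids)
        groups = pd.Series([1] * 24 + [0] * 6, index=ids)
        mr = optimal_full_match(scores, groups)
        w = compute_match_weights(mr, groups)
        assert (w >= 0).all()
        assert w[groups == 0].sum() == pytest.approx(6.0)
        assert (w[groups == 1] == 1.0).all()


class TestIPW:
    def test_uniform_scores_give_unit_weights(self):
        ids = list("abcd")
        scores = pd.Series([0.5] * 4, index=ids)
        groups = pd.Series([1, 1, 0, 0], index=ids)
        w = ipw_weights(scores, groups)
        assert np.allclose(w, 1.0)

    def test_extreme_scores_trimmed(self):
        ids = list("ab")
        w = ipw_weights(pd.Series([0.999, 0.5], index=ids),
                        pd.Series([0, 1], index=ids))
        # control score trimmed to 0.99: stabilized weight (1-p)/(1-e) = 50·0.5
        assert w["a"] == pytest.approx(0.5 / 0.01)

    def test_ipw_reduces_covariate_imbalance(self):
        cfg = SynthConfig(n_case=400, n_control=100, seed=5)
        meta = meta_to_frame(generate_demographics(cfg))
        pm = fit_propensity(meta)
        meta = meta.loc[pm.scores.index]
        w = ipw_weights(pm.scores, meta["group"])
        tbl = balance_table(meta, w)
        sex_row = tbl[tbl["covariate"] == "sex"].iloc[0]
        assert abs(sex_row["smd_post"]) < abs(sex_row["smd_pre"])


class TestBalance:
    def test_identical_groups_zero_smd(self):
        meta = _meta_frame([1, 1, 0, 0], ages=[30, 40, 30, 40],
                           sexes=["male", "female", "male", "female"])
        w = pd.Series(1.0, index=meta.index)
        tbl = balance_table(meta, w)
        assert np.allclose(tbl["smd_pre"], 0.0)
        assert np.allclose(tbl["smd_post"], 0.0)

    def test_constant_covariate_flagged_nan(self):
        meta = _meta_frame([1, 1, 0, 0], ages=[30.0] * 4)
        tbl = balance_table(meta, pd.Series(1.0, index=meta.index),
                            covariates=("age_months",))
        assert np.isnan(tbl["smd_pre"]).all()

    def test_full_match_improves_balance_across_seeds(self):
        """Post-match |SMD| < pre-match |SMD| for the confounded covariate
        in nearly all seeded replicates."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SynthConfig(n_case=120, n_control=30, seed=seed)
            meta = meta_to_frame(generate_demographics(cfg))
            pm = fit_propensity(meta)
            meta_s = meta.loc[pm.scores.index]
            mr = optimal_full_match(pm.scores, meta_s["group"])
            w = compute_match_weights(mr, meta_s["group"])
            tbl = balance_table(meta_s, w).set_index("covariate")
            if abs(tbl.loc["sex", "smd_post"]) < abs(tbl.loc["sex", "smd_pre"]):
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_score_balanced_after_matching(self):
        """Weighted group means of the propensity score itself agree."""
        cfg = SynthConfig(n_case=200, n_control=50, seed=77)
        meta = meta_to_frame(generate_demographics(cfg))
        pm = fit_propensity(meta)
        meta_s = meta.loc[pm.scores.index]
        mr = optimal_full_match(pm.scores, meta_s["group"])
        w = compute_match_weights(mr, meta_s["group"])
        g = meta_s["group"]
        mc = np.average(pm.scores[g == 1], weights=w[g == 1])
        mk = np.average(pm.scores[g == 0], weights=w[g == 0])
        assert abs(mc - mk) < 0.02
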