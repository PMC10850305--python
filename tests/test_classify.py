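"""Ridge logistic solver, ranking metrics, forward selection, LOOCV
plumbing (leakage canary), and univariate ROC cutoffs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegscreen.classify import (bootstrap_ci, confusion_and_pv, forward_select,
                                loocv_classify, prc_auc, rank_features_nested,
                                ridge_logistic_fit, roc_auc,
                                univariate_threshold)
from eegscreen.config import PipelineConfig


def brute_force_roc_auc(labels, scores):
    """Oracle: exhaustive concordant-pair counting, ties at half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRidgeLogistic:
    def test_matches_direct_optimizer_on_small_instance(self):
        """Penalized-likelihood optimum vs scipy.optimize to 1e-4."""
        from scipy.optimize import minimize
        X = np.array([[0.1], [0.4], [0.35], [0.8], [0.9], [0.62]])
        y = np.array([0.0, 0, 1, 1, 1, 0])
        alpha = 0.7

        def loss(beta):
            eta = beta[0] + X[:, 0] * beta[1]
            return np.sum(np.log1p(np.exp(-eta * (2 * y - 1)))) \
                + 0.5 * alpha * beta[1] ** 2

        ref = minimize(loss, np.zeros(2), method="BFGS").x
        model = ridge_logistic_fit(X, y, alpha, class_weight=None)
        assert model.intercept == pytest.approx(ref[0], abs=1e-4)
        assert model.coef[0] == pytest.approx(ref[1], abs=1e-4)

    def test_probabilities_monotone_in_feature(self):
        X = np.linspace(-2, 2, 12).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        model = ridge_logistic_fit(X, y, 1.0)
        probs = model.predict_proba(X)
        assert np.all(np.diff(probs) > 0)

    def test_huge_alpha_shrinks_to_balanced_half(self, rng):
        X = rng.standard_normal((40, 3))
        y = (rng.random(40) < 0.8).astype(float)
        model = ridge_logistic_fit(X, y, 1e8)
        assert np.abs(model.coef).max() < 1e-4
        # balanced class weights pull the intercept to log(1) = 0
        assert model.predict_proba(X) == pytest.approx(0.5, abs=0.01)

    def test_constant_column_gets_zero_coefficient(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = (X[:, 1] > 0).astype(float)
        model = ridge_logistic_fit(X, y, 1.0, standardize=True)
        assert model.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ridge_logistic_fit(np.zeros((5, 1)), np.ones(5), 1.0)


class TestMetrics:
    def test_perfect_ranking(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_worked_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_roc_auc(labels, scores))

    def test_roc_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.4])

    def test_prc_all_positive_classifier_baseline(self):
        """A constant classifier's PRC-AUC equals the positive prevalence."""
        labels = [1, 1, 1, 1, 1, 1, 0]
        assert prc_auc(labels, [0.7] * 7) == pytest.approx(6 / 7, abs=1e-9)

    def test_prc_perfect(self):
        assert prc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.random(100)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))


class TestBootstrap:
    def test_ci_contains_point_estimate(self, rng):
        y = rng.integers(0, 2, 60)
        y[:5] = 1; y[-5:] = 0
        s = rng.random(60) + 0.3 * y
        lo, hi = bootstrap_ci(y, s, roc_auc, n_boot=300, seed=1)
        assert lo <= roc_auc(y, s) <= hi

    def test_degenerate_perfect_classifier_collapses(self):
        y = np.array([0] * 10 + [1] * 10)
        s = y.astype(float)
        lo, hi = bootstrap_ci(y, s, roc_auc, n_boot=200, seed=2)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_under_seed(self, rng):
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        s = rng.random(40)
        assert bootstrap_ci(y, s, roc_auc, 200, 7) == \
            bootstrap_ci(y, s, roc_auc, 200, 7)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (70, 280):
            y = np.r_[np.ones(n * 6 // 7, int), np.zeros(n // 7, int)]
            s = rng.random(n) + 0.5 * y
            lo, hi = bootstrap_ci(y, s, roc_auc, n_boot=400, seed=4)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestConfusion:
    def test_printed_toy(self):
        # TP=5, FP=1, TN=3, FN=2
        labels = [1] * 7 + [0] * 4
        probs = [0.9] * 5 + [0.1] * 2 + [0.9] * 1 + [0.1] * 3
        matrix, ppv, npv = confusion_and_pv(labels, probs)
        assert matrix.tolist() == [[3, 1], [2, 5]]
        assert ppv == pytest.approx(5 / 6)
        assert npv == pytest.approx(0.6)

    def test_perfect(self):
        m, ppv, npv = confusion_and_pv([0, 1], [0.0, 1.0])
        assert ppv == 1.0 and npv == 1.0

    def test_all_positive_predictions_leave_npv_undefined(self):
        labels = [1] * 6 + [0]
        m, ppv, npv = confusion_and_pv(labels, [1.0] * 7)
        assert ppv == pytest.approx(6 / 7)
        assert np.isnan(npv)


class TestUnivariateThreshold:
    def test_perfectly_separated(self):
        cut = univariate_threshold([1, 2, 3, 4], [0, 0, 1, 1])
        assert cut.threshold == pytest.approx(2.5)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0
        assert cut.direction == ">"

    def test_anti_predictive_feature_reversed(self):
        cut = univariate_threshold([4, 3, 2, 1], [0, 0, 1, 1])
        assert cut.direction == "<"
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0

    def test_matches_exhaustive_scan(self, rng):
        values = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        cut = univariate_threshold(values, labels)
        best = None
        uniq = np.unique(values)
        for thr in (uniq[:-1] + uniq[1:]) / 2:
            for direction in (">", "<"):
                pred = values > thr if direction == ">" else values < thr
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                d = np.hypot(1 - sens, 1 - spec)
                if best is None or d < best - 1e-12:
                    best = d
        assert np.hypot(1 - cut.sensitivity, 1 - cut.specificity) == \
            pytest.approx(best)

    def test_single_class_stratum_rejected(self):
        with pytest.raises(ValueError):
            univariate_threshold([1.0, 2.0], [1, 1])


def _selection_cohort(rng, n=36, n_noise=14, effect=3.0):
    ids = pd.Index([f"s{i:03d}" for i in range(n)], name="participant_id")
    y = np.r_[np.ones(n * 2 // 3, int), np.zeros(n - n * 2 // 3, int)]
    feats = pd.DataFrame(rng.standard_normal((n, n_noise + 1)), index=ids,
                         columns=["signal"] + [f"noise{j:02d}" for j in range(n_noise)])
    feats["signal"] += effect * y
    meta = pd.DataFrame({"group": y, "sex": rng.choice(["male", "female"], n),
                         "age_months": rng.normal(36, 10, n).clip(12)}, index=ids)
    return feats, meta


class TestForwardSelection:
    def test_finds_predictive_among_noise(self, default_config):
        rng = np.random.default_rng(0)
        feats, meta = _selection_cohort(rng)
        sel = forward_select(feats, meta["group"].to_numpy(),
                             list(feats.columns), default_config, seed=1)
        assert "signal" in sel

    def test_duplicate_candidates_add_once(self, default_config):
        rng = np.random.default_rng(1)
        feats, meta = _selection_cohort(rng, n_noise=0)
        feats["copy1"] = feats["signal"]
        feats["copy2"] = feats["signal"]
        sel = forward_select(feats, meta["group"].to_numpy(),
                             ["signal", "copy1", "copy2"], default_config, seed=2)
        assert len(sel) == 1

    def test_never_empty(self, default_config):
        rng = np.random.default_rng(2)
        feats, meta = _selection_cohort(rng, effect=0.0)
        sel = forward_select(feats, meta["group"].to_numpy(),
                             list(feats.columns)[:5], default_config, seed=3)
        assert len(sel) >= 1

    def test_deterministic(self, default_config):
        rng = np.random.default_rng(3)
        feats, meta = _selection_cohort(rng)
        args = (feats, meta["group"].to_numpy(), list(feats.columns))
        assert forward_select(*args, default_config, seed=9) == \
            forward_select(*args, default_config, seed=9)


class TestNestedRanking:
    def test_recovers_effect_feature(self, default_config):
        rng = np.random.default_rng(5)
        feats, meta = _selection_cohort(rng, n=60, effect=2.5)
        top = rank_features_nested(feats, meta, default_config, k=3)
        assert "signal" in top

    def test_k_larger_than_usable_returns_all(self, default_config):
        rng = np.random.default_rng(6)
        feats, meta = _selection_cohort(rng, n=40, n_noise=4)
        top = rank_features_nested(feats, meta, default_config, k=50)
        assert len(top) == 5

    def test_ipw_ranking_also_recovers_effect(self):
        cfg = PipelineConfig(matching_method="ipw")
        rng = np.random.default_rng(12)
        feats, meta = _selection_cohort(rng, n=60, effect=2.5)
        top = rank_features_nested(feats, meta, cfg, k=3)
        assert "signal" in top


class TestLOOCV:
    def test_one_prediction_per_participant(self, default_config):
        rng = np.random.default_rng(7)
        feats, meta = _selection_cohort(rng, n=24, n_noise=4)
        cfg = PipelineConfig()
        cfg.classify.top_k = 3
        cfg.classify.bootstrap_reps = 200
        cv = loocv_classify(feats, meta, cfg)
        assert len(cv.predictions) == 24
        assert set(cv.predictions["participant_id"]) == set(meta.index)
        assert cv.predictions["prob"].between(0, 1).all()
        m = np.array(cv.metrics["confusion"])
        assert m.sum() == 24

    def test_no_leakage_canary(self, default_config, monkeypatch):
        """The held-out participant's row must never reach the nested
        ranking step."""
        import eegscreen.classify as C
        rng = np.random.default_rng(8)
        feats, meta = _selection_cohort(rng, n=20, n_noise=3)
        cfg = PipelineConfig()
        cfg.classify.top_k = 2
        cfg.classify.bootstrap_reps = 200
        seen = []
        original = C.rank_features_nested

        def spy(f, m, c, k=None):
            seen.append(set(m.index))
            return original(f, m, c, k)

        monkeypatch.setattr(C, "rank_features_nested", spy)
        cv = loocv_classify(feats, meta, cfg)
        all_ids = set(meta.index)
        assert len(seen) == 20
        for held_out, train_ids in zip(meta.index, seen):
            assert held_out not in train_ids
            assert train_ids == all_ids - {held_out}

    def test_baseline_mode_uses_demographics_only(self, default_config):
        rng = np.random.default_rng(9)
        feats, meta = _selection_cohort(rng, n=20, n_noise=2)
        cfg = PipelineConfig()
        cfg.classify.bootstrap_reps = 200
        cv = loocv_classify(feats, meta, cfg, mode="baseline")
        assert len(cv.predictions) == 20
        assert set(cv.predictions["selected_features"]) == {"age_months|sex"}

    def test_metrics_reproducible_from_predictions(self, default_config):
        from eegscreen.classify import compute_cv_metrics
        rng = np.random.default_rng(10)
        feats, meta = _selection_cohort(rng, n=20, n_noise=2)
        cfg = PipelineConfig()
        cfg.classify.top_k = 2
        cfg.classify.bootstrap_reps = 200
        cv = loocv_classify(feats, meta, cfg)
        again = compute_cv_metrics(cv.predictions, cfg)
        assert again == cv.metrics

    def test_too_few_participants_rejected(self, default_config):
        rng = np.random.default_rng(11)
        feats, meta = _selection_cohort(rng, n=8, n_noise=2)
        with pytest.raises(ValueError):
            loocv_classify(feats, meta, PipelineConfig())
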