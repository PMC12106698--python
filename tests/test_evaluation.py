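import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from cfsomatic.evaluation import (
    RULE_LEVELS,
    confusion_and_metrics,
    partial_dependence,
    permutation_importance,
    pr_curve_and_ap,
    predict_hcsv,
    rule_based_filter,
)
from cfsomatic.feature_extraction import FEATURE_COLUMNS, ScalerStats
from cfsomatic.model_training import BalancingRatio, FinalModel


def ap_bruteforce(scores, labels):
    """AP by explicit enumeration of every distinct-score threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    ap, r_prev = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        calls = scores >= t
        tp = int((calls & (labels == 1)).sum())
        p = tp / calls.sum()
        r = tp / labels.sum()
        ap += (r - r_prev) * p
        r_prev = r
    return ap


def fitted_model(X, y, threshold=0.75, n_estimators=40, seed=0):
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    est.fit(X, y)
    return FinalModel(
        estimator=est,
        scaler=ScalerStats(0.0, 1.0),
        ratio=BalancingRatio(1, 1),
        hyperparameters={},
        probability_threshold=threshold,
        seed=seed,
    )


def feature_frame(X):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    return df


class TestConfusion:
    def test_perfect_calls(self):
        m = confusion_and_metrics([1, 1, 1], [1, 1, 1])
        assert (m.precision, m.recall) == (1.0, 1.0)

    def test_table_arithmetic(self):
        m = confusion_and_metrics([1, 1, 1, 1], [1, 1, 1, 0])
        assert (m.tp, m.fp, m.fn) == (3, 1, 0)
        assert m.precision == 0.75 and m.recall == 1.0

    def test_all_negative_calls(self):
        m = confusion_and_metrics([0, 0, 0], [1, 0, 1])
        assert m.precision is None and m.recall == 0.0

    def test_counts_partition(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        m = confusion_and_metrics(calls, labels)
        assert m.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([1], [1, 0])


class TestPRCurve:
    def test_perfect_ranking(self):
        curve = pr_curve_and_ap([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.ap == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        curve = pr_curve_and_ap([0.5] * 10, labels)
        assert curve.ap == pytest.approx(0.2)

    def test_small_mixed_case_matches_bruteforce(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 0, 1, 0, 0, 1]
        curve = pr_curve_and_ap(scores, labels)
        assert curve.ap == pytest.approx(ap_bruteforce(scores, labels), abs=1e-12)

    def test_random_cases_match_bruteforce(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 50))
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
            curve = pr_curve_and_ap(scores, labels)
            assert curve.ap == pytest.approx(ap_bruteforce(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(5, 80))
            labels = rng.integers(0, 2, n)
            labels[0] = 1
            scores = rng.random(n)
            curve = pr_curve_and_ap(scores, labels)
            assert curve.ap == pytest.approx(average_precision_score(labels, scores), abs=1e-12)

    def test_recall_monotone_and_anchor(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1
        curve = pr_curve_and_ap(scores, labels)
        assert curve.recall[0] == 0.0  # anchor point
        assert np.all(np.diff(curve.recall) >= 0)
        assert 0.0 <= curve.ap <= 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_and_ap([0.5, 0.4], [0, 0])


class TestPredict:
    def test_threshold_conventions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, len(FEATURE_COLUMNS)))
        y = (X[:, 0] > 0).astype(int)
        model = fitted_model(X, y)
        df = feature_frame(X)
        preds = predict_hcsv(model, df)
        # >= convention at the threshold
        assert (preds["call"] == (preds["probability"] >= 0.75).astype(int)).all()
        model.probability_threshold = 0.0
        assert predict_hcsv(model, df)["call"].all()

    def test_raising_threshold_never_raises_tp_or_fp(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, len(FEATURE_COLUMNS)))
        y = (X[:, 1] + 0.5 * rng.normal(size=120) > 0).astype(int)
        model = fitted_model(X, y)
        proba = model.predict_proba(feature_frame(X))
        prev_tp, prev_fp = np.inf, np.inf
        for t in np.linspace(0, 1, 11):
            calls = (proba >= t).astype(int)
            m = confusion_and_metrics(calls, y)
            assert m.tp <= prev_tp and m.fp <= prev_fp
            prev_tp, prev_fp = m.tp, m.fp


class TestPermutationImportance:
    def _setup(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, len(FEATURE_COLUMNS)))
        y = rng.integers(0, 2, 300)
        sig = FEATURE_COLUMNS.index("in_cosmic")
        const = FEATURE_COLUMNS.index("called_bcftools")
        X[:, sig] = y + 0.05 * rng.normal(size=300)  # label-correlated feature
        X[:, const] = 1.0  # constant feature
        model = fitted_model(X, y)
        return model, feature_frame(X), y

    def test_constant_feature_scores_zero(self):
        model, df, y = self._setup()
        (res,) = permutation_importance(model, df, y, n_permutations=5, seed=0,
                                        features=["called_bcftools"])
        assert res.mean_drop == 0.0 and res.sd_drop == 0.0

    def test_signal_feature_drops_ap(self):
        model, df, y = self._setup()
        (res,) = permutation_importance(model, df, y, n_permutations=10, seed=0,
                                        features=["in_cosmic"])
        assert res.mean_drop > 0.1

    def test_deterministic(self):
        model, df, y = self._setup()
        r1 = permutation_importance(model, df, y, n_permutations=3, seed=5,
                                    features=["whr", "in_cosmic"])
        r2 = permutation_importance(model, df, y, n_permutations=3, seed=5,
                                    features=["whr", "in_cosmic"])
        assert [(a.mean_drop, a.sd_drop) for a in r1] == [(b.mean_drop, b.sd_drop) for b in r2]

    def test_single_class_rejected(self):
        model, df, y = self._setup()
        with pytest.raises(ValueError):
            permutation_importance(model, df, np.ones_like(y))


class TestPartialDependence:
    def test_ignored_feature_gives_flat_profile(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, len(FEATURE_COLUMNS)))
        y = (X[:, 0] > 0).astype(int)
        # a lone tree on a perfectly separable feature ignores all others
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        model = FinalModel(
            estimator=tree,
            scaler=ScalerStats(0.0, 1.0),
            ratio=BalancingRatio(1, 1),
            hyperparameters={},
            probability_threshold=0.5,
            seed=0,
        )
        prof = partial_dependence(model, "called_lofreq", [0.0, 1.0], feature_frame(X))
        assert prof.mean_probability[0] == prof.mean_probability[1]

    def test_depth1_tree_step_profile(self):
        # single stump on one feature: profile equals the two leaf rates
        col = FEATURE_COLUMNS.index("allele_frequency")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, len(FEATURE_COLUMNS)))
        y = (X[:, col] > 0.0).astype(int)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        model = FinalModel(
            estimator=stump,
            scaler=ScalerStats(0.0, 1.0),
            ratio=BalancingRatio(1, 1),
            hyperparameters={},
            probability_threshold=0.5,
            seed=0,
        )
        thr = stump.tree_.threshold[0]
        prof = partial_dependence(model, "allele_frequency", [thr - 1.0, thr + 1.0], feature_frame(X))
        leaf_rates = stump.tree_.value[1:, 0, 1] / stump.tree_.value[1:, 0].sum(axis=1)
        assert prof.mean_probability == pytest.approx(sorted(leaf_rates))

    def test_empty_background_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, len(FEATURE_COLUMNS)))
        model = fitted_model(X, (X[:, 0] > 0).astype(int))
        with pytest.raises(ValueError):
            partial_dependence(model, "whr", [0.0], feature_frame(X).iloc[:0])


class TestRuleBasedFilter:
    def make_variants(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "read_depth": rng.integers(0, 40, n),
                "qual": rng.uniform(0, 80, n),
                "in_dbsnp": rng.integers(0, 2, n),
                "in_cosmic": rng.integers(0, 2, n),
                "allele_frequency": rng.random(n),
                "label": rng.integers(0, 2, n),
            }
        )

    def test_hard_level_conjunction(self):
        df = pd.DataFrame(
            [{"read_depth": 25, "qual": 60.0, "in_dbsnp": 0, "in_cosmic": 1,
              "allele_frequency": 0.2}]
        )
        mask, _ = rule_based_filter(df, "hard", mode="low")
        assert mask[0]

    def test_dbsnp_member_removed_everywhere(self):
        df = pd.DataFrame(
            [{"read_depth": 1000, "qual": 99.0, "in_dbsnp": 1, "in_cosmic": 1,
              "allele_frequency": 0.2}]
        )
        for level in RULE_LEVELS:
            mask, _ = rule_based_filter(df, level, mode="low")
            assert not mask[0]

    def test_depth_boundary_strict(self):
        df = pd.DataFrame(
            [{"read_depth": 10, "qual": 60.0, "in_dbsnp": 0, "in_cosmic": 1,
              "allele_frequency": 0.2},
             {"read_depth": 11, "qual": 60.0, "in_dbsnp": 0, "in_cosmic": 1,
              "allele_frequency": 0.2}]
        )
        mask, _ = rule_based_filter(df, "medium", mode="low")
        assert list(mask) == [False, True]

    def test_high_mode_uses_high_depth_cut(self):
        df = pd.DataFrame(
            [{"read_depth": 600, "qual": 60.0, "in_dbsnp": 0, "in_cosmic": 1,
              "allele_frequency": 0.2}]
        )
        assert rule_based_filter(df, "soft", mode="high")[0][0]
        assert not rule_based_filter(df, "medium", mode="high")[0][0]

    def test_nesting_hard_medium_soft(self):
        df = self.make_variants(seed=8, n=300)
        hard, _ = rule_based_filter(df, "hard", mode="low")
        medium, _ = rule_based_filter(df, "medium", mode="low")
        soft, _ = rule_based_filter(df, "soft", mode="low")
        assert not (hard & ~medium).any()
        assert not (medium & ~soft).any()

    def test_matches_bruteforce_predicates(self):
        df = self.make_variants(seed=9, n=200)
        for level, th in RULE_LEVELS.items():
            mask, metrics = rule_based_filter(df, level, mode="low")
            for i, r in df.iterrows():
                expected = (
                    r.read_depth > th.depth_low
                    and r.qual >= th.qual_min
                    and r.in_dbsnp == 0
                    and r.in_cosmic == 1
                    and not (0.4 <= r.allele_frequency <= 0.6)
                    and not r.allele_frequency > 0.9
                )
                assert mask[i] == expected
            assert metrics.total == len(df)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            rule_based_filter(self.make_variants(), "extreme")
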