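import numpy as np
import pandas as pd
import pytest

from cfsomatic.feature_extraction import FEATURE_COLUMNS
from cfsomatic.model_training import (
    CANONICAL_RATIOS,
    BalancingRatio,
    CandidateModel,
    FinalModel,
    ModelFormatError,
    SearchSpace,
    cv_random_search,
    load_model,
    persist_model,
    random_undersample,
    ratio_sweep,
    select_final_model,
    split_train_validation,
)
from cfsomatic.feature_extraction import ScalerStats


def make_vectors(n, n_pos, seed=0, n_samples=4, separation=0.0):
    """Labelled feature frame; `separation` shifts positives on two features."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    df["label"] = labels
    df["read_depth"] = rng.integers(10, 60, size=n)
    df["sample"] = [f"S{i % n_samples + 1}" for i in range(n)]
    if separation:
        df.loc[df["label"] == 1, "in_cosmic"] += separation
        df.loc[df["label"] == 1, "allele_frequency"] += separation
    return df


class TestRatios:
    def test_canonical_values(self):
        assert [r.label for r in CANONICAL_RATIOS] == ["1:10", "1:5", "2:5", "3:5", "4:5", "1:1"]

    def test_validation(self):
        with pytest.raises(ValueError):
            BalancingRatio(0, 5)


class TestSplit:
    def test_stratified_counts(self):
        df = make_vectors(1000, 10, seed=1)
        train, val = split_train_validation(df, fraction=0.7, seed=5)
        assert (len(train), len(val)) == (700, 300)
        assert train["label"].sum() == 7 and val["label"].sum() == 3

    def test_deterministic(self):
        df = make_vectors(200, 8, seed=2)
        a1, b1 = split_train_validation(df, seed=9)
        a2, b2 = split_train_validation(df, seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_degenerate_fraction_rejected(self):
        df = make_vectors(100, 5)
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                split_train_validation(df, fraction=frac)

    def test_no_positives_rejected(self):
        df = make_vectors(100, 1)
        df["label"] = 0
        with pytest.raises(ValueError):
            split_train_validation(df)


class TestUndersample:
    @pytest.mark.parametrize(
        "ratio,expected_neg",
        [
            (BalancingRatio(1, 1), 10),
            (BalancingRatio(1, 10), 100),  # already at ratio: no-op bound
            (BalancingRatio(2, 5), 25),  # floor(10 * 5 / 2)
            (BalancingRatio(3, 5), 16),  # floor(50 / 3)
            (BalancingRatio(4, 5), 12),
            (BalancingRatio(1, 5), 50),
        ],
    )
    def test_exact_negative_counts(self, ratio, expected_neg):
        df = make_vectors(110, 10, seed=3)
        out = random_undersample(df, ratio, seed=0)
        assert out["label"].sum() == 10  # positives untouched
        assert (out["label"] == 0).sum() == expected_neg

    def test_never_drops_positives_and_caps_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 300))
            df = make_vectors(n_pos + n_neg, n_pos, seed=int(rng.integers(2**16)))
            ratio = CANONICAL_RATIOS[int(rng.integers(len(CANONICAL_RATIOS)))]
            out = random_undersample(df, ratio, seed=int(rng.integers(2**16)))
            assert out["label"].sum() == n_pos
            kept_neg = (out["label"] == 0).sum()
            assert kept_neg == min(n_neg, (n_pos * ratio.neg_part) // ratio.pos_part)

    def test_reproducible(self):
        df = make_vectors(500, 20, seed=4)
        out1 = random_undersample(df, BalancingRatio(1, 5), seed=77)
        out2 = random_undersample(df, BalancingRatio(1, 5), seed=77)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_positives_rejected(self):
        df = make_vectors(50, 1)
        df["label"] = 0
        with pytest.raises(ValueError):
            random_undersample(df, BalancingRatio(1, 1))


class TestSearch:
    def test_singleton_space_returns_it(self):
        df = make_vectors(120, 30, seed=5, separation=3.0)
        space = SearchSpace(
            grid={"n_estimators": [20], "max_depth": [3]}, n_candidates=1
        )
        params, est = cv_random_search(df, space, seed=1)
        assert params == {"n_estimators": 20, "max_depth": 3}
        assert est.n_estimators == 20

    def test_deterministic_selection(self):
        df = make_vectors(150, 40, seed=6, separation=2.0)
        space = SearchSpace.small(5)
        p1, _ = cv_random_search(df, space, seed=3)
        p2, _ = cv_random_search(df, space, seed=3)
        assert p1 == p2

    def test_separable_data_reaches_perfect_cv_recall(self):
        df = make_vectors(200, 60, seed=7, separation=6.0)
        space = SearchSpace(grid={"n_estimators": [50]}, n_candidates=1)
        _, est = cv_random_search(df, space, seed=2)
        X = df[FEATURE_COLUMNS].to_numpy(float)
        assert (est.predict(X)[df["label"] == 1] == 1).all()


class TestSweepAndSelect:
    def _candidate(self, i, recall, precision, pr_auc):
        return CandidateModel(
            ratio=CANONICAL_RATIOS[i],
            ratio_index=i,
            hyperparameters={},
            estimator=None,
            validation_precision=precision,
            validation_recall=recall,
            validation_pr_auc=pr_auc,
        )

    def test_sweep_produces_one_candidate_per_ratio(self):
        df = make_vectors(400, 40, seed=8, separation=8.0)
        train, val = split_train_validation(df, seed=1)
        space = SearchSpace(grid={"n_estimators": [60]}, n_candidates=1)
        cands = ratio_sweep(train, val, space=space, seed=1)
        assert [c.ratio.label for c in cands] == [r.label for r in CANONICAL_RATIOS]
        # separable cohort: every ratio reaches full validation recall
        assert all(c.validation_recall == 1.0 for c in cands)

    def test_recall_ties_broken_by_pr_auc(self):
        cands = [
            self._candidate(0, 1.0, 0.07, 0.43),
            self._candidate(1, 1.0, 0.07, 0.31),
            self._candidate(2, 0.9, 0.50, 0.90),
        ]
        model = select_final_model(cands, ScalerStats(10.0, 2.0))
        assert model.ratio == CANONICAL_RATIOS[0]
        assert model.probability_threshold == 0.75

    def test_comparator_matches_brute_force_sort(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            cands = [
                self._candidate(i, *rng.choice([0.2, 0.5, 0.9, 1.0], size=3))
                for i in range(6)
            ]
            chosen = select_final_model(cands, ScalerStats(1.0, 1.0))
            expected = max(
                cands,
                key=lambda c: (
                    c.validation_recall,
                    c.validation_precision,
                    c.validation_pr_auc,
                    -c.ratio_index,
                ),
            )
            assert chosen.ratio == expected.ratio

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_final_model([], ScalerStats(1.0, 1.0))


class TestPersistence:
    def _fit_model(self):
        df = make_vectors(150, 50, seed=9, separation=3.0)
        space = SearchSpace(grid={"n_estimators": [25]}, n_candidates=1)
        _, est = cv_random_search(df, space, seed=4)
        return (
            FinalModel(
                estimator=est,
                scaler=ScalerStats(30.0, 5.0),
                ratio=BalancingRatio(2, 5),
                hyperparameters={"n_estimators": 25},
                probability_threshold=0.75,
                seed=4,
            ),
            df,
        )

    def test_roundtrip_predictions_identical(self, tmp_path):
        model, df = self._fit_model()
        path = tmp_path / "model.joblib"
        persist_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict_proba(df), model.predict_proba(df))
        assert loaded.ratio == model.ratio
        assert loaded.scaler == model.scaler
        assert loaded.seed == model.seed

    def test_shuffled_columns_realigned_by_name(self, tmp_path):
        model, df = self._fit_model()
        shuffled = df[list(reversed(df.columns))]
        np.testing.assert_array_equal(
            model.predict_proba(shuffled), model.predict_proba(df)
        )

    def test_missing_feature_column_named(self):
        model, df = self._fit_model()
        with pytest.raises(KeyError, match="whr"):
            model.predict_proba(df.drop(columns=["whr"]))

    def test_corrupt_file_raises(self, tmp_path):
        path = tmp_path / "model.joblib"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_version_mismatch(self, tmp_path):
        import joblib

        path = tmp_path / "model.joblib"
        joblib.dump({"format_version": 999}, path)
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)
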