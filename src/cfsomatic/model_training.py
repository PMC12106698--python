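"""Class-balanced Random Forest training.

The class imbalance between high-confidence somatic variants and
artefacts is on the order of 1:1000, so the undersampling ratio is
treated as a parameter to optimise in a nested loop:

* outer loop — training data is randomly undersampled (all positives
  kept, negatives downsampled) to each of six HCSV:AV ratios
  (1:10, 1:5, 2:5, 3:5, 4:5, 1:1);
* inner loop — a randomized search (100 candidates by default) over
  Random Forest hyperparameters, scored by mean recall under 3-fold
  cross-validation with variants grouped per sample;
* selection — each ratio's best model predicts on the full,
  *un*-undersampled validation data; the model with the highest recall,
  then precision, then PR-AUC wins and is frozen together with the
  depth scaler and the HCSV probability threshold (default 0.75).

Everything is deterministic given one global seed.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import make_scorer, precision_score, recall_score
from sklearn.model_selection import (
    GroupKFold,
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)

from .feature_extraction import FEATURE_COLUMNS, ScalerStats, apply_depth_scaler, fit_depth_scaler

logger = logging.getLogger(__name__)

__all__ = [
    "BalancingRatio",
    "CANONICAL_RATIOS",
    "SearchSpace",
    "CandidateModel",
    "FinalModel",
    "split_train_validation",
    "random_undersample",
    "cv_random_search",
    "ratio_sweep",
    "select_final_model",
    "train_final_model",
    "persist_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ModelFormatError(RuntimeError):
    """A persisted model file is unreadable or from another format version."""


@dataclass(frozen=True, slots=True)
class BalancingRatio:
    """Target HCSV:AV class ratio for random undersampling (e.g. 2:5)."""

    pos_part: int
    neg_part: int

    def __post_init__(self) -> None:
        if self.pos_part <= 0 or self.neg_part <= 0:
            raise ValueError("ratio parts must be positive")

    @property
    def label(self) -> str:
        return f"{self.pos_part}:{self.neg_part}"

    @property
    def neg_per_pos(self) -> float:
        return self.neg_part / self.pos_part


#: The six ratios swept by the outer loop, ordered from most to least imbalanced.
CANONICAL_RATIOS = (
    BalancingRatio(1, 10),
    BalancingRatio(1, 5),
    BalancingRatio(2, 5),
    BalancingRatio(3, 5),
    BalancingRatio(4, 5),
    BalancingRatio(1, 1),
)


@dataclass(slots=True)
class SearchSpace:
    """Randomized-search configuration for the forest."""

    grid: dict[str, list] = field(default_factory=dict)
    n_candidates: int = 100
    n_folds: int = 3
    scoring: str = "recall"

    def __post_init__(self) -> None:
        if not self.grid:
            self.grid = self.default_grid()
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @staticmethod
    def default_grid() -> dict[str, list]:
        return {
            "n_estimators": [100, 200, 300, 400, 500, 600, 700, 800],
            "max_depth": [None, 5, 10, 15, 20, 25, 30, 35, 40],
            "min_samples_leaf": list(range(1, 11)),
            "min_samples_split": list(range(2, 21)),
            "max_features": ["sqrt", "log2", 0.3],
        }

    @classmethod
    def small(cls, n_candidates: int = 20) -> "SearchSpace":
        """Reduced grid for desk-scale cohorts (fewer, smaller forests)."""
        return cls(
            grid={
                "n_estimators": [100, 200, 300, 400],
                "max_depth": [None, 10, 20, 30],
                "min_samples_leaf": [1, 2, 4, 8],
                "min_samples_split": [2, 4, 8, 16],
                "max_features": ["sqrt", "log2", 0.3],
            },
            n_candidates=n_candidates,
        )


@dataclass(slots=True)
class CandidateModel:
    """Best model for one undersampling ratio, scored on validation data."""

    ratio: BalancingRatio
    ratio_index: int
    hyperparameters: dict[str, Any]
    estimator: Any
    validation_precision: float
    validation_recall: float
    validation_pr_auc: float


@dataclass(slots=True)
class FinalModel:
    """Frozen pipeline output: forest + scaler + threshold + provenance."""

    estimator: Any
    scaler: ScalerStats
    ratio: BalancingRatio
    hyperparameters: dict[str, Any]
    probability_threshold: float
    seed: int
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")

    def feature_matrix(self, vectors: pd.DataFrame) -> np.ndarray:
        """Column-order-safe feature matrix, filling read_depth_std on the fly."""
        vectors = vectors.copy()
        if "read_depth_std" in self.feature_columns and (
            "read_depth_std" not in vectors.columns
            or vectors["read_depth_std"].isna().any()
        ):
            if "read_depth" not in vectors.columns:
                raise KeyError("missing feature column: read_depth")
            vectors["read_depth_std"] = apply_depth_scaler(self.scaler, vectors["read_depth"])
        missing = [c for c in self.feature_columns if c not in vectors.columns]
        if missing:
            raise KeyError(f"missing feature column: {missing[0]}")
        return vectors[self.feature_columns].to_numpy(float)

    def predict_proba(self, vectors: pd.DataFrame) -> np.ndarray:
        """Per-variant probability of the HCSV class."""
        X = self.feature_matrix(vectors)
        return self.estimator.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# seeding helpers — all derived seeds stay below 2**31


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# data splitting and balancing


def split_train_validation(
    vectors: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 70:30 train/validation split, deterministic given seed."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    if "label" not in vectors.columns:
        raise ValueError("vectors must carry a label column")
    labels = vectors["label"].to_numpy(int)
    if labels.sum() == 0:
        raise ValueError("no positive examples to split")
    # stratify only when both sides can hold at least one of each class
    stratify = labels if labels.sum() >= 2 and (labels == 0).sum() >= 2 else None
    train, val = train_test_split(
        vectors,
        train_size=fraction,
        random_state=seed % (2**31),
        stratify=stratify,
        shuffle=True,
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


def random_undersample(
    training: pd.DataFrame, ratio: BalancingRatio, seed: int = 0
) -> pd.DataFrame:
    """Randomly downsample negatives to the requested HCSV:AV ratio.

    Every positive is kept; negatives retained =
    ``min(N, floor(P * neg_part / pos_part))``, drawn uniformly without
    replacement.  Output preserves the original row order.
    """
    labels = training["label"].to_numpy(int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size == 0:
        raise ValueError("cannot undersample with zero positive examples")
    n_keep = min(neg_idx.size, (pos_idx.size * ratio.neg_part) // ratio.pos_part)
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg_idx, size=n_keep, replace=False) if n_keep else np.array([], int)
    keep = np.sort(np.concatenate([pos_idx, kept_neg.astype(int)]))
    return training.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# hyperparameter search


def _recall_scorer():
    return make_scorer(recall_score, zero_division=0)


def cv_random_search(
    balanced: pd.DataFrame,
    space: SearchSpace,
    seed: int = 0,
    group_column: str = "sample",
) -> tuple[dict[str, Any], RandomForestClassifier]:
    """Randomized hyperparameter search with grouped cross-validation.

    Candidates are scored by mean recall over ``n_folds`` folds that keep
    variants from one sample together (GroupKFold); with fewer than
    ``n_folds`` distinct samples the search falls back to a stratified
    K-fold with a logged warning.  A fold without positive examples
    scores recall 0.  The best candidate is refit on the full balanced
    set and returned.
    """
    X = balanced[FEATURE_COLUMNS].to_numpy(float)
    y = balanced["label"].to_numpy(int)
    seeds = _child_seeds(seed, 2)
    groups = None
    if group_column in balanced.columns:
        groups = balanced[group_column].to_numpy()
    if groups is not None and len(np.unique(groups)) >= space.n_folds:
        cv = GroupKFold(n_splits=space.n_folds)
    else:
        logger.warning(
            "fewer than %d sample groups; falling back to stratified %d-fold CV",
            space.n_folds,
            space.n_folds,
        )
        cv = StratifiedKFold(n_splits=space.n_folds, shuffle=True, random_state=seeds[0])
        groups = None
    base = RandomForestClassifier(random_state=seeds[1], n_jobs=1)
    search = RandomizedSearchCV(
        base,
        param_distributions=space.grid,
        n_iter=space.n_candidates,
        scoring=_recall_scorer(),
        cv=cv,
        random_state=seeds[0],
        refit=True,
        error_score=0.0,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        search.fit(X, y, groups=groups)
    return dict(search.best_params_), search.best_estimator_


def ratio_sweep(
    training: pd.DataFrame,
    validation: pd.DataFrame,
    ratios: Sequence[BalancingRatio] = CANONICAL_RATIOS,
    space: SearchSpace | None = None,
    seed: int = 0,
    group_column: str = "sample",
) -> list[CandidateModel]:
    """Outer loop: one tuned candidate per undersampling ratio.

    Validation metrics (precision/recall at the 0.5 selection cut, plus
    PR-AUC) are computed on the identical, never-undersampled validation
    rows for every candidate.
    """
    from .evaluation import pr_curve_and_ap  # local import avoids a cycle

    space = space or SearchSpace()
    Xval = validation[FEATURE_COLUMNS].to_numpy(float)
    yval = validation["label"].to_numpy(int)
    candidates: list[CandidateModel] = []
    seeds = _child_seeds(seed, 2 * len(ratios))
    for i, ratio in enumerate(ratios):
        balanced = random_undersample(training, ratio, seed=seeds[2 * i])
        params, estimator = cv_random_search(
            balanced, space, seed=seeds[2 * i + 1], group_column=group_column
        )
        proba = estimator.predict_proba(Xval)[:, 1]
        calls = (proba >= 0.5).astype(int)  # selection cut; 0.75 applies at prediction
        prec = float(precision_score(yval, calls, zero_division=0))
        rec = float(recall_score(yval, calls, zero_division=0))
        ap = pr_curve_and_ap(proba, yval).ap if yval.sum() else 0.0
        candidates.append(
            CandidateModel(
                ratio=ratio,
                ratio_index=i,
                hyperparameters=params,
                estimator=estimator,
                validation_precision=prec,
                validation_recall=rec,
                validation_pr_auc=float(ap),
            )
        )
        logger.info(
            "ratio %s: recall=%.3f precision=%.3f pr_auc=%.3f",
            ratio.label,
            rec,
            prec,
            ap,
        )
    return candidates


def select_final_model(
    candidates: Sequence[CandidateModel],
    scaler: ScalerStats,
    probability_threshold: float = 0.75,
    seed: int = 0,
) -> FinalModel:
    """Pick the winning candidate, prioritising recall.

    Order: validation recall desc, then precision desc, then PR-AUC
    desc, then the smaller ratio index (more imbalanced ratio) wins.
    """
    if not candidates:
        raise ValueError("no candidate models to select from")
    best = sorted(
        candidates,
        key=lambda c: (
            -c.validation_recall,
            -c.validation_precision,
            -c.validation_pr_auc,
            c.ratio_index,
        ),
    )[0]
    return FinalModel(
        estimator=best.estimator,
        scaler=scaler,
        ratio=best.ratio,
        hyperparameters=dict(best.hyperparameters),
        probability_threshold=probability_threshold,
        seed=seed,
    )


def candidates_report(candidates: Sequence[CandidateModel]) -> pd.DataFrame:
    """Per-ratio validation scores (training report table)."""
    return pd.DataFrame(
        {
            "ratio": [c.ratio.label for c in candidates],
            "precision": [c.validation_precision for c in candidates],
            "recall": [c.validation_recall for c in candidates],
            "pr_auc": [c.validation_pr_auc for c in candidates],
        }
    )


def train_final_model(
    vectors: pd.DataFrame,
    ratios: Sequence[BalancingRatio] = CANONICAL_RATIOS,
    space: SearchSpace | None = None,
    split_fraction: float = 0.7,
    probability_threshold: float = 0.75,
    seed: int = 0,
    group_column: str = "sample",
) -> tuple[FinalModel, list[CandidateModel], pd.DataFrame, pd.DataFrame]:
    """Full training loop on labelled feature vectors.

    Splits 70:30, fits the depth scaler on training data only, sweeps
    the six ratios, and selects the final model.  Returns
    ``(model, candidates, training_rows, validation_rows)`` with the
    standardized depth column filled in both row sets.
    """
    train, val = split_train_validation(vectors, fraction=split_fraction, seed=seed)
    scaler = fit_depth_scaler(train["read_depth"])
    train = train.copy()
    val = val.copy()
    train["read_depth_std"] = apply_depth_scaler(scaler, train["read_depth"])
    val["read_depth_std"] = apply_depth_scaler(scaler, val["read_depth"])
    candidates = ratio_sweep(
        train, val, ratios=ratios, space=space, seed=seed, group_column=group_column
    )
    model = select_final_model(
        candidates, scaler, probability_threshold=probability_threshold, seed=seed
    )
    return model, candidates, train, val


# ---------------------------------------------------------------------------
# persistence


def persist_model(model: FinalModel, path: str | os.PathLike) -> None:
    """Serialise the final model (forest, scaler, ratio, threshold, seed)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "scaler": {"mean": model.scaler.mean, "sd": model.scaler.sd},
        "ratio": {"pos_part": model.ratio.pos_part, "neg_part": model.ratio.neg_part},
        "hyperparameters": model.hyperparameters,
        "probability_threshold": model.probability_threshold,
        "seed": model.seed,
        "feature_columns": list(model.feature_columns),
    }
    joblib.dump(payload, os.fspath(path))


def load_model(path: str | os.PathLike) -> FinalModel:
    try:
        payload = joblib.load(os.fspath(path))
    except Exception as exc:  # corrupt or not a joblib file
        raise ModelFormatError(f"cannot load model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model file {path} has unsupported format version "
            f"{payload.get('format_version') if isinstance(payload, dict) else '?'}"
        )
    return FinalModel(
        estimator=payload["estimator"],
        scaler=ScalerStats(**payload["scaler"]),
        ratio=BalancingRatio(**payload["ratio"]),
        hyperparameters=dict(payload["hyperparameters"]),
        probability_threshold=float(payload["probability_threshold"]),
        seed=int(payload["seed"]),
        feature_columns=list(payload["feature_columns"]),
    )
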