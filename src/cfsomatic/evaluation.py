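"""Model assessment and the rule-based filtering benchmark.

Precision, recall and confusion counts at the HCSV probability
threshold; precision-recall curves with the step-wise weighted-mean
average precision AP = sum_n (R_n - R_{n-1}) * P_n (no interpolation —
appropriate for heavily imbalanced variant data, where ROC curves are
over-optimistic); permutation feature importance (AP drop over repeated
shuffles of one column); partial dependence profiles; and the
rule-based filtering baseline with hard/medium/soft threshold sets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_training import FinalModel

__all__ = [
    "EvaluationMetrics",
    "PRCurve",
    "ImportanceResult",
    "PDProfile",
    "RuleThresholds",
    "RULE_LEVELS",
    "predict_hcsv",
    "confusion_and_metrics",
    "pr_curve_and_ap",
    "permutation_importance",
    "partial_dependence",
    "rule_based_filter",
    "write_evaluation_report",
]


@dataclass(slots=True)
class EvaluationMetrics:
    """Confusion counts with precision and recall.

    ``precision`` is None when nothing was called positive (TP+FP = 0).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float | None
    recall: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, Any]:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
        }


@dataclass(slots=True)
class PRCurve:
    """Precision-recall curve over decreasing score thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    ap: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "precision": self.precision, "recall": self.recall}
        )


@dataclass(slots=True)
class ImportanceResult:
    feature: str
    mean_drop: float
    sd_drop: float
    n_permutations: int


@dataclass(slots=True)
class PDProfile:
    feature: str
    grid: np.ndarray
    mean_probability: np.ndarray


def predict_hcsv(model: FinalModel, vectors: pd.DataFrame) -> pd.DataFrame:
    """Per-variant HCSV probability and thresholded call.

    A variant is called HCSV when its probability is greater than or
    equal to the model's threshold (default 0.75).
    """
    proba = model.predict_proba(vectors)
    return pd.DataFrame(
        {
            "probability": proba,
            "call": (proba >= model.probability_threshold).astype(int),
        },
        index=vectors.index,
    )


def confusion_and_metrics(
    calls: Sequence[int] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> EvaluationMetrics:
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError(f"calls ({calls.shape}) and labels ({labels.shape}) differ in length")
    tp = int(((calls == 1) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return EvaluationMetrics(tp=tp, tn=tn, fp=fp, fn=fn, precision=precision, recall=recall)


def pr_curve_and_ap(
    probabilities: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> PRCurve:
    """Precision-recall curve and step-wise average precision.

    Thresholds are the distinct scores in decreasing order; at each
    threshold t, items with score >= t are predicted positive.  AP is
    the weighted mean of precisions with recall increments as weights
    (R_0 = 0).  A recall-0 anchor carrying the first threshold's
    precision is prepended to the stored curve for plotting; it does not
    affect AP.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("cannot compute a PR curve without positive labels")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, len(y_sorted) + 1)
    # last index of each distinct score block = state after thresholding at it
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    block_ends = np.append(distinct, len(s_sorted) - 1)
    thresholds = s_sorted[block_ends]
    precision = tp_cum[block_ends] / pred_cum[block_ends]
    recall = tp_cum[block_ends] / n_pos
    ap = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    thresholds = np.concatenate([[thresholds[0]], thresholds])
    precision = np.concatenate([[precision[0]], precision])
    recall = np.concatenate([[0.0], recall])
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall, ap=ap)


def permutation_importance(
    model: FinalModel,
    vectors: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    n_permutations: int = 30,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> list[ImportanceResult]:
    """Mean AP drop when one feature column is shuffled, per feature.

    Each feature is shuffled ``n_permutations`` times in the validation
    vectors; the drop is baseline AP minus AP on the permuted copy.
    Deterministic given the seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("validation data must contain both classes")
    features = list(features) if features is not None else list(model.feature_columns)
    X = model.feature_matrix(vectors)
    baseline = pr_curve_and_ap(model.estimator.predict_proba(X)[:, 1], y).ap
    rng = np.random.default_rng(seed)
    results = []
    for feat in features:
        col = model.feature_columns.index(feat)
        drops = np.empty(n_permutations)
        for rep in range(n_permutations):
            Xp = X.copy()
            Xp[:, col] = Xp[rng.permutation(len(Xp)), col]
            ap = pr_curve_and_ap(model.estimator.predict_proba(Xp)[:, 1], y).ap
            drops[rep] = baseline - ap
        results.append(
            ImportanceResult(
                feature=feat,
                mean_drop=float(drops.mean()),
                sd_drop=float(drops.std(ddof=0)),
                n_permutations=n_permutations,
            )
        )
    return results


def partial_dependence(
    model: FinalModel,
    feature: str,
    grid: Sequence[float] | np.ndarray,
    background: pd.DataFrame,
) -> PDProfile:
    """Mean predicted HCSV probability as one feature is varied.

    For each grid value the feature is set to that value in every
    background vector and the predicted probabilities are averaged
    (all other features marginalised empirically).
    """
    if len(background) == 0:
        raise ValueError("background vectors must be non-empty")
    col = model.feature_columns.index(feature)
    X = model.feature_matrix(background)
    grid = np.asarray(grid, dtype=float)
    means = np.empty(len(grid))
    for i, v in enumerate(grid):
        Xv = X.copy()
        Xv[:, col] = v
        means[i] = float(model.estimator.predict_proba(Xv)[:, 1].mean())
    return PDProfile(feature=feature, grid=grid, mean_probability=means)


# ---------------------------------------------------------------------------
# rule-based filtering benchmark


@dataclass(frozen=True, slots=True)
class RuleThresholds:
    """One row of the rule-based benchmark (hard/medium/soft).

    Depth cuts are strict (depth must exceed the cut, as printed);
    QUAL is inclusive; dbSNP flag must be 0 and COSMIC flag 1; the
    germline allele-frequency filter always applies.
    """

    level: str
    depth_low: int
    depth_high: int
    qual_min: float
    dbsnp_required: int = 0
    cosmic_required: int = 1


RULE_LEVELS: dict[str, RuleThresholds] = {
    "hard": RuleThresholds("hard", depth_low=20, depth_high=1000, qual_min=50.0),
    "medium": RuleThresholds("medium", depth_low=10, depth_high=750, qual_min=40.0),
    "soft": RuleThresholds("soft", depth_low=5, depth_high=500, qual_min=20.0),
}


def rule_based_filter(
    variants: pd.DataFrame,
    thresholds: RuleThresholds | str,
    mode: str = "low",
) -> tuple[np.ndarray, EvaluationMetrics | None]:
    """Apply one rule-based filtering level; optionally score against labels.

    ``variants`` needs read_depth (or depth), qual, in_dbsnp, in_cosmic
    and allele_frequency (or af) columns.  Returns a boolean retained
    mask plus metrics when a ``label`` column is present (retained =
    positive call).
    """
    if isinstance(thresholds, str):
        try:
            thresholds = RULE_LEVELS[thresholds]
        except KeyError:
            raise ValueError(f"unknown rule level {thresholds!r}") from None
    if mode not in ("low", "high"):
        raise ValueError(f"mode must be 'low' or 'high', got {mode!r}")
    depth_col = "read_depth" if "read_depth" in variants.columns else "depth"
    af_col = "allele_frequency" if "allele_frequency" in variants.columns else "af"
    depth = variants[depth_col].to_numpy(float)
    qual = variants["qual"].to_numpy(float)
    af = variants[af_col].to_numpy(float)
    if np.any((af < 0) | (af > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    cut = thresholds.depth_low if mode == "low" else thresholds.depth_high
    mask = depth > cut
    mask &= ~np.isnan(qual) & (qual >= thresholds.qual_min)
    mask &= variants["in_dbsnp"].to_numpy(int) == thresholds.dbsnp_required
    mask &= variants["in_cosmic"].to_numpy(int) == thresholds.cosmic_required
    mask &= ~((af >= 0.4) & (af <= 0.6)) & ~(af > 0.9)
    metrics = None
    if "label" in variants.columns:
        metrics = confusion_and_metrics(mask.astype(int), variants["label"].to_numpy(int))
    return mask, metrics


def write_evaluation_report(
    path: str | os.PathLike,
    metrics: EvaluationMetrics,
    pr_curve: PRCurve | None = None,
    extra: Mapping[str, Any] | None = None,
) -> None:
    """Evaluation summary as JSON (confusion counts, metrics, AP, extras)."""
    payload: dict[str, Any] = {"metrics": metrics.as_dict()}
    if pr_curve is not None:
        payload["pr_auc"] = pr_curve.ap
    if extra:
        payload.update(dict(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
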