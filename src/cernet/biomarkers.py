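"""Random-forest biomarker selection and LOOCV ROC/AUC evaluation.

Selection ranks candidate features by importance averaged over several
forest refits, then evaluates nested panels (top-1, top-2, ..., top-p) by
out-of-bag (OOB) error and keeps the panel minimizing it (ties break toward
the smaller panel).  The fixed panel is then evaluated by leave-one-out
cross-validation; per-sample out-of-fold scores are the positive-class vote
fraction of a forest trained on the remaining samples.

The positive class defaults to ``low_BMD`` (the at-risk group a diagnostic
flags).  AUC is computed by the trapezoidal rule over the threshold-swept
ROC curve and cross-checked against the tie-corrected Mann-Whitney
statistic.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .io import (
    GROUP_HIGH,
    GROUP_LOW,
    ExpressionMatrix,
    GroupLabels,
    ValidationError,
)

PREDICTION_COLUMNS = ["sample_id", "true_group", "score", "predicted_group"]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings shared by selection and evaluation."""

    n_trees: int = 1000
    mtry_rule: str = "sqrt"
    importance_type: str = "permutation"
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.n_repeats < 1:
            raise ValidationError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.importance_type not in ("permutation", "impurity"):
            raise ValidationError(
                f"importance_type must be 'permutation' or 'impurity', "
                f"got {self.importance_type!r}"
            )
        self._max_features()  # validate eagerly

    def _max_features(self):
        if self.mtry_rule in ("sqrt", "log2"):
            return self.mtry_rule
        try:
            value = float(self.mtry_rule)
        except ValueError:
            raise ValidationError(f"bad mtry_rule {self.mtry_rule!r}")
        return int(value) if value >= 1 else value

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def _forest(config: RFConfig, random_state: int, oob: bool = True) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config._max_features(),
        oob_score=oob,
        bootstrap=True,
        random_state=random_state,
        n_jobs=1,
    )


def _design(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    features: Sequence[str],
    positive: str = GROUP_LOW,
) -> tuple[np.ndarray, np.ndarray]:
    restricted = matrix.restrict(list(features))
    X = restricted.values.T  # samples x features
    y = labels.binary(matrix.sample_ids, positive)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both groups must be present")
    return X, y


def oob_error(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    features: Sequence[str],
    config: RFConfig,
) -> float:
    """Out-of-bag misclassification rate, averaged over ``n_repeats`` refits."""
    if len(features) < 1:
        raise ValidationError("oob_error needs >= 1 feature")
    X, y = _design(matrix, labels, features)
    errors = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        for i in range(config.n_repeats):
            forest = _forest(config, config.seed + i).fit(X, y)
            errors.append(1.0 - forest.oob_score_)
    return float(np.mean(errors))


def feature_importances(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    candidates: Sequence[str],
    config: RFConfig,
) -> pd.Series:
    """Importance per candidate, averaged over ``n_repeats`` forest refits."""
    X, y = _design(matrix, labels, candidates)
    total = np.zeros(len(candidates))
    for i in range(config.n_repeats):
        forest = _forest(config, config.seed + i, oob=False).fit(X, y)
        if config.importance_type == "impurity":
            total += forest.feature_importances_
        else:
            result = permutation_importance(
                forest, X, y, n_repeats=5, random_state=config.seed + i, n_jobs=1
            )
            total += result.importances_mean
    return pd.Series(total / config.n_repeats, index=list(candidates))


@dataclass
class BiomarkerPanel:
    """Ordered selected features plus the OOB-error trace justifying them."""

    selected: tuple[str, ...]
    importances: dict[str, float]
    oob_trace: tuple[tuple[int, float], ...]
    config_digest: str = ""

    @property
    def size(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.selected) + 1),
                "gene_id": self.selected,
                "importance": [self.importances[g] for g in self.selected],
            }
        )


def select_biomarkers(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    config: RFConfig,
    candidates: Sequence[str] | None = None,
    max_panel_size: int | None = None,
) -> BiomarkerPanel:
    """Rank candidates by importance and pick the nested panel with minimal OOB error.

    ``max_panel_size`` caps the nested sweep (top-1 ... top-k) as a
    performance knob; by default every panel up to the full candidate set is
    visited.
    """
    cand = list(candidates) if candidates is not None else matrix.gene_ids
    if not cand:
        raise ValidationError("candidate feature set is empty")
    importances = feature_importances(matrix, labels, cand, config)
    ranked = sorted(cand, key=lambda g: (-importances[g], g))
    limit = len(ranked) if max_panel_size is None else min(max_panel_size, len(ranked))
    trace = []
    for k in range(1, limit + 1):
        trace.append((k, oob_error(matrix, labels, ranked[:k], config)))
    best_k = min(trace, key=lambda item: (item[1], item[0]))[0]
    return BiomarkerPanel(
        selected=tuple(ranked[:best_k]),
        importances={g: float(importances[g]) for g in ranked},
        oob_trace=tuple(trace),
        config_digest=config.digest(),
    )


def intersect_panel(panel: BiomarkerPanel, available: Iterable[str]) -> BiomarkerPanel:
    """Restrict a panel to the features available on another platform."""
    available = set(available)
    kept = tuple(g for g in panel.selected if g in available)
    if not kept:
        raise ValidationError("panel has no overlap with the available features")
    return replace(panel, selected=kept)


# ---------------------------------------------------------------------------
# LOOCV evaluation
# ---------------------------------------------------------------------------


def loocv_evaluate(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    panel: BiomarkerPanel,
    config: RFConfig,
    positive_group: str = GROUP_LOW,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-out out-of-fold scores for the fixed panel.

    Returns one row per sample (:data:`PREDICTION_COLUMNS`); ``score`` is the
    held-out sample's positive-class vote fraction.
    """
    X, y = _design(matrix, labels, panel.selected, positive_group)
    n = len(y)
    for value in (0, 1):
        if (y == value).sum() < 2:
            raise ValidationError(
                "LOOCV needs >= 2 samples per group so no training fold loses a group"
            )
    rows = []
    negative_group = GROUP_HIGH if positive_group == GROUP_LOW else GROUP_LOW
    for i in range(n):
        mask = np.arange(n) != i
        forest = _forest(config, config.seed + i, oob=False).fit(X[mask], y[mask])
        proba = forest.predict_proba(X[i : i + 1])[0]
        score = float(proba[list(forest.classes_).index(1)])
        sample = matrix.sample_ids[i]
        rows.append(
            {
                "sample_id": sample,
                "true_group": labels.mapping[sample],
                "score": score,
                "predicted_group": positive_group if score >= threshold else negative_group,
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def predictions_from_counts(
    n_correct_positive: int,
    n_total_positive: int,
    n_correct_negative: int,
    n_total_negative: int,
    positive_group: str = GROUP_LOW,
) -> pd.DataFrame:
    """Reconstruct a prediction set from published confusion counts.

    Correctly classified positives get score 1, misclassified positives 0,
    and vice versa for negatives, so thresholding at 0.5 reproduces the
    counts exactly.
    """
    if not (0 <= n_correct_positive <= n_total_positive):
        raise ValidationError("positive counts inconsistent")
    if not (0 <= n_correct_negative <= n_total_negative):
        raise ValidationError("negative counts inconsistent")
    negative_group = GROUP_HIGH if positive_group == GROUP_LOW else GROUP_LOW
    rows = []
    for i in range(n_total_positive):
        correct = i < n_correct_positive
        rows.append(
            {
                "sample_id": f"pos_{i + 1}",
                "true_group": positive_group,
                "score": 1.0 if correct else 0.0,
                "predicted_group": positive_group if correct else negative_group,
            }
        )
    for i in range(n_total_negative):
        correct = i < n_correct_negative
        rows.append(
            {
                "sample_id": f"neg_{i + 1}",
                "true_group": negative_group,
                "score": 0.0 if correct else 1.0,
                "predicted_group": negative_group if correct else positive_group,
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# ---------------------------------------------------------------------------
# ROC / AUC / confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """ROC curve, AUC (with optional CI), and threshold confusion metrics."""

    roc_points: tuple[tuple[float, float], ...] = ()
    auc: float = float("nan")
    auc_ci: tuple[float, float] | None = None
    ci_method: str | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    confusion: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "ci_method": self.ci_method,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "roc_points": [list(p) for p in self.roc_points],
        }


def _scores_and_truth(
    predictions: pd.DataFrame, positive_group: str
) -> tuple[np.ndarray, np.ndarray]:
    y = (predictions["true_group"] == positive_group).to_numpy().astype(int)
    s = predictions["score"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both groups must be present in the prediction set")
    return s, y


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the tie-corrected Mann-Whitney U statistic / (n1*n2)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_and_auc(
    predictions: pd.DataFrame, positive_group: str = GROUP_LOW
) -> EvaluationReport:
    """ROC by threshold sweep, AUC by the trapezoidal rule.

    The trapezoidal AUC is cross-checked against the tie-corrected
    Mann-Whitney statistic.  All-identical scores yield AUC 0.5 with a
    degeneracy warning.
    """
    s, y = _scores_and_truth(predictions, positive_group)
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; ROC is degenerate, AUC = 0.5")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each distinct score
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    mw = mann_whitney_auc(s, y)
    if abs(auc - mw) > 1e-10:  # pragma: no cover - internal consistency guard
        raise AssertionError(f"trapezoid AUC {auc} != Mann-Whitney AUC {mw}")
    return EvaluationReport(
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())), auc=auc
    )


def confusion_metrics(
    predictions: pd.DataFrame,
    positive_group: str = GROUP_LOW,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Accuracy, sensitivity, specificity at ``score >= threshold``."""
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    s, y = _scores_and_truth(predictions, positive_group)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    total = tp + tn + fp + fn
    return EvaluationReport(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def percent(value: float, ndigits: int = 1) -> float:
    """Express a proportion as a percentage at 0.1% precision by default."""
    return round(100.0 * value, ndigits)


def auc_ci(
    predictions: pd.DataFrame,
    level: float = 0.95,
    method: str = "bootstrap",
    positive_group: str = GROUP_LOW,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``bootstrap`` resamples within each group (stratified, percentile
    interval); ``hanley_mcneil`` uses the closed-form standard error.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    s, y = _scores_and_truth(predictions, positive_group)
    pos, neg = s[y == 1], s[y == 0]
    n1, n2 = len(pos), len(neg)
    if method == "bootstrap":
        if n1 < 2 or n2 < 2:
            raise ValidationError("stratified bootstrap needs >= 2 samples per group")
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, n1, n1)]
            bn = neg[rng.integers(0, n2, n2)]
            greater = (bp[:, None] > bn[None, :]).sum()
            ties = (bp[:, None] == bn[None, :]).sum()
            aucs[b] = (greater + 0.5 * ties) / (n1 * n2)
        lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)
    if method == "hanley_mcneil":
        auc = mann_whitney_auc(s, y)
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)
        ) / (n1 * n2)
        se = float(np.sqrt(max(var, 0.0)))
        z = float(stats.norm.ppf(1 - (1 - level) / 2))
        return max(0.0, auc - z * se), min(1.0, auc + z * se)
    raise ValidationError(f"unknown CI method {method!r}")


def evaluate(
    predictions: pd.DataFrame,
    positive_group: str = GROUP_LOW,
    threshold: float = 0.5,
    ci_method: str = "bootstrap",
    ci_level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Full evaluation: ROC/AUC, CI, and threshold confusion metrics."""
    roc = roc_and_auc(predictions, positive_group)
    conf = confusion_metrics(predictions, positive_group, threshold)
    ci = auc_ci(predictions, ci_level, ci_method, positive_group, seed=seed)
    return EvaluationReport(
        roc_points=roc.roc_points,
        auc=roc.auc,
        auc_ci=ci,
        ci_method=ci_method,
        accuracy=conf.accuracy,
        sensitivity=conf.sensitivity,
        specificity=conf.specificity,
        confusion=conf.confusion,
    )
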