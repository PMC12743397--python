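"""Linear SVM discrimination of each subpopulation from healthy controls.

One soft-margin linear SVM (box constraint C = 1, kernel scale 1) is trained
per subpopulation against the healthy-control cohort in PC space.  Pre-surgery
performance is measured by seeded stratified 10-fold cross-validation with
pooled out-of-fold predictions: classification rate, sensitivity (pathologic
positive), specificity, ROC-AUC, and the pathologic ratio (percentage of the
subpopulation classified to the pathologic side).  The paired post-surgery
cohort is projected through the final model (trained on all pre-surgery data),
which is the only model defined for unseen subjects.

Decision-value orientation: positive = healthy-control side, so larger values
mean gait closer to the healthy pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "LinearGaitClassifier",
    "ClassificationReport",
    "train_linear_svm",
    "crossvalidate_10fold",
    "pathologic_ratio",
    "project_followup",
]

PATHOLOGIC, HC = -1, 1  # class codes; SVC orders classes as (-1, +1) so a
# positive decision value lands on the HC side by construction.


@dataclass
class ClassificationReport:
    """Performance summary in the layout of the per-subpopulation results table."""

    subpop_id: int
    era: str  # "pre" | "post"
    classification_rate: float  # % correct over pooled predictions (NaN post-surgery)
    n_classified_pathologic: int
    n_classified_hc: int
    pathologic_ratio: float  # % of the subpopulation on the pathologic side
    sensitivity: float
    specificity: float
    roc_auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.roc_auc <= 1.0:
            raise ValueError("ROC-AUC must lie in [0, 1]")

    def to_row(self) -> dict:
        return {
            "subpop": self.subpop_id,
            "era": self.era,
            "classification_rate": self.classification_rate,
            "n_pathologic": self.n_classified_pathologic,
            "n_hc": self.n_classified_hc,
            "pathologic_ratio": self.pathologic_ratio,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc": self.roc_auc,
        }


@dataclass
class LinearGaitClassifier:
    """A trained subpopulation-vs-HC linear SVM in PC space.

    weights/bias are in raw (unscaled) feature units; decision(x) =
    weights @ x + bias, positive on the healthy-control side.  background is
    the training-set feature mean, used downstream as the Shapley reference
    point.  cv_predictions holds one out-of-fold row per training subject.
    """

    subpop_id: int
    weights: np.ndarray
    bias: float
    background: np.ndarray
    cv_predictions: pd.DataFrame | None = None
    report: ClassificationReport | None = None

    def __post_init__(self) -> None:
        if np.linalg.norm(self.weights) == 0:
            raise ValueError("weight vector must be nonzero")

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match classifier ({self.weights.shape[0]})"
            )
        return x @ self.weights + self.bias


def train_linear_svm(
    pathologic_scores: np.ndarray,
    hc_scores: np.ndarray,
    box_constraint: float = 1.0,
    kernel_scale: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Fit the soft-margin linear SVM; returns (weights, bias) in raw units.

    Features are divided by kernel_scale before fitting; the returned weights
    fold that scaling back in, so scaling all features by c together with
    kernel_scale by c leaves decision values unchanged.
    """
    pathologic_scores = np.atleast_2d(np.asarray(pathologic_scores, dtype=float))
    hc_scores = np.atleast_2d(np.asarray(hc_scores, dtype=float))
    if pathologic_scores.shape[0] == 0 or hc_scores.shape[0] == 0:
        raise ValueError("both classes need at least one subject")
    if pathologic_scores.shape[1] != hc_scores.shape[1]:
        raise ValueError("feature dimensions differ between classes")
    if kernel_scale <= 0 or box_constraint <= 0:
        raise ValueError("box_constraint and kernel_scale must be > 0")
    x = np.vstack([pathologic_scores, hc_scores]) / kernel_scale
    y = np.concatenate(
        [np.full(len(pathologic_scores), PATHOLOGIC), np.full(len(hc_scores), HC)]
    )
    model = SVC(kernel="linear", C=box_constraint, tol=1e-6)
    model.fit(x, y)
    weights = model.coef_.ravel() / kernel_scale
    bias = float(model.intercept_[0])
    return weights, bias


def pathologic_ratio(n_pathologic_classified: int, n_total: int) -> float:
    """Percentage of a subpopulation classified to the pathologic side, 1 d.p."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_pathologic_classified <= n_total:
        raise ValueError("need 0 <= n_pathologic_classified <= n_total")
    return round(100.0 * n_pathologic_classified / n_total, 1)


def _metrics(y_true: np.ndarray, decision: np.ndarray) -> tuple[float, float, float, float]:
    """(rate %, sensitivity, specificity, auc) with pathologic as positive."""
    pred = np.where(decision < 0, PATHOLOGIC, HC)
    correct = pred == y_true
    rate = 100.0 * correct.mean()
    is_path = y_true == PATHOLOGIC
    sensitivity = float(correct[is_path].mean()) if is_path.any() else np.nan
    specificity = float(correct[~is_path].mean()) if (~is_path).any() else np.nan
    # rank statistic: pathologic positive, scored by distance to the pathologic side
    auc = float(roc_auc_score(is_path.astype(int), -decision))
    return rate, sensitivity, specificity, auc


def crossvalidate_10fold(
    pathologic_scores: np.ndarray,
    hc_scores: np.ndarray,
    subpop_id: int = 1,
    seed: int = 0,
    n_folds: int = 10,
    box_constraint: float = 1.0,
    kernel_scale: float = 1.0,
    pathologic_ids: list[str] | None = None,
    hc_ids: list[str] | None = None,
) -> LinearGaitClassifier:
    """Stratified seeded k-fold CV with pooled out-of-fold predictions.

    Returns the classifier carrying the final model (trained on all data),
    the out-of-fold prediction table and the pre-surgery report.  If a class
    has fewer members than folds, the fold count is reduced with a warning.
    """
    pathologic_scores = np.atleast_2d(np.asarray(pathologic_scores, dtype=float))
    hc_scores = np.atleast_2d(np.asarray(hc_scores, dtype=float))
    n1, n2 = len(pathologic_scores), len(hc_scores)
    if n1 + n2 < n_folds:
        raise ValueError("need at least as many subjects as folds")
    min_class = min(n1, n2)
    folds = n_folds
    if min_class < n_folds:
        folds = max(2, min_class)
        logger.warning(
            "reducing folds from %d to %d: smallest class has %d members",
            n_folds,
            folds,
            min_class,
        )
    if pathologic_ids is None:
        pathologic_ids = [f"P{i:03d}" for i in range(n1)]
    if hc_ids is None:
        hc_ids = [f"C{i:03d}" for i in range(n2)]

    x = np.vstack([pathologic_scores, hc_scores])
    y = np.concatenate([np.full(n1, PATHOLOGIC), np.full(n2, HC)])
    ids = list(pathologic_ids) + list(hc_ids)

    decision = np.empty(len(x))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        w, b = train_linear_svm(
            x[train][y[train] == PATHOLOGIC],
            x[train][y[train] == HC],
            box_constraint,
            kernel_scale,
        )
        decision[test] = x[test] @ w + b

    rate, sens, spec, auc = _metrics(y, decision)
    n_path_classified = int((decision[:n1] < 0).sum())
    report = ClassificationReport(
        subpop_id=subpop_id,
        era="pre",
        classification_rate=rate,
        n_classified_pathologic=n_path_classified,
        n_classified_hc=n1 - n_path_classified,
        pathologic_ratio=pathologic_ratio(n_path_classified, n1),
        sensitivity=sens,
        specificity=spec,
        roc_auc=auc,
    )
    cv_predictions = pd.DataFrame(
        {
            "subject_id": ids,
            "true_class": np.where(y == PATHOLOGIC, "pathologic", "hc"),
            "decision_value": decision,
            "predicted_class": np.where(decision < 0, "pathologic", "hc"),
        }
    )
    w, b = train_linear_svm(pathologic_scores, hc_scores, box_constraint, kernel_scale)
    return LinearGaitClassifier(
        subpop_id=subpop_id,
        weights=w,
        bias=b,
        background=x.mean(axis=0),
        cv_predictions=cv_predictions,
        report=report,
    )


def project_followup(
    classifier: LinearGaitClassifier,
    followup_scores: np.ndarray,
    hc_scores: np.ndarray,
) -> ClassificationReport:
    """Evaluate the paired post-surgery cohort through the final model.

    Follow-up subjects with negative (pathologic-side) decision values count
    as pathologic.  Sensitivity is the fraction of follow-up subjects still
    classified pathologic; specificity and ROC-AUC are computed against the
    healthy-control cohort under the same final model.  The classification
    rate is not defined for this projection and is reported as NaN.
    """
    followup_scores = np.atleast_2d(np.asarray(followup_scores, dtype=float))
    if followup_scores.shape[0] < 1:
        raise ValueError("need at least one follow-up subject")
    d_fu = classifier.decision(followup_scores)
    d_hc = classifier.decision(hc_scores)
    m = len(d_fu)
    n_path = int((d_fu < 0).sum())
    y = np.concatenate([np.full(m, PATHOLOGIC), np.full(len(d_hc), HC)])
    _, sens, spec, auc = _metrics(y, np.concatenate([d_fu, d_hc]))
    return ClassificationReport(
        subpop_id=classifier.subpop_id,
        era="post",
        classification_rate=float("nan"),
        n_classified_pathologic=n_path,
        n_classified_hc=m - n_path,
        pathologic_ratio=pathologic_ratio(n_path, m),
        sensitivity=sens,
        specificity=spec,
        roc_auc=auc,
    )
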