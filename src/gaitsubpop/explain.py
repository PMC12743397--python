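"""Explainability: Shapley attributions, waveform importance, and COGS.

For a linear decision function f(x) = w.x + b with an independent-features
background distribution concentrated at the training mean m, the Shapley
value of feature i has the closed form phi_i = w_i (x_i - m_i) and satisfies
the efficiency identity sum_i phi_i = f(x) - f(m) exactly.

Per-PC attributions are mapped back to the 18 original waveform channels by
weighting each subject's PC score with the absolute Shapley value, projecting
the weighted score vector through the eigenbasis back to waveform space, and
averaging the absolute reconstructed values over the stance grid and over
the subpopulation's subjects.  The five top-ranked channels characterize the
subpopulation biomechanically.

COGS (classifier-oriented gait score) is the signed orthogonal distance of a
subject's PC vector to the SVM hyperplane, positive toward the healthy side,
so an increase after surgery reads as improved gait quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EigenBasis
from .svm import LinearGaitClassifier

__all__ = [
    "ShapleyVector",
    "ImportanceProfile",
    "CogsRecord",
    "linear_shap",
    "waveform_importance",
    "top_k",
    "cogs",
    "cogs_table",
]


@dataclass
class ShapleyVector:
    """Per-PC Shapley attribution of one subject's decision value."""

    subject_id: str
    phi: np.ndarray  # [P]
    expected_value: float  # decision function at the background point


@dataclass
class ImportanceProfile:
    """Per-channel waveform importance for one subpopulation's classifier."""

    subpop_id: int
    channel_names: tuple[str, ...]
    importance: np.ndarray  # [n_channels], non-negative
    ranking: tuple[str, ...]  # channels by decreasing importance

    def __post_init__(self) -> None:
        if len(self.importance) != len(self.channel_names):
            raise ValueError("importance length does not match channel count")
        if not np.all(np.isfinite(self.importance)) or np.any(self.importance < 0):
            raise ValueError("importances must be finite and non-negative")
        if sorted(self.ranking) != sorted(self.channel_names):
            raise ValueError("ranking must be a permutation of the channel names")

    @property
    def top5(self) -> tuple[str, ...]:
        return self.ranking[:5]

    def to_frame(self) -> pd.DataFrame:
        by_name = dict(zip(self.channel_names, self.importance))
        return pd.DataFrame(
            {
                "subpop": self.subpop_id,
                "rank": np.arange(1, len(self.ranking) + 1),
                "channel": self.ranking,
                "importance": [by_name[c] for c in self.ranking],
            }
        )


@dataclass
class CogsRecord:
    """Classifier-oriented gait score of one subject at one examination era."""

    subject_id: str
    era: str  # "pre" | "post"
    cogs: float


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def linear_shap(
    weights: np.ndarray,
    bias: float,
    score_vector: np.ndarray,
    background_mean: np.ndarray,
    subject_id: str = "",
) -> ShapleyVector:
    """Exact Shapley values of a linear decision function.

    phi_i = w_i (x_i - m_i); expected_value = w.m + b.
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(score_vector, dtype=float)
    m = np.asarray(background_mean, dtype=float)
    if not weights.shape == x.shape == m.shape:
        raise ValueError(
            f"dimension mismatch: weights {weights.shape}, x {x.shape}, background {m.shape}"
        )
    phi = weights * (x - m)
    return ShapleyVector(
        subject_id=subject_id, phi=phi, expected_value=float(weights @ m + bias)
    )


def waveform_importance(
    classifier: LinearGaitClassifier,
    subpop_scores: np.ndarray,
    basis: EigenBasis,
    channel_names: tuple[str, ...],
    n_timepoints: int = 101,
) -> ImportanceProfile:
    """Back-project per-PC Shapley attributions to per-channel importances.

    For each subject: u_i = |phi_i| * score_i (the Shapley-weighted PC
    vector), r = eigenvectors @ u reconstructed to the waveform grid, then
    the subject's per-channel contribution is the mean of |r| over the 101
    timepoints (absolute values prevent cancellation between stance
    sub-phases).  The profile averages contributions over the subpopulation's
    subjects; ties in the ranking break by canonical channel order.
    """
    subpop_scores = np.atleast_2d(np.asarray(subpop_scores, dtype=float))
    if subpop_scores.shape[0] == 0:
        raise ValueError("importance requires at least one subject")
    if subpop_scores.shape[1] != basis.n_retained:
        raise ValueError("scores and basis disagree on the number of components")
    if classifier.weights.shape[0] != basis.n_retained:
        raise ValueError("classifier and basis disagree on the number of components")
    n_channels = len(channel_names)
    if basis.eigenvectors.shape[0] != n_channels * n_timepoints:
        raise ValueError("basis dimensionality does not match channels x timepoints")

    phi = np.abs(classifier.weights[None, :] * (subpop_scores - classifier.background))
    u = phi * subpop_scores  # [n, P]
    r = u @ basis.eigenvectors.T  # [n, D]
    r = r.reshape(len(u), n_channels, n_timepoints)
    contributions = np.abs(r).mean(axis=2)  # [n, C]
    importance = contributions.mean(axis=0)  # [C]
    order = np.argsort(-importance, kind="stable")  # stable: ties keep canonical order
    ranking = tuple(channel_names[i] for i in order)
    return ImportanceProfile(
        subpop_id=classifier.subpop_id,
        channel_names=tuple(channel_names),
        importance=importance,
        ranking=ranking,
    )


def top_k(profile: ImportanceProfile, k: int = 5) -> tuple[str, ...]:
    """The k most influential waveform channels."""
    if k <= 0:
        raise ValueError("k must be > 0")
    if k > len(profile.ranking):
        raise ValueError(f"k ({k}) exceeds the number of channels ({len(profile.ranking)})")
    return profile.ranking[:k]


def cogs(weights: np.ndarray, bias: float, score_vector: np.ndarray) -> float:
    """Signed orthogonal distance to the SVM hyperplane (positive = healthy side)."""
    weights = np.asarray(weights, dtype=float)
    norm = np.linalg.norm(weights)
    if norm == 0:
        raise ValueError("COGS undefined for a zero weight vector")
    x = np.asarray(score_vector, dtype=float)
    if x.shape != weights.shape:
        raise ValueError("score vector and weights differ in dimension")
    return float((weights @ x + bias) / norm)


def cogs_table(
    classifier: LinearGaitClassifier,
    scores: np.ndarray,
    subject_ids: list[str],
    era: str,
) -> list[CogsRecord]:
    """COGS for a cohort of subjects under one classifier."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return [
        CogsRecord(subject_id=sid, era=era, cogs=cogs(classifier.weights, classifier.bias, row))
        for sid, row in zip(subject_ids, scores)
    ]
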