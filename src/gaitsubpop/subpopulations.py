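"""Subpopulation discovery by hierarchical + consensus k-means clustering.

The number of clusters is chosen from the Ward dendrogram of the patient
PC scores via the largest relative merge-height gap.  Membership is then
assigned by k-means executed several times with different seeds; subjects
whose (label-aligned) assignment is not unanimous across runs are marked
EXCLUDED, mirroring the practice of dropping patients that cannot be
consistently placed in any single subpopulation.  Cluster fit is scored by
classic silhouette coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "SubpopulationAssignment",
    "ward_select_k",
    "ward_merge_heights",
    "kmeans_consensus",
    "silhouettes",
    "assignments_frame",
]


@dataclass
class SubpopulationAssignment:
    """One subject's cluster membership.

    label is an integer in 1..k for consistently assigned subjects and None
    for EXCLUDED ones; consistent is False exactly when the subject is
    EXCLUDED; silhouette is filled in by :func:`silhouettes`.
    """

    subject_id: str
    label: int | None
    consistent: bool
    silhouette: float | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == self.consistent:
            raise ValueError("EXCLUDED (label None) must coincide with consistent=False")


# --------------------------------------------------------------------------
# Ward k selection
# --------------------------------------------------------------------------


def ward_merge_heights(scores: np.ndarray) -> np.ndarray:
    """Fusion heights h_k joining k clusters into k-1, for k = 2..N.

    Returned in increasing-k order: entry 0 is h_2 (the final merge), entry
    i is h_{i+2}.  Useful for auditing the k-selection rule.
    """
    z = linkage(scores, method="ward")
    heights = z[:, 2]
    return heights[::-1].copy()


def ward_select_k(scores: np.ndarray, k_min: int = 2, k_max: int = 10) -> int:
    """Pick the number of clusters from the Ward dendrogram.

    Returns the k in [k_min, k_max] maximizing the relative merge-height gap
    g(k) = (h_k - h_{k+1}) / h_{k+1}, where h_k is the fusion height at which
    k clusters merge into k-1: a large gap means the data resist being merged
    below k clusters.  Ties break toward smaller k.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if n <= k_max:
        raise ValueError(f"need more subjects ({n}) than k_max ({k_max})")
    if k_min == k_max:
        return k_min
    h = ward_merge_heights(scores)  # h[k-2] = h_k
    best_k, best_g = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        hk, hk1 = h[k - 2], h[k - 1]
        g = (hk - hk1) / hk1 if hk1 > 0 else np.inf
        if g > best_g:  # strict: ties keep the smaller k
            best_k, best_g = k, g
    return best_k


# --------------------------------------------------------------------------
# Consensus k-means
# --------------------------------------------------------------------------


def _align_to_reference(reference: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to best agree with ``reference`` (Hungarian matching)."""
    confusion = np.zeros((k, k), dtype=int)
    for r, l in zip(reference, labels):
        confusion[r, l] += 1
    _, col = linear_sum_assignment(-confusion)
    mapping = np.empty(k, dtype=int)
    mapping[col] = np.arange(k)
    return mapping[labels]


def consensus_from_runs(
    run_labels: np.ndarray, subject_ids: list[str]
) -> list[SubpopulationAssignment]:
    """Combine aligned labels of repeated runs into consensus assignments.

    run_labels is [n_runs, N] with labels 0..k-1; runs after the first are
    aligned to run 1 by maximum-agreement bipartite matching.  A subject is
    consistent iff all aligned labels agree.  Consistent clusters are
    renumbered 1..k by decreasing size, ties by smallest member subject_id.
    """
    run_labels = np.asarray(run_labels)
    n_runs, n = run_labels.shape
    k = int(run_labels.max()) + 1
    aligned = run_labels.copy()
    for r in range(1, n_runs):
        aligned[r] = _align_to_reference(aligned[0], aligned[r], k)
    consistent = (aligned == aligned[0]).all(axis=0)
    consensus = aligned[0]

    # canonical numbering: by decreasing consistent-member count, ties by the
    # lexicographically smallest subject_id contained
    order_keys = []
    for c in range(k):
        members = [subject_ids[i] for i in range(n) if consistent[i] and consensus[i] == c]
        size = len(members)
        order_keys.append((-size, min(members) if members else "~", c))
    ranked = sorted(range(k), key=lambda c: order_keys[c])
    renumber = {c: rank + 1 for rank, c in enumerate(ranked)}

    out = []
    for i in range(n):
        if consistent[i]:
            out.append(
                SubpopulationAssignment(
                    subject_id=subject_ids[i], label=renumber[consensus[i]], consistent=True
                )
            )
        else:
            out.append(
                SubpopulationAssignment(subject_id=subject_ids[i], label=None, consistent=False)
            )
    return out


def kmeans_consensus(
    scores: np.ndarray,
    k: int,
    subject_ids: list[str] | None = None,
    n_runs: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> list[SubpopulationAssignment]:
    """Repeated seeded k-means with unanimity-based consistency filtering.

    Run r (1-based) uses k-means++ initialization seeded by ``seed + r`` with
    ``n_init`` restarts (so each run reports its best local optimum and the
    consensus filter flags genuinely ambiguous subjects, not optimizer
    noise); later runs are label-aligned to run 1 before the unanimity check.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of subjects ({n})")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if subject_ids is None:
        subject_ids = [f"{i:04d}" for i in range(n)]
    runs = np.empty((n_runs, n), dtype=int)
    for r in range(n_runs):
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed + r + 1)
        runs[r] = km.fit_predict(scores)
    return consensus_from_runs(runs, subject_ids)


# --------------------------------------------------------------------------
# Silhouettes
# --------------------------------------------------------------------------


def silhouettes(
    scores: np.ndarray, assignments: list[SubpopulationAssignment]
) -> list[SubpopulationAssignment]:
    """Fill in classic silhouette values s = (b - a)/max(a, b) per subject.

    EXCLUDED subjects are omitted from the computation and keep silhouette
    None; singleton clusters get s = 0 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    idx = [i for i, a in enumerate(assignments) if a.consistent]
    labels = np.array([assignments[i].label for i in idx])
    if np.unique(labels).size < 2:
        raise ValueError("silhouettes require >= 2 clusters with members")
    values = silhouette_samples(scores[idx], labels, metric="euclidean")
    out = list(assignments)
    for j, i in enumerate(idx):
        a = assignments[i]
        out[i] = SubpopulationAssignment(
            subject_id=a.subject_id,
            label=a.label,
            consistent=True,
            silhouette=float(values[j]),
        )
    return out


def assignments_frame(assignments: list[SubpopulationAssignment]) -> pd.DataFrame:
    """Tabular view: subject_id, label ('EXCLUDED' for dropped), consistent, silhouette."""
    return pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "label": [a.label if a.label is not None else "EXCLUDED" for a in assignments],
            "consistent": [a.consistent for a in assignments],
            "silhouette": [a.silhouette for a in assignments],
        }
    )
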