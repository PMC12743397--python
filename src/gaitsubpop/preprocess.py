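"""Waveform preprocessing and the shared reduced feature space.

The pipeline averages each subject's trials, z-standardizes every variable
(channel x timepoint) by the healthy-control mean and standard deviation so
all cohorts live in the same dimensional space, flattens the standardized
grid to one row per subject (channel-major, 18 x 101 = 1818 variables on the
canonical grid), fits a PCA on the patient (HOA) cohort retaining the minimal
number of components whose cumulative explained variance reaches the
threshold (default 90%), and projects every cohort through that single
eigenbasis so patients, post-surgery records and controls are directly
comparable in the identical reduced space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import WaveformStudy

__all__ = [
    "StandardizationStats",
    "EigenBasis",
    "ReducedFeatureSet",
    "average_trials",
    "fit_standardization",
    "standardize",
    "flatten",
    "unflatten",
    "fit_pca",
    "project",
    "reduce_study",
]


@dataclass(frozen=True)
class StandardizationStats:
    """Pointwise healthy-control mean and sample SD, per channel x timepoint."""

    mean: np.ndarray  # [C, T]
    sd: np.ndarray  # [C, T]
    source_group: str = "HC"

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd shapes differ")
        if not np.all(self.sd > 0):
            raise ValueError("standard deviations must be strictly positive")


@dataclass
class EigenBasis:
    """The HOA-fitted eigenbasis defining the shared reduced feature space."""

    center: np.ndarray  # [D]
    eigenvectors: np.ndarray  # [D, P], orthonormal columns
    explained_variance_ratio: np.ndarray  # [P]
    variance_threshold: float

    @property
    def n_retained(self) -> int:
        return self.eigenvectors.shape[1]

    def __post_init__(self) -> None:
        g = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(g, np.eye(self.n_retained), atol=1e-8):
            raise ValueError("eigenvector columns are not orthonormal to 1e-8")

    def save(self, path: str | Path) -> None:
        """Write the basis as an NPZ archive plus a JSON sidecar."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            center=self.center,
            eigenvectors=self.eigenvectors,
            explained_variance_ratio=self.explained_variance_ratio,
        )
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "variance_threshold": self.variance_threshold,
                    "n_retained": self.n_retained,
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "EigenBasis":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            center=arrays["center"],
            eigenvectors=arrays["eigenvectors"],
            explained_variance_ratio=arrays["explained_variance_ratio"],
            variance_threshold=meta["variance_threshold"],
        )


@dataclass
class ReducedFeatureSet:
    """Per-subject PC scores with identity and group labels."""

    scores: np.ndarray  # [N, P]
    subject_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.subject_ids) != self.scores.shape[0] or len(self.groups) != self.scores.shape[0]:
            raise ValueError("labels do not match score rows")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        p = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"pc{i + 1}" for i in range(p)])
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def average_trials(study: WaveformStudy) -> np.ndarray:
    """Arithmetic mean over the trial axis -> [subject, channel, timepoint]."""
    bad = np.flatnonzero(~np.isfinite(study.data).all(axis=(1, 2, 3)))
    if bad.size:
        ids = [study.subjects.subject_id.iat[i] for i in bad]
        raise ValueError(f"subjects with missing/non-finite trials: {ids}")
    return study.data.mean(axis=1)


def fit_standardization(hc_means: np.ndarray) -> StandardizationStats:
    """Pointwise mean and sample SD (ddof=1) over healthy-control subjects."""
    if hc_means.ndim != 3 or hc_means.shape[0] < 2:
        raise ValueError("need >= 2 HC subjects shaped [subject, channel, timepoint]")
    mean = hc_means.mean(axis=0)
    sd = hc_means.std(axis=0, ddof=1)
    zero = np.argwhere(sd == 0)
    if zero.size:
        c, t = zero[0]
        raise ValueError(
            f"zero healthy-control variance at channel index {c}, timepoint {t}; "
            "degenerate input cannot be standardized"
        )
    return StandardizationStats(mean=mean, sd=sd)


def standardize(subject_means: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """(x - HC mean) / HC sd, elementwise."""
    if subject_means.shape[1:] != stats.mean.shape:
        raise ValueError(
            f"shape mismatch: data {subject_means.shape[1:]} vs stats {stats.mean.shape}"
        )
    return (subject_means - stats.mean) / stats.sd


def flatten(standardized: np.ndarray) -> np.ndarray:
    """Channel-major flattening [N, C, T] -> [N, C*T].

    Element (channel j, timepoint t) lands at column j*T + t, so the map is
    inverted by a plain reshape.
    """
    if standardized.ndim != 3:
        raise ValueError("expected [subject, channel, timepoint]")
    n = standardized.shape[0]
    return standardized.reshape(n, -1)


def unflatten(matrix: np.ndarray, n_channels: int, n_timepoints: int) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    return matrix.reshape(matrix.shape[0], n_channels, n_timepoints)


def fit_pca(hoa_matrix: np.ndarray, variance_threshold: float = 0.90) -> EigenBasis:
    """PCA on the patient cohort, retaining minimal P with cumulative
    explained variance >= threshold.

    Centering uses the fitting cohort's column means (the basis is derived
    from the patient data; the healthy-referenced standardization happens
    upstream).  Eigenvector signs are fixed so each component's
    largest-magnitude element is positive, for backend-independent
    reproducibility.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    hoa_matrix = np.asarray(hoa_matrix, dtype=float)
    if hoa_matrix.ndim != 2 or hoa_matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    center = hoa_matrix.mean(axis=0)
    xc = hoa_matrix - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("fitting cohort has zero total variance")
    ratio = var / total
    cum = np.cumsum(ratio)
    p = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    vectors = vt[:p].T.copy()  # [D, P]
    # sign convention: largest-|.| element of each component positive
    for j in range(p):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return EigenBasis(
        center=center,
        eigenvectors=vectors,
        explained_variance_ratio=ratio[:p],
        variance_threshold=variance_threshold,
    )


def project(
    matrix: np.ndarray,
    basis: EigenBasis,
    subject_ids: list[str] | None = None,
    groups: list[str] | None = None,
) -> ReducedFeatureSet:
    """(matrix - center) @ eigenvectors: express any cohort in the shared space."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != basis.center.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns, basis expects {basis.center.shape[0]}"
        )
    scores = (matrix - basis.center) @ basis.eigenvectors
    n = matrix.shape[0]
    return ReducedFeatureSet(
        scores=scores,
        subject_ids=subject_ids if subject_ids is not None else [str(i) for i in range(n)],
        groups=groups if groups is not None else ["?"] * n,
    )


def reduce_study(
    study: WaveformStudy, variance_threshold: float = 0.90
) -> tuple[ReducedFeatureSet, EigenBasis, StandardizationStats]:
    """Run the full preprocessing chain on a study.

    Trials are averaged; standardization statistics are fitted on the HC
    subjects; all cohorts are standardized, flattened and projected through
    the eigenbasis fitted on the HOA cohort.  Returns the scores of every
    subject (in study row order), the basis, and the standardization stats.
    """
    means = average_trials(study)
    hc = study.group_index("HC")
    hoa = study.group_index("HOA")
    if hc.size < 2:
        raise ValueError("need >= 2 HC subjects to fit standardization")
    if hoa.size < 2:
        raise ValueError("need >= 2 HOA subjects to fit the eigenbasis")
    stats = fit_standardization(means[hc])
    z = standardize(means, stats)
    flat = flatten(z)
    basis = fit_pca(flat[hoa], variance_threshold)
    reduced = project(
        flat,
        basis,
        subject_ids=list(study.subjects.subject_id),
        groups=list(study.subjects.group),
    )
    return reduced, basis, stats
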