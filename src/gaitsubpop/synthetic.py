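"""Synthetic gait-waveform cohorts.

Generates time-normalized stance-phase waveform studies with the statistical
structure the downstream analysis assumes: smooth per-channel healthy template
curves, smooth correlated between-subject variation, independent within-subject
trial noise, planted subpopulation effect patterns confined to chosen channels,
and a paired post-surgery cohort whose effects shrink toward the healthy
template by a per-subpopulation recovery fraction.

The 18 channels are the standard lower-body gait set: 11 joint-angle waveforms
(pelvis, hip, knee, ankle, foot progression) and 7 joint-moment waveforms
(hip, knee, ankle; external moments normalized to body mass, N*m/kg), each
time-normalized to 101 points over the stance phase.

Noise scales (``subject_variation_sd``, ``trial_noise_sd``) are expressed as
fractions of each channel's natural scale (the peak absolute value of its
template curve), so a single pair of numbers produces channel-appropriate
variability for degree-scaled angles and N*m/kg-scaled moments alike.  Planted
effect magnitudes are expressed in healthy-control standard-deviation units of
the per-subject trial-mean curves, so "magnitude 2" yields a standardized
channel deviation of about 2 after healthy-referenced z-standardization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ANGLE_CHANNELS",
    "MOMENT_CHANNELS",
    "CHANNEL_NAMES",
    "Bump",
    "ChannelSpec",
    "SubpopEffect",
    "CohortConfig",
    "WaveformStudy",
    "default_channel_specs",
    "default_effects",
    "smooth_bump",
    "broad_effect_curve",
    "generate_templates",
    "gp_curves",
    "generate_cohort",
]

# --------------------------------------------------------------------------
# Channel inventory
# --------------------------------------------------------------------------

#: Joint-angle waveforms (degrees), in canonical order.
ANGLE_CHANNELS: tuple[str, ...] = (
    "pelvic_tilt_angle",
    "pelvic_obliquity_angle",
    "pelvic_rotation_angle",
    "hip_flexion_angle",
    "hip_adduction_angle",
    "hip_rotation_angle",
    "knee_flexion_angle",
    "knee_adduction_angle",
    "knee_rotation_angle",
    "ankle_plantarflexion_angle",
    "foot_progression_angle",
)

#: Joint-moment waveforms (N*m/kg, external), in canonical order.
MOMENT_CHANNELS: tuple[str, ...] = (
    "hip_flexion_moment",
    "hip_adduction_moment",
    "hip_rotation_moment",
    "knee_flexion_moment",
    "knee_adduction_moment",
    "knee_rotation_moment",
    "ankle_plantarflexion_moment",
)

#: The full 18-channel canonical ordering used everywhere downstream.
CHANNEL_NAMES: tuple[str, ...] = ANGLE_CHANNELS + MOMENT_CHANNELS


# --------------------------------------------------------------------------
# Channel specs and templates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Bump:
    """One smooth Gaussian bump of a template curve.

    center is on the normalized stance axis [0, 1]; width is the Gaussian
    sigma (> 0); amplitude is in the channel's real units (deg or N*m/kg).
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"bump width must be > 0, got {self.width}")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((t - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class ChannelSpec:
    """Template description of one biomechanical waveform channel."""

    name: str
    kind: str  # "angle" | "moment"
    bumps: tuple[Bump, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("angle", "moment"):
            raise ValueError(f"kind must be 'angle' or 'moment', got {self.kind!r}")

    def template(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the smooth template (superposition of bumps) on grid t."""
        out = np.zeros_like(t, dtype=float)
        for b in self.bumps:
            out += b(t)
        return out


# Hand-set bump parameters giving visually plausible stance-phase shapes.
# Angles in degrees, moments in N*m/kg; magnitudes are in the range reported
# for level walking in adults.
_DEFAULT_BUMPS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "pelvic_tilt_angle": ((0.5, 0.6, 10.0), (0.3, 0.15, 1.5)),
    "pelvic_obliquity_angle": ((0.2, 0.12, 3.0), (0.75, 0.15, -3.0)),
    "pelvic_rotation_angle": ((0.1, 0.2, 4.0), (0.9, 0.2, -4.0)),
    "hip_flexion_angle": ((0.0, 0.25, 30.0), (1.0, 0.18, -10.0)),
    "hip_adduction_angle": ((0.3, 0.2, 6.0), (0.9, 0.15, -4.0)),
    "hip_rotation_angle": ((0.4, 0.3, 5.0),),
    "knee_flexion_angle": ((0.15, 0.1, 18.0), (1.0, 0.15, 35.0), (0.0, 0.08, 5.0)),
    "knee_adduction_angle": ((0.2, 0.2, 4.0), (0.85, 0.2, 2.0)),
    "knee_rotation_angle": ((0.15, 0.15, -5.0), (0.9, 0.2, 4.0)),
    "ankle_plantarflexion_angle": ((0.08, 0.06, 5.0), (0.55, 0.25, -10.0), (1.0, 0.08, 15.0)),
    "foot_progression_angle": ((0.5, 0.5, -8.0),),
    "hip_flexion_moment": ((0.12, 0.1, 0.9), (0.85, 0.15, -0.8)),
    "hip_adduction_moment": ((0.2, 0.12, 0.9), (0.8, 0.12, 0.8)),
    "hip_rotation_moment": ((0.3, 0.2, 0.15), (0.8, 0.12, -0.1)),
    "knee_flexion_moment": ((0.15, 0.08, 0.5), (0.45, 0.15, -0.3), (0.9, 0.1, 0.2)),
    "knee_adduction_moment": ((0.2, 0.1, 0.4), (0.8, 0.12, 0.35)),
    "knee_rotation_moment": ((0.25, 0.15, 0.12), (0.8, 0.15, -0.08)),
    "ankle_plantarflexion_moment": ((0.75, 0.18, 1.5), (0.08, 0.06, -0.15)),
}


def default_channel_specs() -> list[ChannelSpec]:
    """The canonical 18-channel specification with plausible template shapes."""
    specs = []
    for name in CHANNEL_NAMES:
        kind = "angle" if name in ANGLE_CHANNELS else "moment"
        bumps = tuple(Bump(*p) for p in _DEFAULT_BUMPS[name])
        specs.append(ChannelSpec(name=name, kind=kind, bumps=bumps))
    return specs


def _validate_channel_specs(channel_specs: Sequence[ChannelSpec]) -> None:
    names = [s.name for s in channel_specs]
    if len(set(names)) != len(names):
        raise ValueError("channel names must be unique")


def generate_templates(
    channel_specs: Sequence[ChannelSpec],
    n_timepoints: int = 101,
    seed: int | None = None,
) -> np.ndarray:
    """Evaluate the healthy mean curve of every channel on the uniform grid.

    Returns an array [n_channels, n_timepoints].  The templates are a
    deterministic function of the specs; ``seed`` is accepted for interface
    symmetry with the stochastic generators and ignored.
    """
    _validate_channel_specs(channel_specs)
    t = np.linspace(0.0, 1.0, n_timepoints)
    return np.stack([spec.template(t) for spec in channel_specs])


# --------------------------------------------------------------------------
# Subpopulation effects
# --------------------------------------------------------------------------


def smooth_bump(center: float, width: float) -> Callable[[np.ndarray], np.ndarray]:
    """A peak-1 Gaussian bump, usable as a smooth effect curve on [0, 1]."""
    if not width > 0:
        raise ValueError("width must be > 0")
    return lambda t: np.exp(-0.5 * ((t - center) / width) ** 2)


def broad_effect_curve(t: np.ndarray) -> np.ndarray:
    """Raised-cosine effect spanning most of stance (peak 1 at mid-stance).

    Gait alterations in hip osteoarthritis (reduced moments, offset rotations)
    typically persist across the stance phase rather than being confined to a
    narrow event, so the default planted effects use this broad shape.
    """
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(t, 0.0, 1.0)))


@dataclass(frozen=True)
class SubpopEffect:
    """A planted subpopulation deviation pattern.

    effect_curves maps affected channel names to smooth curves on [0, 1]
    (callables or precomputed arrays); channels absent from the mapping have
    identically zero effect.  magnitude is a non-negative multiplier in
    healthy-control standard-deviation units.
    """

    subpop_id: int
    effect_curves: Mapping[str, Callable[[np.ndarray], np.ndarray] | np.ndarray]
    magnitude: float

    def __post_init__(self) -> None:
        if self.subpop_id < 1:
            raise ValueError("subpop_id must be >= 1")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @property
    def affected_channels(self) -> tuple[str, ...]:
        return tuple(self.effect_curves)

    def curve(self, channel: str, t: np.ndarray) -> np.ndarray:
        c = self.effect_curves.get(channel)
        if c is None:
            return np.zeros_like(t)
        if callable(c):
            return np.asarray(c(t), dtype=float)
        arr = np.asarray(c, dtype=float)
        if arr.shape != t.shape:
            raise ValueError(
                f"precomputed effect curve for {channel!r} has shape {arr.shape}, "
                f"expected {t.shape}"
            )
        return arr


def default_effects(magnitudes: Sequence[float] = (3.0, 3.0, 3.0)) -> list[SubpopEffect]:
    """Planted subpopulations with distinct hip-centred channel patterns.

    One effect per entry of ``magnitudes`` (up to three).  The affected
    channel sets echo the clinical picture of distinct hip-OA adaptation
    strategies: one rotation/moment dominated, one sagittal-plane (hip/knee
    flexion) dominated, one frontal-plane/pelvis dominated.
    """
    sets = (
        ("hip_rotation_angle", "hip_flexion_moment"),
        ("hip_flexion_angle", "knee_flexion_angle"),
        ("hip_adduction_angle", "pelvic_tilt_angle"),
    )
    signs = ((1.0, -1.0), (-1.0, 1.0), (-1.0, 1.0))
    if len(magnitudes) > len(sets):
        raise ValueError(f"at most {len(sets)} default effects are defined")
    effects = []
    for i, (chans, sgns) in enumerate(zip(sets[: len(magnitudes)], signs)):
        curves = {
            ch: (lambda t, s=s: s * broad_effect_curve(t)) for ch, s in zip(chans, sgns)
        }
        effects.append(
            SubpopEffect(subpop_id=i + 1, effect_curves=curves, magnitude=float(magnitudes[i]))
        )
    return effects


# --------------------------------------------------------------------------
# Cohort configuration
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Cohort sizes, noise levels and reproducibility seed.

    Defaults mirror the study layout this generator emulates: 109 patients
    with hip osteoarthritis (HOA) split over three subpopulations, 63 of whom
    are re-examined after total hip replacement (THR), and 56 healthy
    controls (HC); three trials per subject on a 101-point stance grid.
    """

    n_per_subpop: tuple[int, ...] = (28, 43, 38)
    n_hc: int = 56
    n_followup_per_subpop: tuple[int, ...] = (17, 28, 18)
    recovery_fraction: tuple[float, ...] = (0.7, 0.7, 0.7)
    trial_noise_sd: float = 0.05
    subject_variation_sd: float = 0.15
    smoothness_lengthscale: float = 0.15
    n_trials: int = 3
    n_timepoints: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_subpop = tuple(int(n) for n in self.n_per_subpop)
        self.n_followup_per_subpop = tuple(int(n) for n in self.n_followup_per_subpop)
        self.recovery_fraction = tuple(float(r) for r in self.recovery_fraction)
        if any(n < 0 for n in self.n_per_subpop) or self.n_hc < 0:
            raise ValueError("cohort counts must be >= 0")
        if len(self.n_followup_per_subpop) != len(self.n_per_subpop):
            raise ValueError("n_followup_per_subpop must match n_per_subpop in length")
        if len(self.recovery_fraction) != len(self.n_per_subpop):
            raise ValueError("recovery_fraction must match n_per_subpop in length")
        for nf, n in zip(self.n_followup_per_subpop, self.n_per_subpop):
            if nf > n:
                raise ValueError(
                    f"n_followup ({nf}) cannot exceed n_per_subpop ({n})"
                )
        if any(not 0.0 <= r <= 1.0 for r in self.recovery_fraction):
            raise ValueError("recovery_fraction entries must lie in [0, 1]")
        if self.trial_noise_sd < 0 or self.subject_variation_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 < self.smoothness_lengthscale <= 1.0:
            raise ValueError("smoothness_lengthscale must lie in (0, 1]")
        if self.n_trials < 1 or self.n_timepoints < 2:
            raise ValueError("need n_trials >= 1 and n_timepoints >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# Group-level metadata distributions (mean, sd) emulating a typical unilateral
# hip-OA surgical cohort and its healthy reference group.
_METADATA_DISTS = {
    "HOA": {"age": (61.3, 10.7), "mass": (80.5, 14.6), "height": (1.70, 0.09), "speed": (1.01, 0.19), "p_male": 56 / 109},
    "THR": {"age": (62.4, 9.9), "mass": (82.3, 13.7), "height": (1.72, 0.07), "speed": (1.17, 0.15), "p_male": 34 / 63},
    "HC": {"age": (63.5, 7.6), "mass": (69.0, 11.9), "height": (1.68, 0.09), "speed": (1.32, 0.15), "p_male": 23 / 56},
}


# --------------------------------------------------------------------------
# Study container
# --------------------------------------------------------------------------


@dataclass
class WaveformStudy:
    """A waveform cohort: subject table plus a dense data array.

    subjects: DataFrame with columns subject_id, group (HOA/THR/HC),
    true_subpop (nullable int), paired_id (nullable str), affected_side,
    age, sex, mass, height, walking_speed.  Row order matches axis 0 of
    ``data``, which is [subject, trial, channel, timepoint].
    """

    subjects: pd.DataFrame
    data: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        n, _, c, _ = self.data.shape
        if len(self.subjects) != n:
            raise ValueError("subject table and data array disagree on subject count")
        if c != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("waveform data must be finite")
        paired = self.subjects.loc[self.subjects.group == "THR", "paired_id"]
        known = set(self.subjects.loc[self.subjects.group == "HOA", "subject_id"])
        missing = [p for p in paired if p not in known]
        if missing:
            raise ValueError(f"THR subjects with unknown paired_id: {missing}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def group_index(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.subjects.group == group).to_numpy())

    def subset(self, index: np.ndarray) -> "WaveformStudy":
        return WaveformStudy(
            subjects=self.subjects.iloc[index].reset_index(drop=True),
            data=self.data[index],
            channel_names=self.channel_names,
        )

    # -- wide CSV round trip ------------------------------------------------

    def to_csv(self, waveform_path: str | Path, metadata_path: str | Path) -> None:
        """Write the wide waveform CSV and the companion metadata CSV."""
        n, tr, c, tp = self.data.shape
        cols = [f"t{i:03d}" for i in range(tp)]
        sub = self.subjects
        rows = []
        for i in range(n):
            for j in range(tr):
                for k in range(c):
                    rows.append(
                        (
                            sub.subject_id.iat[i],
                            sub.group.iat[i],
                            sub.true_subpop.iat[i],
                            sub.paired_id.iat[i],
                            j + 1,
                            self.channel_names[k],
                        )
                    )
        head = pd.DataFrame(
            rows, columns=["subject_id", "group", "true_subpop", "paired_id", "trial", "channel"]
        )
        wide = pd.concat(
            [head, pd.DataFrame(self.data.reshape(n * tr * c, tp), columns=cols)], axis=1
        )
        wide.to_csv(waveform_path, index=False)
        self.subjects.to_csv(metadata_path, index=False)

    @classmethod
    def from_csv(cls, waveform_path: str | Path, metadata_path: str | Path) -> "WaveformStudy":
        wide = pd.read_csv(waveform_path, dtype={"subject_id": str, "paired_id": str})
        meta = pd.read_csv(metadata_path, dtype={"subject_id": str, "paired_id": str})
        tcols = [c for c in wide.columns if c.startswith("t") and c[1:].isdigit()]
        subject_ids = list(meta.subject_id)
        channels = tuple(dict.fromkeys(wide.channel))
        trials = sorted(wide.trial.unique())
        n, tr, c, tp = len(subject_ids), len(trials), len(channels), len(tcols)
        data = np.full((n, tr, c, tp), np.nan)
        sidx = {s: i for i, s in enumerate(subject_ids)}
        cidx = {ch: i for i, ch in enumerate(channels)}
        tridx = {t: i for i, t in enumerate(trials)}
        vals = wide[tcols].to_numpy()
        for r, (s, t, ch) in enumerate(zip(wide.subject_id, wide.trial, wide.channel)):
            data[sidx[s], tridx[t], cidx[ch]] = vals[r]
        if np.isnan(data).any():
            raise ValueError("waveform CSV does not cover every subject x trial x channel")
        meta["true_subpop"] = meta["true_subpop"].astype("Int64")
        return cls(subjects=meta, data=data, channel_names=channels)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _gp_cholesky(n_timepoints: int, lengthscale: float) -> np.ndarray:
    """Cholesky factor of a unit-variance squared-exponential kernel on [0,1]."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    d = t[:, None] - t[None, :]
    k = np.exp(-0.5 * (d / lengthscale) ** 2)
    k[np.diag_indices_from(k)] += 1e-9
    return np.linalg.cholesky(k)


def gp_curves(
    rng: np.random.Generator, n: int, n_timepoints: int, lengthscale: float
) -> np.ndarray:
    """Draw n smooth unit-variance curves from a stationary Gaussian process."""
    chol = _gp_cholesky(n_timepoints, lengthscale)
    z = rng.standard_normal((n, n_timepoints))
    return z @ chol.T


def _draw_metadata(rng: np.random.Generator, group: str) -> dict:
    d = _METADATA_DISTS[group]
    return {
        "age": float(np.round(rng.normal(*d["age"]), 1)),
        "sex": "male" if rng.random() < d["p_male"] else "female",
        "mass": float(np.round(rng.normal(*d["mass"]), 1)),
        "height": float(np.round(rng.normal(*d["height"]), 2)),
        "walking_speed": float(np.round(rng.normal(*d["speed"]), 2)),
    }


def generate_cohort(
    config: CohortConfig,
    channel_specs: Sequence[ChannelSpec] | None = None,
    effects: Sequence[SubpopEffect] | None = None,
) -> WaveformStudy:
    """Generate a full HOA / THR / HC waveform study.

    Each healthy-control subject is template + smooth correlated subject
    deviation + independent trial noise.  A patient in subpopulation k
    additionally carries the planted effect of magnitude m_k (in HC-SD units
    of the trial-mean curves).  The first ``n_followup`` patients of each
    subpopulation get a paired post-surgery record whose effect is shrunk by
    the subpopulation's recovery fraction; the subject's own deviation curve
    is retained across surgery, only the pathological offset shrinks and
    fresh trial noise is drawn.

    Deterministic: identical config (including seed) + specs + effects give a
    bit-identical study.
    """
    if channel_specs is None:
        channel_specs = default_channel_specs()
    _validate_channel_specs(channel_specs)
    if effects is None:
        effects = default_effects()
    if len(effects) != len(config.n_per_subpop):
        raise ValueError(
            f"got {len(effects)} effects for {len(config.n_per_subpop)} subpopulations"
        )

    rng = np.random.default_rng(config.seed)
    tp, tr = config.n_timepoints, config.n_trials
    n_channels = len(channel_specs)
    t = np.linspace(0.0, 1.0, tp)
    templates = generate_templates(channel_specs, tp)  # [C, T]

    # Channel natural scale: peak absolute template value (1 for a flat template).
    scale = np.abs(templates).max(axis=1)
    scale[scale == 0] = 1.0

    # HC standard deviation of per-subject trial means, per channel (stationary).
    sv = config.subject_variation_sd * scale
    tn = config.trial_noise_sd * scale
    sd_ref = np.sqrt(sv**2 + tn**2 / tr)  # [C]

    chol = _gp_cholesky(tp, config.smoothness_lengthscale)

    # Pre-evaluate planted effect offsets in real units: [subpop, C, T].
    effect_real = np.zeros((len(effects), n_channels, tp))
    for k, eff in enumerate(effects):
        for c, spec in enumerate(channel_specs):
            effect_real[k, c] = eff.magnitude * eff.curve(spec.name, t) * sd_ref[c]

    def draw_subject_deviation() -> np.ndarray:
        z = rng.standard_normal((n_channels, tp))
        return (z @ chol.T) * sv[:, None]

    def draw_trials(mean_curves: np.ndarray) -> np.ndarray:
        noise = rng.standard_normal((tr, n_channels, tp)) * tn[None, :, None]
        return mean_curves[None] + noise

    records: list[dict] = []
    blocks: list[np.ndarray] = []
    followup: list[tuple[str, int, np.ndarray]] = []  # (hoa_id, subpop idx, deviation)

    idx = 0
    for k, n_k in enumerate(config.n_per_subpop):
        for i in range(n_k):
            sid = f"HOA{idx:03d}"
            idx += 1
            dev = draw_subject_deviation()
            mean_curves = templates + dev + effect_real[k]
            blocks.append(draw_trials(mean_curves))
            meta = _draw_metadata(rng, "HOA")
            records.append(
                dict(
                    subject_id=sid,
                    group="HOA",
                    true_subpop=k + 1,
                    paired_id=None,
                    affected_side="left" if rng.random() < 0.45 else "right",
                    **meta,
                )
            )
            if i < config.n_followup_per_subpop[k]:
                followup.append((sid, k, dev))

    for sid, k, dev in followup:
        rho = config.recovery_fraction[k]
        mean_curves = templates + dev + (1.0 - rho) * effect_real[k]
        blocks.append(draw_trials(mean_curves))
        meta = _draw_metadata(rng, "THR")
        records.append(
            dict(
                subject_id=sid.replace("HOA", "THR"),
                group="THR",
                true_subpop=k + 1,
                paired_id=sid,
                affected_side="left" if rng.random() < 0.45 else "right",
                **meta,
            )
        )

    for i in range(config.n_hc):
        dev = draw_subject_deviation()
        blocks.append(draw_trials(templates + dev))
        meta = _draw_metadata(rng, "HC")
        records.append(
            dict(
                subject_id=f"HC{i:03d}",
                group="HC",
                true_subpop=None,
                paired_id=None,
                affected_side="left" if rng.random() < 0.45 else "right",
                **meta,
            )
        )

    subjects = pd.DataFrame.from_records(records)
    subjects["true_subpop"] = subjects["true_subpop"].astype("Int64")
    data = np.stack(blocks) if blocks else np.zeros((0, tr, n_channels, tp))
    return WaveformStudy(
        subjects=subjects, data=data, channel_names=tuple(s.name for s in channel_specs)
    )
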