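"""End-to-end orchestration: data -> preprocessing -> clustering -> SVMs ->
explanations -> waveform inference -> tables and figures.

Stages run in a fixed order; each stage's outputs are written standalone so
every step is independently auditable.  A single master seed derives
per-stage seeds by fixed offsets, giving reproducibility with stage-level
isolation: re-running with the same config produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
import yaml

from . import __version__
from .explain import CogsRecord, ImportanceProfile, cogs_table, top_k, waveform_importance
from .preprocess import EigenBasis, ReducedFeatureSet, StandardizationStats, average_trials, reduce_study, standardize
from .spm import SpmResult, compare_paired, compare_unpaired
from .subpopulations import (
    SubpopulationAssignment,
    assignments_frame,
    kmeans_consensus,
    silhouettes,
    ward_merge_heights,
    ward_select_k,
)
from .svm import ClassificationReport, LinearGaitClassifier, crossvalidate_10fold, project_followup
from .synthetic import CohortConfig, WaveformStudy, default_effects, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run", "make_figures"]

# fixed per-stage seed offsets derived from the master seed
_SEED_KMEANS = 1009
_SEED_SVM = 2003
_SEED_SPM = 3001


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    Either ``synthetic`` (a CohortConfig) or ``waveform_csv``/``metadata_csv``
    must be provided.  Defaults reproduce the reference analysis settings:
    90% PCA variance retention, five k-means runs, 10-fold CV, box constraint
    and kernel scale 1, alpha 0.05 two-sided, top-5 channels.
    """

    synthetic: CohortConfig | None = None
    waveform_csv: str | None = None
    metadata_csv: str | None = None
    variance_threshold: float = 0.90
    k_min: int = 2
    k_max: int = 10
    n_kmeans_runs: int = 5
    cv_folds: int = 10
    box_constraint: float = 1.0
    kernel_scale: float = 1.0
    alpha: float = 0.05
    n_perm: int = 1000
    top_k: int = 5
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.waveform_csv is None or self.metadata_csv is None):
            # default to the synthetic study-layout cohort
            self.synthetic = CohortConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = CohortConfig(**raw["synthetic"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    study: WaveformStudy
    reduced: ReducedFeatureSet
    basis: EigenBasis
    stats: StandardizationStats
    k: int
    assignments: list[SubpopulationAssignment]
    classifiers: dict[int, LinearGaitClassifier]
    reports: list[ClassificationReport]
    importances: dict[int, ImportanceProfile]
    cogs_records: dict[int, dict[str, list[CogsRecord]]]  # subpop -> era -> records
    spm_results: dict[int, dict[str, list[SpmResult]]]  # subpop -> design -> results
    provenance: dict

    def cogs_frame(self) -> pd.DataFrame:
        rows = []
        for sp, eras in self.cogs_records.items():
            for era, recs in eras.items():
                for r in recs:
                    rows.append(
                        {"subject_id": r.subject_id, "subpop": sp, "era": era, "cogs": r.cogs}
                    )
        return pd.DataFrame(rows)

    def classification_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports])

    def importance_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.importances.values()], ignore_index=True)

    def spm_frame(self) -> pd.DataFrame:
        rows = []
        for sp, designs in self.spm_results.items():
            for design, results in designs.items():
                for res in results:
                    rows.append(
                        {
                            "subpop": sp,
                            "design": design,
                            "channel": res.channel,
                            "critical_value": res.critical_value,
                            "significant_fraction": res.significant_fraction,
                            "regions": ";".join(f"{a}-{b}" for a, b in res.regions),
                        }
                    )
        return pd.DataFrame(rows)


def _log_stage(name: str, t0: float) -> None:
    logger.info("stage %-16s done in %.2fs", name, time.perf_counter() - t0)


def run(config: PipelineConfig, study: WaveformStudy | None = None) -> RunReport:
    """Execute the full workflow and write all tables to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- data -------------------------------------------------------------
    t0 = time.perf_counter()
    if study is None:
        if config.synthetic is not None:
            study = generate_cohort(config.synthetic)
        else:
            study = WaveformStudy.from_csv(config.waveform_csv, config.metadata_csv)
    _log_stage("data", t0)

    # -- preprocessing ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        reduced, basis, stats = reduce_study(study, config.variance_threshold)
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess' failed: {e}") from e
    means = average_trials(study)
    z = standardize(means, stats)  # standardized subject-mean waveforms, for SPM
    hoa = study.group_index("HOA")
    hc = study.group_index("HC")
    reduced.to_frame().to_csv(out / "scores.csv", index=False)
    basis.save(out / "eigenbasis")
    _log_stage("preprocess", t0)

    # -- subpopulations ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        hoa_scores = reduced.scores[hoa]
        hoa_ids = [reduced.subject_ids[i] for i in hoa]
        k = ward_select_k(hoa_scores, config.k_min, config.k_max)
        assignments = kmeans_consensus(
            hoa_scores,
            k,
            subject_ids=hoa_ids,
            n_runs=config.n_kmeans_runs,
            seed=config.seed + _SEED_KMEANS,
        )
        populated = {a.label for a in assignments if a.consistent}
        if len(populated) >= 2:
            assignments = silhouettes(hoa_scores, assignments)
        else:
            logger.warning(
                "fewer than 2 populated clusters after consistency filtering; "
                "silhouettes skipped"
            )
    except Exception as e:
        raise RuntimeError(f"stage 'subpopulations' failed: {e}") from e
    assignments_frame(assignments).to_csv(out / "assignments.csv", index=False)
    pd.DataFrame(
        {"k": np.arange(2, len(ward_merge_heights(hoa_scores)) + 2),
         "merge_height": ward_merge_heights(hoa_scores)}
    ).to_csv(out / "dendrogram_heights.csv", index=False)
    _log_stage("subpopulations", t0)

    # -- per-subpopulation modelling --------------------------------------
    t0 = time.perf_counter()
    by_id = {a.subject_id: a for a in assignments}
    hc_scores = reduced.scores[hc]
    hc_ids = [reduced.subject_ids[i] for i in hc]
    thr = study.group_index("THR")
    thr_pairs = {
        study.subjects.paired_id.iat[i]: i for i in thr
    }  # HOA subject_id -> THR row index

    classifiers: dict[int, LinearGaitClassifier] = {}
    reports: list[ClassificationReport] = []
    importances: dict[int, ImportanceProfile] = {}
    cogs_records: dict[int, dict[str, list[CogsRecord]]] = {}
    spm_results: dict[int, dict[str, list[SpmResult]]] = {}

    row_of = {sid: i for i, sid in enumerate(reduced.subject_ids)}

    for sp in range(1, k + 1):
        member_ids = [a.subject_id for a in assignments if a.consistent and a.label == sp]
        if len(member_ids) < 2:
            logger.warning(
                "subpopulation %d has %d consistent members; skipping its models",
                sp,
                len(member_ids),
            )
            continue
        member_rows = np.array([row_of[s] for s in member_ids])
        try:
            clf = crossvalidate_10fold(
                reduced.scores[member_rows],
                hc_scores,
                subpop_id=sp,
                seed=config.seed + _SEED_SVM + sp,
                n_folds=config.cv_folds,
                box_constraint=config.box_constraint,
                kernel_scale=config.kernel_scale,
                pathologic_ids=member_ids,
                hc_ids=hc_ids,
            )
        except Exception as e:
            raise RuntimeError(f"stage 'svm_classify' failed for subpopulation {sp}: {e}") from e
        classifiers[sp] = clf
        reports.append(clf.report)

        # follow-up projection through the final model
        fu_ids = [s for s in member_ids if s in thr_pairs]
        fu_rows = np.array([row_of[study.subjects.subject_id.iat[thr_pairs[s]]] for s in fu_ids])
        if fu_rows.size:
            reports.append(project_followup(clf, reduced.scores[fu_rows], hc_scores))

        # explanations
        try:
            profile = waveform_importance(
                clf,
                reduced.scores[member_rows],
                basis,
                study.channel_names,
                n_timepoints=study.n_timepoints,
            )
        except Exception as e:
            raise RuntimeError(f"stage 'explain' failed for subpopulation {sp}: {e}") from e
        importances[sp] = profile

        eras: dict[str, list[CogsRecord]] = {
            "pre": cogs_table(clf, reduced.scores[member_rows], member_ids, "pre")
        }
        if fu_rows.size:
            eras["post"] = cogs_table(clf, reduced.scores[fu_rows], fu_ids, "post")
        cogs_records[sp] = eras

        # waveform inference on the top-k channels
        try:
            chan_idx = {c: i for i, c in enumerate(study.channel_names)}
            designs: dict[str, list[SpmResult]] = {"subpop_vs_hc": []}
            member_study_rows = np.array([row_of[s] for s in member_ids])
            for rank, chan in enumerate(top_k(profile, config.top_k)):
                ci = chan_idx[chan]
                designs["subpop_vs_hc"].append(
                    compare_unpaired(
                        chan,
                        z[member_study_rows, ci],
                        z[hc, ci],
                        alpha=config.alpha,
                        n_perm=config.n_perm,
                        seed=config.seed + _SEED_SPM + 100 * sp + rank,
                    )
                )
            if len(fu_ids) >= 2:
                designs["pre_vs_post"] = []
                pre_rows = np.array([row_of[s] for s in fu_ids])
                for rank, chan in enumerate(top_k(profile, config.top_k)):
                    ci = chan_idx[chan]
                    designs["pre_vs_post"].append(
                        compare_paired(
                            chan,
                            z[pre_rows, ci],
                            z[fu_rows, ci],
                            alpha=config.alpha,
                            n_perm=config.n_perm,
                            seed=config.seed + _SEED_SPM + 100 * sp + 50 + rank,
                        )
                    )
        except Exception as e:
            raise RuntimeError(f"stage 'spm_compare' failed for subpopulation {sp}: {e}") from e
        spm_results[sp] = designs
    _log_stage("modelling", t0)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n_retained_pcs": basis.n_retained,
        "k": k,
    }

    report = RunReport(
        config=config,
        study=study,
        reduced=reduced,
        basis=basis,
        stats=stats,
        k=k,
        assignments=assignments,
        classifiers=classifiers,
        reports=reports,
        importances=importances,
        cogs_records=cogs_records,
        spm_results=spm_results,
        provenance=provenance,
    )
    report.classification_frame().to_csv(out / "classification.csv", index=False)
    report.importance_frame().to_csv(out / "importance.csv", index=False)
    report.cogs_frame().to_csv(out / "cogs.csv", index=False)
    report.spm_frame().to_csv(out / "spm.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return report


# --------------------------------------------------------------------------
# Figures
# --------------------------------------------------------------------------


def make_figures(report: RunReport, output_dir: str | Path | None = None) -> list[Path]:
    """PC scatter with cluster hulls, waveform overlays with significance
    shading, and pre/post COGS violins.  Returns the written file paths."""
    from scipy.spatial import ConvexHull

    out = Path(output_dir or report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not report.classifiers:
        raise ValueError("cannot plot an empty report")
    paths = []
    reduced, study = report.reduced, report.study

    # PC1-PC2 scatter with hulls
    fig, ax = plt.subplots(figsize=(6, 5))
    hoa = study.group_index("HOA")
    by_id = {a.subject_id: a for a in report.assignments}
    colors = plt.cm.tab10(np.linspace(0, 1, 10))
    for sp in range(1, report.k + 1):
        rows = [
            i
            for i in hoa
            if by_id[reduced.subject_ids[i]].consistent
            and by_id[reduced.subject_ids[i]].label == sp
        ]
        pts = reduced.scores[rows][:, :2]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=colors[sp - 1], label=f"subpop {sp}")
        if len(pts) >= 3:
            hull = ConvexHull(pts)
            cyc = np.append(hull.vertices, hull.vertices[0])
            ax.plot(pts[cyc, 0], pts[cyc, 1], color=colors[sp - 1], lw=1)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    p = out / "pc_scatter.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    # waveform overlays with significance shading
    means = average_trials(study)
    z = standardize(means, report.stats)
    chan_idx = {c: i for i, c in enumerate(study.channel_names)}
    hc = study.group_index("HC")
    row_of = {sid: i for i, sid in enumerate(reduced.subject_ids)}
    for sp, designs in report.spm_results.items():
        results = designs.get("subpop_vs_hc", [])
        if not results:
            continue
        fig, axes = plt.subplots(1, len(results), figsize=(3 * len(results), 3), squeeze=False)
        member_rows = np.array(
            [row_of[a.subject_id] for a in report.assignments if a.consistent and a.label == sp]
        )
        t = np.arange(study.n_timepoints)
        for ax, res in zip(axes[0], results):
            ci = chan_idx[res.channel]
            for grp_rows, color in ((member_rows, "tab:red"), (hc, "tab:blue")):
                m = z[grp_rows, ci].mean(axis=0)
                s = z[grp_rows, ci].std(axis=0, ddof=1)
                ax.plot(t, m, color=color, lw=1.2)
                ax.fill_between(t, m - s, m + s, color=color, alpha=0.15)
            for a, b in res.regions:
                ax.axvspan(a, b - 1, color="grey", alpha=0.3)
            ax.set_title(res.channel, fontsize=7)
        fig.suptitle(f"subpopulation {sp} vs HC (standardized)", fontsize=9)
        fig.tight_layout()
        p = out / f"waveforms_subpop{sp}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

    # COGS violins
    cog = report.cogs_frame()
    if not cog.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        sns.violinplot(
            data=cog, x="subpop", y="cogs", hue="era", split=("post" in set(cog.era)),
            inner="quart", ax=ax,
        )
        ax.axhline(0.0, color="k", lw=0.8, ls="--")
        ax.set_ylabel("COGS (distance to hyperplane)")
        fig.tight_layout()
        p = out / "cogs_violin.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
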