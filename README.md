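# gaitsubpop

Discovery and explainable characterization of **biomechanical subpopulations
in hip osteoarthritis (hip OA)** from time-normalized gait waveforms, with
quantification of each subpopulation's response to total hip replacement
(THR).

Patients with hip OA adapt their gait in heterogeneous ways — some walk with
an internally rotated, flexed hip, others reduce sagittal-plane joint moments,
and so on.  Treating them as one homogeneous group blurs these strategies and
their distinct surgical outcomes.  This package implements, as a tested and
reusable pipeline, a workflow for clinical movement scientists who have
stance-phase joint-angle and joint-moment waveforms for a patient cohort, a
paired post-surgery subset, and a healthy-control (HC) reference group.
Because motion-capture patient cohorts are rarely shareable, the package
ships a first-class synthetic cohort generator with the statistical structure
the analysis assumes, so the entire pipeline is reproducible and testable
without any data download.

## Method

Input: per subject, 3 trials x 18 channels (11 joint-angle, 7 joint-moment
waveforms) x 101 stance-phase points, for three cohorts — HOA (patients
pre-surgery), THR (paired post-surgery), HC (controls).

1. **Preprocessing.** Trials are averaged; every variable (channel x
   timepoint) is z-standardized by the HC mean and SD,
   `z = (x - mu_HC) / sigma_HC`; each subject becomes a row vector of
   18 x 101 = 1818 variables.
2. **Shared eigenbasis.** PCA is fitted on the HOA cohort, retaining the
   minimal *P* components whose cumulative explained variance reaches 90%.
   THR and HC are projected through the same eigenvector matrix **V**
   (scores `= (X - x̄_HOA) V`), so all cohorts live in the identical reduced
   space.
3. **Subpopulation discovery.** The number of clusters *k* is read off the
   Ward dendrogram of the HOA scores via the largest relative merge-height
   gap; membership comes from k-means executed five times with different
   seeds; subjects not assigned unanimously across runs (after
   maximum-agreement label alignment) are excluded; fit is scored by
   silhouette coefficients.
4. **Classification.** Per subpopulation, a soft-margin linear SVM
   (C = 1, kernel scale 1) discriminates subpopulation vs HC in PC space.
   Stratified 10-fold cross-validation yields the classification rate,
   sensitivity, specificity, ROC-AUC and the **pathologic ratio** (share of
   the subpopulation on the pathologic side).  The paired THR records are
   projected through the final model to quantify post-surgical change.
5. **Explainability.** For the linear decision function f(x) = w·x + b the
   Shapley value of PC *i* is closed-form, `phi_i = w_i (x_i - m_i)` with
   background *m* the training mean.  Shapley-weighted scores
   `u_i = |phi_i| * x_i` are back-projected through the eigenbasis
   (`r = V u`), and the mean absolute reconstructed value per channel, averaged
   over the subpopulation, ranks the 18 waveforms; the top 5 characterize the
   subpopulation.  The **COGS** (classifier-oriented gait score) is the signed
   orthogonal distance to the hyperplane, `(w·x + b) / ||w||`, positive toward
   HC — higher means gait closer to the healthy pattern.
6. **Waveform inference.** Pointwise two-sample or paired t trajectories over
   the 101 stance points, with family-wise error control by max-statistic
   permutation (group-label permutation or sign flips of paired differences);
   significant regions are reported as % of stance phase.

## Worked example

```python
import gaitsubpop as g

cohort = g.CohortConfig(
    n_per_subpop=(20, 20, 20), n_hc=25,
    n_followup_per_subpop=(10, 10, 10),
    recovery_fraction=(0.8, 0.8, 0.8), seed=42,
)
config = g.PipelineConfig(synthetic=cohort, seed=42, n_perm=500,
                          output_dir="demo")
report = g.run(config)

print(f"retained PCs: {report.basis.n_retained}")
print(f"subpopulations (k): {report.k}")
for r in report.reports:
    if r.era == "pre":
        print(f"subpop {r.subpop_id}: rate {r.classification_rate:.1f}%, "
              f"pathologic ratio {r.pathologic_ratio}%, AUC {r.roc_auc:.3f}")
for sp, prof in report.importances.items():
    print(f"subpop {sp} top-5: {', '.join(prof.top5)}")
cogs = report.cogs_frame()
for sp, grp in cogs.groupby("subpop"):
    pre = grp.loc[grp.era == "pre", "cogs"].mean()
    post = grp.loc[grp.era == "post", "cogs"].mean()
    print(f"subpop {sp} mean COGS: pre {pre:.2f} -> post {post:.2f}")
```

prints

```
retained PCs: 34
subpopulations (k): 3
subpop 1: rate 91.1%, pathologic ratio 80.0%, AUC 0.992
subpop 2: rate 100.0%, pathologic ratio 100.0%, AUC 1.000
subpop 3: rate 88.9%, pathologic ratio 75.0%, AUC 0.996
subpop 1 top-5: hip_rotation_angle, hip_flexion_moment, pelvic_tilt_angle, ...
subpop 2 top-5: hip_flexion_angle, knee_flexion_angle, hip_rotation_angle, ...
subpop 3 top-5: pelvic_tilt_angle, hip_adduction_angle, hip_rotation_angle, ...
subpop 1 mean COGS: pre -10.65 -> post 5.16
subpop 2 mean COGS: pre -11.58 -> post 5.72
subpop 3 mean COGS: pre -9.30 -> post 4.62
```

The generator planted three subpopulations, each deviating from the healthy
template by 3 HC standard deviations on two channels; the pipeline recovers
k = 3, the planted channel pairs top each subpopulation's importance ranking,
and with recovery fraction 0.8 the mean COGS rises from clearly pathologic
(negative) to the healthy side of the hyperplane after surgery.

A CLI mirrors the library (`gaitsubpop simulate`, `gaitsubpop run`,
`gaitsubpop figures`); `run` writes all result tables as CSV (scores,
assignments, classification, importance, COGS, waveform inference) plus a PC
scatter with cluster hulls, waveform overlays with significance shading, and
pre/post COGS violins.

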