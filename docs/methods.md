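# Methods

This note documents the modelling and numerical choices of `gaitsubpop`: what
each stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Data model

The universal container is a `WaveformStudy`: a subject table (group HOA /
THR / HC, planted subpopulation where applicable, pairing of post-surgery
records to their pre-surgery patient, affected side, and scalar metadata)
plus a dense array `[subject, trial, channel, timepoint]`.  The canonical
grid is 18 channels x 101 stance-phase points: 11 joint angles (pelvic tilt,
obliquity and rotation; hip flexion, adduction and rotation; knee flexion,
adduction and rotation; ankle plantarflexion; foot progression) and 7
external joint moments normalized to body mass (hip, knee: flexion,
adduction, rotation; ankle plantarflexion).  Angles are in degrees, moments
in N·m/kg.  The pipeline starts at time-normalized waveforms; marker
processing and inverse dynamics are upstream concerns of the motion-capture
lab, not of this package.

## Synthetic cohort generator

The generator produces cohorts with exactly the structure the analysis
assumes, no more:

- **Templates.** Each channel's healthy mean curve is a superposition of
  Gaussian bumps with hand-set, physiologically plausible centers, widths
  and amplitudes.
- **Between-subject variation.** Per channel, each subject carries a smooth
  random curve drawn from a stationary Gaussian process with a
  squared-exponential kernel (default lengthscale 0.15 of the stance phase —
  visually smooth gait-like variation without claiming a physiological
  model), scaled by `subject_variation_sd`.
- **Within-subject trial noise.** Independent Gaussian noise per trial and
  timepoint, scaled by `trial_noise_sd`.  Both noise levels are expressed as
  fractions of the channel's natural scale (peak absolute template value),
  so one pair of numbers yields sensible variability for degree-scaled
  angles and N·m/kg-scaled moments alike.  Defaults
  (`subject_variation_sd = 0.15`, `trial_noise_sd = 0.05`) put
  between-subject variation an order of magnitude above trial noise, which
  is the usual situation in gait labs; no published within-subject variance
  for this population was available to calibrate against, so these are
  stated defaults, not fitted ones.
- **Planted effects.** A subpopulation deviates from the healthy template on
  a chosen set of channels by `magnitude x effect_curve(t) x sd_ref`, where
  `sd_ref` is the HC standard deviation of per-subject trial-mean curves
  (`sqrt(sv^2 + tn^2/n_trials)` per channel).  Magnitude is therefore
  directly a standardized effect size: magnitude 2 produces a standardized
  channel deviation of about 2 after HC-referenced z-standardization, which
  the tests verify.  The default effect shape is a raised cosine spanning
  the stance phase, reflecting that hip-OA gait alterations (offset
  rotations, reduced moment ranges) persist across stance rather than being
  confined to one event.  The three default subpopulations affect disjoint
  hip-centred channel pairs (rotation/moment, sagittal flexion,
  frontal/pelvis), echoing clinically described adaptation strategies.
- **Surgery.** The first `n_followup` patients of each subpopulation get a
  paired post-surgery record: the subject's own deviation curve is retained,
  the pathological offset is multiplied by `1 - recovery_fraction`, and
  fresh trial noise is drawn.  `recovery_fraction = 1` removes the effect
  bit-exactly (tested), `0` leaves it untouched.
- **Metadata** (age, sex, mass, height, walking speed) are drawn from
  group-level normal distributions typical of a unilateral hip-OA surgical
  cohort; they deliberately do not influence the waveforms, because the
  clustering operates on biomechanics only.
- **Defaults** mirror the emulated study layout: 109 patients
  (28 + 43 + 38), 63 paired follow-ups (17 + 28 + 18), 56 controls, 3 trials,
  101 points.

What the generator does **not** emulate: skewed or bounded metadata
distributions, heteroscedastic trial noise, inter-channel correlation of
subject deviations (each channel's deviation is drawn independently),
missing trials, asymmetric recovery (recovery acts uniformly on all affected
channels), or any real marker/force-plate artifact.  Passing tests therefore
demonstrate that the *pipeline* behaves correctly under its own assumptions,
not that real hip-OA cohorts contain k recoverable clusters.

## Preprocessing and the shared eigenbasis

Standardization uses the HC pointwise mean and sample SD (denominator n−1;
the convention was unspecified upstream, and with ~50 controls the choice is
immaterial).  Zero-variance variables raise an error rather than being
dropped: in practice they signal a degenerate synthetic configuration.

PCA is computed by SVD of the HOA matrix centered on its own column means.
The basis is derived from the patient cohort, so the patient mean is the
natural centering point, and the same center is subtracted before projecting
THR and HC.  The retained count *P* is minimal with cumulative explained
variance ≥ the threshold (default 0.90).  Eigenvector signs are fixed by
making each component's largest-magnitude element positive, for
backend-independent reproducibility.

One property worth knowing: a mean offset *shared by the whole fitting
cohort* is absorbed by centering and contributes nothing to the
eigenvectors.  Channel-restricted group effects are representable in the
reduced space only insofar as they carry *between-patient* variance — which
they do when several subpopulations (or within-group spread) exist, as in
the emulated study design.  With a single perfectly homogeneous
subpopulation, back-projected importance cannot recover the affected
channels; the tests exercise the multi-subpopulation design for this reason.

On synthetic cohorts the 90% criterion typically retains 30–50 components
(smooth GP noise spreads variance over many directions), more than the ~14
seen on real gait data, where waveforms are strongly correlated across
channels.  Nothing downstream depends on the exact count.

## Cluster-count rule and consensus filtering

The Ward criterion "determines the optimal number of clusters" without a
canonical rule, so the package uses a deterministic, auditable one: with
h_k the fusion height at which k clusters merge into k−1, choose the k in
[k_min, k_max] maximizing the relative gap (h_k − h_{k+1}) / h_{k+1}, ties
toward smaller k.  The dendrogram heights are written out for audit.

k-means is executed five times (configurable) with different seeds, each run
using ten k-means++ restarts so that each run reports its best local optimum
— the consensus filter should flag genuinely ambiguous subjects, not
optimizer noise.  Runs are label-aligned to the first run by
maximum-agreement bipartite matching; a subject is consistent iff all runs
agree (unanimity — the strictest reproducible reading of "consistently
assigned"; majority voting would be a one-line change).  Clusters are
renumbered 1..k by decreasing size (ties by smallest member id) purely for
determinism; the numbering carries no meaning.  Silhouettes use the classic
(b − a)/max(a, b) with Euclidean distances; excluded subjects are omitted
and singleton clusters score 0.

## Classification

One linear SVM per subpopulation vs HC, box constraint C = 1 and kernel
scale 1 (features are divided by the kernel scale; the stored weights fold
it back, so decisions are invariant under jointly rescaling features and
kernel scale).  Orientation is fixed with positive decision values on the HC
side.  Classes are unweighted despite the size imbalance, matching the
reference settings.

Pre-surgery metrics come from seeded stratified 10-fold cross-validation
with pooled out-of-fold decision values: classification rate (% correct),
sensitivity (pathologic positive), specificity, ROC-AUC (rank statistic of
the pooled decision values) and the pathologic ratio.  Defined this way,
pre-surgery sensitivity and pathologic_ratio/100 coincide by construction.
If a class has fewer members than folds, the fold count is reduced with a
logged warning.  Post-surgery records are unseen data, so they are evaluated
through the final model trained on all pre-surgery data — the only model
defined for them; subjects with negative decision values count as pathologic,
and specificity/AUC for the post era are computed against the HC cohort
under that same final model.

Beware the selection effect inherent to cluster-then-classify: because
cluster membership is derived from the same subjects' features, even
out-of-fold metrics of a null cohort sit above chance.  The package's null
tests therefore bound pathologic ratios rather than asserting AUC = 0.5.

## Shapley importance and COGS

For a linear decision function with an independent-features background
concentrated at the training mean, the Shapley value of PC i is exactly
phi_i = w_i (x_i − m_i), and efficiency (sum phi = f(x) − f(m)) holds to
machine precision; the tests verify both the closed form against coalition
enumeration and the identity per subject.  The background is the classifier's
training set mean (subpopulation + HC); subpopulation subjects only enter the
importance average.

The back-projection weights each subject's PC score by the absolute Shapley
value (u_i = |phi_i| x_i), reconstructs r = V u on the waveform grid, and
aggregates per channel as the mean of |r| over the 101 timepoints, then over
subjects.  Absolute values prevent cancellation between stance sub-phases.
The "importance factor" here *is* |phi_i| x_i; no second scaling is applied —
this is the single interpretive choice in the reconstruction, and the
package's validation surface is the channel *ranking* under planted effects,
not importance magnitudes, which are model-specific and not comparable
across subpopulations.

COGS = (w·x + b)/||w||, the signed orthogonal distance to the hyperplane,
positive toward HC so that post-surgical improvement appears as an increase.
It is invariant under positive rescaling of (w, b), and zero exactly on the
hyperplane.

## Waveform inference

Pointwise pooled-variance two-sample t (subpopulation vs HC) or paired
one-sample t of differences (pre vs post), over the 101-point grid.
Family-wise inference is non-parametric: the null distribution of the
maximum absolute t over the trajectory is built from group-label
permutations (unpaired) or random sign flips of the paired differences
(paired), with exhaustive enumeration whenever the number of distinct
permutations does not exceed `n_perm` (e.g. all 2^n sign patterns for small
paired designs); the observed labelling is always included in sampled nulls,
making the test exact.  The critical value is the empirical (1 − alpha)
quantile taken with the conservative "higher" method; alpha defaults to 0.05
two-sided.  This is a deliberate divergence from parametric random-field
inference: the permutation variant of the same 1D-inference framework is
assumption-light and exactly calibrated at desk scale (the test suite
verifies family-wise error 0.05 ± 0.02 over 1000 simulated null datasets).

Significant fractions use the 101-point denominator (the endpoint convention
was unspecified; 101 is the grid size).  Degenerate inputs: zero pooled
variance is an error naming the timepoint; a paired difference that is
identically zero at a timepoint yields t = 0 there (identical data is a null
result), while zero variance with a nonzero shift is an error, because the
statistic is genuinely undefined.

## Orchestration, seeds and problem sizes

Stages run in fixed order (generate/load → preprocess → cluster → per-
subpopulation SVM → explanations → waveform inference), each writing its
table standalone.  A single master seed derives per-stage seeds by fixed
offsets, so runs are byte-reproducible (tested) while stages stay
independently seedable.  Waveform inference is run on each subpopulation's
top-5 channels, unpaired vs HC and paired pre/post.

Default problem sizes are the emulated study layout (109/63/56 subjects);
a full run including 1000-permutation inference on 15 channel comparisons
completes in a few seconds on one CPU.  The simulation suites in the tests
use 50–100 seeds with cohorts of 12–30 subjects per subpopulation — chosen
as the smallest sizes at which the statistical properties under test (cluster
recovery, importance ranking, error calibration, response direction) are
stable, keeping the whole suite inside a coffee break.

## Known limitations

- The generator's independence of channels understates the cross-channel
  correlation of real gait, which is why the synthetic eigenbasis needs more
  components than real cohorts.
- Unanimity-based consistency is stricter than majority voting; with very
  noisy cohorts it can exclude many subjects (the pipeline then skips
  under-populated subpopulations with a warning rather than failing).
- Importance magnitudes are not comparable across subpopulations or cohorts;
  only rankings are validated.
- The cluster-then-classify selection effect biases null-performance metrics
  upward; reported classification metrics describe separability of the
  *discovered* groups, not an external diagnostic accuracy.
- No nonlinear dimensionality reduction or SVM hyperparameter tuning is
  offered: interpretability of the linear model in the fixed eigenbasis is
  the point of the method.
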