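# Methods

`hiernet` classifies two groups of subjects from regional cortical
morphometry by (1) building morphometric similarity networks at four
parcellation resolutions, (2) selecting discriminative features with a
three-stage cascade, and (3) fusing an ROI kernel and a network kernel in
a multi-kernel SVM evaluated by repeated twofold nested cross-validation.
This note records the model, its assumptions, the tunable parameters, and
the design choices made where the design was genuinely open.

## Parcellation hierarchy

The bottom layer holds the 78 cortical regions of the AAL parcellation
(the 90-region atlas with its 12 subcortical structures removed),
renumbered 1–78 with odd = left, even = right.  Layer 3 merges gyri into
36 lobar surfaces, layer 2 into 14 lobes, and layer 1 treats the cortex
as one region.  The hierarchy ships as a flat TSV (one row per
bottom-layer ROI with its names/indices at every layer) so it can be
audited row by row; loading validates index contiguity, merge-map
surjectivity and that the 4→2 map factors through the 4→3 map.

One labelling oddity in the source material is preserved deliberately:
the operculum pair printed with indices 17, 18 carries a "left" qualifier
for both hemispheres.  We encode the pair as left/right "Rolandic
operculum" following the printed index pairs and flag the label here
rather than guessing intent.

## Similarity networks

For one subject, the edge between ROIs *i* and *j* at any layer is

    C(i, j) = exp( −(t_i − t_j)² / (2 (σ_i² + σ_j²)) ),

with *t* the ROI's mean cortical thickness and σ its within-ROI
standard deviation.  Values lie in (0, 1]; the matrix is symmetric with
unit diagonal, and depends on thickness *differences* only, so a uniform
shift of all means leaves every network unchanged.  Despite being
described in some of the literature as a correlation, this is a Gaussian
similarity kernel, and that is what is implemented.  Coarse-layer ROIs
use the unweighted mean of their constituents' *t* and (by default) the
unweighted mean of their σ; a root-mean-square pooling rule is available
(`sigma_rule="pooled"`).  If both dispersions are zero the edge is 1 for
equal means and an error otherwise (degenerate input).

Before any feature is computed, volumes are divided by the subject's
total intracranial volume, thickness by the subject's global mean
thickness and surface area by the total cortical area.  The within-ROI
thickness SD is divided by the same factor as the mean so the
dimensionless ratio in the kernel is unchanged by normalization.

Feature blocks: `roi_L4` (78 ROIs × 5 measures = 390), `net_L4`/`net_L3`
/`net_L2` (strict upper triangles, row-major: 3003/630/91 edges) and
`net_all` (layers 4, 3, 2, 1 concatenated = 3724; the single-node layer
contributes nothing).  Only in-layer edges exist; no between-layer
connections are defined.

## Feature-selection cascade

Applied independently per block, always on training data only:

1. **t-test screen** — pooled-variance two-sample t, two-sided, keep
   p < α (default 0.05), no multiple-testing correction (it is a coarse
   screen).  Features with zero variance in both groups get p = 1.
   Inside cross-validation a `screen_floor` of 1 keeps the single
   lowest-p feature when nothing passes, so a null fold remains
   classifiable; outside CV an empty screen is a hard error.
2. **mRMR** — greedy MID ranking (mutual information with the label
   minus mean MI with already-chosen features; MIQ available) on
   features discretized into 3 bins at mean ± 1 SD.  Default retention
   `min(200, survivors)`.
3. **SVM-RFE** — repeatedly fit a linear SVM (C = 1) on z-scored
   features, drop the smallest squared weights (10% of the remaining set
   above 50 features, singly below), until `rfe_keep` remain.  By
   default `rfe_keep` is chosen from a small grid (10, 20, 30) by
   3-fold accuracy of an RBF-SVM over the nested subsets the elimination
   order defines.  Tied grid scores go to the **largest** candidate:
   on small samples the scores saturate, and falsely excluding an
   informative feature collapses a fold to chance while a few retained
   noise features only dilute the kernel slightly (both behaviors were
   measured on synthetic cohorts).

All ties (p-values, mRMR scores, RFE weights) break on feature name, so
a cascade run is a pure function of its inputs.

## Multi-kernel SVM and cross-validation

Each block's selected features are z-scored on training statistics and
turned into an RBF kernel with γ = 1/(n_features · variance) (a
`gamma_scale` grid can put γ on the inner search).  The two kernels are
fused as β·K_roi + (1−β)·K_net, β ∈ [0, 1], and an SVM is trained on the
precomputed fused kernel.  The positive class is the high-self-esteem
group.

The protocol is repeated stratified twofold CV (default 100
repetitions; the canonical experiments use 20 to keep runtimes in
minutes).  Per fold: cascade on the training half, then an inner
stratified 5-fold grid search over (β, C, γ-scale).  Two points matter:

* **Leakage-free inner estimates.**  The cascade is re-run inside every
  inner fold (`inner_selection=True`).  If instead the features chosen
  on the full training half are reused, the inner accuracies saturate at
  1.0 for every β and the search degenerates to tie-breaking.
* **Coarse inner β grid.**  Inner validation sets hold ~7 subjects, so a
  fine β grid only overfits estimation noise; the inner default is
  (0, 0.25, 0.5, 0.75, 1).  The weight-coefficient *sweep* — the
  experiment that maps accuracy as a function of β — accepts any grid,
  e.g. a 0.05 step.
* Ties in the inner search prefer β = 0.5 (balanced fusion as the
  uninformative prior), then the default kernel width, then smaller C.

Metrics follow the standard definitions: ACC, SEN, SPE, AUC (rank
statistic on decision scores), F-score, Youden's index Y = SEN+SPE−1 and
balanced accuracy BAC = (SEN+SPE)/2.  (Published tables in this area
sometimes print Y/BAC values inconsistent with their own SEN/SPE; the
identities above are enforced instead.)  Per repetition every subject is
tested exactly once; reported values are means ± SD over repetitions.
Feature stability is the count of fold-fits in which a feature survives
the cascade (≤ repetitions × folds), reported as ranked frequency tables
annotated with ROI names, hemispheres and measures/layers.

Baseline classifiers (RBF-SVM, linear SVM, 5-NN, Gaussian naive Bayes,
decision tree) run under the same outer protocol on the concatenated
selected features.

## Synthetic cohorts

The generator emulates the morphometry table of a two-group study
(default 34 + 34 subjects).  Per-ROI templates: thickness means
~N(2.5, 0.2²) mm, within-ROI σ ~N(0.25, 0.05²) mm, and log-normal
volume/area templates around 6000/4000/1500 mm³ and 2500 mm² (CV 0.3).
Subject-level noise: additive thickness deviations (SD 0.15 mm),
multiplicative volume noise (CV 0.08), plus per-subject global size and
thickness factors that normalization must (and does) cancel.  Globals
are computed from the generated regions, not drawn separately.  All
baseline constants are plausibility defaults of this package, not
measured values.

Planted group differences:

* **Regional effects** shift one measure of one ROI in the high group by
  d subject-level SDs.  Realized standardized effects match the nominal
  d on average (checked over seeds).
* **Edge effects** couple an ROI pair's thickness deviations in the high
  group (shared latent factor, correlation ρ) while the low group stays
  independent; marginals are unchanged, so only the pairwise similarity
  differs.  The pair's template means are equalized so the edge responds
  to the coupling rather than a fixed offset.  A measured property of
  this construction: the induced similarity-feature effect saturates
  near Cohen's d ≈ 1.2 as ρ → 1 (the uncoupled group's similarity is a
  heavy-tailed transform of a χ² variable), so edge effects are
  intrinsically moderate.  ρ = 0.9 is used in the canonical experiments.

What the generator does *not* emulate: spatial covariance between
neighbouring ROIs, non-Gaussian morphometry, site/scanner effects,
age/sex structure, or any claim of biological realism.  Passing tests
demonstrate that the pipeline recovers the statistical structure it
assumes — not performance on real MRI data.

## Canonical experiments and problem sizes

`hiernet.experiments` fixes three study conditions (all 34 + 34, 20 CV
repetitions unless noted):

* **Null calibration** — no effects; mean ACC must land in [0.45, 0.55].
  Measured ≈ 0.50.
* **Recovery** — five regional effects (d = 2, volume/area measures) and
  four coupled edges (ρ = 0.9) on *disjoint* ROI sets.  Disjointness is
  deliberate: a planted thickness regional effect perturbs all ~77 edges
  touching its ROI, making a 4-edge ground-truth list unrecoverable in a
  top-15 table.  Outcomes: nested-CV accuracy (measured ≈ 0.87–0.95
  across cohort draws; the gap to the ≈0.99 known-features oracle is the
  cost of per-fold selection at n = 34/group, where ~5% of null features
  pass the screen with inflated in-fold effects) and top-15 frequency
  hits (regional 5/5, edges ≥ 3/4 in measured runs).
* **Weight sweep** — single-channel-signal cohorts at 5 repetitions over
  β ∈ {0, .25, .5, .75, 1}; accuracy peaks at low β when only the
  network carries signal and at high β when only the ROI block does.

Sizes were chosen so each experiment completes in a few minutes on one
CPU; repetition counts are the experiments' definitions, not caps.

## Known limitations

* With 34 subjects per group the selection cascade admits a handful of
  spuriously significant features per fold; nested-CV accuracy therefore
  plateaus ≈ 0.1 below the Bayes-optimal level even for strong planted
  effects.  This is a property of the method at this sample size.
* mRMR mutual information uses a fixed 3-bin discretization; very
  skewed features lose information.
* The inner grid search is only as good as ~7-subject validation folds;
  hyperparameter choices are noisy and the tie-break priors matter.
* Between-layer network connections are not defined and not implemented.
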