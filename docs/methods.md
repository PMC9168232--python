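# Methods

This note documents the modeling and numerical choices behind `joingcla`:
what the model computes, what the synthetic-cohort generator does and does
not emulate, and where the design was genuinely open.

## Model

The classifier operates transductively on a cohort of P imaging scans.  Two
families of population graphs carry all cross-sample information; the node
features carry only within-sample information.

**Population scan graph (PSG).**  For each imaging modality the pairwise
Pearson similarity matrix of the vectorized connectivity features is min-max
normalized over *all* P×P entries, including the diagonal (self-similarity 1
is typically the maximum, so the diagonal maps to 2 before the graph
convolution adds its own self-loop); a constant similarity matrix — which
carries no information — maps to the all-ones factor, the identity of the
multiplicative fusion.  Factors from M modalities are multiplied
elementwise, giving entries in [1, 2^M].  Min-max normalization is applied
per modality before fusion, not once after.

**Population omics graph (POG).**  Subject-level Pearson correlations of one
omics type's features are computed, the diagonal is forced to exactly 1
(a fixed point of the subsequent powering), the unsigned WGCNA soft
threshold a = |r|^β rescales the graph, and the subject graph is expanded to
scans by block duplication (a subject with k scans induces a k×k block of
identical entries).  The unsigned variant is required because the spectral
normalization needs nonnegative weights; whether the correlations should
instead enter signed is an open modeling question flagged for sensitivity
analysis.  The default power β = 6 is the published unsigned-network
convention; `pick_soft_threshold` optionally selects the smallest candidate
whose degree distribution reaches a signed scale-free fit R² ≥ 0.8 (log-log
regression of bin frequency on mean connectivity over at least five
populated bins), falling back to β = 6 below 10 nodes or when the fit is
undefined everywhere.

**Network.**  Encoder: H¹ = ReLU(X^c W¹ + b¹), then one graph convolution
H² = ReLU(D̂^(−1/2)(A+I)D̂^(−1/2)H¹W²).  The degree matrix is that of A+I
(the self-looped graph), the standard Kipf–Welling normalization; it is
positive definite for any nonnegative A.  Omics networks: one linear graph
convolution per type over its POG followed by the doubly rectified head
H⁴ = ReLU(ReLU(H³)W⁴ + b⁴) — the double rectification is implemented
exactly as the model is defined, not simplified.  Attention: per sample the
query is the mean of the omics-network logits; keys and values are the
scalar projections H³W^(3c) and H⁴W^(4c); raw scores (query × keys, no √d
scaling) are softmaxed **over the omics axis**, so each class row of the
L⁴×N attention matrix is a probability distribution over omics networks —
this is the normalization under which "which omics type did the model use
for this class" is a well-posed question.  The self-attention ablation
baseline uses conventional 1/√L⁴ scaling.  With N = 1 the attention layer is
bypassed (logits → softmax); with N = 0 a linear head sits directly on the
encoder.

**Loss.**  The binary class-weighted cross-entropy is implemented in its
stated form, J = E[−w_y·y_d·log y − (1−w_y)(1−y_d)log(1−y)] with
w_c = 1 − P_c/P and probabilities clamped at 1e-12.  Note an algebraic
property of this form: for binary labels the coefficient on a positive
sample, w₁ = P₀/P, equals the coefficient 1−w₀ = P₀/P on a negative sample,
so the weighting rescales the loss but cannot re-balance gradients between
classes.  This is consistent with the empirical observation that class
weighting alone does not rescue training under severe imbalance, and it is
why oversampling is the load-bearing imbalance treatment.  For more than
two classes the loss generalizes to weighted categorical cross-entropy with
coefficient w_{y_d}.

**Implementation.**  The network, loss, and gradients are written directly
in numpy; backpropagation is derived by hand layer by layer and verified
against central finite differences (absolute tolerance 1e-7) for every
parameter of every architecture variant (N = 0, 1, ≥2; both fusion
operators).  Adam uses conventional defaults (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8).  Initialization is Glorot-uniform, fully determined by the run
seed.  Dropout (inverted scaling) is applied only after the graph
convolutions, the stated placements; evaluation-mode passes are
deterministic and bitwise reproducible.  Connectivity features are
column-standardized over all scans before the encoder — a numerical
conditioning step in the same transductive spirit as the graph
construction itself.

## Protocol

Subjects (never scans) are split 2:1 into non-test and test, stratified by
class; the non-test subjects are dealt round-robin into 5 folds, so fold
sizes differ by at most one subject per class.  Scans flagged as augmented
are confined to training under every plan — validation and test sets always
consist of real scans.  Oversampling duplicates minority-class training
scans with replacement to exact class parity; the duplicates enter the
population graphs as additional scan nodes, which transductively
strengthens the minority block of every graph (test-set minority scans gain
same-class neighbors), the same mechanism by which augmented scans
participate in a population-graph study.

`train_model` supports two modes.  *Early-stopping mode* monitors
validation MCC with a patience of 20 epochs (ties keep the earliest epoch)
and restores the best epoch's parameters.  *Fixed-epoch mode* trains for a
preset count — the deployment mode.  The deployment preset
(`deployment_config()`) mirrors the study design in which hyperparameters
are tuned once and reused unchanged across all data combinations: dropout
0.1, 16 hidden units per graph-convolution layer, learning rate 0.001, and
a training length of 4000 epochs, the budget at which training loss has
converged on the tuning combination at desk scale.  The fixed length is
load-bearing: under severe imbalance the model begins as a constant
predictor, so validation MCC sits exactly at 0 (and validation loss
initially *rises* while the class prior unwinds) for tens of epochs at this
learning rate — a patience-20 monitor of either quantity therefore stops
near epoch 21 with an epoch-1 "best", long before any signal is extracted.
Selecting the epoch count per combination by early stopping is retained as
an implemented, tested mode, but it is not the deployment default.

Metrics: accuracy in percent and MCC, reported as mean ± sd over seeds to
two decimals.  MCC is computed from the 2×2 confusion table with the
zero-denominator → 0 convention, so any constant predictor scores exactly
0; the implementation is cross-checked against an independent
covariance-form oracle and scikit-learn.

Backward elimination over omics types starts from the full set, scores all
leave-one-out subsets, moves to the best strictly improving child
(ties broken by lexicographic order of the removed name), and stops when no
child improves or one type remains.  Scoring failures are recorded as −∞
rather than aborting the search.  Seeds are shared across subsets so
comparisons are paired.

## Synthetic cohorts

The generator emulates the *structure* of a paired multi-modal,
multi-omics, imbalanced cohort with known ground truth: per-subject class
labels ~ Bernoulli(1−π), a latent factor z ~ N(0, I_d) shared by all of a
subject's data, 1 + Poisson scans per subject, symmetric unit-diagonal
connectivity matrices (modality template + class-specific rank-one
component + subject component + scan noise), and omics tables composed of a
shared baseline profile, an optional symmetric class mean shift of the
stated effect size on a random 10% of features, a weak subject-latent term,
and i.i.d. noise.

The internal scales were set by analyzing how a mean-shift signal reaches
the classifier.  The within- vs. cross-class Pearson gap of an informative
omics type is 0.2·(e/2)²/var in units of the feature noise, so the baseline
profile scale controls both the absolute correlation level (which the β = 6
powering must not annihilate — neighbor mass has to dominate the GCN
self-loop) and the relative class-block contrast.  The defaults — baseline
2.0× noise sd, subject-latent loading 0.15, shift split ±e/2 — put
pre-powering inter-subject correlations near 0.74 and post-powering edges
mostly in 0.15–0.25, the regime described for informative omics types in
real cohorts, and give the informative POG a clear class-block structure
(degree separation of roughly three within-class standard deviations at a
2-sd effect).  Default desk-scale preset: 120 subjects, π = 0.75, 20-region
atlas (190 features per modality), two uninformative imaging modalities,
three omics types with 50/200/500 features, ~1.5 scans per subject — sized
so the full 10-seed protocol runs in minutes on one CPU; the real cohort's
dimensionalities (atlas of 116 regions → 6,670 features per modality, omics
panels up to ~6.8×10⁵ features) are reachable through the same
configuration type.

What the generator does *not* emulate: realistic tractography or
hemodynamics (connectivity matrices are Gaussian-structured, not
biophysical), omics measurement idiosyncrasies (count distributions,
batch effects, missingness — missing values are a read-time error by
contract), or correlated informative features.  Passing the recovery tests
therefore demonstrates that the pipeline extracts class structure routed
through population-graph similarity under realistic imbalance and
dimensionality — not that it would attain the same scores on any particular
real cohort.

## Known limitations

* The attention matrix is seed-variable on weakly separable cohorts; single
  runs should not be interpreted — the reported matrices are means over
  seeds and over test scans per predicted class.
* The class-weighted loss in its binary form cannot re-balance gradients
  (see above); severe imbalance is handled by oversampling, and disabling
  it reproduces majority-collapse.
* Transductive evaluation means graph construction sees test-scan features
  (never test labels); this matches the population-graph setting but is not
  an inductive generalization claim.
* One graph convolution per stage limits the model to first-order
  neighborhood statistics (e.g. weighted degree); deeper stacks are out of
  scope.
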