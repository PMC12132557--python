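# Methods

## The question and the model

`modagg` studies whether element-wise summation of embeddings drawn from
*unaligned* latent spaces — one independently trained encoder per data
modality, coordinated only in output dimensionality — preserves (a) the
identity of the contributing modalities and (b) patient-level biological
signal such as tumor of origin.  The package contains both the data-side
machinery (a synthetic multimodal cohort generator and the per-modality
embedders) and the analysis-side machinery (sampling/aggregation
strategies, recognisers, classifiers, stratified metrics, clustering and
distance analyses).

## Synthetic cohort generator

Each patient *i* carries a latent factor

    z_i = c_t(i) + s_u(i) + ε_i,     ε_i ~ N(0, I_L)

with `c_t` the tumor-type centroid, `s_u` a subtype sub-centroid offset
and `L = latent_dim` (default 16).  Centroids are random directions scaled
so that pairs sit approximately `class_separation` apart (near-orthogonal
random unit vectors scaled by `class_separation / √2`); subtype offsets
are built the same way at `subtype_separation`.

Each modality then observes `z_i` through its **own** fixed random map,
realising unalignment at the data level:

* **RNA** (one profile per patient): affine map to `n_genes_rna` (600)
  continuous features plus `N(0, noise_sd²)` noise.
* **Mutations** (one one-hot row per patient): the expected mutation count
  is log-normal and tied to the latent
  (`λ_i = exp(1.8 + 0.8·standardised burden score)`), distributed over 500
  genes by latent-dependent softmax weights.  This spans zero-mutation
  patients through high-burden ones, so all three TMB classes occur at the
  defaults.  TMB = count / 30 Mb; class 1 (high) at ≥ 0.5 mut/Mb, class 0
  (low) below, class 2 for a zero count.
* **Image tiles** (Poisson(40)+1 per patient): per-tile latent jitter,
  affine map, sigmoid squashing into [0, 1] pixel features that reshape to
  small RGB tiles (768 features ↔ 16×16×3).
* **Annotations** (Poisson(10)+1 segments per patient): per-segment latent
  jitter only; the embedding map itself lives in the embedders module.

Defaults (the study conditions used throughout the tests and the
acceptance script): 6 tumor types × 50 patients, `class_separation = 10`,
`subtype_separation = 3`, `noise_sd = 1`, `embed_dim = 768`, seed-derived
determinism throughout.  `class_separation` is calibrated so that
between-type centroid distance clearly exceeds the within-type latent
spread (≈ √(2L) ≈ 5.7 plus subtype offsets): tumor types in real
transcriptomic data are nearly completely separable, and the low/no-signal
regimes remain reachable by turning the knob down (0 gives chance-level
behaviour, which the tests exercise).

## Embedders

RNA, mutation and image data are encoded by VAEs built on the package's
own minimal NumPy neural-net engine (dense / batch-norm / dropout layers,
Adam, early stopping).  Configuration defaults follow the training
schedule of the study being emulated: batch size 256, at most 50 epochs,
early stopping with patience 10 on a 10% validation split (best weights
restored), loss = per-sample summed squared reconstruction error +
β(t)·KL, with

    β(t) = min(1, β₀ + (1 − β₀)·t/κ),   κ = 1, β₀ = 0  →  one-epoch warm-up.

Encoding returns the latent mean, so inference is deterministic.  The RNA
encoder is trained in two phases (pretraining, then fine-tuning at 10× the
lower learning rate with β fixed at 1).  The image path mimics a
foundation-model tile pipeline: images are partitioned into non-overlapping
square tiles (border remainders dropped), background tiles removed when
more than 80% of pixels exceed an RGB threshold on all channels, tile
features encoded by a VAE with a 2×768-d latent, and the embedding
truncated to its **latter** 768 dimensions.  Annotations use a fixed
two-layer tanh map from the latent to 768 dimensions — deterministic, with
no probabilistic structure, and parameterised independently of every VAE.

Reconstruction likelihoods follow the data: squared error for continuous
inputs (RNA, tile features) and Bernoulli cross-entropy with a logit
decoder for the binary mutation matrix — with a squared-error likelihood
the sparse one-hot rows offer so little reconstruction incentive that the
posterior collapses and the embeddings carry no mutational signal.  The
mutation VAE also uses a higher learning rate (1e-2) because 256-row
batches over a ~300-patient cohort give very few gradient updates per
epoch.  Hidden architectures are not dictated by the emulated schedule and
default to (1024, 1024) for the RNA/mutation VAEs, (512, 512) for the tile
VAE.
The tile VAE is fitted on a seeded subsample of at most 3000 tiles (then
encodes all ~12k tiles); at these data sizes the fit is unchanged and the
runtime stays desk-scale.

## Aggregation

Constituents are drawn **with replacement**: first a modality (uniform
probabilities by default, configurable), then a uniform embedding of that
modality.  Under cancer-specific sampling each aggregate first draws a
tumor type and restricts all constituents to it.  Presence targets
collapse repeats to one.  Patient-level aggregation performs `R`
independent rounds of "draw `k` embeddings of one patient (all modalities
mixed, no per-modality quota), sum", and concatenates the `R` sums.

Noise perturbation replaces `max(1, round(f·k))` whole constituents
(`f > 0`) with i.i.d. `N(0, noise_sd²)` vectors, preserving the total
constituent count, recomputing the sum and removing replaced constituents
from the composition targets.  The floor of one replacement keeps small
fractions active at low sample counts (round alone would give zero at
`f = 0.1, k = 3`).  Per-position corruption of the summed vector is *not*
the implemented mode; whole-constituent replacement is.

## Models

* **Recogniser**: shared trunk of dense + batch-norm + ReLU + dropout
  blocks (default 768→1024→512, dropout 0.2), branching into one
  sigmoid-scalar presence head per modality (branch width 128); optional
  softmax cancer-type head on the trunk for the cancer-specific setting.
  Adam at learning rate 0.001, MSE loss against binary presence targets
  (+ cross-entropy for the cancer head), at most 100 epochs with patience
  10.  Inputs are standardised per dimension on the training split —
  aggregate sums mix modality directions of very different scales, and
  without this the weakest-scale branch (mutation) trains erratically.
  Presence threshold 0.5, inclusive.
* **Baseline (MCRM)**: the multi-label task is read as independent
  one-vs-rest logistic regressions per modality (plus a multinomial
  regression for the cancer label); single-class targets fall back to a
  constant head with a warning.
* **Classifiers**: feed-forward softmax networks (default hidden
  (512, 256), dropout 0.2) over patient aggregates for tumor type, subtype
  (only emitted for types with > 100 labelled patients) and TMB class,
  trained and evaluated over repeated independent runs (default 30; the
  acceptance script uses 5) with fresh 80/20 splits and initialisations.

Splits everywhere: 20% test, then 20% of the remainder for validation
(the classifier's validation split is internal to its training rows and
used only for early stopping).

## Evaluation conventions

Composition labels are zero-inflated, so metrics are stratified per
modality: the zero-labelled group (modality absent; within-group accuracy
is the false-positive guard) and the non-zero-labelled group (modality
present; within-group recall exposes the trivial always-absent predictor).
Because within-group truths are single-class, MCC / balanced accuracy / F1
are computed over rows whose label vector is not all-zero (the whole test
set for clean isolation data); `nonzero_mcc()` reports that per-modality
MCC and is the statistic quoted throughout.  One degenerate-metric policy
applies everywhere: an MCC whose denominator vanishes (single-class truth
or predictions) is reported as 0.0 with a `degenerate` flag.  Both
balanced accuracy and raw accuracy are reported side by side.

GMM clustering uses one full-covariance component per tumor type, with a
PCA reduction to 50 components first — patient aggregates are up to
`R × 768`-dimensional with only ~300 samples, where an ambient-space full
covariance would be singular.  Components are matched to labels by the
Hungarian assignment maximising agreement, making the aligned accuracy
invariant to label permutation and never worse than the majority-class
share.  PCA projections fix signs by making each component's
largest-magnitude loading positive.  Distance analyses report Euclidean as
a distance and cosine / dot product as similarities, over all non-self
pairs, summarised per tumor type as intra (same-type) vs inter
(cross-type) means and quartiles.

## Problem sizes

Defaults keep every experiment on one CPU: recogniser datasets of 5000
aggregates (15,000 per isolation dataset when reproducing the full
composite construction, whose merged size is exactly the sum of its
parts), 300-patient cohorts, 5-run protocols in the acceptance script
(30-run default in the library).  The workflow module derives per-stage
and per-run seeds from a master seed by hashing, records them in a JSON
manifest alongside a config hash and the emitted artifacts, and skips
completed stages on re-run.

## What the synthetic data does and does not show

The generator reproduces the *structural* conditions of the multimodal
aggregation problem: unaligned per-modality maps, heterogeneous
(probabilistic VAE vs deterministic semantic) embedding geometries,
realistic per-patient record multiplicities, zero-inflated composition
labels, and a tunable signal-to-noise knob.  It does not reproduce the
nonlinear manifold structure of real tumor data: all modality maps are
(near-)affine in the latent, so linear baselines are stronger here than on
real embeddings — the deep/baseline gap on the annotation modality at high
sample counts is therefore much smaller than with real data, and at high
sample counts the linear baseline can even lead.  Passing tests show the
pipeline's correctness and that signal survives aggregation under these
conditions; they do not certify effect sizes on real cohorts.  Other known
limitations: the annotation "semantic space" is a smooth map of the same
latent factor rather than genuinely discrete text structure; tiles are
low-resolution renderings, not histology; and subtype labels are
generator-assigned rather than biologically curated.
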