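# Methods

This note documents the models, the data protocol, the synthetic
benchmark, and the design decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A wound ROI is a rectangular crop containing a wound and some surrounding
skin, labelled with a wound class — diabetic (D), venous (V), arterial +
venous (A+V), pressure (P), surgical (S) — or one of two non-wound
classes, background (BG) and normal skin (N). Each ROI additionally
carries an anatomical location code from an enumerated body map. The task
is wound-class prediction from the image, from the location, or from
both. V and A+V index different dataset rosters and never co-occur in one
manifest.

## Body map

The location vocabulary is a registry of positive integer codes with
anatomical labels. The packaged original registry has 484 locations; a
merge map folds groups of neighbouring locations onto a canonical member
(e.g. 436–438 → 436 and 390–393 → 390), removing 161 codes and leaving a
simplified registry of 323. Only a handful of anatomical labels are
documented publicly; the packaged file carries those verbatim and
placeholder labels elsewhere — the registry's *structure* (counts, codes,
merge semantics) is exact, its anatomy text is data that a clinical
deployment would replace.

One-hot encoding: a registry of L codes encodes into vectors of length
L + 1 — ascending-code rank for positive codes, final slot for the
background sentinel −1. Encoding background inside the vector (rather
than as all-zeros) keeps BG a learnable location state, since background
ROIs flow through the same location branch as everything else.

## Data pipeline

* **Split.** 60/15/25 train/val/test. The test fraction is drawn first,
  per class (round(0.25·n) with half-up rounding), from un-augmented
  ROIs; validation is round(0.15·n); the remainder trains. Stratified by
  default (configurable to unstratified); deterministic under a seed.
  Classes with fewer than 3 originals cannot populate all splits and
  produce a warning.
* **Augmentation.** Exactly five copies per train/val ROI: horizontal
  flip, vertical flip, and 25°, 45°, 90° rotations. Flips and the 90°
  rotation are pixel-exact; oblique rotations keep the original canvas,
  interpolate bilinearly, and fill uncovered corners with pure black
  (0, 0, 0). Augmented records inherit class and location from their
  source; test ROIs are never augmented, and no view of a test ROI
  reaches training (source-index isolation).
* **Pairing.** Image and location are paired by the unique ROI index, not
  by list position, so record order cannot misalign modalities.

## Networks

All networks are built on a compact numpy layer engine inside the package
(dense, conv, max-pool, LSTM, dropout; Adam; fused softmax/cross-entropy
and sigmoid/BCE losses; backprop verified against central differences in
the test suite). Architecture summaries (`describe()`) expose layer kind,
width, activation, and trainability as data.

* **WIC.** Backbone + Dense(512, ReLU) ×3, dropout (default rate 0.5)
  after each, then the output layer. Backbones are randomly initialized
  re-implementations: VGG16/VGG19/AlexNet follow the original layer
  layouts (AlexNet with non-overlapping 2×2 pooling), ResNet50 follows
  the 3-4-6-3 bottleneck layout without batch normalisation, and the
  Inception-style backbone is a reduced three-block multi-branch stack
  ending in a 2048-wide global average pool. No pretrained weights are
  distributed; the four transfer backbones are frozen by default, AlexNet
  and the small `tinytest` stack (two conv blocks; trains on one CPU in
  minutes) are trainable.
* **WLC.** MLP: nine ReLU dense layers, widths 128×3, 256×3, 512×3.
  LSTM: four layers of 32, 32, 64, 64 units (ReLU activations, sigmoid
  gates) and a Dense(512). A single one-hot vector has no natural time
  axis; the default shaping feeds it as L+1 timesteps of width 1
  (`single_step` is available).
* **WMC.** The branches' terminal 512-wide representations are
  concatenated (width 1024) and passed through Dense(512), Dense(256),
  and the output layer. Whether the original design concatenated features
  or class scores is ambiguous; features are the default and
  `fusion='probabilities'` is provided for ablation. An `ohv_direct`
  variant concatenates the raw one-hot vector straight into the image
  head, bypassing any location stack.
* Heads everywhere: softmax of width K for K > 2, one sigmoid unit for
  K = 2. Argmax ties break toward the lowest class index.

## Training protocol

Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), batch size 25, 250 epochs by
default; sparse categorical cross-entropy or binary cross-entropy. Two
checkpoints are tracked throughout: best validation accuracy, and best
combined train/val accuracy — "combined" is implemented as the mean,
configurable to the min, since the combination rule is not otherwise
pinned down. Fitted estimators restore the best-validation weights, so
`predict` reflects the selected model. Training accuracy in the history
is accumulated over mini-batches with dropout active (as trained);
validation metrics come from a clean full pass per epoch.

**Fused training.** Training the WMC end to end from random
initialisation is unstable at small sample sizes: the convolutional
branch can memorise the training images before the location branch learns
anything, leaving test accuracy at unimodal level. The default protocol
therefore trains each branch on its own modality first, freezes the
branches inside the fused network, and trains the post-fusion layers on
the concatenated branch outputs (computed without dropout, since frozen
branches are deterministic at inference). `branch_pretraining=False`
restores end-to-end training.

**Binary positive class.** Unstated in the source experiments; the
convention here is the second-listed class of the experiment name, always
recorded in the report.

## Synthetic benchmark

The generator emulates the *structure* of a clinical wound dataset, not
its appearance. Images: a skin-toned noisy background with a
class-coloured, class-textured ellipse for wound classes; plain skin for
N; non-skin checker texture for BG. Locations: each wound class owns a
block of body-map codes; N draws from the union of wound supports
(mirroring the location overlap between normal skin and wounds in real
data); BG always carries −1.

Signal strengths are categorical mixtures, chosen so every Bayes-optimal
accuracy is exactly enumerable:

* `s_img`: with probability `s_img` an image renders its own class
  signature, otherwise a uniformly random class signature. (A pure
  amplitude attenuation of the signature was rejected: without an
  explicit noise model its Bayes accuracy is 1 for any strength > 0,
  so the knob would not control separability.)
* `s_loc`: a location is drawn from the class's signal distribution with
  probability `s_loc`, otherwise uniformly over all positive codes.
* `location_overlap` (β): fraction of each wound class's signal mass on
  *boundary* codes shared with the cyclically next wound class; the rest
  is uniform over its own core codes. β = 0 gives disjoint supports and
  per-modality Bayes accuracy s + (1−s)/K.

β matters for one structural reason: fusing two plain categorical votes
can never beat the more reliable vote (every conflict is won by the
channel with the larger likelihood ratio; at equal reliability conflicts
are exact ties). Overlap makes the location evidence *graded* — core
codes are near-certain, boundary codes are two-way ambiguous — which is
what gives the fused classifier a genuine target above both unimodal
ceilings. `bayes_reference` enumerates the image, location, and joint
ceilings for any configuration.

Default generator conditions: the six-class roster (BG, N, D, P, S, V),
60 originals per class, 64×64 images, `s_img` 0.8 > `s_loc` 0.6 (the
image modality is the more informative one, as observed on clinical
data), β 0.5, two core codes per wound class.

**Benchmark ("advantage") conditions** (`woundmm.studies`): four wound
classes (D, P, S, V), 100 originals per class, 32×32 images,
`s_img` = 2/3, `s_loc` = 0.98, β = 0.5 — per-modality Bayes ceilings
0.750/0.740 and a joint ceiling of 0.904. Classifiers use the `tinytest`
backbone and the MLP location branch, 40 epochs, a 60/15/25 holdout, and
3 seeds (2 for the ablation). These sizes were chosen so the full study
trains in a few minutes on one CPU while keeping the per-seed test set at
100 samples.

What passing the benchmark does and does not show: it certifies that the
implementation learns each modality to near its ceiling, that late fusion
exploits complementary signals, and that the advantage disappears when
index pairing is broken. It says nothing about absolute clinical
accuracy — real wound images are photometrically far harder than the
synthetic signatures, and clinical location distributions are not
mixtures with known supports.

## Numerical choices and degenerate inputs

* float32 weights and activations; He initialisation for ReLU layers,
  1/√fan-in scaling otherwise; LSTM forget-gate bias +1.
* Dropout is inverted (scaled at train time), identity at evaluation.
* Max-pool gradient mass is split evenly among tied maxima; odd spatial
  remainders are cropped.
* Precision/recall/F1 with zero denominators are defined as 0 and
  flagged (`MetricsReport.degenerate`) rather than raised.
* Non-finite loss aborts training with a diagnostic (`TrainingDiverged`).
* All stochastic steps (initialisation, shuffling, splits, dropout,
  generator) take explicit seeds; rebuilding from the same config and
  seed reproduces weights bit-for-bit.

## Known limitations

* Backbone implementations are structural stand-ins with random weights;
  transfer learning in the literal sense (pretrained features) is out of
  scope, which mainly matters for real-image experiments.
* The LSTM location branch over 324 timesteps is slow in pure Python/numpy;
  it is practical for small registries and provided for architectural
  completeness at full registry scale.
* Cross-validation re-augments each fold's training portion on disk;
  for large datasets this trades disk for correctness (no augmented view
  of any held-out ROI ever exists at training time).
* The synthetic generator's class signatures are trivially separable at
  `s_img` = 1 by design; it is a benchmark of the pipeline and fusion
  machinery, not of image representation learning.
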