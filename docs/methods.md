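# Methods

## Model and assumptions

The package treats slide-level HER2 prediction as multiple-instance learning:
a slide s_j is a bag of T_j tiles, only the bag carries a label, and the
slide call is a deterministic function of the per-tile positivity
probabilities p_ij emitted by a tile classifier. The cascade assumes that
(i) background can be separated from tissue by brightness alone, (ii) the
morphological signal correlated with HER2 status is visible at tile scale,
and (iii) a slide's status is recoverable from the *distribution* of its
tile probabilities — every aggregation feature (P1*, P1, P2, P3, F_h) is a
permutation- and duplication-invariant functional of that distribution.

## Stage parameters

| parameter | default | meaning |
|---|---|---|
| tile size | 512 px | square tile edge; the grid is row-major, 0-based, half-open intervals |
| stride | = tile size | "no stride" means non-overlapping; 256 px gives the overlapping grid used for 2048×1536 training images (35 tiles each) |
| gray threshold | 0.8 | tiles with mean Rec. 601 luma (scaled to [0,1]) strictly above this are dropped |
| G cutoff | 0.5 | tile counts as positive when p ≥ 0.5; ties go to the positive class everywhere |
| P2 cutoff | 0.66 | threshold on the masked mean (1/T)Σ p·G(p) |
| P3 cutoff | 0.35 | threshold on the super-threshold tile fraction |
| tabular layers | 500/250/125 | hidden sizes of the fully connected slide-level learner |

Partial tiles at the right/bottom border are discarded (no padding): the
grid count floor((W−s)/stride+1)·floor((H−s)/stride+1) is the only reading
consistent with 35 tiles per 2048×1536 image at 512/256. The 0.8 threshold
is interpreted on the [0,1] brightness scale; grayscale conversion uses the
Rec. 601 luma weights (0.299, 0.587, 0.114) and both are exposed as
configuration.

Two readings of P2 exist: the formula divides the masked sum by T (all
tiles), while a prose-style conditional mean would divide by the count of
super-threshold tiles. The formula reading is the default;
`FeatureConfig(p2_over_positive_tiles=True)` selects the conditional mean.
Similarly, the printed half-open bins [h, h+0.1) would silently lose tiles
with p exactly 1.0 from the top bin, so the default closes it at 1.0
(`top_bin_closed=False` restores strict half-open bins). With the closed top
bin, Σ_h F_h equals the fraction of tiles with p ≥ 0.5 — a property the test
suite asserts.

An empty probability vector (every tile filtered away) raises an error
naming the slide rather than fabricating a default prediction.

## Classifiers

Both tile classifiers and the tabular learner share one training engine: a
dense softmax network (ReLU hidden layers) optimized by mini-batch Adam with
cross-entropy loss under a one-cycle learning-rate schedule (linear ramp from
lr_max/10 to lr_max over the first 30% of steps, then linear anneal to
lr_max/100). Weight decay is 1e-4. All randomness — initialization and batch
shuffling — flows through one integer seed per model; inference is exactly
deterministic.

"Precision as loss" (Stage 3) and "accuracy as loss" (Stage 5B) are not
differentiable; they are implemented as per-epoch *monitored metrics*
recorded in the training history, while the optimized loss is always
cross-entropy. Two-phase fine-tuning trains the output layer alone for the
head epochs (hidden weights frozen) before unfreezing the whole network —
the analogue of fine-tune-last-layer-then-whole-network on a pretrained
backbone. With zero total epochs a classifier degrades to predicting the
empirical class prior, which keeps the pipeline runnable in smoke tests.

Tile features are the flattened pixels of the tile downsampled to 16×16×3
(the "small" backbone preset; an 8×8 "tiny" preset exists for the fastest
tests). The deep architectures used at paper scale (DenseNet-201 for the
cancer pre-filter, ResNet152 for the HER2 classifier) are recognized
configuration names but require an external deep-learning backend and
pretrained weights; selecting them raises with a clear message. Training
augmentation mirrors the standard family — flips, right-angle rotations,
zoom up to 1.1×, shear warp, luminosity and contrast jitter — applied only
to training tiles.

The cancer pre-filter keeps tiles with predicted cancer probability ≥ 0.5
(ties kept, consistent with the G convention); its training labels collapse
the four-class scheme normal/benign → "no cancer", in-situ/invasive
carcinoma → "cancer", and unknown label strings are rejected outright.

The tabular learner standardizes its features, trains for 200 epochs by
default (100 in the faster test settings), and thresholds its positive-class
probability at 0.5. Its default feature row is (P1*, F0.5…F0.9); adding the
binary indices is supported behind `include_binary_indices` but off by
default.

## Synthetic data: what it emulates and what it does not

The slide generator paints a non-overlapping tile grid: background cells at
a target brightness (default 0.95, safely above the 0.8 filter threshold),
tissue cells in an eosin-pink base color with dark elliptical blobs
(brightness ≈ 0.55–0.65, safely below), and — on positive slides — a planted
fraction of tissue cells whose color shifts toward blue-purple with a higher
blob density. Tissue and cue cells are placed by exact count through a
seeded permutation, so generated fractions are exact within rounding and a
given spec is bit-reproducible. The probability-bag generator draws tile
probabilities from Beta components with means 0.2 (negative) and 0.8
(positive-cue) at concentration 12; a positive slide mixes the two at the
positive-tile rate (default 0.6), a negative slide uses only the low
component.

These generators validate the *plumbing and the aggregation mathematics*:
that the filter thresholds act as specified, that a learnable tile cue
propagates through weak labelling to correct slide calls, and that both
aggregation strategies recover planted labels. They do not emulate stain
variability, scanner artifacts, tissue morphology, or the weak and spatially
heterogeneous correlation between morphology and HER2 status in real
H&E material — so passing tests demonstrate correctness of the method's
implementation, not clinical-grade performance on real slides.

## Problem sizes and numerical choices

The default desk-scale study conditions are: 200 probability bags of 50
tiles (balanced labels, split 100/100 for the tabular path), and an image
cohort of 24 training plus 12 held-out slides of 512×384 px with 64-px
tiles (8×6 grid, 60% tissue, 60% cue tiles in positive slides). At these
sizes the whole suite and the acceptance script each run in seconds to a
few minutes on one CPU core.

Threshold comparisons use ≥ exactly, with no floating-point tolerance: the
compared quantities are short means of well-scaled numbers, and the
acceptance-style boundary cases (p = 0.5, super-threshold fraction exactly
0.35, masked mean exactly 0.66 from a single-tile bag) are exact in binary
arithmetic as constructed in the tests.

## Known limitations

- The built-in trainer is CPU-bound and suitable for small inputs only;
  paper-scale backbones are out of scope by design.
- The cancer pre-filter and the HER2 classifier share one synthetic cue at
  desk scale, so the cancer_subset branch is exercised with oracle or
  cue-trained filters rather than an independently learned cancer concept.
- Output probabilities are not calibrated; the 0.5 decision threshold is a
  convention, not an optimized operating point.
- Real-WSI ingestion expects already-rasterized PNG/TIFF at the caller's
  chosen magnification; proprietary scanner formats and resolution
  pyramids beyond level selection are not handled.
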