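# Methods

## The problem

A full-thickness macular hole (FTMH) is a defect that disrupts every
neurosensory retinal layer at the fovea, from the internal limiting membrane
(ILM) down to the retinal pigment epithelium (RPE); it needs timely surgical
repair. An epiretinal membrane (ERM) is a contractile plaque on the retinal
surface that can distort foveal anatomy into hole-like shapes (pseudoholes,
lamellar defects) while leaving the retina intact, and is usually managed
conservatively. Distinguishing the two on optical coherence tomography (OCT)
B-scans is therefore a classification problem with a clinically asymmetric
cost, and labelled datasets are small (hundreds of eyes).

## Random Slice Contrastive Learning

RaSCL is a SimCLR-style self-supervised pre-training scheme for multi-slice
OCT volumes. Macular OCT protocols acquire parallel B-scans 121 or 243 µm
apart; neighbouring slices of one eye image nearly the same tissue, so they
are natural positive pairs that share anatomy without sharing pixels.

**Positive-pair sampling.** For each batch element an anchor B-scan is drawn
uniformly from an eye's training slices, and a partner is drawn uniformly
from the slices at signed offset `d`, `1 ≤ |d| ≤ D` (default `D = 2`). At
volume edges the offset support is clipped to in-bounds indices and the
uniform law renormalised over what remains (a rejection-and-resample
alternative is available as `boundary_mode: resample`). The offset
distribution is uniform over nonzero offsets, deliberately not a
zero-centred Gaussian: offset zero (the identical slice) is never a
positive. Each batch takes one pair from each of `N` eyes, eyes drawn
without replacement and at most one eye per patient, so every cross-pair
view is from an unrelated eye and acts as a negative.

**Objective.** Both views are augmented independently, encoded, projected,
L2-normalised, and scored with NT-Xent:

    ℓ(i,j) = −log [ exp(sim(zᵢ,zⱼ)/τ) / Σ_{k≠i} exp(sim(zᵢ,zₖ)/τ) ]

with cosine similarity and temperature `τ` (default 0.5), averaged over both
directions of all `N` pairs. The implementation computes the loss and its
analytic gradient in closed form; a brute-force double-loop oracle guards it
in the tests.

**Checkpoint selection.** The encoder is validated every `val_interval`
epochs (default 10) on held-out eyes. A contrastive model has no intrinsic
accuracy, so validation accuracy is defined as top-1 positive retrieval: the
fraction of validation views whose positive partner is their nearest
neighbour (cosine) within the batch. The transferred checkpoint minimises
`val_loss / val_accuracy`; records with zero retrieval accuracy are treated
as +∞, and ties resolve to the earliest epoch.

**Fine-tuning and ensembling.** The convolutional encoder is frozen; a
classifier head (the three-layer MLP trunk plus a fresh 2-way softmax layer)
is trained with binary cross-entropy on up to three B-scans per eye centred
on the fovea, under 8-fold cross-validation with the same selection
criterion per fold. The eight heads form an equal-weight ensemble: the FTMH
score of a scan is the arithmetic mean of member softmax scores, and a scan
is called FTMH iff score ≥ 0.5 (ties positive). The baseline comparator is
the same architecture with randomly initialised, frozen encoder weights and
the identical fine-tuning budget, so the comparison isolates the value of
pre-training; a `trainable` encoder mode implements the externally
initialised transfer-learning configuration.

## Architecture

The reference encoder is a standard-width ResNet-50 (2048-d pooled
features); the MLP is three fully connected layers of 512 nodes, the last
of which is the projection head during pre-training. Because the package
trains on one CPU core, it also ships `small_cnn`: four conv(3×3,
stride 2)–BatchNorm–ReLU blocks with channel widths `f/8, f/4, f/2, f`
followed by global average pooling (`f` = `feature_dim`, default 64;
accepts inputs down to 32×32). An optional `pool_grid: g` replaces global
pooling with averaging onto a g×g grid, keeping coarse location in the
feature vector — useful when studying how much of the pre-training
advantage stems from the pooled bottleneck (location-preserving features
make even a random frozen encoder strong on the phantom task). The batch
normalisation matters beyond
optimisation speed: without it the pooled post-ReLU features of a random
CNN share a dominant mean direction, all pairwise cosines sit near 1, and
NT-Xent is stuck at its chance value `log(2N−1)`. All training contracts
are architecture-agnostic; everything is implemented in a compact numpy
engine (`rascl.nn`) with im2col convolutions, analytic backpropagation and
Adam (lr 1e-3 pre-training / 1e-4 fine-tuning by default, no schedule).

Grayscale scans are replicated across the encoder's input channels.
Checkpoints are self-describing `.npz` archives (specs + weights + history,
including normalisation running statistics).

## Augmentation

Views are produced by a fixed chain — aspect-preserving random crop of
50–100% of the scan area resized to 224×224, horizontal flip (p = 0.5),
brightness delta in [−0.2, 0.2] and contrast scaling about the image mean
in [0.8, 1.2], then additive Gaussian noise with per-view `µ ∈ [−0.1, 0.15]`
and variance `σ² ∈ [0, 0.2]`, clipped to [0, 1]. Noise is applied last so it
acts at the model's input resolution, where B-scan noise lives. Vertical
flips and elastic deformations are excluded as anatomically invalid.
Evaluation never augments. In frozen-encoder fine-tuning, features for a
fixed set of augmented variants per slice (default 3, plus the clean view)
are pre-computed once per encoder — with frozen weights this is exact
computation reuse, not an approximation.

## Covariate-balanced splitting

Test sets are class-exact (default 10 FTMH + 40 control eyes, ≈15% of a
334-eye cohort), drawn in three pairwise-disjoint replicates, with both
eyes of a patient always on the same side. Each training set is split into
8 folds stratified primarily by diagnosis — a hard constraint keeps
per-fold class counts within ±1 of proportionality — and balanced on age,
sex (ordinal 0/1) and pre-operative vision by minimising

    Σ_folds Σ_features ( |mean_f − mean_all| + |sd_f − sd_all| ) / sd_all .

The optimiser is random-restart greedy pairwise swapping (default 50
restarts × 500 swaps) between patient groups of identical class
composition, which preserves the hard constraint by construction; the tests
require it to dominate the best of 100 random proportional assignments.

## The synthetic retinal phantom

Because the clinical dataset is private, the package generates layered
B-scan phantoms with exactly the structure the method exploits:

* four smooth per-eye boundary curves (ILM, inner/outer interface, RPE top
  and bottom) from low-order cosine families, a foveal pit, and wide
  per-eye jitter of band reflectivities and retina position, so class
  membership is not readable from global intensity statistics;
* within-eye coherence: from slice to slice the geometry drifts by a
  smooth random walk (vertical shift, tilt, lateral fovea shift), giving
  adjacent-slice correlations around 0.75 versus ≈0.5 between eyes;
* three lesion classes. FTMH: a contiguous foveal column band carrying only
  RPE and choroid — no neurosensory signal above the (intact, bright) RPE —
  shrinking on more peripheral slices. Control/ERM: a hyperreflective
  surface membrane of variable brightness and lateral extent over a pit
  ranging from traction-flattened to steep pseudoholes, and a faint
  membrane co-occurs with 40% of FTMH eyes, so membrane presence and pit
  depth are confounds rather than shortcuts. Lamellar (challenge class): the
  inner retina is excavated down to about the inner/outer interface with the
  outer layers and RPE intact, carrying ERM-like membranes (pseudoholes are
  membrane-defined and most lamellar holes show epiretinal proliferation);
  no membrane ever bridges an open defect;
* multiplicative log-normal speckle (OCT speckle is multiplicative) applied
  before the final clip to [0, 1];
* demographics per the emulated cohort: ages N(69.6, 6.4²) for FTMH and
  N(70.5, 8.6²) for ERM, a female-skewed FTMH group (46 F / 15 M), a
  generic continuous acuity score (worse for FTMH), and occasional
  two-eyed patients. Default class sizes are 61 FTMH / 273 ERM, with a
  34-eye lamellar challenge set.

A pixel-threshold oracle (`detect_full_thickness_defect`) classifies
noiseless phantoms perfectly by finding a run of columns whose first
supra-threshold pixel is already RPE-bright and far below the surrounding
surface; it guarantees the task is learnable and anchors the class
definitions. Volumes default to 7 slices so the ±2 offset range is
exercised without constant boundary clipping; training subsets (3 central
slices) are selected downstream.

What the phantoms do *not* model: A-scan physics, shadowing and motion
artifacts, vitreous traction bands, cystoid edema, device-specific noise,
or Gass staging. Passing the synthetic benchmark shows the pipeline's
machinery is correct and that contrastive pre-training extracts the
within-eye structure; it does not certify clinical performance.

## The desk-scale benchmark

`rascl.benchmark.DESK_BENCHMARK` (mirrored in `configs/desk_benchmark.yaml`)
is a scaled-down analogue of the clinical study: 120 eyes (20 FTMH,
100 ERM) of 7 slices at 64×64, a 20-eye lamellar challenge set, `small_cnn`
with a 3×128-node head, 100 pre-training epochs at 16 pairs per batch
(an epoch is one pass over the ≈250 training scans, about 8 batches),
frozen-encoder 8-fold fine-tuning (300 full-batch epochs, lr 1e-3, plain
unweighted cross-entropy — a `class_weight: balanced` option exists but
shifts the operating point toward calling borderline partial-thickness
defects positive), and three disjoint 5 FTMH + 20 control holdout
replicates. Augmentation intensity scales down with the
resolution (crops 80–100%, noise variance ≤ 0.01, brightness ±0.1,
contrast 0.9–1.1): the clinical ranges are calibrated to 224×224 views of
496×512 scans, and at 64×64 the full-strength noise makes two views of the
same eye mutually uninformative, stalling any contrastive learner at
chance. Library defaults keep the full-scale values throughout.

## Numerical and design notes

* All randomness flows from `numpy.random.Generator`; the pipeline fans a
  global seed out to stage seeds via `SeedSequence.spawn`, so runs are
  bit-reproducible for a fixed config + seed in single-threaded mode, and
  every stage directory carries a content hash making re-runs no-ops.
* TIFF round trips are lossless up to quantization (≤ 1/(2·(2^depth −1))
  per pixel); integer pixel types rescale by the dtype maximum; color pages
  are rejected rather than silently converted.
* Metrics are exact rationals on integer confusion counts; 0/0 ratios are
  reported as 0 with an explicit degenerate flag. ROC uses a threshold
  sweep with simultaneous inclusion of tied scores; the trapezoidal AUC
  equals the Mann-Whitney U statistic over n₊·n₋ (asserted to 1e-10 in
  tests). Replicate aggregation reports mean ± sample SD (ddof = 1).
* Saliency defaults to Grad-CAM on the activations entering the global
  average pool, bilinearly upsampled and max-normalised; plain
  input-gradient maps are available and are verified analytically against
  a linear model.
* Known limitations: the numpy engine is single-threaded CPU code — the
  ResNet-50 path is constructed and verified in the forward direction but
  is not a practical training target here; phantom realism is calibrated
  to what the method needs (coherence + separability), not to clinical
  appearance; the challenge class is out-of-distribution by design, so its
  accuracy depends on how far lamellar defects sit from the FTMH manifold.
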