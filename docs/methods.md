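# Methods

## The benchmark idea

Post-hoc attribution methods produce a heat map **s** over the input
pixels of a trained classifier. Validating them requires inputs for which
the *correct* explanation is known. `lesionbench` constructs such inputs:
a background brain slice B is overlaid with a few synthetic lesions L
whose shape class is the prediction target, so the set
F = {(i,j) : L_ij > 0} of lesion pixels is, by construction, the complete
set of class-informative pixels. Everything else in the image is
class-irrelevant — though not *prediction*-irrelevant: with the
multiplicative composite X = clip(B·(1+L), 0, 1), the appearance of a
lesion depends on the background beneath it, so background pixels can act
as suppressor variables that a model legitimately uses while a faithful
explanation should still not highlight them. This is the failure mode the
benchmark is designed to expose.

## Lesion generation

Candidates are carved from a 256×256 i.i.d. uniform noise image: Gaussian
smoothing (σ = 2 px, reflective boundaries), Otsu binarization, then
mathematical morphology with a 3×3 square structuring element — erosion
followed by opening for the round branch, one further erosion for the
elongated branch. Connected components (8-connectivity) that touch the
image border or cover fewer than 16 pixels are discarded; an optional
bounding-box cap (`max_extent`) restricts stamps to sizes that fit small
backgrounds.

Shape classes are defined by the isoperimetric ratio 4πA/p², which is 1
for a perfect disk: components above 0.8 are "regular", below 0.4
"irregular", the band in between is rejected so the classes are cleanly
separated. The perimeter p is a Crofton estimate (4 projection
directions). This choice is a calibration requirement, not a convenience:
with naive boundary-pixel counting, discretized disks systematically score
below 1 and thin lines score far too round. With the Crofton estimator,
disks of radius 5–30 score 0.88–0.98 and 1-pixel lines of length ≥ 20
score ≤ 0.17, so the bounds 0.8/0.4 act as intended (asserted in the test
suite).

Accepted components are padded with a 2-pixel zero margin, smoothed with a
Gaussian of σ = 0.75 px to taper the boundary, and rescaled so the peak
intensity equals the contrast parameter w (default 0.5, i.e. up to +50 %
local brightening). Note the taper means F contains a faint halo around
each lesion core; |F| is therefore larger than the core area, which
depresses attainable EP values for all methods equally.

### Otsu implementation

For images with ≤ 256 distinct values the threshold is found by exact
maximization of the between-class variance over every cut of the value
histogram. The common 256-bin histogram approximation (used for
continuous images) can misassign values that fall in the right half of the
threshold bin; the exact path makes the generator agree with an exhaustive
search oracle, which the tests assert.

## Backgrounds

Real 2-D axial T1 slices can be supplied as PNG or NIfTI; slices with
≥ 55 % black pixels are discarded, geometry is standardized to 270×270
(symmetric zero-padding of rows, extra row to the top; symmetric column
crop, extra column dropped from the right) and intensities are linearly
rescaled so the maximum is 0.7 — leaving headroom so lesion brightening
stays within [0, 1].

Because suitable MRI corpora are access-restricted, the default source is
a seeded brain phantom: an ellipse (semi-axes 0.80–0.88 × and 0.74–0.82 ×
the half-size, which guarantees the black fraction stays below 55 %)
filled with tissue intensity 0.42 + 0.12·texture, a brighter cortical rim,
and 1–2 darker ventricle-like blobs, rescaled to a 0.7 maximum. The
texture is smoothed noise with correlation length ≈ size/10 — deliberately
much coarser than lesion scale, because tissue texture at lesion scale
would make lesions statistically indistinguishable from background, which
is neither realistic (white matter is fairly homogeneous at these scales)
nor useful for a benchmark. The phantom emulates only the properties the
pipeline consumes: value range, black exterior, one contiguous brain
region, sub-55 % black fraction and a per-subject seed for split
bookkeeping. It does not model MRI acquisition, anatomy beyond the above,
or intra-subject slice geometry, so conclusions about real scanner data
require real slices.

## Compositing and datasets

Each sample draws its background uniformly at random from the cohort, a
lesion count uniform on {3, 4, 5}, and stamps (with replacement) from the
class's bank; positions are rejection-sampled until the stamp's whole
support lies inside the brain mask and touches no earlier lesion (cap:
1000 proposals per lesion, then the sample retries on a fresh background).
Labels alternate sample-by-sample, so class balance is exact. Drawing the
background independently of the label matters: any systematic
background–label pairing lets a classifier read the label off background
identity, which silently invalidates the benchmark (the alternative
assignment schemes we tried during development did exactly that).

Splits are by subject — all samples of a subject share a split — with
fractions 60/20/20 and a stratified greedy assignment (most class-
imbalanced subjects placed first, seeded reshuffles) that keeps per-split
class imbalance within one sample. Dataset directories store images and
masks as 16-bit PNG with a CSV manifest, a JSON config snapshot, and
SHA-256 checksums verified on read.

## The EP metric

EP is the precision of the n = |F| top-scoring pixels against F. Exactly
n pixels are selected, so precision equals recall, and the score is
invariant under any strictly increasing transform of the heat map — in
particular under the rendering transform −log(1−s(1−1/b))/log b (b = 0.5),
which is therefore never applied before scoring. A uniformly random map
scores |F|/N in expectation (hypergeometric mean, N = total pixels). Ties
between equal scores are broken deterministically in row-major order;
a seeded random tie-break is available to probe tie sensitivity for
sparse maps. Batch evaluation flags each sample's classification
correctness and reports both the all-samples view and the intersection of
samples correctly classified by every model, since headline comparisons
are only meaningful on inputs the models actually got right.

## Classifier harness

The demonstrator is a five-block CNN for 64×64 inputs: per block one 3×3
convolution (8, 16, 32, 32, 32 channels), batch normalization, ReLU and a
2×2 max-pool; a linear 2-class head on the flattened 2×2×32 features.
Five blocks (not four) so that the five fine-tuning degrees
1conv < 2conv < 3conv < 4conv < all have strictly increasing trainable
parameter counts. Degree `kconv` unfreezes blocks 1..k from the input
side; the head is always trainable, since a task head cannot be inherited
from pre-training. A frozen block's batch-norm also stops updating its
batch statistics, so frozen behaviour is bit-stable.

Two architectural elements exist to make from-scratch training reliable
under the fixed schedule (SGD, lr 0.02, momentum 0.5, ×0.9 every 5 epochs,
batch 32, cross-entropy, ≤ 30 epochs, best-validation weights kept):

- a fixed, parameter-free input layer that subtracts a Gaussian blur
  (σ = 3 px) and standardizes each image — the smooth background carries
  most of the pixel variance but no class signal, and removing it lets a
  small network find lesion-scale features within the epoch budget. The
  layer participates in backpropagation, so input-gradient saliency maps
  are taken with respect to the raw image;
- per-convolution batch normalization, without which training under the
  momentum-0.5 schedule is erratic (best validation accuracy varied by
  more than 20 percentage points across seeds in development).

On the reference conditions — 1,000 samples, 50 phantom subjects, lesion
banks of 30 + 30 stamps with `max_extent` 16, w = 0.5 — this model reaches
validation accuracy above 0.90 (0.93–0.96 across the seeds we ran), and
the median EP of its saliency maps on correctly classified test samples
exceeds the untrained-model saliency median and both edge-detector
medians. Those conditions, and the assertions, live in
`tests/test_acceptance.py`.

Gradient saliency (|∂ score of predicted class / ∂ input|, then absolute
value and peak normalization) is the one natively implemented attribution
method; other methods plug in through `attribution_adapter`, which
supplies the all-zeros baseline image to methods that need a reference
point and normalizes their output identically.

## Numerical and design notes

- All randomness flows through `numpy.random.SeedSequence`; identical
  seeds and configs give bit-identical banks, phantoms, datasets and
  training histories (single-threaded).
- "Radius" of the pipeline's Gaussian filters is interpreted as the
  standard deviation in pixels; smoothing uses reflective boundaries.
- The learning-rate reduction "by 10 % every 5 epochs" is implemented as
  multiplication by 0.9 (compounding), i.e. lr(e) = 0.02·0.9^⌊e/5⌋.
- The additive overlay X = clip(B + L, 0, 1) is available as a sensitivity
  variant; the multiplicative rule is the default because it preserves the
  suppressor-variable property (lesions vanish on black background).
- Degenerate inputs (constant images for Otsu, all-zero images for
  rescaling or masking, empty ground truth) raise typed errors rather
  than returning conventional values.

## Known limitations

- The phantom is a stand-in for real slices; results transfer to real MRI
  backgrounds only qualitatively. Real slices can be dropped in through
  `load_slice`/`filter_slices`/`standardize_geometry`/`rescale_intensity`.
- The harness demonstrates the pipeline at desk scale; it is not a VGG-16
  replication, and pre-training corpora (natural images, auxiliary MRI
  tasks) are out of scope — externally trained weights can be loaded into
  any config expressible by `ClassifierConfig`.
- EP depends on |F|, which includes the smoothing halo; absolute EP values
  are therefore comparable within this benchmark but not across benchmarks
  with different ground-truth conventions.
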