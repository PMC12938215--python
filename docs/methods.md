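# Methods

## Problem and scope

During endobronchial ultrasound (EBUS), bronchoscopists localize
mediastinal and hilar lymph-node stations (IASLC numbering; here the eight
classes 4L, 4R, 7L, 7R, 10L, 10R, 11L, 11R, with station 7 split by side of
the carina) from grayscale sector-scan B-mode images. A convolutional
classifier can predict the station, but clinical trust requires knowing
*where* the model looks. This package implements a quantitative audit of
that question: Grad-CAM saliency on the classifier's last convolutional
layer is reduced to a 7×7 grid, the high-activation region is labeled
against the anatomy it covers (lymph node/vessel, other structure,
artifact, or not interpretable), labels from several raters are merged by
majority rule, inter-rater agreement is quantified with kappa statistics,
and classification metrics are stratified by the consensus attention
category.

Because clinical EBUS recordings are not redistributable, the package
ships a synthetic phantom generator whose frames carry pixel-exact
ground-truth masks. The masks make a deterministic "oracle" annotator
possible, which in turn lets every statistic in the audit be exercised and
tested end to end without human raters.

## Phantom model

Each frame is a fan-shaped sector with the transducer apex at the
top-center (row 0 is proximal, matching conventional B-mode display).
Content is synthesized in sector coordinates (radius fraction, azimuth
fraction of the half-width):

* **Background and speckle.** A smooth echogenicity map with mild
  depth-dependent attenuation is multiplied by a gamma-distributed
  multiplicative field (shape 1/noise_scale², mean 1, lightly smoothed) —
  the standard first-order appearance model of fully developed speckle.
  No wave propagation is simulated.
* **Lymph nodes** are hypoechoic ellipses (echogenicity ×0.35), with
  station-specific priors on radial depth, azimuth, count and size.
* **Vessels** are anechoic discs (×0.05) at station-specific positions.
* **Other structure** is a bright near-field tissue band (×1.9).
* **Artifacts** are either an acoustic-shadow wedge distal to a node
  (×0.18) or periodic reverberation arcs (additive, geometrically
  decaying), drawn with probability `artifact_prob`.

Every structure is rasterized analytically, so the four per-category masks
are exact. A per-frame quality score is drawn from
`quality_score_range`; frames below the interpretability floor (0.3) are
blurred (σ = 2.5 px) and contrast-compressed, giving the annotation oracle
a deterministic trigger for "not interpretable".

The eight station templates differ in azimuth sign (left/right pairs
mirror each other), node depth band, node multiplicity and vessel
placement — a deliberately cartoonish but learnable encoding of the
anatomical landmarks that distinguish real stations. Separability is
guarded by a test: a nearest-centroid classifier on mean radial intensity
profiles must beat chance for at least two stations.

What the phantoms do **not** model: acoustic physics, vendor
post-processing, respiratory/cardiac motion, needle artifacts, genuine
anatomical variability between patients, or the correlation structure of
real speckle. Passing tests therefore demonstrate that the *audit
machinery* is correct and that the classifier can learn the synthetic
station geometry — not that any model reaches clinical accuracy on real
EBUS data.

## Classifier

The training harness mirrors the reference recipe: categorical
cross-entropy, AdamW, batch size 32, dropout 0.5 on the globally averaged
features, early stopping on validation loss with a patience window, and
the checkpoint with the minimum validation loss retained (ties broken by
the earliest epoch). Splitting is patient-wise: patients are shuffled with
the split seed and allotted to train/validation/test by largest remainder
on the 70/20/10 fractions, with every non-empty partition guaranteed at
least one patient; no patient contributes frames to two partitions.

Two backbones satisfy the model contract (class probabilities over a fixed
class order, plus the post-ReLU feature map of a designated convolutional
layer and the analytic gradient of any pre-softmax class score with
respect to it):

* **small** (default at desk scale): a compact trainable convnet — three
  strided conv+BatchNorm+ReLU blocks (16/32/64 channels) taking 56×56
  input to an exactly 7×7 feature map, then global average pooling,
  dropout and a dense softmax over 8 units. Implemented directly in numpy
  (im2col convolutions with hand-derived backprop, verified against
  central finite differences to ~1e-8 relative).
* **frozen**: the same architecture with fixed random convolutional
  filters; only the head trains. This preserves the frozen-feature-extractor
  training pattern without a pretrained-weights dependency.

Inputs are min-max normalized to [0, 1] and bilinearly resized to 56×56;
the first layer centers them at zero. Training uses learning rate 1e-2
with cosine decay to a tenth (the reference recipe's 1e-4 belongs to a
frozen large-backbone transfer setting; a from-scratch convnet given only
~180 optimizer steps at desk scale needs the larger, decaying rate, and
batch normalization to keep those few steps stable). The per-epoch history
records loss and accuracy for train and validation; the precision/recall
columns are micro-averaged, which for single-label multiclass prediction
coincide with accuracy.

Augmentation applies five transforms independently, each with probability
0.5: gamma in [0.7, 1.5], Gaussian blur σ in [0, 1.5] px, rotation in
[−15°, +15°], contrast scaling in [0.8, 1.2] about the mean, and one
multiplicative Gaussian-profile shadow band of depth 0.3–0.7. Outputs are
clamped to [0, 1]. All magnitudes are package defaults and overridable.

## Grad-CAM and the 7×7 grid

For a target class c (the predicted class unless overridden), channel
weights are α_k = mean_{ij} ∂s_c/∂F_{kij}, where s_c is the pre-softmax
score and F the designated layer's feature map; the map is
CAM = ReLU(Σ_k α_k F_k). Because the head is linear in the globally
averaged features, the gradient is exact: ∂s_c/∂F_{kij} = W_{ck}/(H·W).
If the native layer is not 7×7 the rectified map is bilinearly resampled
first; it is then divided by its maximum so the top cell is exactly 1.0.
An all-nonpositive map is flagged *degenerate* and never normalized
(division by zero cannot occur); degenerate grids produce empty regions
that downstream stages route to "not interpretable" and exclude from
frequency maps (reported as a separate count, so tallies stay
interpretable).

The activation region is the set of cells with value ≥ threshold
(inclusive; default 0.9), treated as one collective region regardless of
contiguity. The max-intensity cell breaks ties by the smallest row-major
index — documented because the frequency maps depend on it. The 0.9
threshold is applied to grid-cell values (annotation operates on grid
squares), and normalization guarantees at least one qualifying cell in
every non-degenerate grid.

Max-cell positions are tallied into per-station and overall 7×7 frequency
maps (columns = probe left–right, rows = proximal–distal). Spatial
concentration is rendered, not statistically tested.

## Annotation, consensus, agreement

The oracle annotator decides deterministically: quality below the floor or
an empty region → not interpretable; else if ≥ 25% of at least one region
cell's pixel footprint lies inside the lymph-node or vessel mask → lymph
node/vessel; else the same rule against the artifact mask → artifact;
else → other structure. The 25% fraction and the precedence (anatomy over
artifact over background) are numeric proxies for the human judgement
"the region overlaps a clinically meaningful structure"; both are
configurable. Simulated raters return the oracle label with probability
1 − p and otherwise draw from a confusion kernel (default: uniform over
the three other labels); p defaults to 0.15.

Consensus over exactly three raters: unanimous → *complete*; a label
shared by two → *majority* (that label is final); all distinct →
*disagreement*, pending until an adjudication table resolves it (the
pipeline adjudicates with the oracle label, standing in for a consensus
meeting). Agreement statistics are computed exclusively from the
independent pre-consensus labels: percent agreement (share of items with
all raters identical), pairwise Cohen's κ (chance from the product of the
two raters' marginals) and Fleiss' κ (chance from squared pooled category
proportions), all over the fixed 4-category space even when categories go
unobserved. With two raters both Cohen's and Fleiss' constructions are
reported; they differ by chance model and are not conflated. κ is
undefined when chance agreement is 1; that case is flagged (NaN) rather
than fabricated, except Cohen's with perfect observed agreement, which
returns 1. Interpretation uses the Landis–Koch bands (<0 poor, 0–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect). Kappas are reported to three decimals,
percentages to one.

## Evaluation

The confusion matrix (rows = true station, columns = predicted) yields
per-class precision, sensitivity and F1 in percent with supports;
zero-denominator cases return 0 and are flagged. Macro averages weight
stations equally; weighted averages use supports, so weighted sensitivity
equals overall accuracy exactly (micro identity — asserted as an
invariant). Metrics are kept at full precision and rounded half away from
zero to one decimal only at report time. Stratified metrics partition the
test images by final consensus label and aggregate macro-style over the
stations present within each stratum (a weighted switch is provided; the
choice is configurable because the reference analysis does not state it).

## Pipeline and reproducibility

`run_pipeline` chains generate → split → train → explain → annotate →
consensus → agree → evaluate, writing CSV/JSON artifacts per stage plus a
combined JSON (and HTML) report. A single global seed fans out to named
per-stage seeds via independent `SeedSequence` children (each < 2³¹,
logged), so any stage can be re-run in isolation and the whole report is
byte-reproducible from (config, seed). Stage failures abort with the stage
name; artifacts already written remain.

Desk-scale study conditions used by the tests and the acceptance script:
10 patients × 40 frames at 64 px (70/20/10 patient-wise split → 280/80/40
frames), the small trainable backbone, 20 epochs. The "easy" phantom
preset for these runs fixes quality in [0.5, 1.0] (all frames above the
interpretability floor), artifact probability 0.15 and node-size jitter
0.15 — well-separated conditions under which the audit's properties
(learnability above chance, region non-emptiness, count conservation,
agreement behavior under rater noise) are meaningful to assert.

## Numerical choices and edge cases

* Validation-loss ties: earliest epoch wins (reproducibility).
* Grid threshold comparisons are inclusive (≥).
* Max-cell ties: smallest row-major index.
* Empty test/val partitions are prevented by the split's minimum-one-patient
  rule; an empty train partition is an error.
* Rounding: half away from zero, one decimal for percentages, three for
  kappas; serialized reports sort keys so identical runs are byte-identical.
* The 8-bit PNG round trip quantizes images to 1/255; masks are exact.

## Known limitations

* The phantom's realism limits are listed above; in particular the
  "other structure" and "artifact" strata can be small or absent in easy
  configurations, exactly as underrepresented categories were in the
  reference analysis.
* The numpy network is single-threaded and desk-scale by design; it is not
  a general deep-learning framework, and the frozen backbone uses random
  (not pretrained) filters.
* Kappa confidence intervals, weighted kappa and Krippendorff's alpha are
  out of scope; point estimates only.
* Grad-CAM variants (Grad-CAM++, multi-layer aggregation) are not
  implemented.
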