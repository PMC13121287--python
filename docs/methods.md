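# Methods

## The pipeline

`cacvit` quantifies coronary artery calcium in non-contrast chest CT in
three stages. A vision transformer pre-trained by self-distillation embeds
each slice; a linear probe on the frozen embeddings flags slices likely to
contain calcification; a U-Net segments only the flagged slices into
background plus the four coronary arteries (RCA, LAD, LCA, LCX); and the
segmented lesions are Agatston-scored from raw Hounsfield units. The
filtering stage exists because calcifications appear in roughly one slice
in ten — segmenting everything wastes computation and multiplies false
positives, while misses at this stage are the clinically expensive error,
which is why the slice classifier is trained with a 9:1 class weighting at
10% prevalence.

## Self-distillation with label guidance

Pre-training follows the student/teacher self-distillation scheme: for each
slice a multi-crop set is built (2 global views, several small local
views), the teacher — an exponential moving average of the student — sees
only the global views, and the student is trained so its output
distribution over K prototypes matches the teacher's sharpened, centered
distribution for every (teacher view, student view) pair except a view
with itself. Collapse is prevented by centering the teacher logits with a
running mean (momentum 0.9) and sharpening with a teacher temperature
warmed from 0.04 to 0.07 while the student stays at 0.1. The projection
head is a 3-layer MLP to an L2-normalized bottleneck followed by a
weight-normalized, bias-free map onto unit-norm prototype vectors, so the
logits are cosine similarities in [−1, 1] — the scale those temperatures
are designed for. Without unit-norm prototypes the logit spread is a small
fraction of that range, sharpening does nothing, and training collapses to
the uniform distribution; this was observed directly during development.

*Label guidance* is the one addition: for slices with annotations, four
extra guided local crops are generated whose anchor pixel is drawn
uniformly from the lesion mask, in addition to the eight random local
crops every slice receives (twelve local views for labeled slices, eight
otherwise). A guided crop is a square of area uniform in 5–40% of the
image, centered on its anchor and clamped to the image bounds; the anchor
is always inside the crop (a property the suite checks over 10⁴ draws).
Because local views are student-only, guidance creates training terms in
which the student must predict the teacher's whole-slice representation
from a lesion-centered patch, pushing the representation to encode the
calcified region.

Photometric augmentation is the medical variant of the standard recipe:
horizontal/vertical flips (p = 0.5 each), 3×3 Gaussian blur, brightness and
contrast jitter within ±40% in a [0, 1] working range, sharpness factor 1.5
with p = 0.8, and additive Gaussian noise (σ = 1% of the dynamic range,
p = 0.5). Solarization and hue/saturation jitter are RGB-specific and never
applied. Blur and noise probabilities are not pinned down by the recipe we
follow; the defaults above are exposed in `AugmentParams`.

Slices are normalized per slice before entering the network: shift by the
1024 HU soft-tissue reference, min–max normalize with ε = 10⁻⁷ in the
denominator, scale to [−1, 1]. The shift cancels under min–max and is kept
for fidelity to the preprocessing definition; a constant slice is defined
to map to all −1. Raw HU is retained alongside every normalized slice
because Agatston scoring must never see normalized values.

## Agatston scoring

A lesion is an in-plane 8-connected component of segmented pixels with
attenuation ≥130 HU; components under 1 mm² are discarded. Each lesion
contributes area (mm²) times a density weight from its peak HU (1: 130–199,
2: 200–299, 3: 300–399, 4: ≥400), and totals map to risk categories 0–10 /
11–100 / 101–400 / >400. Two deliberate choices: lesions are per-slice (the
score is a flat per-lesion sum; no through-plane merging), and the classic
3 mm slice normalization factor is *not* applied — the implemented formula
is exactly Σ AᵢDᵢ with A in mm². Fractional scores at a bin boundary
resolve downward (10.5 → moderate is the only non-integer case the
convention affects: low if ≤10). The ≥130 HU mask is intersected with the
segmentation rather than applied before it.

## The phantom generator

Every stage is exercised on synthetic chest-CT phantoms: an air background,
a soft-tissue body ellipse (20–60 HU, clipped below 126 HU), bone-density
ribs (700–1200 HU) on a ring inside the body boundary, and a central heart
region in which lesions are planted. Rib geometry is fixed per patient with
small per-slice jitter, mirroring how anatomy persists across slices of a
real scan. Lesions are compact blobs assigned to one artery each, anchored
in fixed heart quadrants so per-artery metrics are meaningful; lesion HU is
drawn uniformly inside the target density bin with small clipped noise so
the peak-HU bin is unambiguous.

Defaults emulate the summary statistics of real calcium-scoring
collections: ~10% positive slices, mean lesion area 119 px at 512² scaled
by (size/512)² (≈2 px at the 64² desk default), four density bins with
weights (0.35, 0.30, 0.20, 0.15), 3 mm slices, and a pixel spacing that
preserves the 512 × 0.49 mm field of view. The lesion-size distribution is
not pinned by those statistics; we use 1 + Poisson(mean − 1), which meets
the configured mean exactly and keeps a one-pixel minimum. Ground truth
(per-lesion area, peak HU, weight; per-patient score and risk) is computed
by construction-time bookkeeping completely independent of the scoring
module, and the suite checks the scorer reproduces it to 10⁻⁹ on 100
seeded phantoms. Cohorts can be generated to hit an exact risk-category
mix (lesion budgets are solved per patient to land in the target score
range), and splits are stratified by risk with largest-remainder rounding.

What the phantom does **not** emulate: cardiac anatomy, motion or
beam-hardening artifacts, contrast enhancement, scanner noise spectra, and
non-gated acquisition differences. Passing tests therefore demonstrate
correctness of the pipeline's mechanics and arithmetic on CT-like data,
not clinical performance.

## Desk-scale profile and its calibration

All training runs on a NumPy reverse-mode autodiff core written for this
package (`cacvit.nn`): tensors wrap arrays, a tape records operations, and
Adam/AdamW with cosine schedules drive the updates. Analytic gradients for
every operation are verified against central differences in the suite.
This makes CPU cost the binding constraint, and the shipped desk profile
is sized accordingly — the full-scale profile (ViT-B/8, 768-dim embeddings,
224² global / 96² local views, 150 epochs, U-Net with 64 initial filters at
512²) uses the same code path and is the default `PipelineConfig`.

Desk profile: 64² phantoms; ViT with patch 8, embed 64, depth 3, 4 heads;
32² global and 16² local views; 64 prototypes (bottleneck 32); 15 epochs,
batch 16, AdamW lr 5·10⁻³, weight decay 0.04, gradient-norm clip 3.0; EMA
momentum on a cosine schedule 0.98 → 0.9995. The momentum deviates from
the classic 0.996 → 1.0 deliberately: that schedule assumes ~10⁵ steps,
and at the ~10² steps of a desk run the teacher would never leave its
initialization. Feature extraction feeds slices at native resolution
(positional embeddings are bilinearly interpolated between patch grids),
matching full-scale practice where whole slices, not training crops, are
embedded. The desk U-Net uses 8 initial filters and depth 2.

The desk comparison experiment (`cacvit reproduce-desk`, also an
acceptance test) trains the backbone twice on one 32-patient phantom
cohort — once with guided crops, once standard — probes both feature sets
with the linear classifier on training patients, and compares
calcified-slice detection on held-out patients over seeds 1–3. The probe
uses lr 10⁻² instead of the full-scale 10⁻⁴, which is calibrated for
768-dim features and thousands of slices; at 64 dims and ~200 slices the
50-step optimization would otherwise never leave initialization.

**Known limitation.** At this scale the experiment is directionally
consistent but degenerate: lesions occupy ~2 px, the tiny backbone's
embeddings separate calcified slices only weakly (probe AUC ≈ 0.6), and
the 9:1-weighted probe then maximizes its objective by flagging every
slice — both models sit at sensitivity 1.0 / specificity 0.0, so the
guided-vs-standard sensitivity comparison holds as a tie. A supervised
end-to-end upper bound under identical conditions reaches only ≈0.65 test
AUC, locating the limitation in desk-scale information content rather than
the self-distillation implementation. The full per-seed confusion matrices
and McNemar's test are emitted by `reproduce-desk` rather than a single
headline number. Separating the two training modes measurably requires
larger slices, larger backbones and orders of magnitude more steps than a
CPU run affords.

## Numerical and degenerate-case conventions

- Constant normalized slice → all −1; constant input to the PCA feature
  map → all-zero map (tokens then differ only through positional
  embeddings, which carry no image information).
- Argmax ties in segmentation resolve to the lowest class index; max-pool
  gradient ties route to the first maximum.
- Metrics with zero denominators are NaN internally and "n/a" in reports,
  never 0; a class absent from both masks is excluded from IoU/Dice
  averages; foreground Dice against an all-background reference is
  undefined.
- McNemar's test uses the exact binomial form below 25 discordant pairs
  and the continuity-corrected chi-square above; zero discordance returns
  p = 1 with a degenerate flag.
- The classifier's decision threshold is ≥ (probability exactly at the
  threshold counts positive); the reported best epoch is the
  highest-validation-F1 epoch, whose weights are restored.
- DICOM series are sorted by z position with instance number as
  tie-break; mixed-orientation series and missing spacing are hard errors.
- Annotation masks are a single integer-label volume (0 background,
  1–4 = RCA/LAD/LCA/LCX).
- All randomness flows through seeded `numpy.random.Generator` instances;
  training is bit-reproducible on one machine.

Reporting rounds to two decimals only at the reporting layer; internal
computation stays at full precision.
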