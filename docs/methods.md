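# Methods

`renalscint` implements a complete acquisition-time-reduction workflow for
pediatric ^99m^Tc-DMSA posterior planar imaging: a synthetic dynamic
phantom, rigid frame registration, short-time/full-time pair construction,
three residual denoising CNNs, image-quality metrics, and renal-uptake
quantification with agreement analysis.  This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## The problem being modelled

A routine study acquires ten 1-minute posterior frames two hours after
injection; the ten-frame composite ("full-time", 10 min) is used to read
cortical defects and to quantify per-kidney uptake.  Motion argues for
shorter acquisitions, but a 2-minute composite ("short-time", the sum of
two frames) carries roughly five-fold fewer counts and proportionally more
Poisson noise.  The workflow trains CNNs to predict the full-time image
from a short-time image, then asks two questions: how close is the
prediction by NMSE/PSNR/SSIM, and does quantitative uptake survive.

## Synthetic phantom

Clinical images are not distributable, so every stage runs against a
seeded phantom: two elliptical kidneys over a low-count elliptical body on
a zero background, piecewise-constant expected counts, independent Poisson
draws per pixel per frame.

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| image size | 64 x 64 px | CPU-feasible training; 256 x 256 available by config |
| pixel size | 5.4 mm | keeps the 64-px field of view at the clinical 256 x 1.35 mm extent |
| frames | 10 x 60 s | the clinical dynamic protocol |
| kidney mean | 21 counts/px/frame | 10-frame kidney sum ~210 counts/px, the clinical average count level; maxima in the phantom sit near the clinical ~390 only when geometry overlaps are added, which we do not model |
| background mean | 2 counts/px/frame | low-count soft-tissue background, ~10% of kidney level |
| uptake fractions | drawn U(0.14, 0.28) per kidney per case | brackets the clinical mean uptake of ~21% |

**Consistency model.**  Counts equal activity directly (no camera
sensitivity constant), so per-kidney uptake is
`(kidney counts − area-scaled background counts) / D` on the noiseless
full-time image.  One dose count `D` cannot generally satisfy two
independently chosen kidney means *and* two uptake fractions, so the spec
is closed in one of two ways: with `total_dose_counts=None` (default) `D`
is derived from kidney 0's mean and fraction and the other kidney's mean
is solved from its fraction (all requested fractions are realised
exactly); with an explicit `D` the means are honoured and the *realised*
fractions are stored as ground truth.

**Rasterization.**  A pixel belongs to an ellipse iff its centre (integer
row/col, origin at the corner) lies inside.  **Motion** is applied to the
noiseless map before the Poisson draw — the patient moves, not the noise.

What the phantom deliberately omits: renal cortex structure and defects,
scatter, septal penetration, depth-dependent collimator blur, and
attenuation (hence `k = 1` is the correct coefficient for phantom uptake).
Passing tests therefore demonstrate the pipeline's arithmetic and
statistical behaviour at clinical count levels, not clinical image realism.

## Rigid registration

Each frame is registered to the first frame under rotation + translation +
isotropic scale, minimising the MSE between mean-normalised images.  The
transform maps source to target coordinates, rotation about the image
centre; resampling is bilinear with zero fill.  Optimisation is Adam on
(rotation rad, translation / half-image-size, log scale) with step 0.01
for 100 iterations, single resolution, no regularisation.  Gradients are
analytic: sampled image gradients chained through the inverse coordinate
map.  The reported trace is the running-best MSE, and the best-so-far
transform is returned, so the final MSE never exceeds the identity
initialisation even though raw Adam iterates oscillate.  All-zero images
short-circuit to the identity transform with a warning (zero gradient
everywhere).  Recovery accuracy at phantom noise levels: 50/50 seeded
trials within 0.5 px / 1 deg / 2% for |t| <= 5 px, |rot| <= 5 deg,
scale in [0.95, 1.05].

## Dataset and standardization

All C(10, 2) = 45 two-frame subsets per case, each paired with the shared
ten-frame target; sums are exact integer additions.  Splits are by case
(seeded random; the clinical study split by acquisition date, which
synthetic data has no analogue of), sized by rounded fractions with the
remainder absorbed into training — 155 cases at 109/23/23 reproduce the
clinical design and its 4 905 training subsets.

Standardization is per-image to zero mean / unit population sd.  The
*input* image's parameters standardize both members of a pair, and
predictions are inverse-standardized with the input's parameters: this
makes the ~5x count amplification between short- and full-time images a
learnable, exactly invertible map, and gives count-scale outputs for the
uptake analysis.  (Whether the original work standardized per image or
per dataset is not stated; per-image-by-input is the choice here.)

## Architectures

All three map one standardized channel to one, same spatial shape,
zero-padded convolutions, Kaiming fan-in initialisation, seeded.

* **DnCNN**: Conv3x3+ReLU, 15 x (Conv3x3+BN+ReLU), Conv3x3 — 17
  convolutions; output = input − predicted residual.  The canonical
  residual direction is used; the sign is configurable.
* **Win5RB**: 4 x (Conv7x7+BN+ReLU) + Conv7x7+BN with an input→output
  skip — 5 convolutions, 31 x 31 receptive field.
* **ResUnet**: three encoder levels of pre-activation residual units
  (BN→ReLU→Conv3x3, twice, identity or 1x1-projection shortcut), stride-2
  convolution for down-sampling (64→32→16, bridge at 8 for 64 x 64 input),
  nearest-neighbour upsample + Conv3x3 for up-sampling, encoder-decoder
  concatenation, final 1x1 convolution.  Level widths default to
  64/128/256 with a 512 bridge; the reference description fixes the unit
  structure but not the level count or widths, so these are explicit,
  configurable defaults.

Batch normalization uses frozen running statistics at inference.  The
whole stack runs on a small NumPy layer engine written for this package
(explicit forward/backward passes, im2col convolutions through BLAS, Adam);
every architecture's reverse-mode gradients are verified against central
finite differences to ~1e-9 relative error in the test suite.

## Training protocol

MSE loss in standardized space, Adam, initial learning rate 1e-4, batch
size 8, fixed 50-epoch budget, per-epoch reshuffling from the config seed,
no augmentation, no schedule.  The checkpoint with minimum validation loss
is returned (selection is post hoc; no early stopping).  Validation loss
is computed in standardized space, the same space as the objective.

**Desk-scale study conditions.**  The test suite trains on a 20-case,
64 x 64 cohort (16 train / 4 validation, 8 pairs per case) with the
reference depths retained and widths narrowed — DnCNN 6 filters, Win5RB 4,
ResUnet 6/12/24 with a 48-wide bridge — for 8 epochs at learning rate
1e-3.  Depth is architecture-defining and is kept; width, epochs and the
learning rate are capacity/compute scalings chosen so one CPU trains each
model in about a minute.  Under these conditions every model's validation
NMSE falls far below the ~64% short-time level, and the encoder-bridge-
decoder model attains validation losses at or below DnCNN's across seeds,
the same direction of effect as the clinical comparison.

## Metrics

NMSE, PSNR and SSIM treat the full-time image `y` as reference.  SSIM
defaults to the literal single-evaluation global-statistics formula with
c1 = (0.01 L)^2, c2 = (0.03 L)^2; the windowed form (11 x 11 Gaussian,
sigma 1.5, mean-aggregated) is available by flag since published values
may come from a library default.  The dynamic range L defaults to max(y),
mirroring the PSNR peak convention; a fixed 16-bit range is configurable.
Identical images give PSNR = +inf, which aggregation excludes from means
with a logged count.  Aggregates report mean (SD) and median (Q1, Q3) with
linear-interpolation quartiles.  Joint histograms pool voxel pairs across
images; r^2 is Pearson on the pooled voxels.

A useful closed form for validation: for 2-of-10 Poisson frame sums with
per-pixel per-frame mean mu, E[sum(y−x)^2] = sum(64 mu^2 + 8 mu) and
E[sum y^2] = sum(100 mu^2 + 10 mu); at the phantom's count levels the mean
NMSE sits at ~64.1%, matching the short-time noise level reported for
clinical data.

## Uptake quantification

Gates-style: U = kidney-ROI count sum; B = background per-pixel mean times
kidney-ROI area; uptake% = (U − B)/D x (1/k) x 100.  Kidney depth Y (cm)
from the Tauxe regression (0.82 W − 0.36 H − 0.06 A + 61.088)/10.  The
attenuation rule k(Y) is configurable and defaults to narrow-beam
exponential attenuation k = exp(−mu Y), mu = 0.153 /cm for 140 keV in soft
tissue; the rule actually used is recorded in every result.  Because the
true rule inside clinical workstations is proprietary, uptake comparisons
across image types hold k fixed, which is how the quantity is used here.
Negative net counts (B > U) are preserved and flagged, not clipped.
Agreement between two uptake series is Pearson r^2 plus Bland-Altman bias
and bias ± 1.96 sd(differences) (sample sd), plotted with a solid bias
line and dashed limit lines.

## Pipeline

`run_experiment` chains simulate → register → build-dataset → train (x3)
→ evaluate → uptake from a single config whose global seed is expanded
per stage via `SeedSequence`; each stage writes artifacts plus a `.done`
sentinel, so interrupted runs resume and completed stages are skipped
unless forced.  A run manifest (versions, config, per-stage seeds and
timings) makes a rerun fully determined on one machine.

## Known limitations

* The phantom's piecewise-constant activity has no intra-kidney texture;
  denoising it is easier than denoising cortical detail, so metric levels
  for *trained models* are not comparable to clinical values (the
  short-time noise level, which is count-statistics-driven, is).
* Registration assumes rigid, inter-frame motion only; no deformation or
  intra-frame blur.
* The NumPy engine is single-threaded BLAS; training at 256 x 256 with
  full widths is possible but slow, and is not exercised by the default
  configurations.
* ROI placement comes from phantom ground truth (or user masks); there is
  no automatic segmentation.
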