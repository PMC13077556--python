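# Methods

## The measurement problem

Cryo-EM is the only imaging modality that resolves the lipid bilayer of
an extracellular vesicle (EV) in its native hydrated state — two dark
leaflets ~4 nm apart, visible at strong underfocus — and the bilayer is
what distinguishes an EV from the lipoprotein discs (HDL, LDL, VLDL),
exomere-like dense particles and ice contamination that co-isolate with
EVs. This package implements the image-analysis half of an automated
characterization workflow: per-pixel segmentation of each structure
class, circle detection on the segmentations, and size-distribution
statistics, with a simulator supplying ground truth so each stage is
verifiable quantitatively rather than by visual inspection.

## Units and coordinate conventions

Nanometres are the single physical unit across all in-memory
interfaces; Angstrom appears only inside the MRC header reader/writer.
Coordinates are 0-based `(row, col) = (y, x)` with pixel centres at
integer positions. Radii are pixels internally, converted to nm only in
`ParticleRecord.diameter_nm` and downstream reports.

## Simulator

`simulate.SceneSpec` defaults mirror the standard acquisition geometry:
0.55 nm pixels at the specimen level, ~32 e/Å² total dose, and one 2 µm
hole in the carbon support foil per field. Rendering is
phenomenological:

- **Bilayer vesicles** are dark rings with two Gaussian leaflet dips
  (separation 4 nm, per-leaflet sigma 1.2 nm) at radius R ± 2 nm. After
  4× binning to 2.2 nm pixels the two leaflets merge into a single dark
  ring centred on the membrane — the same loss of leaflet resolution
  binning causes in real data. Vesicles may optionally be rendered as
  partial arcs (uniform completeness 0.5–1.0) to exercise
  incomplete-circle detection.
- **Dense particles** (HDL 7–12, LDL 18–25, VLDL 30–70 nm uniform;
  exomere-like `small_dense` normal 45.3 ± 4.5 nm) are logistic-edged
  dark discs, darkest at the centre and monotone toward background.
- **Ice blobs** are high-contrast discs whose radial coordinate is
  modulated by low-order angular harmonics (irregular boundaries).
- **The hole rim** is a Gaussian-profile dark band along a 2 µm circle
  whose closest approach to the field centre is randomized — the
  canonical false-positive source for bilayer detection.
- **Background** is a configurable grey level times (1 + a smooth
  random low-order gradient), emulating ice-thickness variation.
- **Noise** is the Gaussian approximation to shot noise: relative
  standard deviation `gain / sqrt(dose × pixel_area_Å²)`, so pixel
  variance scales as 1/dose. No CTF, detector MTF or movie-frame
  physics is modelled; contrast values per class are free parameters
  (defaults 0.35–0.6 of background), chosen to give per-pixel
  SNR ≈ 5–10 at the default dose — a "good imaging day". Consequently,
  passing tests establish algorithmic correctness (geometry, scoring,
  statistics, class-contrast logic), not performance on adversarial
  real data with CTF fringes, surface texture or crowding.

Particle counts per class are Poisson(density × field area). Placement
rejects centre pairs closer than half the sum of footprint radii
(vesicles mostly isolated, as in typical fields) and keeps footprints
wholly inside the image; 100 rejected retries raise an overcrowding
error rather than silently densifying. Everything is driven by one
`numpy` Generator seeded from the spec, so identical specs give
bit-identical images and truth; per-image seeds for datasets derive
from a `SeedSequence` spawn of the base seed.

## Preprocessing

- `normalize_to_8bit`: clip at intensity percentiles (default
  0.1/99.9) and map linearly to [0, 255]. The exact clipping rule of
  the common converter tools is not standardized; the percentile rule
  is this package's documented choice. A constant image maps to flat
  mid-grey with a warning.
- `bandpass_filter`: a Gaussian band mask over FFT frequencies,
  parameterized by feature sizes (spatial periods) `filter_small`–
  `filter_large` px, default 2–50. The compatibility contract is
  behavioural, not bit-exact with any particular plugin: periods
  outside the band (including DC) are attenuated ≥ 90% in amplitude,
  the geometric mid-band is preserved ≥ 80%, output is exactly
  zero-mean, and the operator is linear. The fixed exponents (2 on the
  high-pass, 3 on the low-pass) make those bounds hold at the default
  setting.
- `bin_image`: mean pooling (preserves SNR; subsampling would not),
  crop to multiples of the factor, pixel size multiplied by the
  factor. 4× binning takes 0.55 nm pixels to the 2.2 nm grid used for
  Hough sizing.
- `despeckle`: 3×3 median filter, the standard cleanup for
  single-pixel false positives in predicted masks.

## Segmentation

Per-class **independent binary models** — not one multi-class softmax —
so overlapping predictions are possible and resolved downstream, which
matches how per-structure models are used in practice.

`PixelClassifier` is a small MLP (default hidden layers 32/16) over
`skimage` multiscale basic features (intensity, edges, texture at
Gaussian scales 1–8 px). Trainable-segmentation over a generic filter
bank is the established approach for electron-micrograph pixel
classification; the underlying published CNN architecture of the
original workflow is unavailable, and conformance here is behavioural:
co-registered masks, high accuracy on held-out synthetic patches, and
class specificity. Training pixels are a seeded, stratified subsample
(cap 100k) of the annotated patches; optional augmentation is limited
to the 8 dihedral flips/rotations — elastic deformation would distort
the 4 nm leaflet separation, the one geometric feature that defines
the bilayer class. The optimizer runs at most `epochs` iterations and
the per-epoch loss is recorded; a non-finite loss raises an error
naming the epoch. Bilayer models intended to ignore lipoproteins
should be trained on scenes that contain dense particles as labelled
negatives; without such hard negatives a per-pixel model learns
"dark = bilayer".

Prediction tiles large images with overlap tapering so tile seams
introduce no probability discontinuity; binarization threshold defaults
to 0.5 and is exposed.

`RingMatchedFilter` is the deterministic classical baseline used by the
default pipeline: normalized cross-correlation of the (inverted,
standardized) image with the simulator's own double-leaflet ring
template over a radius sweep (default diameters 30–150 nm), peaks
≥ 0.5 NCC kept after the same non-maximum suppression as the Hough
stage, then painted back as annuli (half-width 4 nm) to form a bilayer
mask. The template includes a negative-weight lumen term
(`lumen_weight`, default 0.5): a vesicle interior is at background
level while a lipoprotein disc is dark throughout, so penalizing
interior darkness is exactly what separates rings from discs. With it,
VLDL-only and blank fields produce (after despeckling) essentially no
bilayer mask, while vesicle rings correlate at 0.6–0.9.

Bandpass preprocessing is intended before lipoprotein/ice models but
not before bilayer detection, mirroring the workflow's use of filtered
images for lipoprotein models and unfiltered ones for the bilayer
model.

## Detection and sizing

`mask_to_outlines` produces the voting input: `edge` (mask minus its
erosion) for filled-particle segmentations, `skeleton` (morphological
thinning) for ring-shaped bilayer segmentations.

The **Hough circle transform** accumulates, for every centre (y, x) and
integer radius r in 6–100 px, the number of outline pixels lying on the
midpoint-rasterized circle of radius r. The score is votes divided by
the pixel count of that ideal rasterized circle — the same
rasterization is used for voting templates, simulator test rings and
the brute-force oracle, so a complete ideal ring scores exactly 1 and
an arc covering a fraction α scores ≈ α. Score thresholds follow the
published protocol: 0.8 for circles, 0.5 for rings; the ring threshold
is what makes half-predicted bilayers still measurable. The plugin
historically used for this analysis does not document its internal
score normalization; the perimeter normalization above is this
package's definition, against which the 0.8/0.5 thresholds are
interpreted.

One printed inconsistency is worth recording: the protocol states
"radius between 6 and 100 pixels (26.4 and 440 nm)", but at 2.2 nm per
binned pixel those nm values equal *diameters* (6 px radius = 13.2 nm
radius = 26.4 nm diameter). This package treats 6–100 px as radii and
26.4–440 nm as the corresponding diameter bounds
(`HoughConfig.diameter_bounds_nm`), and reports both with that
convention stated rather than silently reinterpreting either number.

Non-maximum suppression processes peaks in descending score (ties:
smaller radius, then raster order); a peak is suppressed only when its
centre lies within max(r_kept, r_new)/2 of an accepted peak *and* the
radii differ by < 25%. The radius clause lets concentric rings of
multilamellar vesicles survive while collapsing near-duplicate peaks.
No sub-pixel refinement is attempted; radius resolution is 1 px
(2.2 nm at default binning), which sets the quantization floor on
recovered diameters.

Filled-particle segmentations are sized by the **area-equivalent
diameter** d = 2√(A/π) over 8-connected components (≥ `min_area` px),
which applies to oval particles as well; touching particles merge into
one component — a documented limitation, not silently corrected.

**Artifact exclusion** flags records (never deletes): (a) rim-consistent
detections — either concentric with the hole circle, or osculating it
(centre at distance R_rim ∓ r from the hole centre within 3 px, which
is how short stretches of rim arc are fitted by small circles);
(b) border-truncated circles; (c) records whose disc overlaps an
ice-class mask by > 30%. Exclusion reasons are logged per record and
excluded records are omitted from distributions.

`size_distribution` reports median, sample SD (n−1), count and a
half-open-bin histogram (default 10 nm bins); a single diameter yields
SD 0 with an explicit flag, an empty set a flagged undefined median.

## Evaluation

Greedy matching in descending prediction score: a (truth, prediction)
pair is valid if the centroid distance is ≤ max(5 px, 0.5·r_truth) and
the relative radius error ≤ 25%. For a detection task with no true
negatives, "accuracy" is deliberately defined as tp/(tp+fp+fn) — the
Jaccard index of the detection sets — and precision/recall/F1 are
always reported alongside, so the numbers remain interpretable under
any convention. A seeded image-subset mode supports the
spot-inspection protocol of checking a few percent of a large dataset.

## Pipeline and problem sizes

The default `run_pipeline` condition is the package's study condition:
1024×1024 fields at 0.55 nm/px (a 0.56 µm crop of a hole), vesicle
density 40/µm² with lognormal diameters (median 60 nm, σ_log 0.3),
hole rim present, 4× binning, ring matched filter → despeckle →
skeletonize → Hough (ring threshold) → rim/border exclusion. The
acceptance experiment uses 50 such micrographs (~600 vesicles), which
puts the standard error of the truth-sample median near 1 nm — small
enough that a recovered median within 5% of 60 nm is a meaningful
end-to-end check, with detected medians quantized to the 4.4 nm
diameter grid of integer radii. Typical results: recall ≈ 0.92–0.96,
precision ≈ 1.0 after exclusion, per-particle diameter bias ≈ −0.35 nm
(well under the 2.2 nm one-binned-pixel budget).

Stage outputs are content-addressed by a hash of the resolved config;
re-running an unchanged config skips the computation and leaves
byte-identical outputs. The global seed fully determines simulate and
detect outputs; classifier training is deterministic to the solver's
limits for a fixed seed.

## Known limitations

- The simulator's contrast model is not calibrated to any instrument;
  per-class contrasts and densities are free parameters with defaults,
  and no CTF/optics is modelled.
- Per-pixel (not instance) segmentation: overlapping or touching
  particles of one class can merge.
- Vesicles > 200 nm flatten in thin ice in real samples; projected
  sizes are reported uncorrected.
- The pixel classifier's specificity depends on the negatives seen in
  training; it is a property of the training set, not the
  architecture.
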