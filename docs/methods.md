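# Methods

## Coordinate model

A scout view is a 2D grayscale array whose rows run cranial (index 0) to
caudal, one row per `row_spacing_mm` (default 1.0 mm, the inclusion rule
of the cohorts this models — scout views with any other pixel spacing
are excluded at load time). The pulmonary-trunk region is a half-open
integer row interval `[start_row, end_row)`; half-open intervals make
lengths, masks, intersections and unions exact integer arithmetic. The
reference-standard row must lie strictly inside the band; loaders flag
violations per case rather than clamping them. The band centre is
`floor((start + end − 1)/2)`, which is always a contained row regardless
of parity. Mapping an inclusive axial CT slice span onto scout rows
scales by `slice_thickness / row_spacing` (5 mm slices by default) and
rounds boundaries half-up; a span that rounds to an empty interval is an
error rather than a silent one-row region.

Score vectors become bands via a deterministic rule: the longest maximal
run of rows with score ≥ threshold (default 0.5); ties on length break
toward the higher mean score, then toward the more cranial start; if no
row reaches threshold, the arg-max row becomes a single-row band so a
selection always exists. The rule is validated against exhaustive run
enumeration in the tests.

## Phantom generator

The clinical images are private, so training and evaluation run on
stylized anterior–posterior chest phantoms (default 128 × 64 px):

- a torso ellipse (brightness 0.50–0.62) on a dark background (0.05);
- two lung ellipses (0.18–0.30) whose vertical position tracks the band,
  so the band correlates with visible landmarks as it does anatomically;
- a mediastinal column between the lungs (+0.05 over the torso);
- the ground-truth band: +0.14 contrast across the mediastinum, with
  height drawn from 15–35 rows (3–7 axial slices of 5 mm; the clinical
  median is 5 slices) and centre drawn from 0.35–0.55 of image height
  plus ±3 rows of jitter;
- additive Gaussian noise (sd 0.05), then quantization to a 16-bit
  grayscale grid so PNG round-trips are bit-exact.

The reference row is defined as the band centre: the clinical "optimal
slice" is a human judgement with no synthetic analogue, and the centre
is the only defensible stand-in. Per-case seeds are a SplitMix64-style
hash of (cohort seed, index), making cohorts order-independent and
reproducible. Shift augmentation translates image and annotation
together, padding with the background intensity, and rejects any shift
that would move the band or reference row out of frame.

What the phantom does *not* model: contrast-media dynamics, breathing
mismatch between scout and CT, scanner-specific exposure, and real
anatomical texture. Passing the end-to-end tests therefore demonstrates
that the learning and evaluation machinery works, not that the trained
weights transfer to clinical images.

## Network and training protocol

The localizer is a U-Net-body row scorer: per encoder level one 3 × 3
convolution + ReLU + 2 × 2 max-pool (channels 8, 16, 32 at depth 3); a
3 × 3 bottleneck; per decoder level nearest-neighbour ×2 upsampling, an
additive skip connection from the same-resolution encoder activation,
and a 3 × 3 convolution + ReLU. Additive (rather than concatenated)
skips keep channel counts symmetric and halve decoder cost; the skip
topology is unchanged. The head collapses the column axis with 1 × 3
stride-2 convolutions until ≤ 4 columns remain, then a dense
(channels × width → 1) projection per row yields one logit per image
row; its bias starts at −1.1, the logit of the ≈ 20 % prior band
fraction. Weights are He-normal from a seeded generator; two builds with
the same seed are identical.

Training: Adam (only the learning rate exposed), per-row binary
cross-entropy with logits, batch size 16, a fixed 50-epoch schedule, and
per-epoch re-sampled shift augmentation (≤ 10 rows, ≤ 5 columns, clipped
per case to keep the annotation valid). The learning rate is selected by
case-level 5-fold cross-validation on the training cohort — balanced
folds, per-fold slice-hit accuracy on the held-out fold, best mean wins,
ties to the smaller rate — followed by a retrain on the full cohort.
Cross-validation screens candidates with a shortened 12-epoch schedule
(`cv_epochs`): at this phantom scale both sane candidates separate from
pathological ones well before 12 epochs, and screening at full length
would spend ~10× the compute of the final fit for no extra information.
The final model always trains the full 50 epochs.

The layers are float32 numpy arrays with numba-compiled convolution
kernels (channels-first, width-contiguous inner loops); the backward
pass is hand-derived and checked against finite differences. The input
gradient of the 3 × 3 convolution reuses the forward kernel with a
flipped, channel-transposed filter. Max-pool backward routes gradient to
every entry tying the block maximum; positive-valued ties have measure
zero and tied zeros are killed by the preceding ReLU mask. Inference is
deterministic; training is deterministic given the config seed on a
fixed platform.

The documented acceptance configuration — 300 training phantoms, 50
held-out, depth 3, base 8, learning rate from {1e-3, 1e-4}, seed 7 —
reaches held-out slice-hit accuracy ≥ 0.90 and mean 1D IoU ≥ 0.60 and
runs in minutes on one CPU core.

## Evaluation conventions

Accuracy is reported as a half-up-rounded one-decimal percentage; mean
rank to one decimal; mean usefulness ((n_optimal − n_useless)/n) to two
decimals. These rounding rules reproduce every printed value of the
published comparison table from its printed counts. Error-distance
statistics cover exactly the missed cases and are reported as absent
when there are none — a mean over an empty set is not fabricated as 0.
IoU is only reported for band-producing methods; human raters mark a
single slice and have none. Dispersions are sample (n − 1) standard
deviations. The automatic rank stand-in used in synthetic benchmarks is
competition ranking (1, 1, 3, …) of distances to the reference row.

## Non-inferiority statistics

Margins follow the clinical design: 10 percentage points of accuracy,
5 mm of slice distance (one CT slice), 0.25 rank/usefulness units.
"Non-inferior" always means "not worse by more than the margin", with
worse = fewer hits, larger distance, worse (larger) rank, or lower
usefulness. All tests are one-sided at α = 0.05 with no multiplicity
adjustment, mirroring the analysis this models.

- **Paired binary (accuracy):** Wald z on the margin-shifted paired
  difference, `z = (d + margin)/se` with `d = (n10 − n01)/n` and
  `se² = (n10 + n01 − (n10 − n01)²/n)/n²`. The exact test variant used
  clinically is not recoverable from the published description, so this
  standard construction is stated explicitly and calibrated by
  simulation: at the margin boundary with 239 pairs its type-I error is
  0.05 ± 0.01.
- **Ranks / usefulness:** the published description ("paired rank-sum")
  is self-contradictory; it is implemented as the standard reading, a
  Wilcoxon signed-rank test on margin-shifted paired differences. Zero
  differences are dropped (the description is silent; this is the
  classical convention). With ≤ 25 non-zero pairs the p-value is exact,
  computed by convolving doubled midranks — valid under ties and
  verified against full 2ⁿ sign enumeration; beyond that a normal
  approximation with tie correction is used.
- **Distances:** one-sided paired t-test on `B − A + margin`.
- Degenerate zero-variance inputs return p = 0 or 1 with an explicit
  flag instead of dividing by zero.

Sample-size calculators: the t-design uses the normal-approximation
closed form iterated with t quantiles to a fixed point and is verified
against a noncentral-t power scan; the paired-binary design uses
`n = (z₁₋α + z₁₋β)² (disc − δ²)/(δ + margin)²` with an optional
simulation-scan mode, cross-checked against a brute-force power scan.
The published sample sizes (172, 52, 137) are not reproduced as targets:
their auxiliary assumptions (discordance rates; whether "10 mm" is an
expected difference, an sd, or a variance) are under-specified, and at
the only self-consistent reading of the distance design (shifted effect
5 mm, sd 10 mm) a cohort of 52 pairs would have power ≈ 0.97, not 0.80.
Power calibration therefore runs at the design point the calculator
itself returns (n = 27 for that effect), where simulated power is
0.80 ± 0.03.

## Problem sizes and seeds

Tests use fixed seeds throughout; Hypothesis runs derandomized. The
end-to-end check trains 10 CV fold models (240 cases × 12 epochs) plus
one final model (300 × 50); Monte-Carlo calibrations use 10,000
replicates for test size and 5,000 for power. These sizes were chosen so
the whole suite is a desk-scale run while keeping Monte-Carlo error well
inside the stated tolerances.

## Known limitations

- The phantom's band cue is a clean intensity step; clinical difficulty
  (breathing mismatch, overlapping mediastinal structures) is absent, so
  absolute metric values on phantoms exceed what clinical data yields.
- Additive skips, the exact head layout, optimizer, batch size and
  augmentation magnitudes are this package's documented choices; the
  original architecture supplement is not public, and all of these are
  config-exposed rather than claimed faithful.
- Training determinism is per-platform (float32 accumulation order).
- The DICOM reader handles uncompressed secondary-capture-style images
  only and normalizes intensities to the per-image maximum.
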