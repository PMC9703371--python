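# Methods

## The measurement problem

Replicate 2D-PAGE gels of the same biological contrast differ by a
rigid-ish placement error (scanner position, gel shrinkage), a global
intensity factor (protein load, staining time) and pixel noise. To
compare a protein's abundance across gels, the same spot must be read
from the same pixels on every gel. gelspot does this by segmenting
*once*, on the mean of the registered gels, and superimposing that
single label map on every gel. All stages operate on a canonical
float-in-[0, 1] grayscale domain, so every tunable parameter is
bit-depth independent.

## Registration model

Each gel is mapped to the standard gel by a nonreflective similarity
transform: (x, y) ↦ s·R(θ)(x, y) + (tx, ty), determinant s² > 0, so
mirror flips are excluded (a reflected gel is a data error, not a
placement error). Two landmark correspondences determine the four
parameters exactly via the complex closed form a = (d₂−d₁)/(s₂−s₁),
b = d₁ − a·s₁. Consequences worth knowing:

- the fit is exact at the control points (residual ~1e-14 px) for any
  input, including noisy clicks — accuracy *elsewhere* on the gel
  degrades with click error amplified by the lever arm between the
  two landmarks, so the landmarks should be far apart;
- the standard gel is never resampled; every other gel is interpolated
  once, bilinearly, into the standard frame;
- out-of-frame samples take a constant fill, default 1.0 (white), so
  warped borders look like empty gel and never segment as spots. The
  warp pads the source by one fill-valued pixel ring so border samples
  blend bilinearly with the fill rather than snapping to it.

Coordinates are (x = column, y = row), 0-based, origin top-left,
sub-pixel allowed — one convention everywhere, including the
control-points TSV.

## Mean gel

Pixel-wise arithmetic mean of the aligned-and-cropped stack, with no
per-gel intensity normalization beforehand. Averaging N gels shrinks
uncorrelated pixel noise by √N and keeps every spot that is present in
most replicates; a spot missing from a few gels is attenuated but
usually still detected, and then quantified as near-background on the
gels that lack it — which is the informative outcome.

## Segmentation chain

All steps run on the spots-bright orientation (stained gels are
complemented first).

- **White top-hat, disk radius r (default 15 px).** Image minus its
  grayscale opening. Removes any background structure wider than the
  disk and flattens the baseline to ~0; anti-extensive (0 ≤ output ≤
  input) and invariant to constant offsets. r must exceed the radius of
  the largest spot to keep; within one radius of the image border the
  opening under-reaches and leaves a residual, so crops should keep a
  margin around the region of interest.
- **h-maxima marker suppression (default h = 0.02).** Morphological
  reconstruction by dilation of (image − h) under the image; regional
  maxima with prominence ≤ h disappear. This is the oversegmentation
  knob: h just above the noise-induced prominence (a few noise σ)
  merges spurious maxima without merging real neighbouring spots.
- **Foreground threshold (default Otsu on ROI pixels).** Pixels of the
  top-hat image above the threshold, inside the rectangular ROI, are
  candidate spot area. A smaller ROI around faint spots lets the
  threshold adapt to local statistics and improves their detection.
- **Marker-controlled watershed.** Markers are the connected regional
  maxima of the h-suppressed image, computed with everything outside
  the foreground held below the image minimum — this guarantees every
  foreground component owns at least one marker, so the basins
  partition the foreground with no unlabeled interior pixels and no
  ridge pixels. Labels are renumbered 1..K in raster-scan order of each
  region's first pixel, making label maps reproducible byte for byte.
- **Area filter (default min_area = 9 px², no max).** Removes
  noise-sized regions; survivors are renumbered preserving raster
  order.

One connectivity setting (default 8) governs maxima, markers and
regions; mixing connectivities creates edge cases with no observable
benefit.

## Quantification

Per (spot, gel): area (pixel count — identical across gels by
construction), mean intensity, integrated intensity (mean × area) and
centroid. Intensities are reported on the spots-bright scale so that
more protein means a larger number; they are read from the
aligned-cropped gels (raw mode, default) because top-hat filtering is a
detection aid, not a photometric calibration. Two alternatives exist
for background handling downstream:

- `quantify_on: tophat` reads intensities from each gel's own top-hat
  image (background removed, but with a small positive noise-floor bias
  of order the noise σ);
- `local_background_table()` estimates, per spot and gel, the median
  intensity of a ring around the spot (excluding all dilated spot
  regions), for explicit background-corrected analysis. Because the
  annulus is symmetric, a locally linear background cancels exactly;
  this is the estimator the acceptance checks use to recover planted
  intensity ratios.

CSV values are written with 9 significant digits; reruns are
byte-identical.

## Synthetic generator

Models a small 2D-PAGE experiment: per gel i,

pixel(x, y) = B(x, y) − cᵢ · Σₖ Aₖ exp(−((x′−cxₖ)²/2σxₖ² + (y′−cyₖ)²/2σyₖ²)) + ε,

with (x′, y′) = Tᵢ⁻¹(x, y), B a constant plus linear gradient
(default 0.85 + 0.05·x/W + 0.04·y/H), ε ~ N(0, 0.005), clamped to
[0, 1]. Tᵢ maps standard-frame to gel-frame coordinates, so a spot
planted at (cx, cy) appears at Tᵢ(cx, cy) on gel i; the emitted control
points are the first two spot centres mapped the same way, which makes
the alignment map the registration must recover exactly Tᵢ⁻¹. Defaults:
5 gels, 12 spots of σ ≈ 4 px (±20% per axis, elliptical) separated by
> 6σ, amplitudes 0.12–0.28, per-gel scales (0.5, 0.8, 1.0, 1.5, 2.0),
|θ| ≤ 3°, |t| ≤ 10 px, s ∈ [0.98, 1.02], seeded and bit-reproducible.
The amplitude ceiling keeps even the 2× gel clear of the zero-intensity
floor, so rendering stays linear in cᵢ — the saturation regime is
deliberately outside the model.

What the generator does *not* emulate: streaks, smears, dust,
nonrigid gel warping, Poisson/scanner noise, spot shape irregularity
beyond ellipticity, and missing spots. Passing tests therefore
demonstrate correctness of the algorithmic chain under the stated
model, not robustness to every real-gel artifact; on real data the
registration quality depends on landmark choice and the two-point
rigidity assumption, and heavily saturated or smeared spots will bias
intensity ratios.

## Numerical and design choices

- Grayscale conversion uses fixed BT.709 luma weights; integer pixels
  divide by their type maximum. Output TIFFs are 16-bit, so a
  save/load round-trip is exact to 1/65535 per pixel.
- Exactly two control points per gel; a least-squares fit over ≥ 3
  points is out of scope, matching the two-landmark protocol.
- Watershed flooding uses the library's deterministic ordering with
  `watershed_line=False`, so basins are ridge-free; determinism of the
  final labeling is enforced by the raster-order renumbering.
- Degenerate inputs: coincident control points raise a geometry error;
  a constant or empty foreground yields K = 0, a warning and
  header-only tables (exit 0 — an empty result is a result).
- Problem sizes in the test and acceptance layers (256² images, 5 gels,
  12 spots, 50–100 random repetitions) are chosen so the full suite
  completes in seconds while every check still exercises the same code
  paths as a full-size run; the pipeline itself is resolution-agnostic.

## Known limitations

- Two-point similarity cannot correct nonrigid gel distortion; spots
  far from the landmarks inherit the residual warp.
- Segmenting only the mean image means a spot present in a single gel
  but absent elsewhere may fall below the mean-image threshold.
- Otsu's threshold assumes a bimodal top-hat histogram; for very sparse
  or very crowded gels an explicit `foreground_threshold` is more
  stable.
- Mean intensity is not normalized across gels (total-load or
  housekeeping normalization is left to downstream statistics, by
  design).
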