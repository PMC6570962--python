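# Methods

## Image model and conditioning chain

The pipeline assumes colour photographs of submerged fungal culture captured
light-on-dark: bright fungal material, dark featureless background. Each image
passes through a fixed conditioning chain:

1. **Contrast stretch.** A symmetric percentile stretch saturating a fraction
   `contrast_saturation` (default 0.05) of all pixels, split equally between
   the two tails; `0` degenerates to a min–max stretch. The mapping is linear
   and monotone, so it never reorders intensities. When both percentiles land
   on the same level — a constant image, or a flat background covering more
   than `1 − saturation/2` of the pixels — the stretch is skipped. This
   matters for sparse-foreground images: stretching a 2.5th–97.5th percentile
   window that lies entirely inside the background would rescale background
   noise across the full grey range, so skipping is the correct degenerate
   behaviour, and for very sparse scenes `--contrast-saturation 0` is the
   safer setting.
2. **Red channel.** The red channel is retained and green/blue discarded.
   Against a dark background, fungal material is bright in all channels;
   using a single fixed channel keeps the measurement deterministic across
   camera colour balance.
3. **Global threshold.** Either a fixed grey level or an automatic histogram
   method (isodata by default, Otsu available). Foreground is *strictly
   brighter* than the cutoff — the cutoff pixel itself is background; this
   tie-break is arbitrary but must be fixed for exact reproducibility. The
   mask's polarity is normalised so downstream code always sees foreground =
   fungus, whatever the source encoding.

No illumination correction, denoising, or hole filling is applied; the chain
is deliberately minimal so its behaviour is fully predictable.

## Particle geometry

Connected components are extracted under 8-connectivity by default (the
convention of the standard particle analysers in this field; 4-connectivity
is available for study). Particle indices are assigned 1..N in raster-scan
order of each component's first pixel, which makes them reproducible across
reruns — these indices link QC overlay labels to CSV rows, so stability is a
correctness property, not a convenience.

Outlines follow the **pixel-corner (half-open grid) convention**: each pixel
is a unit square, the outline traces the outer boundary along pixel edges,
and a single pixel has polygon area 1 and maximum Feret √2. Under this
convention the outline polygon area equals the pixel count for hole-free
particles, and the hull polygon always contains the outline, so solidity is
capped at 1 by construction. At checkerboard corners (two diagonal foreground
pixels meeting at one vertex) the trace passes through under 8-connectivity
and turns tightly under 4-connectivity, matching the labelling. Interior
holes are not filled and never contribute to particle area.

The convex hull is computed from the outline vertices (Qhull); hull vertices
are a subset of outline vertices. Feret extremes come from rotating calipers:
the maximum over antipodal vertex pairs, the minimum over hull-edge
orientations of the supporting-line gap. Both are checked in the test suite
against exhaustive-search oracles.

Border-touching particles are excluded by default (`exclude_all`): a particle
cut by the image edge has truncated geometry and any descriptor computed from
it would be biased low. `keep_all` is available since for very small
dispersed fragments the truncation bias is negligible and discarding them
loses counting statistics; the choice applies uniformly to all classes.

## Descriptors

With calibration `um_per_px` (µm per pixel edge; areas scale with its
square):

* area A = pixel count × um_per_px²;
* Feret F, F_min from the hull calipers × um_per_px;
* aspect ratio AR = F / F_min ≥ 1;
* solidity S = A / A_hull ∈ (0, 1], with A_hull the shoelace area of the
  hull polygon (mixing a pixel-count area with a polygon hull area is what
  keeps S ≤ 1 exactly; a pixel-count hull area would let small particles
  exceed 1);
* morphology number MN = (2·√A·S)/(√π·F·AR), dimensionless, 1 for an ideal
  circle, → 0 for a line. MN is reported unclamped: pixelation can push it
  marginally above 1 on tiny particles and truncating would hide that.

Aspect ratio is deliberately the Feret max/min ratio, not a fitted-ellipse
axis ratio; the two differ for concave particles.

### Rasterization bias

Descriptors of rasterized shapes converge to the analytic values as the shape
grows, but the pixel-corner convention carries a systematic half-pixel
dilation: the corner hull of a centre-rasterized disc of radius r approximates
a disc of radius r + ½ px. Consequently F is biased high by ≈ 1 px, S low by
≈ 1/r, and MN low by ≈ 3/(2r) — about 1.5% at r = 150 px, 0.3% at r = 750 px.
Area is essentially unbiased (the inclusion test gains and loses half-covered
pixels symmetrically). Dimensionless descriptors are exactly invariant under
calibration changes, since the calibration multiplies lengths uniformly.

## Classification and heterogeneity

Classification uses calibrated area only, with inclusive lower bounds:
pellet ≥ `pellet_min_area` (default 500 µm²), dispersed ≥
`dispersed_min_area` (default 95 µm²; 20 µm² is a sensible profile at high
magnification), artefact below. Boundary comparisons are exact; because the
thresholds apply to µm² values, the same scene calibrated differently can
legitimately classify differently. Artefacts are counted and logged but never
written to result CSVs. The pelleted fraction pools areas over all images of
a directory before dividing — 100 · ΣA_pellet / (ΣA_pellet + ΣA_dispersed) —
so it is invariant to how images are split across files; artefact area is
excluded from the denominator, consistent with artefacts being removed from
all analyses. A directory with zero fungal area yields NaN with a warning.

Human QC closes the loop: overlays are inspected, wrong calls listed in a CSV
of (image_path, particle_index) pairs — paths absolute or relative to the
input root; bare file names are rejected as match keys because the same name
recurs in every condition folder — and the pipeline re-run drops them from
every output.

## Synthetic scenes

The generator emulates the capture protocol: uniform dark background
(default grey 20), uniformly bright shapes (default 200), optional additive
Gaussian noise, shapes parameterised in µm and rasterized by pixel-centre
inclusion. Closed-form truths: disc (MN = 1), ellipse with semi-axes a ≥ b
(MN = (b/a)^1.5), rectangle, cross of two orthogonal bars (exact concave
solidity, e.g. 5/7 for 30×10 µm bars). Blob unions of discs get numeric truth
at 10× supersampling and are tagged `derived`. The standard test scene holds
3 pellet discs (radii 20/16/24 µm), 5 dispersed rectangles (121–200 µm²),
2 artefact specks and one border-straddling disc on a 512×512 px canvas at
1 µm/px; fixture trees place shapes on a jittered 128-px grid so they never
overlap or touch the border.

What the generator does **not** emulate: hyphal texture, optical blur,
uneven illumination, touching/overlapping pellets, or the large "mycelial
rafts" of interwoven dispersed hyphae that area-based classification would
miscall as pellets. Passing tests therefore demonstrate correctness of the
measurement and classification machinery on well-separated particles, not
robustness to these real-data effects; the QC overlay workflow is the
intended mitigation for them.

## Numerical and design choices

* Isodata is the default automatic threshold; a fixed grey level reproduces
  a hand-pinned threshold exactly when one is known.
* CSV precision: 2 decimals for µm/µm² quantities, 4 for dimensionless ones
  — enough for any downstream statistic while keeping byte-identical reruns.
* Degenerate inputs: constant images threshold to all-background with a
  warning; empty masks yield empty particle lists, header-only CSVs and
  blank overlays rather than errors; zero-area directories yield NaN
  fractions.
* File discovery is lexicographic and case-insensitive in the suffix;
  files directly in the input root form an implicit group ".".
* Problem sizes in the test suite (512-px scenes; a 200-image 1024×1024
  batch for the determinism/throughput check, ~3 shapes per image) were
  chosen as the smallest sizes at which rasterization error is comfortably
  inside the asserted tolerances while a full batch still completes in tens
  of seconds on a single CPU.

## Known limitations

* No watershed separation of touching pellets — the targeted capture
  protocol physically separates pellets before imaging.
* The half-pixel descriptor bias above; at the 10× magnifications the
  defaults target, pellets are hundreds of pixels across and the bias is
  far below biological variability, but MN of small particles should not be
  over-interpreted at the third decimal.
* Solidity measures surface irregularity only; hyphal tip counts are out of
  scope.
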