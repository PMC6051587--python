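# Methods

## The measurement

Whole dorsal root ganglion (DRG) explants extend axons radially onto the
culture substrate. Degeneration (e.g. after NGF withdrawal) fragments distal
axons first, so the informative readout is axon *density as a function of
distance from the soma*, not a spot measurement at an arbitrary radius. The
pipeline quantifies this from quarter-field micrographs — axis-aligned crops
containing one quadrant of an explant's outgrowth with the ganglion at one
crop corner — in five stages:

1. **Orientation.** The ganglion is the most brightly stained structure; the
   corner whose corner-anchored square window (side = `corner_window_frac`
   × short image side, default 0.25, minimum 1 px) has the highest mean
   intensity is taken as the ganglion corner, with ties broken in the fixed
   order top-left, top-right, bottom-left, bottom-right. The image is rotated
   by the multiple of 90° that puts that corner at the top-left pixel,
   coordinate (0, 0). Only quarter-turn rotations are used because
   quarter-fields are axis-aligned crops; rotations permute pixels, so every
   whole-image statistic is exactly preserved. Whether the original corner
   measurement uses a window or single pixels is not documented anywhere we
   know of; the windowed mean is this package's choice, robust to hot pixels.
2. **Adaptive threshold.** A pixel is axon if its intensity strictly exceeds
   mean + `k`·SD of the whole oriented image (default `k = 1.5`). The SD is
   the population SD (N denominator), computed in float64 whatever the input
   bit depth — the N vs N−1 choice is numerically irrelevant at megapixel
   scale but is fixed for bit-reproducibility. The strict comparator makes a
   zero-variance image produce an empty mask. Because mean and SD transform
   covariantly, the mask is invariant under affine intensity rescaling; no
   smoothing, background subtraction or morphological cleanup is applied.
   Ganglion pixels are included in the statistics and the mask; they only
   affect the innermost bins.
3. **Radial binning.** Each pixel centre is assigned distance
   `d = pixel_scale_um · sqrt((col+0.5)² + (row+0.5)²)` from the origin
   corner (default scale 3.87 µm/px) and falls in the half-open bin
   `[b·w, (b+1)·w)` with `w = 20` µm. Bins are quarter annuli clipped to the
   image rectangle; density is the mask-true fraction of the pixels *present*
   in the bin, so clipping does not deflate far bins, and the per-bin pixel
   count is exported so sparse bins can be filtered. Bins with no pixels are
   reported as missing (NaN), never as zero. Conservation is exact:
   Σ density·count = total masked pixels. The soma region is not excluded
   from the innermost bins, and no Sholl-style intersection counting is done
   — the quantity is areal density, not branching complexity.
4. **Aggregation.** Explant profiles are averaged per well (unweighted mean
   over explants, missing bins excluded pairwise); the embryo is the
   independent unit, so repeated wells of the same embryo × treatment are
   further averaged to one subject record. For statistics, fine bins are
   averaged into 500 µm coarse bins (unweighted mean of non-missing fine
   densities).
5. **Statistics.** A two-factor mixed-design ANOVA — between factor:
   treatment; repeated factor: coarse distance bin; subject: embryo — tests
   the treatment main effect as F = MS_treatment / MS_subjects-within-groups
   with df (g−1, N−g). Distance bins beyond the shortest common maximum are
   dropped listwise so the repeated-measures design is balanced; interior
   holes are an error naming the offending subjects. At least two treatments
   and three embryos per treatment are required. Sphericity is not corrected
   by default (it does not affect the between-subject treatment test); a
   Greenhouse–Geisser option corrects the within-subject tests. Dunnett's
   many-to-one comparison (scipy.stats.dunnett) is run within each coarse
   bin against the named control treatment; the family is the set of
   treatment-vs-control contrasts within that bin, and bins where every
   subject has the identical value (fully saturated or fully empty) are
   reported with p = 1. The ANOVA sums of squares are computed in-package
   and cross-checked against pingouin's mixed ANOVA in the test suite.

## The synthetic-field generator

Real quarter-fields cannot be distributed, so every stage is validated
against generated fields with known ground truth. A field is rendered in a
canonical frame (ganglion at top-left) and then rotated to the requested
corner, which makes same-seed fields at different corners exact quarter-turn
copies — the basis of the bit-exact rotation-invariance checks.

- **Ganglion:** quarter-disc of radius `ganglion_radius_um` (default 250 µm)
  at the origin.
- **Axons:** `n_axons` polylines starting on the ganglion rim at angles
  uniform over the quadrant, advancing in 1 px steps with Gaussian angular
  jitter (SD 0.03 rad/step), rasterized and dilated to `axon_width_px`.
  Total length is drawn Exponential(`decay_length_um`), truncated at the
  image diagonal, so the expected number of axons surviving to radius `d`
  decays as exp(−(d − r₀)/λ).
- **Fragmentation:** a Bernoulli(`fragmentation_fraction`) subset of axon
  pixels (ganglion excluded) is deleted; the random draw is consumed even at
  fraction 0, so an intact/fragmented pair at the same seed shares geometry
  and noise exactly and the fragmented mask is a true random subset — the
  binomial scaling checks are exact.
- **Intensity:** foreground pixels set to `foreground_intensity` (default
  3000), plus Gaussian noise N(`background_mean` = 400, `background_sd` = 80)
  everywhere, rounded and clipped to uint16.
- **Ground truth:** the noiseless mask, and its 20 µm radial profile computed
  by an `np.histogram`-based binner that is a deliberately separate code path
  from the production digitize/bincount profiler.

Default geometry (640 px² at 3.87 µm/px ≈ 2.5 mm extent, 150 axons of width
2 px, λ = 700 µm) emulates the dense halo of a healthy explant, including
near-soma saturation where axons overlap. The generator does **not** model
fasciculation, growth cones, branching, uneven illumination or stitching
seams; passing tests therefore demonstrate correctness of the measurement
chain on fields with known radial structure, not robustness to every
real-world staining artifact.

## Decay-length estimation

`fit_decay_length` fits A·exp(−d/λ) by least squares, after two geometric
corrections that separate axon survival from raw occupancy:

- **Coverage correction:** occupancy saturates where axons overlap; for
  quasi-random placement the occupied fraction is p = 1 − exp(−ρ) in the
  underlying axon abundance ρ, so the fit is performed on −log(1 − p).
  Fully saturated bins (p = 1) carry no decay information and are dropped.
- **Distance compensation:** a quarter annulus at radius d contains ∝ d
  pixels while each surviving axon contributes a fixed crossing area, so
  occupancy carries a geometric 1/d factor; fitting p·d (per-arc-length
  abundance) removes it.

With both corrections the expectation of the fitted quantity is a pure
exponential in the generator's survival model. On 20-field ensembles at the
default geometry the estimate lands within ~7% of the generating λ; omitting
the corrections biases the estimate upward by tens of percent (saturated
near-field bins flatten the apparent decay).

## Simulation scales and numerical choices

- Validation simulations (type-I calibration, power, parameter recovery) use
  96 px fields at 20 µm/px — the same ~2 mm radial extent class as a real
  quarter-field at coarse resolution — with 40 axons of width 1 px; the null
  calibration runs 1000 simulated experiments of 3 treatments × 4 embryos.
  Recovery and fragmentation checks use the full-scale 640 px defaults.
- All intermediate statistics are float64; thresholds are never quantized to
  the image dtype.
- Bin assignment uses `floor(d/w)` on float64 and is tested for exact
  agreement with a pure-Python per-pixel loop; the half-open convention and
  the pixel-centre distance make every bin boundary unambiguous.
- Degenerate inputs are errors, not silent defaults: empty tables, non-2D
  images, non-positive scales/widths, coarse widths that are not multiples
  of the fine width, unknown control treatments, and <3 embryos per
  treatment all raise with the offending field named.

## Known limitations

- The corner-window ganglion detector assumes the soma mass is the brightest
  corner-adjacent structure; a field with a brighter artifact in another
  corner will be mis-oriented.
- The mixed ANOVA assumes a balanced repeated factor after listwise trimming
  and tests the treatment effect without sphericity correction (sphericity
  does not affect the between-subject test; the within-subject tests can use
  the Greenhouse–Geisser option).
- Dunnett comparisons use per-bin group variances pooled across treatments
  at that bin only; they do not borrow strength across bins.
- The density unit is the occupied fraction of in-bin pixels. Absolute
  masked area per bin is recoverable as density × pixel count × (pixel
  scale)².
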