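# Methods

## Scores

### Lesion-to-background contrast I_c

`contrast_score` computes `I_c = g(R_l) − g(R_h)` on the grayscale image,
where g(R) is a summary of region R's intensities. The region summary is
the arithmetic mean by default; the median is available (`stat="median"`)
for annotations that clip specular highlights. Both the signed difference
and its absolute value are retained in the result: the sign says whether
the lesion is darker or brighter than background, while the magnitude is
the visibility score and is what the pipeline aggregates (a dye may
render the same lesion type dark-on-light or light-on-dark depending on
tissue, and a visibility optimum should not depend on that direction).

Color images are converted with ITU-R BT.601 luma weights
(0.299, 0.587, 0.114); the conversion is kept real-valued so no
quantization error enters the scores. The weights are an explicit
argument everywhere so alternative conventions remain reproducible.

### Global texture variance var(R,N)_g

For a center pixel the i-th of N neighbors sits at
`(c_x + R·cos(2πi/N), c_y + R·sin(2πi/N))`, i = 1..N, in image
coordinates with y increasing downward. Off-grid positions are bilinearly
interpolated from the four surrounding pixel centers; a coordinate within
1e-9 of a grid point is read directly (the snap keeps integer-radius
axial samples exact instead of blending with a zero-weight neighbor).

The local score is the population variance (divisor N) of the N sampled
intensities; the center pixel does not enter the mean. The global score
averages the local variance over all *valid* centers — those at least R
from every border, `(v − 2⌈R⌉)(h − 2⌈R⌉)` of them. Summing over every
pixel and dividing by h×v would require padding or partial neighborhoods
at the border; restricting to valid centers avoids padding artifacts and
differs from the full-grid normalization only through the excluded
margin. The multi-scale score averages var(R,N)_g over radii
{10, 20, 30, 40, 50} px so that both fine glandular texture and coarser
tissue-patch structure contribute.

N defaults to 8, the canonical LBP neighborhood; the variance is well
defined for any N ≥ 2 and N is a parameter throughout. The LBP bit
pattern itself (bit i = 1 iff neighbor i ≥ center, so ties count as 1)
is exposed with the standard weight 2^(i−1) encoding for completeness,
but the variance score never depends on the binary coding.

The production implementation vectorizes the computation: for a fixed
sample offset the bilinear interpolation of *all* centers is a
fixed-weight blend of four integer-shifted views of the image, so one
radius costs N array blends. Tests compare it against an independent
scalar double-loop implementation (1e-9 relative tolerance; observed
agreement ~1e-15) and against scikit-image's `local_binary_pattern`
variance map on interior pixels.

## Synthetic stained-mucosa patches

No stained-patch photographs are distributed, so the pipeline is
validated on synthetic patches with known ground truth. One patch is

    base + amplitude · gain(c) · field + uptake shifts + noise,  clipped to [0, 255]

* **field** — Gaussian white noise smoothed with a Gaussian kernel
  (σ = correlation length, default 3 px), normalized to zero mean and
  unit variance: the simplest stationary field with a controllable
  var(R,N)_g response. It does not reproduce the anisotropic pit-and-
  groove geometry of real mucosa, specular reflections, vignetting, or
  uneven dye pooling; passing tests therefore demonstrate correctness of
  the scoring and optimization machinery, not photometric realism.
* **lesion** — an ellipse (default semi-axes 40×28 px on a 256×256
  canvas) with a 1-px smoothed edge. Depressed-type lesions carry an
  intrinsic baseline shift (−10 gray levels) so they are faintly visible
  unstained, keeping the percent-increase baseline positive as it is in
  real imagery; protruding-type lesions add a small highlight (+8).
* **dose-response** — every stain effect follows the unimodal bump
  `f(c) = (c/c*)^k · exp(k(1 − c/c*))` with `f(0) = 0`, maximum 1 at the
  planted optimum c*, and decay beyond it. k (default 2) is the
  oversaturation rate: larger k collapses the score faster past c*.
  Healthy uptake, lesion uptake and the texture gain
  (`1 + G·f(c)`, G = 1 for the methylene-like stain) share this bump
  with their own amplitudes. Only the peak location is treated as
  recoverable ground truth; the curve shape is a modeling choice.
* **noise** — additive white Gaussian (default sd 2 gray levels),
  representing sensor noise of a scientific CCD, applied after all
  deterministic terms.

Default planted optima mirror the region-dependent behaviour the scores
are meant to detect: 0.4% for the methylene-blue-like stain in both
regions, and 0.2% (fundus) / 0.6% (pylorus) for the indigo-carmine-like
stain. These are generator settings, not claims about tissue.

Default amplitudes (texture amplitude 10, peak dye-induced lesion shift
−50, healthy shift −10) were chosen so that the score separation between
adjacent grid concentrations exceeds the replicate standard error at five
replicates by a comfortable margin — i.e. the synthetic experiment has
the statistical power a sensibly designed bench experiment would have,
without being trivially noise-free.

Per-patch seeds derive from the master seed and the cell coordinates
(stain, region, concentration, replicate) via a CRC hash, so regeneration
is bit-identical and independent of enumeration order.

## Experimental design and optimization

A design is a list of (stain, region) cells, each with a strictly
increasing concentration grid including 0 (the unstained baseline) and a
replicate count. The two built-in designs enumerate the printed
concentration series: the contrast-stain series (both regions,
0–1.6% in 0.2% steps, 5 replicates → 90 patches) and the texture-stain
series (fundus 0–2.0%, pylorus 0–1.6%, 5 replicates → 100 patches),
190 patches in total. Each cell is bound to the score that matches its
stain's mechanism: contrast for the pooling stain, texture variance for
the absorptive stain.

Replicate scores are averaged per concentration; the optimum is the grid
argmax of the mean, with no interpolation between grid points (the
experiment is a discrete series and the result should be an applicable
concentration). Ties are broken toward the lowest concentration —
minimal dye exposure is clinically preferable — and flagged. The percent
increase over unstained is `100·(optimal − unstained)/unstained`, defined
only for a positive baseline. Per-concentration replicate standard
deviations are reported as descriptive quantities; no hypothesis testing
between concentrations is performed.

A cell with a single concentration yields a summary with no optimum and a
warning rather than an error, so partial designs can still be scored.

## Numerical choices

* Polygon annotations are rasterized with the even-odd rule, boundary
  pixels inclusive — stable for small hand-drawn regions whose edge
  pixels would otherwise flicker in and out. Degenerate (zero-area)
  polygons and vertices outside the image are rejected.
* Geometric tolerances: 1e-9 for grid snapping, point-on-edge tests and
  polygon degeneracy.
* All scoring runs on float64; constant images give a variance below
  1e-12 (bilinear weight round-off) rather than exactly 0.
* Validation sizes: brute-force equivalence uses images up to 64×64 with
  R ≤ 5; the recovery experiment uses the full 190-patch design at
  256×256 with radii {10,...,50} over 20 master seeds, the size at which
  the multi-scale score is still cheap (≈25 ms per image) while the
  largest radius fits with a wide margin.

## Known limitations

* The texture field is isotropic and Gaussian; real mucosa texture is
  structured, and real dye pooling is spatially correlated with that
  structure. Recovery rates measured here do not transfer to real images.
* The percent increases reported on synthetic data depend directly on the
  generator's amplitude settings and are comparable between runs, not to
  bench measurements.
* Lesion segmentation is out of scope: regions come from annotation files
  or the generator's ground truth.
* The border-restricted normalization makes var(R,N)_g of very small
  images (close to 2R per side) an average over few centers and hence
  noisy; the pipeline enforces min(v, h) > 2·max(R).
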