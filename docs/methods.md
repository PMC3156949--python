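# Methods

This note documents the models, numerical choices and limitations of
`chromoband`. It describes what the code computes; every empirical figure
mentioned here is recomputed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Chromosome geometry

A `ChromSpec` fixes the genomic frame: length *L* (Mb), centromere position
*c* (Mb, 0 < c < L), the number of equal scan windows *n* (default 25) and
the feature-window width (default 10 Mb). The default geometry is human
chromosome 1: *L* = 247, *c* = 120. With *n* = 25 the scan windows are
*L*/25 = 9.88 Mb wide — "nominally 10 Mb". Both schemes are supported for
feature binning: fixed 10-Mb windows (⌈247/10⌉ = 25, last window 240–247
Mb) and 25 exactly equal windows; equal-25 is the scan default, fixed-width
the feature default, and the comparison module reconciles them by
resampling (below).

## Ground-truth band model

The simulator's truth is a baseline *b₀* plus a sum of Gaussian bumps, one
per band, parameterised by centre (Mb), full width at half maximum (Mb) and
amplitude. A Gaussian was chosen because the banding is only ever observed
as a smooth intensity profile at ~10 Mb resolution; any smooth unimodal
bump would serve, and the Gaussian has closed-form evaluation. Band widths
in the default 5-band model (FWHM 10–20 Mb, amplitudes 0.45–0.85 on a
[0, 1] intensity scale, baseline 0.05) match the 10–50 Mb scale of observed
bands. `centromere_gap` zeroes band contributions within ±5 Mb of the
centromere (leaving the baseline), emulating the consistently unstained
centric heterochromatin block; the 10-Mb total gap width matches the
centromeric background window used in profile normalization.

## Warp model (differential stretching)

Chromosome arms stretch by different factors during spreading. The warp
maps genomic position to arc-length fraction piecewise-linearly per arm:
stretch factors s_p, s_q scale the two arms, renormalised so pter → 0 and
qter → 1; the centromere lands at f_cen = c·s_p / (c·s_p + (L−c)·s_q). The
map is strictly monotone and analytically invertible, which the rendering
and the anchoring tests both exploit. Across chromatids the pipeline draws
log-normal stretch factors (σ of log-stretch 0.1 by default, i.e. ~±10%
arm-length variation, a realistic spread for cytospun preparations).

## Rendering

A chromatid is a constant-width tube (half-width 7 px) around a smooth
polyline (length 500 px, optional sinusoidal bend), rasterised by
nearest-axis-point lookup: each pixel within the half-width takes the ideal
green intensity of its nearest axis point, the red (DAPI-like) channel a
constant 0.8, plus i.i.d. Gaussian noise (default σ = 0.02) clipped to the
declared [0, 1] intensity range. The blue centromere marker is a 2-px-thick
line perpendicular to the axis at the warped centromere position —
mirroring the manual annotation convention of marking the centromere with a
line of blue pixels before scanning. The image bit depth and background of
real captures are unknown; the float [0, 1] range with these defaults is a
configuration choice, not an inference. Optics are not modelled (no PSF,
no chromatic shift); a real image has structured background, nonuniform
illumination and touching chromosomes that the simulator deliberately
omits, so passing tests demonstrate correctness of the measurement
pipeline, not robustness to every imaging artefact.

## Annotation generators

* **Features** (genes / CGIs / SINEs / LINEs): midpoints drawn from a
  mixture — with probability `coupling` from a density proportional to the
  band model (inverse-CDF on an 8192-point grid), otherwise uniform — then
  expanded to intervals of class-typical length (gene 30 kb, CGI 1 kb,
  SINE 300 bp, LINE 6 kb). `coupling` ∈ [0, 1] therefore dials the window-
  count correlation with the band model from ≈0 to near 1.
* **Signal**: Poisson counts per 100-kb step with expectation proportional
  to the band intensity at the step centre, scaled to a chromosome-wide
  mean depth.
* **Expression**: per-gene Gamma draws (shape 2) with mean
  `base·((1−coupling) + coupling·b̃)` where b̃ is the band intensity at the
  gene midpoint normalised to mean 1 — at coupling 0 the values are
  exchangeable across positions.

Study-condition defaults mirror the quantitative chromosome-1 design: 24
chromatids averaged, 3,071 genes (the chromosome-1 RefSeq count used for
expression summing), coupling 0.9. All generators are pure functions of
(parameters, seed); a master seed expands into named CRC32-keyed
substreams so adding a generator never shifts another's draws.

## Scanning and calibration

* **Axis tracing** replaces the original manual tracking: Otsu threshold on
  the DAPI channel, largest connected component (a second comparable
  component aborts with a segmentation error), `skeletonize`, longest
  geodesic path by double BFS (exact on tree skeletons), cubic-spline
  smoothing (s = 2·n_points), resampling at 1-px arc steps, and extension
  of both ends along the tangent to the tube cap centres using the
  distance transform (discrete skeletons retract ~half-width from rounded
  ends). `provided` mode validates and passes through a manual polyline.
  Orientation (which end is pter) must come from the caller or from
  simulator truth; there is no automatic p/q inference.
* **Perpendicular sampling**: tangents by finite differences on the
  resampled axis; bilinear interpolation at 1-px spacing across the
  sampling width; default width 60% of the measured chromatid width (from
  the distance transform at the axis — "slightly less than the chromatid
  arm" made concrete). Samples falling on the blue marker (blue > 0.25)
  are excluded from the green/red means, since the marker overwrites the
  underlying stain; segments leaving the image are clamped with a logged
  warning, never an exception.
* **Centromere**: argmax of the blue channel; ties resolve to the lowest
  index with a logged warning; an all-zero blue channel is an error.
* **Calibration**: per-arm linear mapping of arc fractions onto [0, c] and
  [c, L]; the centromere segment is set to *c* exactly. Channels are
  normalised as (v / max)·100 — dividing before multiplying so the maximum
  is exactly 100.0 in floating point.
* **Window statistic**: per chromatid, normalized values are *summed*
  within the 25 equal windows (the per-window total-fluorescence
  convention); with near-uniform sampling the per-window mean differs only
  by a constant factor, and `window_stat: mean` exposes it.
* **Averaging**: arithmetic mean and sample SD (ddof = 1; a single
  chromatid reports SD 0) per window across chromatids.
* **Background**: the mean of the window containing the centromere
  (window 12, 118.56–128.44 Mb, for chr1 at 25 windows — the nominal
  "120–130 Mb" window) is subtracted from every window and negatives are
  clipped to 0; SDs are left unchanged; the subtracted values are recorded.
  An explicit window index can override the centromere default.

## Window binning of genomic data

Windows are computed in bp (1 Mb = 10⁶ bp exactly) to avoid float boundary
ambiguity; windows are half-open with the last closed. Interval features
are assigned to exactly one window by midpoint (configurable to start):
at 10-Mb windows the choice is immaterial for kb-scale features, and
midpoint is symmetric. Counts and expression sums conserve totals exactly;
records on other chromosomes are dropped with a logged count. Signal
binning is a length-weighted mean over the window, with uncovered stretches
counting as zero — equivalent to a per-base expansion, which the tests
verify directly on a small chromosome.

## Correlation

Pearson product-moment r with the two-sided p from the t transform on n−2
df (the convention consistent with reported r/p pairs at n ≈ 25 windows);
Spearman is available as an option. At least 3 included windows and
nonzero variance are required; degenerate matrix cells are recorded as
missing with their reason. All 25 windows are included by default —
`exclusions` (and the CLI's `--exclude-centromere`) exist because both
profiles are near zero at the centromere, which inflates r. No multiple-
testing correction is applied to the matrix; a Benjamini–Hochberg column
(`q_bh`, via `scipy.stats.false_discovery_control`) accompanies raw
p-values for transparency. Metaphase (25 equal windows) and 10-Mb tracks
are aligned by length-weighted resampling of the 10-Mb step function onto
the 25-window scheme, recorded on the result.

With n = 25 windows the Pearson estimate is slightly attenuated:
E[r̂] ≈ ρ(1 − (1−ρ²)/(2n)), e.g. ≈ 0.693 at ρ = 0.7. The acceptance
script measures this directly (mean r̂ over 10,000 Gaussian-copula
replicates at ρ ∈ {0.3, 0.7, 0.9}) and the null rejection rate at p < 0.05,
which is nominal because the t-based p is exact under Gaussian tracks.

## Problem sizes and determinism

The shipped demo and the acceptance script use 24 chromatids at 500 px
length, 3,071 genes, 2,000 CGIs, 20,000 SINEs, a 100-kb-step signal track
and 10,000 replicates for the statistic calibration — sizes at which every
documented property is measurable with comfortable margins while the whole
suite runs in well under a minute per stage. TSV floats are serialized at
9 significant digits and no timestamps are embedded, so reruns with
identical config and seed are byte-identical.

## Known limitations

* Single-chromatid images only: no spread-level karyotyping, chromosome
  identification, sister-chromatid pairing or touching-object separation.
* The skeleton-based trace assumes one tube-like object; highly folded or
  crossing chromatids would defeat the longest-path pruning.
* The warp is piecewise-linear per arm; real stretching may be smoothly
  nonuniform within an arm, which calibration then only corrects to first
  order.
* The synthetic noise model (additive Gaussian, flat background) is
  simpler than real microscope noise; coupling between tracks is induced
  only through the shared band model.
* CGI calling, repeat masking and expression normalization are upstream:
  the package consumes their outputs as BED/bedGraph/TSV.
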