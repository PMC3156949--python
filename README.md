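# chromoband

Quantitative analysis of immunofluorescence banding on metaphase
chromosomes, for chromatin biologists who want single-cell, chromosome-scale
maps of histone modifications that can be compared directly with
sequence-derived genomic tracks.

Immunostaining of metaphase spreads (e.g. with antibodies to H3K4me3,
H3K9ac or H3K27ac, detected by FITC, with a DAPI counterstain) reveals
sharply defined bands corresponding to 10–50 Mb genomic segments.
`chromoband` turns such images into calibrated, per-window band profiles
and correlates them against gene density, CpG-island density, SINE repeat
density, interphase ChIP-seq signal and summed gene expression in fixed
genomic windows.

## The method

For a chromosome of length *L* Mb with centromere at *c* Mb (defaults:
chromosome 1, *L* = 247, *c* = 120):

1. **Scanning.** The chromatid's medial axis is traced (automatically from
   the DAPI channel, or from a supplied manual polyline) and, at each axis
   position, pixel intensities are averaged over a segment perpendicular to
   the local tangent, giving per-segment means for the green (immunostain),
   red (DAPI) and blue (centromere marker line) channels.
2. **Calibration.** The centromere segment is the argmax of the blue
   channel. Arc fractions are mapped piecewise-linearly per arm —
   [0, f_cen] → [0, c] and [f_cen, 1] → [c, L] — which corrects the
   differential stretching of arms during spreading, then each channel is
   rescaled to percent of its own maximum.
3. **Binning and averaging.** Each chromatid's normalized values are summed
   within *n* = 25 equal windows (nominally 10 Mb each); windows are
   averaged across chromatids (mean ± sample SD), and the mean of the
   window containing the centromere is subtracted as background (clipped
   at 0).
4. **Genomic tracks.** BED features are counted per fixed 10-Mb window (by
   midpoint), bedGraph signal is averaged per window with length weighting,
   and per-gene expression is summed per window.
5. **Comparison.** Tracks are correlated with the Pearson product-moment
   coefficient, *p* from t = r·√((n−2)/(1−r²)) on n−2 df (two-sided);
   10-Mb tracks are resampled onto the 25-window scheme by length-weighted
   averaging; a full pairwise correlation matrix with Benjamini–Hochberg
   adjusted values is emitted.

Because raw microscope captures of this kind are rarely shareable, the
package includes a first-class synthetic-data module: chromatids are
rendered from a known band model (baseline plus Gaussian bands, with an
unstained centromeric block) through per-arm stretch warps, photometric
noise and bending, and annotation/signal/expression tables are drawn with a
tunable coupling to the same band model — so every pipeline stage can be
validated against ground truth.

## Worked example

Run the shipped demo: 24 simulated chromatids of a 5-band ground truth on
the chromosome 1 geometry, plus coupled annotation tracks:

```sh
chromoband run --config examples/pipeline.yaml --outdir demo_out
```

which prints the recovery of the generating band model by the full
image-analysis pipeline:

```json
{
  "r": 0.9996141032986503,
  "p": 2.641251193361591e-37,
  "n": 25
}
```

i.e. the 25-window mean profile extracted from the rendered images
correlates at r ≈ 1.00 with the generating band model. `demo_out/`
contains the averaged profile (`profile.tsv`: window bounds in Mb, mean and
SD of the summed percent-of-maximum fluorescence over 24 chromatids, green
and red channels), the per-chromatid scans, the simulated BED/bedGraph/TSV
tracks, and the pairwise correlations:

```text
track_a	track_b	r	p	q_bh
metaphase_profile	gene_density	0.985773797	2.56325618e-19	4.14064459e-19
metaphase_profile	cgi_density	0.992798776	1.05498337e-22	3.16495011e-22
metaphase_profile	sine_density	0.994019817	1.25273247e-23	4.38456363e-23
metaphase_profile	interphase_signal	0.995823045	2.03854448e-25	1.07023585e-24
metaphase_profile	expression	0.973160867	3.56789609e-16	3.94346409e-16
```

With the demo's coupling of 0.9, the image-derived profile correlates
strongly with every coupled genomic track — the synthetic analogue of the
agreement between metaphase band intensity and gene/CGI density,
transcription and interphase signal. Individual stages are available both
as library functions (`render_chromatid`, `trace_medial_axis`,
`scan_profile`, `calibrate`, `bin_profile`, `count_features`, `bin_signal`,
`sum_expression`, `correlate`, …) and as CLI subcommands
(`simulate`, `scan`, `aggregate`, `bin-features`, `bin-signal`,
`bin-expression`, `correlate`, `run`).

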