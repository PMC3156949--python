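# Demo pipeline: 24 chromatids of a 5-band ground truth on the chr1
# geometry, with coupled annotation/signal/expression tracks.
# Run with:  chromoband run --config examples/pipeline.yaml --outdir scratch/demo
spec:
  name: chr1
  length_mb: 247.0
  centromere_mb: 120.0
  n_scan_windows: 25
  feature_window_mb: 10.0
bands:
  baseline: 0.05
  centromere_gap: true
  gap_halfwidth_mb: 5.0
  bands:  # [center_mb, fwhm_mb, amplitude]
    - [20.0, 18.0, 0.55]
    - [60.0, 12.0, 0.75]
    - [95.0, 10.0, 0.45]
    - [155.0, 20.0, 0.85]
    - [205.0, 14.0, 0.60]
n_chromatids: 24
noise_sd: 0.02
bend_amplitude: 6.0
warp_sd: 0.1
window_stat: sum
background: centromere
n_genes: 3071
n_cgi: 2000
n_sine: 20000
coupling: 0.9
mean_depth: 50.0
seed: 0
outdir: chromoband_out
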