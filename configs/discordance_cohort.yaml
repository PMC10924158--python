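# Default cohort configuration demonstrating task-agnostic vs task-based
# discordance for fixed-fraction SUVmax thresholding.
#
# The population and scanner presets put the true tumor boundary between
# the 40% and 50% SUVmax isocontours for a typical case: noise inflates
# the observed SUVmax, pulling the 50% contour inside the true boundary
# while the 40% contour stays outside it. Under exact simulated truth the
# 40% threshold then matches or beats the 50% threshold on mean Dice
# while carrying the strictly larger ensemble normalized MTV bias - the
# same inversion the task-based evaluation is designed to expose.
cohort:
  n: 50
  seed: 123
  population:
    diameter_median_mm: 19.0
    diameter_log_sd: 0.3
    diameter_range_mm: [12.0, 45.0]
    tumor_suv_median: 9.0
    tumor_suv_log_sd: 0.25
    background_suv_range: [0.6, 1.1]
    texture_fraction: 0.15
  scanners:
    - scanner_id: scanner_sharp
      psf_fwhm: [6.5, 6.5, 6.5]
      noise_sd: 0.45
      voxel_spacing: [3.0, 3.0, 3.0]
      grid_shape: [64, 64, 48]
    - scanner_id: scanner_blurry
      psf_fwhm: [8.5, 8.5, 8.5]
      noise_sd: 0.45
      voxel_spacing: [4.0, 4.0, 4.0]
      grid_shape: [64, 64, 48]
algorithms:
  suvmax_fractions: [0.4, 0.5]
evaluation:
  pairs:
    - [suvmax40, suvmax50]
  roi_margin: 8
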