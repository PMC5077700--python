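# Experiment configuration schema (YAML). Any omitted key takes the package
# default; unknown keys are rejected with an explicit error.
experiment: contrast_sweep      # one of: onset_quench, contrast_sweep,
                                # orientation_sweep, aperture,
                                # sa_ea_divergence, correlation_structure
seed: 1                         # master seed; fixes every random draw
scale: desk                     # desk | figure (figure = larger samples)
out: results/contrast_sweep     # report directory (optional)

n_trials: 200                   # repeated trials per stimulus condition
low_contrast: 0.25              # RMS amplitude relative to rms_max
high_contrast: 1.0
spatial_frequency: 3.0          # cycles per patch

model:                          # generative-model overrides (all optional)
  patch_side: 24
  pixel_noise_var: 1.0
  contrast_shape: 2.0           # Gamma shape k
  contrast_scale: 2.0           # Gamma scale theta
  basis:
    orientations: [0, 15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165]
    phases: [0, 90]
    frequencies: [3.0]
  prior_cov:
    mode: parametric            # parametric | identity | explicit
    length_scale: 0.8

encoding:                       # response-model overrides (all optional)
  alpha: 0.8                    # membrane compression exponent
  gain: 40.0                    # Hz
  threshold: 0.6                # membrane units
  beta: 2.0                     # rate exponent
  sample_interval: 20.0         # ms per independent posterior sample
  trial_duration: 400.0         # ms
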