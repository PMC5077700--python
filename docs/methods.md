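# Methods

## Model

`v1sampling` implements a Gaussian scale mixture (GSM) observer model of V1
and the hypothesis that population activity is a sequence of stochastic
samples from the observer's posterior over image features.

**Generative model.** An image patch `x` (flat vector of `patch_side²`
zero-mean gray levels, row-major, origin top-left) is generated as
`x = z·A·y + ε`, with `ε ~ N(0, σx²·I)`, feature activations
`y ~ N(0, C)` and a single global contrast scalar `z ~ Gamma(k, θ)`
(shape–scale). Columns of `A` are unit-norm Gabor filters.

**Inference.** Conditioned on `z` the posterior over `y` is Gaussian with

```
Σ(z) = (C⁻¹ + z²/σx²·AᵀA)⁻¹        μ(z,x) = z/σx²·Σ(z)·Aᵀ·x
```

(the likelihood precision is `z²/σx²·AᵀA`, which fixes the division by
`σx²` in the mean). The contrast posterior
`P(z|x) ∝ Gamma(z; k, θ)·N(x; 0, z²ACAᵀ + σx²I)` is evaluated in log space
on a 400-point log-spaced grid spanning the central `1 − 10⁻⁶` mass of the
Gamma prior; if the posterior mode lands near the upper edge the grid is
re-spanned up to 4× further (at most four times). Grid masses use
trapezoid weights with max-subtraction normalization. `P(y|x)` is the
grid-weighted Gaussian mixture; its moments follow the law of total
variance. All per-`z` linear algebra reduces to diagonal operations after
two symmetric eigendecompositions computed once per model (`ACAᵀ` in pixel
space for the evidence; the whitened Gram `LᵀAᵀAL`, `C = LLᵀ`, in feature
space for `Σ(z)` and sampling). An independent importance-sampling
integrator (contrast particles from the prior, stacked-Cholesky likelihood
evaluation, direct matrix inverses) serves as a cross-check only and shares
no code with the grid path; results with effective sample size below 10 are
flagged unreliable.

The contrast variable is treated as a nuisance: it is marginalized during
inference and never mapped to a recorded quantity. Its posterior is exposed
for diagnostics (e.g. the aperture analysis below).

**Encoding.** Each 20 ms bin of a trial holds one independent posterior
sample (the assumed autocorrelation timescale of V1 membrane potentials).
Membrane potentials are `u = sign(y)·|y|^α` (dimensionless; no millivolt
calibration is attempted), instantaneous rates
`r = m·(u − u_th)₊^β` in Hz, and spike counts integrate `r`
deterministically: the cumulative expected-spike integral per unit is
offset by an independent uniform-[0,1) phase, and the count is the number
of integer crossings. Counts are therefore sub-Poisson for constant rates;
all structured count variability originates in posterior sampling.
For stimulus sequences the posterior is recomputed per frame, and frame
durations must be multiples of the 20 ms sampling interval.

## Default parameters and calibration

The defaults define the study conditions used by every packaged experiment
and test. Values the source theory leaves open are chosen once, as follows.

| parameter | default | rationale |
|---|---|---|
| patch side | 24 px | dense covariance algebra stays cheap on one CPU |
| basis | 12 orientations × 2 phases × 1 frequency (3 cyc/patch) × 3 centers = 72 Gabors | dense orientation coverage gives a diverse population with no overrepresented feature; a coarser (6-orientation) bank induces a common population drive under grating sweeps that inflates the mean signal correlation an order of magnitude |
| Gabor envelope | σ = 0.45 × wavelength | ~1 octave bandwidth |
| centers | patch center ± 6 px diagonally | the two surround groups sit outside a 7 px classical-receptive-field aperture around the center group |
| prior C | unit variances, correlation `exp(−d²/0.8²)` on a normalized Gabor-parameter distance (orientation /45°, phase /90°, log₂ frequency, center distance /6 px); off-diagonals shrunk toward zero if needed for positive definiteness | self-contained stand-in for a natural-image fit: nearby features co-activate; 0.8 balances a structured spontaneous state against conditioning |
| σx² | 1.0 | pixel noise of the same order as single-filter contributions |
| k, θ | 2, 2 | conventional shape–scale reading; heavy-tailed contrast |
| contrast-1.0 grating RMS | 1.25 | places the inferred z of a full-contrast grating (~4) inside the generative prior's own contrast range, i.e. the stimulus is as strong as a typical "natural" patch; the blank-to-high-contrast membrane-variance quench is then ≈2× |
| α, m, u_th, β | 0.8, 40 Hz, 0.6, 2 | weak compression (α<1); standard rectified power law with quadratic exponent; gain and threshold give spontaneous rates of a few Hz and evoked rates of tens of Hz |
| trial length | 400 ms (20 bins) | typical of the emulated protocols |

An optional estimator (`fit_prior_cov`) recovers `C` from a patch ensemble
by pseudo-inverting the marginal covariance identity
`Cov[x] = E[z²]·ACAᵀ + σx²I`, with eigenvalue flooring.

## Stimuli

Gratings are zero-mean sinusoids whose RMS amplitude is
`contrast × rms_max`; drifting gratings advance phase per 20 ms frame.
Orientation flips by 180° equal phase negation under the cosine convention.
Apertures are discs (hard-edged by default, optional raised-cosine taper);
block noise is ±amplitude in square blocks. "Natural" input is emulated by
the adapted surrogate ensemble — fresh samples from the model's own
generative process — which is exactly the condition under which the
prior/average-posterior identity holds.

## Experiments

Six experiments reproduce the model-side variability phenomenology; all
are deterministic given a master seed, and all report directional checks.

- **contrast_sweep / onset_quench** use drifting gratings (one cycle per
  trial). Static-phase gratings were rejected because absolute phase
  alignment with the basis makes the mean-matched Fano comparison
  degenerate (the matched point set reduces to threshold-straddling units).
  Membrane variance is across trials and bins; mean-matched Fano compares
  blank vs. low vs. high contrast (and pre- vs. post-onset windows).
- **orientation_sweep**: 12 orientations at two contrasts, 200 trials.
  Mean matching across all 12 conditions; tuning half-width at half-height
  (baseline = curve minimum, circular linear interpolation around the
  peak) compared across contrasts.
- **aperture**: one surrogate movie (120 frames × 20 ms) shown full-field
  and masked to a 7 px CRF disc (taper 2 px — at this pixel-noise level a
  hard edge itself acts as broadband contrast and corrupts the inferred-z
  comparison). Reliability (mean pairwise across-trial correlation of
  membrane traces) and lifetime sparseness cover the whole population,
  including surround units driven only under the full aperture, as in the
  emulated recordings; separation angles are restricted to center-group
  pairs ("overlapping CRFs"). Significance by paired bootstrap over
  units/pairs.
- **sa_ea_divergence**: spontaneous activity (SA) is 4000 bins of
  blank-stimulus spiking; average evoked activity (aEA) pools 1500 images ×
  3 bins (many short presentations minimize the within-image cluster bias
  of the plug-in estimator). Words are the joint on/off patterns of 6
  co-located units (the center group — an electrode-array-like cluster
  whose genuine correlations give the shuffle control its teeth), with
  pseudo-count 1. Divergences are compared against the split-half floor of
  SA by a paired bootstrap (images resampled at the image level, SA at the
  bin level); "indistinguishable" means the 2.5th percentile of
  KL − baseline is ≤ 0. The shuffle control circularly shifts each unit's
  spike train.
- **correlation_structure**: 25 orientations × 2 phases at full contrast,
  60 trials, plus blank trials; per-pair signal, noise and spontaneous
  correlations (Pearson throughout; undefined pairs excluded, never
  zero-filled) and their pairwise relations with bootstrap p-values.

## What the synthetic data does and does not emulate

The surrogate ensemble realizes a perfectly adapted observer: every
adapted-stimulus result (prior/average-posterior matching, the SA–aEA
match) is tested in its idealized form. Real images would introduce model
mismatch, and real recordings add slow state fluctuations, adaptation, and
measurement noise, none of which are modeled; passing tests show the
sampling mechanism produces the claimed signatures, not that a fitted model
would reproduce their measured magnitudes. Two quantitative residuals are
known and documented:

- the blank-stimulus posterior is not exactly the prior (the inferred
  contrast at blank is small but nonzero), leaving a ~13% covariance
  deficit; this is why the SA-vs-baseline divergence comparison, while
  passing at typical seeds, is statistically marginal.
- tuning half-width is not contrast invariant in this instantiation: at
  contrast 0.25 inference operates in the prior-smoothed regime (broad
  tuning ∝ CAᵀx), at contrast 1.0 in the explaining-away regime (narrow
  tuning ∝ pseudo-inverse). Invariance would require the low-contrast
  stimulus to remain in the resolved regime, which under the single desk-
  scale calibration that the variability and correlation results need is
  not the case. The corresponding check is reported honestly as failing.

## Verification design

The analytic integrator is validated against the independent importance
sampler on random small models (moderate-contrast images keep the
prior-proposal sampler's effective sample size high enough that its own
Monte-Carlo error stays below the 2% comparison band). The
prior/average-posterior identity is checked over 2000 surrogate images
with two exact variance-reduction devices available in simulation: the
signal covariance enters through the cross moment `E[μyᵀ]` (equal to
`E[μμᵀ]` by posterior-mean orthogonality) and the sample covariance of the
known generating latents is used as a regression control variate (its
expectation is exactly `C`). The plain estimator's sampling floor at this
`n` (~9% for 72 units, scaling as `1/√n`) would otherwise swamp the 5%
comparison.

## Numerical notes

- Evidence and grid masses in log space; `z²λ + σx²` evaluated per
  eigenvalue, never as explicit matrix inverses.
- Mean matching bins pooled means into 10 common bins, discards uniformly
  at random down to the per-bin minimum occupancy, and averages over 50
  re-matchings; undefined Fano points (zero mean) are excluded before
  matching.
- Half-width estimation unwraps the circular orientation axis around the
  peak and interpolates linearly; flat curves and curves that never fall
  to half height return NaN and are excluded.
- Degenerate inputs: zero-variance units are flagged NaN in correlation
  and reliability analyses; all-zero units NaN in sparseness; empty
  parameter lists, non-divisor block sizes, frame/bin misalignment and
  non-PD covariances raise typed errors.

## Limitations

Single fixed basis (no learning), single contrast scalar (no spatial
contrast field), no hierarchy, no temporal dynamics beyond independent
20 ms samples, spike timing undefined within bins. Desk-scale population
sizes (72 units, tens of trials) are an order of magnitude below the
emulated datasets; the `--scale figure` presets increase trial and sample
counts but not the basis size.
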