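# glidertex

Local image statistics seen through a 2×2 pixel glider, the psychophysics
of texture segmentation, and the efficient-coding model that links them.

## The scientific problem

Early visual cortex is sensitive to local multi-point correlations of
light — the building blocks of edges, lines and texture.  A complete,
translation-invariant parametrization of the correlations visible through
a 2×2 window of a binary image has ten coordinates: one first-order
(γ, luminance), four second-order (β|, β−, β\, β/ — vertical, horizontal
and the two diagonal pair correlations), four third-order (θ, the
L-shaped triples) and one fourth-order (α, the full 2×2 product).  After
median binarization γ is pinned near zero, leaving a nine-dimensional
space.

`glidertex` implements, for researchers in natural scene statistics and
visual psychophysics, both sides of a single quantitative question —
*does the variability of these statistics across natural images predict
human sensitivity to them?* — plus the normative model that explains why
it should:

* **Image side** — preprocess grayscale images (block average N×N, tile
  into R×R patches, whiten the patch ensemble by the inverse square root
  of its average Fourier power spectrum, binarize at the median), reject
  blurred patches with a two-component Gaussian mixture, and summarize
  the 9-D coordinate distribution: standard deviations σₖ, covariance,
  per-plane contours xᵀMx = 1 (eccentricity ε, tilt δ), and principal
  axes grouped into the four symmetry classes SYM/HVI/ROT/DII.
* **Psychophysics side** — 4AFC texture-segmentation sessions along 8
  rays per coordinate plane; Weibull psychometric fits
  FC(x) = ¼ + ¾(1 − 2^(−(x/aᵣ)^b)) with a shared exponent per plane;
  pooled sensitivities sₖ = ⟨1/aᵣ⟩; and the 9-D isodiscrimination
  ellipsoid {c : cᵀQc = 1} by linear least squares through the criterion
  points.
* **Comparison** — normalized overlaps of the σ, ω (ellipse-shape), f and
  F (principal-axis contribution) vectors, with permutation nulls:
  the 23 set-label permutations, random coordinate-label permutations,
  and per-coordinate patch-label shuffles.
* **Efficient coding** — the linear Gaussian channel model with sampling
  (input) and channel (output) noise.  Analytically,
  |Lₖ|² = [−(2+sₖ²) + √(sₖ⁴+4sₖ²/Λ)]/[2(1+sₖ²)]: gain falls as 1/s when
  output capacity limits (whitening) and **rises** as √s when sampling
  noise limits — variance is salience.  Numerically, the 2×2
  information-maximizing filter under a unit output-power budget flips
  from antialigned (whitening) to signal-aligned at total noise 0.5.

A synthetic-data module generates every input the pipeline needs — binary
textures with prescribed coordinates (Pickard-style rollout), white
noise, Gaussian coordinate ensembles, and a simulated Weibull observer —
so the full analysis runs and is tested without external image databases
or human subjects.

## Worked example

Simulate one psychophysical session (4320 trials in the (β−, α) plane)
from an observer with known sensitivities, refit it, and probe the two
efficient-coding regimes:

```python
import numpy as np
from glidertex import psychophysics as pp, synthetic_data as sd, efficient_coding as ec

s = np.array([6, 6, 3, 3, 1.2, 1.2, 1.2, 1.2, 2.5])   # ground-truth sensitivities
observer = sd.ObserverModel(np.diag(s**2), b=2.5)
design = pp.design_session("beta_h:alpha", seed=7)
trials = sd.simulate_observer(design, observer, seed=8)
fit = pp.fit_weibull(trials)
print(f"shared exponent b = {fit.shared_b:.2f}")
print(f"threshold along +beta_h: {fit.thresholds['+x']:.3f} (true 1/6 = 0.167)")
print(f"threshold along +alpha:  {fit.thresholds['+y']:.3f} (true 1/2.5 = 0.400)")

S = ec.random_signal_covariance(np.random.default_rng(0))
low  = ec.optimize_filter(S, Xi=0.1, Sigma=0.1, seed=0)
high = ec.optimize_filter(S, Xi=0.5, Sigma=0.2, seed=0)
print(f"total noise 0.2 -> {low.alignment}; total noise 0.7 -> {high.alignment}")
```

prints

```
shared exponent b = 2.59
threshold along +beta_h: 0.169 (true 1/6 = 0.167)
threshold along +alpha:  0.395 (true 1/2.5 = 0.400)
total noise 0.2 -> antialigned; total noise 0.7 -> aligned
```

The fitted threshold is the stimulus distance at which the observer is
correct 62.5% of the time (halfway between 4AFC chance and perfect); the
recovered values sit within sampling error of the generating
sensitivities, and the optimal linear filter decorrelates the signal at
low total noise but aligns with it — investing gain where variance is —
at high total noise.

A command-line layer mirrors the pipeline stages
(`glidertex extract-stats / analyze / psycho-fit / compare / ec-regimes /
synth`); see `glidertex --help`.

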