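# Methods

This note documents the models, conventions and numerical choices behind
`glidertex`, and what the synthetic-data tests do and do not establish.

## The glider coordinate system

A binary patch (pixels ±1) is scanned with a 2×2 window with corners
A (top-left), B (top-right), C (bottom-left), D (bottom-right).  Only the
(R−1)² windows fully inside the patch are counted — patch boundaries are
real image boundaries, and nothing in the underlying model suggests
wrapping.  The 16-bin coloring histogram, constrained by translation
invariance (single-pixel marginals agree across the two rows and two
columns; the two horizontal-pair and the two vertical-pair marginals
agree), spans a 10-dimensional affine family, verified by rank
computation in `glider_stats.dof_of_constraint_set`.  These 10 degrees of
freedom are parametrized by expectations of pixel products:

| coordinate | product | order |
|---|---|---|
| `gamma` | (A+B+C+D)/4 | 1 |
| `beta_v`, `beta_h` | (AC+BD)/2, (AB+CD)/2 | 2 (edge-sharing pairs) |
| `beta_d1`, `beta_d2` | AD, BC | 2 (diagonal pairs) |
| `theta_tl`, `theta_tr`, `theta_br`, `theta_bl` | ABC, ABD, BCD, ACD | 3 |
| `alpha` | ABCD | 4 |

The glyph-to-corner convention for the third-order coordinates (which
corner each L-shape *omits*) is not forced by anything upstream; we fix
`theta_tl` = ⟨ABC⟩ (omits D), `theta_tr` = ⟨ABD⟩, `theta_br` = ⟨BCD⟩,
`theta_bl` = ⟨ACD⟩ and use it consistently everywhere, including the
symmetry-class spanning vectors.  All rotationally symmetric results
(ranges, rank orders, class structure) are unaffected by this choice.

The inverse map `histogram_from_coords` evaluates
p = (1/16)(1 + Σ coordinate × product) per coloring; probabilities in
[−1e−12, 0) are treated as rounding and clamped, anything lower is a
genuine infeasibility and raises.  The forward/backward round trip is
exact to machine precision for feasible coordinates.

## Preprocessing

Images are optionally mapped to log luminance, log(x + ε) with ε the
smallest strictly positive pixel value of the image set (the default;
results with linear intensities are equivalent for median-binarized
statistics).  Block averaging uses floor division, discarding remainder
rows/columns; patches tile from the top-left corner.  The whitening
filter W(f) = ⟨|F(f)|²⟩^(−1/2) is computed **once per analysis over the
pooled patch ensemble**, never per image; the DC gain is set to zero
(after mean removal the inverse square root is undefined there, and the
subsequent median binarization makes the choice immaterial).
Median binarization ranks pixels with a stable sort and assigns the lower
half to −1, so ties (exactly constant regions) resolve deterministically
in raster order and the output is invariant under any strictly monotone
intensity transform.  Pixel counts are exactly balanced; note that the
first-order coordinate computed over interior windows is only O(1/R)
rather than exactly zero, because boundary pixels enter fewer windows.
`gamma` is retained in output tables for audit and excluded from all 9-D
analyses.

## Blur rejection

The two-component Gaussian mixture is fitted by EM
(scikit-learn, full covariances, 10 seeded restarts, ridge 1e−6·tr/9 on
near-singular covariances).  Blur saturates second- and fourth-order
coordinates, so the in-focus component is the one whose mean has the
smaller Euclidean norm restricted to the four beta and the alpha
coordinates; this rule tracks content, not component order.  Patches are
hard-assigned by posterior responsibility, ties going to in-focus.

## Ensemble summaries

Covariance and standard deviations use the population (n-denominator)
convention; this affects no shape or overlap quantity.  The
positive/negative asymmetry of a coordinate is the ratio of the RMS of
its positive values (about zero) to the RMS of its negative values.

A planar contour xᵀMx = 1 has semi-axes 1/√λ along the eigenvectors of
M, so the major axis belongs to the smaller eigenvalue.  Eccentricity is
ε = √(1 − (b/a)²) — the only form consistent with the quarter-sphere
vector ω = (sin a cos δ, sin a sin δ, cos a), sin a = ε ∈ [0, 1].
Tilt is the major-axis angle in [−π/2, π/2); circles report tilt 0.  The
same routine serves image covariance blocks (precision-matrix contours)
and 2×2 blocks of the sensitivity quadratic Q (isodiscrimination
contours) — the math is identical.

Principal axes of the 9×9 covariance are grouped into the four symmetry
classes — SYM (4-D, invariant under 90° texture rotations), HVI (2-D,
negated by horizontal/vertical mirrors), ROT (2-D, a 90° rotation maps
(v₁, v₂) → (v₂, −v₁)), DII (1-D, negated by a diagonal mirror) — by
largest squared projection, ties toward the earlier class in that order.
If the greedy assignment violates the class dimensions (4, 2, 2, 1), a
capacity-constrained assignment maximizing total projection is used, and
near-degenerate eigenvalue pairs straddling classes are rotated in their
plane to maximize the total class overlap.  Axes are ordered
SYM(1–4), HVI(5–6), ROT(7–8), DII(9), by eigenvalue within class.
Fractional contributions f (per coordinate set) and F (per coordinate)
are squared components of the unit axes and each sum to 1.

The single scale factor aligning standard deviations with sensitivities
is the closed-form least-squares solution c = Σσₖsₖ / Σσₖ²; it weights
high-variance coordinates most.

## Psychophysics

Sessions follow the standard composition: per plane, 8 rays (4 signed
axes, 4 diagonals); on-axis rays at 5 equally spaced magnitudes up to the
per-coordinate gamut maximum (0.45 for the edge-sharing betas, 0.75 for
the diagonal betas, 1.0 for thetas, 0.85 for alpha); oblique rays with
coordinate magnitudes in fixed proportion to those maxima at 2 levels
(fractions 0.4 and 0.8 of the joint maximum).  The published totals (288
trials/block, 4320/plane over 15 blocks, 47,520 per subject over 11
planes) do not pin down the per-condition multiplicities (28 conditions
do not divide 288); our default gives each on-axis condition 8 and each
oblique condition 16 trials per block — divisible by 8, hence exactly
balanced over 4 target locations × 2 trial types — and reproduces every
printed total.  The composition is configurable.

Weibull fits maximize the Bernoulli likelihood of
FC(x) = 1/4 + 3/4(1 − 2^(−(x/a)^b)) (no lapse parameter), first per ray
(stage 1, diagnostics), then jointly per plane with a shared exponent
(stage 2, authoritative).  Rays with all-correct or all-incorrect
responses have unbounded ML thresholds and are flagged, not estimated.
Sensitivities pool 1/a over the two signed rays of a coordinate and over
planes; a flag keeps signed sensitivities separate for asymmetry
comparisons, and another pools rotationally equivalent coordinates.

The sensitivity ellipsoid minimizes Σᵣ(c(Tᵣ)ᵀQc(Tᵣ) − 1)² over the
entries of symmetric Q that the criterion points actually probe (linear
least squares; unprobed cross-plane entries are zero, or tied to their
90°-rotation orbit when rotational pooling is enabled).  Rank-deficient
designs fall back to the minimum-norm solution with a warning.

## Overlap statistics and permutation nulls

Overlaps are scalar products of normalized vectors (any 1/N inside the
norm cancels).  The ω comparison averages plane-wise scalar products of
the quarter-sphere vectors over all 36 planes; f and F comparisons
average over the 9 symmetry-aligned axes.

Null model 1a applies the 23 non-identity permutations of the four
coordinate-set labels to the psychophysical side.  The sets have sizes
(2, 2, 4, 1), so a set-label permutation is not a coordinate permutation:
9-vectors are permuted by broadcasting each moved block as its mean
(exact for pooled psychophysical data, whose within-set entries
coincide), f-vectors are permuted directly, and plane contours are drawn
from the source set-pair's contour class, with one documented fallback —
a within-set plane whose source set is the single-coordinate alpha set
has no within-set contour to inherit and uses the axis-aligned contour
implied by the permuted on-axis sensitivities.  Null 1b samples uniform
permutations of the 9 coordinate labels (i.i.d., with replacement —
exhaustive enumeration is pointless at 9! and impossible for null 2) and
conjugates Q by the permutation so contours and principal axes are
recomputed consistently.  Null 2 shuffles patch labels independently per
coordinate in the image ensemble; it preserves every marginal exactly
(hence never applies to the σ overlap, enforced by an error) and aligns
shuffled plane contours to coordinate axes with
ε = √(1 − σ²_min/σ²_max).

p-values are plain exceedance fractions (count ≥ observed)/n, reported
with the attainable floor 1/n (1/23 for null 1a — the exact fraction, not
rounded); the add-one convention is available behind a flag, default off.

## Efficient coding

The independent-channel gain |L|² = [−(2+s²) + √(s⁴+4s²/Λ)]/[2(1+s²)]
(clamped at 0) encodes a channel exactly when s² > Λ/(1−Λ): this is what
the formula's root gives, and the implementation follows the algebra.
(Some presentations state the critical condition on s rather than s²;
users comparing against such statements should note the square.)  The
small-Λ asymptote is |L|² ~ [s/(1+s²)]·Λ^(−1/2) — equivalently
|L| ~ s^(1/2)Λ^(−1/4) in the sampling-limited window Λ < s < 1 — and the
large-s behavior is |L|² ~ (1/Λ−1)/(1+s²), the whitening law.

For the 2-D model, both the mutual information
I = ½ log det(I + S^{1/2}L′ᵀL′S^{1/2}) (with L′ = D^{−1/2}VᵀL whitening
the output noise N = ΣI + ΞLLᵀ = VDVᵀ) and the power constraint depend
on L only through LᵀL, so the left orthogonal factor of L is an exact
gauge freedom.  We fix the polar gauge — L symmetric — which makes the
filter shape LLᵀ = L² well-defined and reads L as gains along two
orthogonal axes; the optimizer works on the 3 free symmetric components,
projected onto the power-constraint ellipsoid, with BFGS from (default) 8
seeded restarts, objective tolerance 1e−9.  At exactly Σ = 0 a second,
genuine degeneracy appears: any full-rank filter is lossless, since
sampling noise cannot be beaten by filtering, and I = ½ log det(I + S/Ξ)
for every invertible L.  A tie-breaking channel noise of 1e−4 in the
objective selects the Σ → 0⁺ limit optimum (the perturbation expansion
gives gains b² ∝ √g/(Ξ+g) per signal eigenvalue g — the square-root law).
The induced bias in reported tilt is zero by symmetry and in eccentricity
O(1e−4), far below the comparison tolerances.

Matrix shapes (for both LLᵀ and S) use eigenvalues as semi-axes:
ε = √(1 − (g_min/g_max)²), tilt = leading-eigenvector angle in
[−π/2, π/2).  Alignment compares leading eigenvectors of LLᵀ and S with
a 45° threshold; isotropic signals are flagged degenerate and excluded
from regime fractions.  Feasibility requires Σ < 0.5: with d = 2 the
channel noise alone contributes dΣ to the unit power budget.  Random
signal covariances for regime maps have unit trace, uniform tilt, and
eccentricity uniform on [0.3, 0.95] (clearly anisotropic, so alignment is
well defined).  The transition locator splits total noise evenly between
sampling and channel components (Ξ = Σ = t/2, keeping Σ feasible) and
bisects the majority classification over 50 random signals to a width of
0.02; it lands at total noise 0.5.

## Synthetic data

The texture generator is a Pickard-style rollout: seed pixel from the
single-pixel marginal, first row/column from the pair conditionals,
interior pixels from p(D | A, B, C) of the window distribution.  A
top-down left-to-right scan can only create correlations whose product
contains the drawn corner D, so the anti-diagonal pair ⟨BC⟩ and the
D-free triple ⟨ABC⟩ are unrealizable in the raw scan; the generator
transparently generates in the mirror/rotation frame that moves such
components onto realizable corners and transforms the patch back.  With
this dispatch, the construction is exact for the single-coordinate and
pairwise stimulus gamuts exercised in tests; for arbitrary coordinate
mixtures it is approximate, and ensembles are validated by measurement
with a warning at 5 standard errors.  Two feasibility facts matter for
users: a lone edge-sharing pair correlation b with all other coordinates
zero is only a valid window distribution for |b| ≤ 1/2 — the
maximum-entropy texture at larger |b| (independent Markov rows/columns)
carries the induced fourth-order value α = b², provided by
`maxent_texture_coords` — and the θ gamut endpoints ±1 put conditionals
on the boundary of [0, 1].

Coordinate ensembles are Gaussian or two-component mixture draws, with
optional positive skew implemented as a post-hoc scaling of positive
deviations (a crude but sufficient emulation of the heavy positive tails
of natural second-/fourth-order statistics).  The simulated 4AFC
observer inverts the Weibull law for a ground-truth ellipsoid Q* and
exponent b*: P(correct) = 1/4 + 3/4(1 − 2^(−d^b)) at d = √(cᵀQ*c), with
wrong responses uniform over the three remaining locations.

### What the synthetic tests do and do not show

The generators emulate the *structure* of the real pipeline inputs —
prescribed low-order correlations, two-population blur mixtures,
Weibull-governed observers — but not photographic reality: no 1/f²
spectra with scene-specific departures, no luminance nonstationarity, no
subject lapses or learning.  Passing tests therefore establish that the
estimators recover known ground truth under the stated models at the
stated sample sizes; they do not certify the published natural-image
numbers, which depend on the specific image databases and human subjects
and are out of scope here.

## Problem sizes

Default test problem sizes were chosen as the smallest that make the
statistical tolerances comfortable: texture closure at 200 patches of
64², mixture recovery at n = 5000, plane-contour Monte Carlo at
n = 20,000, one full psychophysical plane (4320 trials) for
threshold/ellipsoid recovery, 16–50 random signals per noise point for
regime classification, and 200–500 replicates for p-value calibration.
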