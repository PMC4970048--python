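# Methods

This note records the models implemented in graintex, the conventions and
numerical choices behind them, and what the synthetic fixtures do and do not
establish about real grain images.

## Steerable Gaussian-derivative filtering

Kernels are analytic: the 1-D derivative of the unit-integral Gaussian is
evaluated through the Hermite-type recurrence p₀ = 1,
p_{n+1}(u) = p_n′(u) − u·p_n(u) in the scaled variable u = t/σ, and 2-D kernels
are outer products. Sampling is on the integer grid with half-width
⌈truncation·σ⌉, truncation 4 by default (mass loss < 1e−7, configurable but
floored at 3). Base responses are computed as two 1-D convolutions; equality
with dense 2-D convolution is a tested contract (≤ 1e−10).

Conventions, fixed once and used everywhere:

- x runs along array axis 1 (columns), y along axis 0 (rows); θ is measured
  counter-clockwise from +x toward +y.
- Filtering is *convolution* (kernel flipped), so the order-1 response of a
  unit ramp is +1.
- Boundary handling is mirror padding; all fitted statistics use interior
  pixels only (margin = kernel half-width), so the padding rule never reaches
  the features.
- Responses have period π up to the parity sign (−1)^m per order-m term;
  orientation sampling lives in [0, π).

Steering coefficients are derived symbolically: each term
w·σ^e·∂^i_x∂^j_y is rotated via ∂_x′ = cosθ ∂_x + sinθ ∂_y,
∂_y′ = −sinθ ∂_x + cosθ ∂_y, expanded binomially, and same-order monomials are
collected. Because steering mixes *all* same-order derivative pairs, the base
response set contains every (i, m−i) split of every order present in a
template, not just the named terms. The construction is validated against an
independent oracle — convolution with the analytically sampled rotated kernel —
to ~1e−15 relative error for all six built-in templates, which pins down every
sign convention.

Template constants are implemented exactly as their published values, including
three leading constants whose typography is ambiguous (plausibly dropped
radical signs: −2/π, −3/(4π), −2/(2+π+2cosφ)); a `radical_constants` switch
selects the √ variants. This choice is deliberately low-stakes: a global
rescaling of a template rescales μ̂ and β̂ of the fitted response distribution
and leaves λ̂ untouched (tested), so downstream classification geometry is
unaffected up to feature standardization. T6's wedge angle φ is nowhere
specified; the default is π/2, exposed in config. T5's printed σ-powers are
irregular (σ¹ on one order-2 term, σ² and σ³ split across the order-4 terms)
and are kept as printed.

## Integral-form Weibull model

Density f(x; μ, λ, β) = C·exp(−(1/λ)|(x−μ)/β|^λ) with
C = λ/(2λ^{1/λ}βΓ(1/λ)). Sampling uses the gamma transform
X = μ + S·β·(λG)^{1/λ}, G ~ Gamma(1/λ, 1), S a fair sign, which gives the
moment identity E|X−μ|^λ = β^λ used as a test oracle.

Maximum likelihood minimizes −n log C + (1/λ)Σ|(x_i−μ)/β|^λ by Nelder–Mead
over (μ, log λ, log β) — the log-parameterization enforces positivity without
constraints. Initialization: μ₀ = median, β₀ = standard deviation, λ₀ = 2;
a warm start from a previous fit is supported and used across adjacent
orientations during feature extraction (≈3× fewer simplex iterations; warm and
cold runs agree at the per-mille level, a tested contract). Simplex tolerances
are 1e−8 on parameters and function value, 2000 iterations maximum;
non-convergence sets a flag, never raises. log λ is clamped to |log λ| ≤ 6
inside the objective to keep |z|^λ finite; fits with λ̂ > 10 (the
"regular/multimodal" regime of near-uniform fine grain fields) are reported
with a logged warning, not clamped. Fits are on raw signed responses — the law
is symmetric about μ, so magnitudes would discard no information but halve the
support.

Goodness of fit uses equal-width bins over [min, max] with
⌈2n^{1/3}⌉ bins clipped to [16, 256]; model bin probabilities are density ×
width renormalized over the binned support, so a self-consistent histogram
scores exactly zero. χ² = Σ(h−f)²/f; the KLD is Σ f·log(f/h), the
model-to-empirical direction as published, with a flag for the conventional
direction. Bins with model probability < 1e−12, and zero-empirical bins under
the KLD, are merged into a neighbor; an impossible merge yields NaN rather than
an exception. The fractal-dimension mapping D_f = −3λ is exposed as a pure
formula.

## Feature extraction

For each template and scale the base responses are computed once and steered to
N directions θ_j = (j−1)π/N (N = 60 by default); the Weibull triple is emitted
in (μ, β, λ) order per direction, directions fastest, then scales, then
regions: the global block followed by the subimage blocks of a non-overlapping
2×2 grid in raster order (remainder pixels join the last row/column blocks).
Per template this is |scales|·N·3·(grid+1) = 4500 features at the standard
settings. The scale list is the geometric sequence
[0.5, √2/2, 1, √2, 2] (ratio √2).

The oriented response is computed once on the full image and *partitioned* into
the grid for the local blocks; per-region fits use the region's pixels
intersected with the global interior margin. This reuses the steering work
across regions and avoids artificial mirror boundaries inside the image; the
cost is that a region must retain at least 64 interior pixels at the largest
scale or a size error names it. Identical image and config reproduce the vector
bit-for-bit.

## TPSRC

The thin-plate-spline classifier solves the standard augmented system

```
[[K + ηI, P], [Pᵀ, 0]] · [ψ; ω] = [y; 0],   K_ij = φ(‖x_i − x_j‖),
φ(r) = r² log r (φ(0) = 0),  P = [1 | X],
```

whose side conditions Σψ = 0, Σψx = 0 make the radial part orthogonal to
affine functions (tested to 1e−8). η = 0 interpolates the training labels;
η = "gcv" selects from a log grid 1e−6…1e2 by generalized cross-validation
using the trace of the influence matrix; a singular system triggers an
automatic η bump with a warning. The Green's function is r²log r for every
feature dimension, as published.

## MARSC

MARS regression on the ±1 targets: the forward pass greedily adds reflected
hinge pairs (parent basis × unused variable × observed-value knot) that
maximize the residual-sum-of-squares reduction, evaluated for all knots of a
(parent, variable) pair at once by projecting both candidate columns out of the
current fitted subspace and solving the per-knot 2×2 normal equations in closed
form — degenerate pairs fall back to the better single column. Knot candidates
are the observed data values where the parent is active (minspan 1). The
backward pass deletes one basis function at a time and keeps the subset with
the lowest GCV = (RSS/M)/(1 − C(K)/M)², C(K) = K(d/2+1), d = 3; because the
kept subset includes the unpruned model, pruning never raises GCV (tested).
Defaults: max_terms = min(21, n/2), max_degree = 2 (configurable to 3).
Products use distinct variables per factor.

## COSC-Boosting

Per round: draw M′ = 100 unlabeled samples with replacement; a sample is a
candidate when both classifiers give it the same thresholded label *and* both
refits (classifier retrained with the candidate appended, carrying that
classifier's own virtual target) do not increase the squared error on that
classifier's current augmented labeled set; each classifier's
confidence-maximizer then joins the *other* classifier's labeled set
(cross-teaching — the published pseudocode's self-teaching assignment is
retained behind a switch). Ties resolve to the lowest pool position. Accepted
samples are removed from the reservoir by default (a flag restores literal
with-replacement re-admission). Both classifiers are retrained once per round
after the picks are fixed; the loop exits early when neither labeled set
changed. The final score is the average of the two classifiers, thresholded at
0 with the boundary mapped to −1 ("high quality").

Two design choices matter in practice and are deliberate:

- **Virtual targets are raw scores.** The appended sample carries the teaching
  classifier's regression output h(x̃), not the thresholded ±1. Saturated ±1
  targets at points whose true score is near zero drag the regression surface
  and measurably *degrade* the ensemble; score targets are consistent with the
  current surface and transfer calibrated information. The thresholded variant
  is available as `soft_virtual_labels=False`.
- **The spline must be smoothed.** With a near-interpolating TPSRC the
  confidence rule is degenerate — training scores barely move when one sample
  is appended, so every confidence is ≈ 0 and selection is arbitrary. The
  default η = 10 keeps the refit informative.

Default iteration cap is 10 (each round adds at most one sample per classifier,
so the cap bounds the virtual-label budget at 2×10 samples); the cap and all
classifier options live in `COSCConfig`. One seeded generator drives the pool
draws; per-round sub-seeds are logged in the model history together with every
candidate's confidences, so any run can be audited or replayed.

Metrics: CE_i = mean |ŷ−y|/2 per group × 100%; ACE_RV is the unweighted group
mean, ACE_TS the pooled error; empty groups are dropped with a warning.

## Synthetic fixtures

`generate_granular_image` renders anti-aliased ellipses (~1 px coverage ramp,
needed so derivative filters see smooth sub-pixel gradients; hard edges make
response histograms pathological) with a linear Lambertian-like shading ramp
along the major axis, Gaussian pixel noise, isotropic or concentrated
orientation, and optional non-overlap placement with a bounded-retry error.
It reproduces the qualitative structure the texture model targets — many
locally homogeneous bright fragments on a darker background with edge/shading
gradients — but not real grain optics: no specular highlights, no translucency,
no conveyor illumination gradients, no touching-grain contact shadows. Passing
tests therefore establish the *mechanics* of the pipeline (steerability, fit
recovery, layout contracts, directional sensitivity) and not field accuracy on
any particular product.

`generate_ss_dataset` draws two Gaussian classes at means ±separation·𝟙 with
covariance scale²·I and labels exactly round(label_rate·n) samples per class.
It emulates the scarce-label grading regime; linear separability makes it
easier than real grading, which is exactly what a co-training *mechanism* test
needs (a method that cannot help here cannot help anywhere).

## Benchmark problem sizes

The semi-supervised benchmark uses k = 4, 200 samples per class, separation
0.8 (≈5.5% Bayes error), label rate 10%, M′ = 100, 10 rounds, MARS capped at 9
terms, over 20 seeded replicates — sizes chosen so a full multi-seed run takes
tens of seconds while leaving the plain ensemble clear headroom above the Bayes
floor. At this scale the per-seed co-training improvement is small (a few
tenths of a CE point) relative to seed-to-seed noise (±1–4 points); the
benchmark therefore reports the multi-seed mean, which is non-negative at the
tested conditions, and individual seeds can go either way. Scaling the
unlabeled pool and iteration budget up strengthens the effect but is outside
unit-test runtimes.

## Known limitations

- The MARS forward pass refits coefficients only through the projection
  identity, so its RSS path can differ from a full refit at degenerate knots
  (guarded by the 2×2 determinant tolerance 1e−10 relative).
- TPSRC materializes the full n×n Green's matrix: fine for the co-training
  regime (tens to hundreds of labeled samples), not for n ≫ 10³.
- The Weibull fit assumes a unimodal symmetric response histogram; strongly
  bimodal responses (pure periodic textures) drive λ̂ into the hundreds, which
  is reported honestly rather than clamped.
- Feature extraction cost is dominated by 60·|scales|·(grid+1) simplex fits
  per template (~20 s per template on a 128×128 image at standard settings);
  the steering itself is negligible.
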