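# Methods

`tbm3d` implements three-dimensional transport-based morphometry (TBM): a
generative way to study how the *spatial distribution* of tissue varies
across a cohort of segmented, co-registered tissue-density images, and how
that variation relates to covariates such as age or cardiorespiratory
fitness.

## Model

Every image is treated as a probability density on a common voxel grid
(nonnegative, smoothed, normalized to unit total mass). A population
reference `I0` is the voxelwise (Euclidean) mean of the cohort, itself
mass-normalized. Each subject `I_i` is then represented by the
mass-preserving map `f_i` that rearranges `I0` into `I_i` at minimal
quadratic cost:

    f* = argmin_f  ∫ ||f(x) − x||²  I0(x) dx
    s.t.           det(Df(x)) · I_i(f(x)) = I0(x)

The constraint is the change-of-variables (mass-preservation) equation:
`f` pushes the reference density forward onto the subject density. The
minimizer is the L2 optimal-transport (Monge) map; its displacement field
`u_i = f_i − id` is the subject's transport-domain representation.
The representation is generative: any transport-domain point can be turned
back into an image through the synthesis equation
`I(x) = det(Df⁻¹(x)) · I0(f⁻¹(x))`.

Statistics happen on vectorized, `sqrt(I0)`-weighted displacement fields
(columns of a matrix `D`, mean map `x̄`). The weighting makes the embedding's
Euclidean metric the linearization of the quadratic transport metric. PCA
truncated at 90% cumulative variance gives reduced coordinates `X`; the
direction most correlated with a covariate `v` is the closed-form maximizer
`w ∝ X v` of `wᵀXv / ||w||`. Subject scores are the projections `Xᵀw`;
their Pearson correlation `r` with `v` is the effect size, and a
permutation test (covariate reassignment, direction re-derived every time,
add-one rule `p = (1+b)/(T+1)`, exhaustive enumeration for `n ≤ 7`) gives
inference. An ordinary least-squares slope of scores on the covariate links
covariate units to positions `t` along the direction, so that
`x̄ + t·w` can be synthesized into the image a given increment (e.g. ten
years of age) implies. Confounds are removed from covariates by projection,
`v = y − Z(ZᵀZ)⁻¹Zᵀy`, with an intercept column always appended to `Z`.

## Transport solver

The solver is a deterministic *iterated linearized transport* (Moser /
Dacorogna–Moser) scheme. Writing the pullback `σ = det(Df)·I_i∘f`, the
constraint reads `σ = I0`. A correction `c = id + ∇φ` composed into `f`
changes the pullback, to first order, by `div(σ∇φ)`, so each iteration
solves the elliptic equation

    div(σ ∇φ) = I0 − σ         (zero-flux boundary)

with a conjugate-gradient method preconditioned by a DCT-based Neumann
Poisson inverse, caps the step for diffeomorphism safety, and composes
`f ← f ∘ c`. Because every increment is a gradient field, the accumulated
map inherits the curl-free (Brenier) structure of the true optimal map
without ever differentiating the cost explicitly. A triangular
1D-CDF-matching initialization (`knothe_map`) is available as a warm start
(`SolverParams(init="knothe")`); it is exact for translations,
axis-separable problems and very coarse grids, while the default identity
start proved more robust in near-empty background regions. An optional
augmented-Lagrangian L-BFGS polish on the displacement field (transport
cost + multiplier-corrected constraint penalty + a Jacobian-asymmetry term
that vanishes on gradient maps) can squeeze the final cost; it is off by
default because the Moser solution is already within a few percent of
optimal on the problems this package targets.

Numerical choices that matter:

- **Pointwise constraint residual.** `mp_residual` evaluates
  `||det(Df)·I_i∘f − I0||₁ / ||I0||₁` with trilinear sampling and
  central-difference Jacobians. This pointwise quantity has a
  discretization floor of roughly 0.5–2% when image features live at the
  1.5–2 voxel scale (finer grids push it down). The default tolerance is
  1e-2 for single-map work; the pipeline default is 5e-2 because cohort
  statistics average the per-map discretization error over subjects, and
  phantom cohorts at 24³–32³ sit close to the floor. Chasing the pointwise
  residual far below its floor demonstrably *distorts* maps (the optimizer
  fits interpolation noise), which is why the solver stops once the
  tolerance plus a fixed number of tail-refinement iterations is reached.
- **Background mobility.** Where the density is near its positivity floor
  the map is physically undetermined. Per-iteration corrections are damped
  by `ρ/(ρ + mobility_floor)` so the background stays near the identity
  instead of drifting; low-density *tails* of real structures remain
  mobile (`mobility_floor = 0.002` on mean-one densities).
- **Inversion.** Maps are inverted by a damped Newton iteration on
  `f(g(x)) = x` using the cofactor formula for the local 3×3 solves.
  Voxels whose preimage leaves the grid (possible only in the massless
  boundary region) are excluded from the convergence criterion.
- **Synthesis.** The change-of-variables formula is evaluated with cubic
  spline sampling: trilinear interpolation carries a sign-even error,
  linear in the displacement, that would contaminate the small-increment
  difference images used for localization. Synthesized images are clipped
  to be nonnegative and renormalized to exact unit mass; the
  pre-normalization mass error is kept as a quality metric.
- **Epsilon flooring.** `normalize_mass` adds `1e-6 ×` the mean intensity
  before rescaling so densities are strictly positive, as both the
  triangular matching and the elliptic solver require.
- **Smoothing.** Gaussian smoothing uses `σ = FWHM/(2√(2 ln 2))` with a
  reflective boundary (mass-conserving); the default FWHM is 2.35 voxels.

## Synthetic cohorts

Because suitable structural-MRI cohorts cannot be redistributed, the
`phantom` module generates fully synthetic ones with recorded ground truth:

- **Template**: a three-compartment radial "head" — high-density annular
  shell (cortex analogue), medium core, low-density central cavity
  (ventricle analogue) — smoothed, floored, unit mass. Default grid 64³ at
  2 mm; the test and acceptance suites run 24³–48³ versions of the same
  geometry to keep a full cohort analysis in the minutes range.
- **Planted effect**: the gradient of a radial potential centred on the
  shell, i.e. a ring expansion/contraction mimicking cortical thinning
  with ventricular enlargement. Subject `i` receives displacement
  `s_i · A · E + noise_i`, where `s_i` is the centered covariate scaled by
  half its range, `A` the effect amplitude (default 1 voxel = 2 mm at the
  covariate extremes, matching the sub-millimetre-per-decade scale of
  reported ageing effects), and the noise an independent Gaussian-smoothed
  random vector field (correlation length 6 mm, peak 1 voxel by default).
  Warps are applied by mass-preserving change of variables — not intensity
  interpolation — so each phantom subject's true transport map is known.
  Planting *gradient* fields is deliberate: the optimal map between a
  density and its small gradient-field warp linearizes to that same field,
  making direction recovery a well-posed oracle. A second, fitness-driven
  effect field with a controlled overlap (weighted cosine, default 0.7)
  can be planted to exercise the overlap analysis.
- **Covariates**: age uniform on 58–81 years; VO2 peak on
  12.9–34.7 ml/kg/min coupled to age through a Gaussian copula whose
  latent correlation is pre-warped so the sampled Pearson correlation hits
  the target (default −0.3, a plausible mild coupling; the true value in
  the emulated population is unknown); gender Bernoulli with a 60:112
  ratio; education sampled from the published category frequencies (levels
  2–8). All generation is driven by a single integer seed and is
  bit-reproducible.
- **Atlas**: seeded k-means on the support voxel coordinates, giving a
  Voronoi-like parcellation with every region nonempty (label 0 =
  background).

What the phantoms do *not* emulate: real anatomy, MRI physics,
partial-volume effects, registration error, or non-linear covariate
response. Passing the recovery suites therefore demonstrates that the
pipeline's machinery is correct and calibrated under its own generative
model, not that any particular real-data effect size would be reproduced.

## Regional localization

For a fitted direction, the image at a covariate increment (10 years,
10 ml/kg/min) and the mean image (`t = 0`) are synthesized and compared as
a voxelwise fractional density change `(I_t − I_mean)/(I_mean + floor)`,
with the denominator floored at 1% of the mean intensity. A region's share
of displacement is its integral of |fractional change| weighted by the
reference mass, as a percentage of the all-region total (shares add to
100%). Region-wise agreement between two change maps (age- vs
fitness-driven) uses the Pearson correlation across the region's voxels
with a within-region voxel-permutation null and Bonferroni control at
FWER < 0.05, where the denominator counts only regions with a defined
correlation. Caveat, deliberate and documented: the voxel-permutation null
assumes exchangeable voxels and is anti-conservative for strongly
spatially autocorrelated maps; its calibration is verified under
independent per-voxel noise.

## Model variants in the pipeline

- *Age model*: `v` = age, intercept-only confounding.
- *Fitness model*: `v` = VO2 peak residualized against age, gender,
  education (+ intercept). The report includes the overlap (Pearson
  correlation in transport space, permutation p, shared variance `100 r²`)
  between the fitness and age directions.
- *Interaction model*: `v` = (mean-centered age) × (age-residualized,
  mean-centered VO2 peak), residualized against gender and education.

Transport maps depend only on the images and the reference, so one solved
set is cached and shared by all three models. Reports serialize with
sorted keys; identical configuration and seed give byte-identical JSON.

## Problem sizes and known limitations

The shipped test and acceptance runs use 24³–48³ grids and cohorts of
8–100 subjects; a full cohort analysis at 48³ with 60 subjects completes
in a few minutes on one core. Known limitations: the solver targets
smooth, strictly positive densities with displacements up to a few voxels
(large discrete rearrangements should use the triangular warm start); the
pointwise constraint residual is resolution-limited as described above;
map tails beyond the 5%-of-peak support are determined only up to the
discrete feasibility noise; and permutation inference treats subjects as
exchangeable (no family or site structure).
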