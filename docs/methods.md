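# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `ccmorph`, in the spirit of the methods documentation of
packages like `msprime` or `statsmodels`.

## Problem setting

The package analyses localized shape differences between two groups of
subjects, each represented by a closed planar curve — typically the
boundary of the mid-sagittal corpus callosum (CC) extracted from a binary
segmentation. The pipeline is: boundary extraction → template selection →
rigid pre-alignment → diffeomorphic registration of the template onto every
subject → per-point Jacobian "deformation markers" → pointwise linear
models with permutation inference. A down-sampling scheme for the template
curve accelerates the registration step; its effect on accuracy and on the
group-difference maps is quantified by the evaluation module.

## Curve model and conventions

A curve is an ordered list of `(x, y)` points in pixel units, stored open
(last point ≠ first) with implicit closure. Coordinates follow the image
convention: `x` = column, `y` = row, origin top-left, `y` down. "Clockwise"
means clockwise on screen, which is a **positive** signed shoelace sum
under this convention. All generated and extracted curves are simple
(non-self-intersecting) clockwise polygons.

Boundary extraction is Moore boundary tracing restricted to the border
pixels of the single 4-connected foreground component (foreground pixels
with a background 4-neighbour), starting from the top-left-most border
pixel and walking clockwise. Holes are ignored; multi-component or
border-touching masks are rejected with specific errors. The template of a
cohort is the curve whose enclosed (shoelace) area is closest to the
cohort mean area, ties broken by lowest index.

Rigid pre-alignment is iterative closest point (ICP): centroid translation
initialization, then alternation of closest-point correspondence and the
closed-form rotation-only Kabsch solution. Correspondences project each
moving vertex onto the fixed *polyline* rather than snapping to the
nearest vertex; vertex-to-vertex matching has a tangential discretization
bias of order the point spacing that prevents accurate rotation recovery
on O(60)-point curves. The MSD improvement tolerance is 1e-8 with a cap of
500 iterations — the closest-point residual decays geometrically at a rate
near 0.93 per iteration on our curves, so a 200-iteration cap would stop
visibly short of convergence while 500 reaches residuals below 3e-3 px
across poses up to ±30° and ±20 px.

## Registration model

Registration is LDDMM for curves: the deformation is the time-1 flow of a
time-dependent velocity field

    v_t(x) = Σ_i k_V(x, q_i(t)) α_i(t),      k_V(x, y) = exp(−‖x−y‖²/σ_V²),

with momenta α attached to the moving template points (particle
formulation). The energy is

    J(α) = γ ∫₀¹ ‖v_t‖²_V dt + E(φ₁·C, S),

with the discrete RKHS norm γ Δt Σ_k α(t_k)ᵀ K_V(q(t_k)) α(t_k). The
matching term E is the currents distance: each closed curve is discretized
as segment centers and tangents, ⟨A,B⟩ = Σ_ij k_W(c_i, c_j)(τ_i·τ_j) with a
Gaussian kernel of width σ_W, and E = ⟨A−B, A−B⟩. Currents compare curves
without point correspondences and are insensitive to reparameterization,
which is what permits down-sampling one side only.

Numerical choices:

* **Flow integration**: forward Euler with T uniform steps on [0, 1].
* **Jacobian markers**: the 2×2 Jacobian of the map is integrated along
  each template-point trajectory by the matrix variational equation
  D ← (I + Δt ∇v) D with the analytic gradient of the Gaussian sum; the
  marker is J = det(D) at t = 1. J > 1 is local outward deformation of the
  target relative to the template, J < 1 local inward deformation
  (atrophy). Finite differences are used only in tests, as an oracle.
* **Gradient**: hand-derived reverse-mode (adjoint) sweep through the
  Euler steps; verified against central finite differences to relative
  error below 1e-4 in the test suite.
* **Optimizer**: gradient descent from α = 0 with Armijo backtracking
  (initial step 1.0, shrink 0.5, c = 1e-4). Accepted iterations never
  increase the energy, and registration is fully deterministic — there is
  no randomness anywhere in the registration path.
* **Defaults**: σ_V = 15 px, σ_W = 6 px, γ = 0.01, T = 10, max_iters = 300,
  grad_tol = 1e-6. σ_V is of the order of half the structure size so the
  deformation stays globally coherent; σ_W is of the order of the band
  thickness so the matching term sees sub-band detail; γ is small enough
  that data attachment dominates while keeping the flow smooth. With these
  defaults circle→ellipse and crescent→crescent registrations on 60-point
  curves reach region Dice ≥ 0.99 within 300 iterations.

### Down-sampling acceleration

Down-sampling keeps every f-th point (offset 0). In `template_only` mode
only the template is down-sampled; in `template_and_target` both sides
are. Because all O(n²) kernel sums involve the template points, halving the
template point count cuts deformation-term kernel evaluations by exactly
4× and matching-term evaluations (deformed-auto plus cross terms; the
constant target auto-term is computed once) by at least 2× per energy
evaluation. Kernel-evaluation counters are maintained as a
hardware-independent cost surrogate; wall time is logged in benchmark
tables but never asserted. Markers from a down-sampled template live at the
down-sampled points; the *statistics* (not the markers) are up-sampled back
to full resolution by periodic linear interpolation, mirroring the choice
to interpolate final group-difference results. Interpolating the markers
before fitting would be the alternative; it would smooth the per-point
null distributions and couple neighbouring tests, so we interpolate last.

## Statistics

At each template point k the marker J_k(s) of subject s is modelled by OLS:

    J_k(s) = β_k0 + β_k1·group(s) + a_age·age + a_sex·sex + a_tiv·tiv + ε,

group coded 0/1. The reported effect is −β_k1, so that with the disease
group coded 1 a positive value means local atrophy relative to controls.
The per-point statistic is the two-sided t for β_k1. Inference is by
permutation with max-statistic (single-step Westfall–Young) correction:

    p_fwer(k) = (1 + #{perm : max_j |t*_j| ≥ |t_k|}) / (1 + n_perm),

which controls the family-wise error rate under exchangeability and is
floored at 1/(n_perm+1). Because nuisance covariates are present, the
default permutation scheme is Freedman–Lane: residuals of the
covariate-only reduced model are permuted and the full model refit. Naive
label permutation is available behind a switch and agrees with
Freedman–Lane when covariate effects are absent. The default n_perm is
10,000; calibration tests use 1,000 for speed. The global p is the
corrected p of the largest observed statistic.

The agreement between a full-resolution group-difference map r and an
up-sampled down-sampled map r₁ is summarized by

    overall error = Σ_i (r(i) − r1(i))² / Σ_i (r(i) + r1(i))².

This ratio lies in [0, 1] when r(i)·r1(i) ≥ 0 for all i; with mixed signs
it can exceed 1 and is returned unclipped. A zero denominator raises an
error rather than returning a sentinel.

## Evaluation

Registration accuracy is region Dice: both closed curves are rasterized on
the input grid (a pixel is foreground iff its center is inside or on the
polygon, even-odd rule, boundary tolerance 1e-9) and Dice = 2|A∩B|/(|A|+|B|)
is computed on the enclosed regions; two empty masks have Dice 1. Dice
vectors of two schemes are compared by a two-sided paired Student's t-test;
zero-variance differences return p = 1 with a degenerate flag.

## Synthetic cohorts

The generator emulates mid-sagittal CC boundaries as crescents: an outer
circular arc spanning `arc_span` radians and an inner arc offset inward by
a smoothly varying thickness profile, joined tip-to-tip. The half-thickness
profile is (1−u²)^0.3-shaped with a sinusoidal skew (`bend`), so the band
stays thick until near the two blunt ends — mimicking the genu and
splenium bulbs — and tapers only very close to the tips. Defaults: outer
radius 40 px, thickness 12 px, arc span 3.4 rad, 200 points (tests and
cohort studies use 60 points to keep a single registration near 1.5 s).

Cohorts add, per subject:

* **Global scale**: total intracranial volume ~ N(1.5e6, 1.2e5) mm³ scales
  the shape by (tiv/1.5e6)^(1/3) — a cube-root volume-to-length link,
  arbitrary but documented and configurable. Age ~ N(70, 8) and
  sex ~ Bernoulli(0.5) are drawn as pure nuisance covariates.
* **Atrophy**: for disease subjects the band is thinned by `effect_size`
  (default 0.30) with cosine roll-off over a contiguous arc of
  `effect_width` (default 0.25) of the curve's index parameterization,
  centered at `effect_center` (default 0.5 — the splenium-like end of the
  band, where the index arc wraps around the tip and therefore covers the
  matching outer- and inner-boundary points). Each affected point moves
  toward the band's medial line by effect × roll-off × its offset.
  Placing the default effect mid-body instead would thin only one boundary
  side; the diffeomorphic compression then genuinely lowers J on the
  geometrically adjacent opposite-boundary points, which an index-space
  truth arc scores as false positives even though the marker is behaving
  correctly. The tip-centered default keeps the geometric support of the
  effect and the index-space truth arc identical.
* **Noise**: independent Gaussian radial noise (default SD 1.0 px — about
  the quantization scale of a segmentation boundary) smoothed along the
  curve with a 5-point moving average to preserve simplicity; a subject's
  noise is redrawn up to 10 times if the polygon self-intersects.
* **Pose**: random rotation U(−15°, 15°) and translation U(−10, 10) px so
  rigid pre-alignment is genuinely exercised.

Ground truth is the boolean index arc of the affected points. Recovery
scoring tolerates ±3 points of boundary blur: sensitivity is computed on
the truth arc eroded by 3 points and specificity outside the truth arc
dilated by 3 points.

What the generator does *not* emulate: MRI intensities and segmentation
errors, genuinely 3D anatomy, scanner/site effects, topological variants,
or correlated covariate-shape interactions beyond the global tiv scale.
Passing recovery tests therefore demonstrates that the pipeline detects
and localizes a known boundary-displacement effect under realistic noise
and pose variation — not that it reproduces effect sizes from any clinical
cohort.

Marker-level simulation (`simulate_marker_matrix`) draws J matrices
directly from the linear model (unit mean, tiv and age effects, spatially
smoothed noise, optional group offset on a mask). It exists so the
permutation machinery can be calibrated over hundreds of replicate null
cohorts — 500 replicates of the curve-level pipeline would cost tens of
thousands of registrations, while the FWER property being calibrated
depends only on the marker matrix and covariates, not on how the markers
were produced.

## Problem sizes used in tests and the acceptance script

Cohort-level runs use 60-point curves, 150 optimizer iterations
(convergence-quality spot checks against the 300-iteration default showed
no change in recovery results), 1,000 permutations, and cohorts of 20
(down-sampling benchmark) or 120 (effect recovery) subjects; FWER
calibration uses 500 marker-level null cohorts of 60 subjects. These sizes
are the package's own benchmark conditions; all thresholds were fixed
before the corresponding runs.

## Known limitations

* Forward Euler and plain gradient descent are the simplest adequate
  choices; geodesic shooting and quasi-Newton optimizers would converge in
  fewer iterations but are out of scope.
* The Jacobian marker has the spatial resolution of the deformation kernel:
  effects thinner than σ_V blur across the band, which is intrinsic to the
  marker, not an implementation artifact.
* Curves with very sharp concavities relative to σ_W can register to
  locally folded configurations at aggressive down-sampling factors; the
  per-point Jacobians flag this (J ≤ 0 would fail the diffeomorphism
  check).
* The [0, 1] range of the overall-error summary presumes same-sign maps;
  mixed-sign maps are documented to escape the range.
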