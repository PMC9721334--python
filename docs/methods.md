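# Methods

This note records the models, conventions and numerical choices behind
`fibrilsaxs`, and what the synthetic benchmarks do and do not demonstrate.

## Scattering conventions

Momentum transfer is q = 4π sin(θ)/λ, so a Bragg spacing d appears at
q = 2π/d; the cross-β stacking of 4.7 Å diffracts at q = 2π/4.7 = 1.337 Å⁻¹.
All lengths are Å, all q are Å⁻¹. Intensities are on an arbitrary
(relative) scale throughout: the package makes no absolute-intensity
calibration claims.

The transform pairs used are, in spherical (whole-particle) geometry

    I(q)   = 4π ∫ P_s(r) sinc(qr) dr
    P_s(r) = (r²/2π²) ∫ q² I(q) sinc(qr) dq

and in fibril cross-section geometry (a 2D Hankel pair)

    I_e(q) = 2π ∫ P_c(r) J₀(qr) dr
    P_c(r) = (r/2π) ∫ q I_e(q) J₀(qr) dq

with correlation functions a_s = P_s/r², a_c = P_c/r, normalised to
a(0) = 1. Different texts differ in constant prefactors; these conventions
are self-consistent (forward and inverse are verified against each other in
the test suite) and are pinned down externally by Monte-Carlo
distance-histogram oracles, not by comparison to published curves.

## Forward models

**Solid cylinder.** F(q_x, Z) = V · [2J₁(q_x R)/(q_x R)] · sinc(Z h/2) with
V = contrast·πR²h; removable singularities take their limits. The
equatorial slice (Z = 0) is the Airy pattern of a circular aperture, with
zeros at q_x R = roots of J₁. The isotropic average

    I(q) = ∫₀^{π/2} |F(q sinφ, q cosφ)|² sinφ dφ

is evaluated by Gauss–Legendre quadrature in u = cosφ on [0, 1]
(the integrand is symmetric about the equator). Default order 256;
doubling the order changes I(q) by ≪ 0.1% on the SAXS window for the
benchmark geometries, and the choice is deterministic.

**Debye formula.** I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) with the i = j and
q → 0 terms equal to fᵢfⱼ. Form factors are q-independent constants
(element electron counts when read from PDB, or unit weights): at SAXS
resolution shape dominates and the q-dependence of atomic form factors is
negligible. Above 5000 atoms the pairwise sum switches to a distance
histogram with 0.1 Å bins — the binning corresponds to structure at
q ≈ 60 Å⁻¹, far beyond any window used here. No excluded-volume or
hydration-layer corrections are applied: this is a vacuum calculation, and
the tests compare it only against the package's own analytic and
Monte-Carlo oracles.

**Stacked-layer fibrils.** n copies of a layer translated along +z at a
fixed pitch. The reported model length is n × pitch (one axial repeat per
layer), the conventional bookkeeping for such models — note the coordinate
bounding box spans only (n−1) intervals, so a 30-layer, 4.7 Å model reports
141 Å while its coordinates span 136.3 Å.

## Equatorial recovery and its validity

For a randomly oriented long fibril the spherical average distributes the
planar equatorial transform over shells; multiplying by a factor ∝ q
approximately inverts this. Only the ∝q form is implemented (the exact
disorientation correction is an extension point). Below a floor
q_floor (default 1.5 × the smallest measured q) the corrected curve is
continued linearly to zero at q = 0 — the exact correction departs from ∝q
at very small q, and this continuation is a declared convention rather than
a physical claim; the analysis windows used downstream normally exclude
that region anyway.

The recovery is only meaningful if the measured window contains no
layer-plane intensity. `check_equatorial_validity` flags a fibril as
`valid` when the first layer plane 2π/c lies beyond q_max and the repeat c
is below 25 Å, `boundary` for c in 25–30 Å, `invalid` otherwise.

The ∝q approximation is the dominant systematic of the whole pipeline: for
a 35 Å × 1000 Å cylinder it shifts the recovered a_c zero crossing by about
−2 Å, and band-limiting at q_max = 0.3 Å⁻¹ by about −1 Å, so "70 Å" is
recovered as ≈ 68–71 Å depending on the estimator.

## Indirect Fourier transform

P(r) is expanded in cubic B-splines with uniform knots on [0, d_max]
(default n_basis = 30) and fitted to the intensity through the
geometry-appropriate forward kernel by weighted linear least squares with a
second-difference penalty on the coefficients. Choices that matter:

* **Boundary conditions.** P(0) = 0 is always enforced (the first clamped
  spline is dropped); without it, P(0) ≠ 0 makes a = P/r blow up at the
  origin and destroys the normalisation. P(d_max) = 0 is enforced by
  default — correct for an isolated finite particle — but can be released
  (`constrain_dmax=False`) for systems whose correlations extend beyond
  d_max.
* **Weights.** 1/σ² where measured uncertainties exist. When a profile
  carries no uncertainties, counting statistics are assumed (σ = √I).
  Model intensities span many decades; with literal unit weights the
  residual is blind to everything but the lowest-q points and the fit is
  meaningless.
* **Smoothness weight.** When not given, it is chosen by a deterministic
  discrepancy-style sweep: among 15 log-spaced values (scaled by
  trace(AᵀWA)/trace(DᵀD)), the largest whose weighted residual is within
  1.5× the smallest achievable. On data the basis can represent exactly
  this collapses to minimal smoothing (round-trip recovery of a smooth
  P(r) is accurate to ≪ 1% of peak); when an irreducible misfit dominates
  (e.g. the ∝q approximation error), it buys maximal smoothing at
  negligible cost in fit quality. An L-curve corner search (maximum
  curvature over the sweep) was implemented first and rejected: on
  noiseless forward-model benchmarks the residual–seminorm curve has no
  usable corner and the detector collapses to near-zero smoothing,
  producing oscillatory, ill-conditioned solutions.
* **d_max and the fit window.** When d_max is not given it defaults to
  2π/q_min — the largest correlation length observable given the smallest
  measured q. The cross-section workflow applies the same rule in reverse:
  with d_max fixed, it fits only q ≥ 2π/d_max, because intensity below
  that q is produced by structure the [0, d_max] basis cannot represent
  (for long fibrils, the finite-length ramp; in tissue, long-range
  fibril–matrix correlations) and would only distort the fit.
* Quadrature is trapezoidal on the measured grid; no extrapolation to
  q = 0 is ever performed. The returned P(r) is evaluated on 512 uniform
  points. Singular normal equations are reported with their condition
  number; negative smoothness is rejected.

The **direct** transforms (plain quadrature of the measured window) are
kept as first-class alternatives. For interacting systems
(`interference_correlation_workflow`) the direct route is the *only*
correct one: a finite packing's structure factor carries finite-size
oscillations at periods ≈ 2π/box that no compact-support basis can fit,
while direct quadrature integrates them away. Truncating the window at
q_min = 2π/r_max (default r_max = 300 Å) removes the mean-density forward
scattering; depletion zones then appear as negative correlation and
neighbour shells as positive peaks — the features the analysis is after.

Feature measures: `first_zero_crossing` interpolates the first
positive-to-nonpositive crossing linearly (falling back, when a curve never
crosses, to the largest r below 2% of a(0));`first_positive_maximum`
refines grid maxima with a three-point parabola.

## Scan processing

* Azimuthal averaging bins unmasked pixels uniformly in q between the
  image extremes; σ is the standard error of the bin mean; empty bins are
  dropped. Substrate Bragg peaks are masked as rectangular pixel regions
  carried with the image.
* SAXS/WAXS merging scales the WAXS curve by the least-squares scalar over
  the overlap window and switches curves at the overlap midpoint.
* The cross-β heat map integrates intensity above a straight baseline
  anchored at the window edges, over q = 1.337 ± 0.03 Å⁻¹ by default, and
  clips negatives to zero. Anchored baselines make the map exactly
  invariant to adding any q-linear component to every profile, so diffuse
  tissue scattering does not register — only the sharp cross-β excess.
* Background subtraction I = (I_l − I_b) − a(I_t − I_b) fits a in closed
  form (ratio of inner products) over 1.6–2.0 Å⁻¹, unweighted by default
  (a σ-weighted variant is available); σ propagates in quadrature. On
  noiseless inputs constructed with a known a the recovery is exact to
  machine precision.
* Background cells for a candidate lesion are the n (default 5) lowest
  heat-map cells in an annulus of 3–10 grid steps (Euclidean) around it,
  ties broken by distance then row-major index. The annulus radii are a
  convention: near enough to share the tissue environment, far enough to
  avoid the lesion itself.
* Grid bookkeeping is end-inclusive: a raster over an extent E at step s
  has E/s + 1 positions per axis (300 × 400 µm² at 5 µm → 61 × 81 = 4941
  patterns).

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth returned for assertions; all are bit-reproducible given (spec, seed).

* **Counting noise**: Poisson at a given exposure, returned as
  counts/exposure with σ = √counts/exposure. The default scan exposure
  (10⁶ counts per intensity unit) reflects that each 1D q-bin aggregates
  thousands of detector pixels.
* **Tissue diffuse scattering**: a smooth power law (exponent 2.5) plus a
  broad Gaussian band at 1.4 Å⁻¹ (width 0.35 Å⁻¹) — the generic
  disordered-matter band. It is verified featureless at the 1% level
  across the 1.6–2.0 Å⁻¹ fit window, which is what makes the background
  scale fit meaningful. This is a fixture convention, not a quantitative
  tissue model.
* **Substrate**: a flat floor plus sharp Gaussian spikes at fixed q
  (mica-like Bragg peaks).
* **Scan grids**: substrate + tissue·density + (inside planted plaque
  disks) fibril scattering and a cross-β Gaussian peak (σ_q = 0.01 Å⁻¹ —
  the width is a convention; only "sharp" is physically specified).
  Lesions carry a 1.3× denser diffuse component than adjacent tissue, and
  the fibril forward scattering is set comparable to the tissue diffuse
  term at the smallest q — dense plaques are fibril-dominated.
* **Gel packings**: sequential random insertion with hard-core rejection
  in a 4500 Å box (for the default 200 particles this puts the hard-core
  area fraction near 0.48 — dense and liquid-like, as in a concentrated
  gel of 180 Å rods; a dilute box produces no nearest-neighbour shell at
  the mean NN distance). The hard-core diameter is tuned by bisection so
  the realised mean nearest-neighbour distance lands within 2% of the
  target (default 275 Å). Interference is computed in the
  oriented-parallel-rod approximation:
  I_e(q) = |F_eq(q)|² · S(q), S(q) = 1 + (2/N) Σ_{j<k} J₀(q d_jk),
  with no orientational averaging of S.

What passing the synthetic benchmarks shows: the transforms, the
equatorial recovery, the regularised fit, and the scan chain are
internally consistent and recover planted parameters under realistic
counting noise. What it does not show: performance on real detector
artefacts (flat field, polarisation, mica auto-detection), fibrils of
mixed diameter, partially oriented samples, or absolute intensities — all
outside scope. Random sequential insertion is also less ordered than an
equilibrium liquid at the same density, so the gel benchmark's
interparticle peak is broader than a real gel's.

## Benchmark problem sizes

The shipped benchmarks use 600-point q grids to 0.3 Å⁻¹ for cylinder
recovery, 10⁶ Monte-Carlo pairs for histogram oracles, ~1.8 × 10⁴ lattice
points for the Debye cross-check, 21 × 21 synthetic scans, and 5 × 200
particle packings — sizes chosen so the entire suite runs in well under a
minute per module on one CPU while leaving every statistical margin wide.

## Known limitations

* The ∝q equatorial correction is the whole pipeline's accuracy floor
  (≈ 2–3% on recovered diameters at the benchmark geometry); the exact
  disorientation correction is an acknowledged extension point.
* The indirect fit assumes compact support; for interacting systems use
  the interference workflow (direct quadrature).
* Helical selection rules, off-equatorial layer-line modelling, and
  layer-line deconvolution for repeats ≳ 30 Å are out of scope; so are
  excluded-volume/hydration corrections to the Debye calculation.
* The 2π/q_min versus 1/q_min convention for the maximum observable
  correlation length is genuinely ambiguous in the field; the package
  exposes both (any d_max can be passed explicitly) and defaults to
  2π/q_min, asserting neither.
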