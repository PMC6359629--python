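# Methods

Internal units are Å (length), ps (time) and Å⁻¹ (wavevector)
throughout; converters live at the I/O boundary.  This note records the
models, conventions and numerical choices behind each stage, what the
synthetic generator does and does not emulate, and the known
limitations.

## Lamellar X-ray analysis

**Peak finding and integration.**  Bragg peaks are local maxima whose
prominence exceeds `min_prominence` (default 10⁻³) times the curve
maximum.  Orders are assigned by the nearest multiple of the fundamental
spacing, refined by a least-squares slope through the origin; missing
intermediate orders are kept with zero intensity so orders always run
1..N.  Each integrated intensity is the area above a linear baseline
drawn between the endpoints of a ±3σ window around the apex (σ from the
half-height width), with the window clipped at midpoints to neighbouring
peaks.  The ±3σ window plus linear baseline systematically clips ~3% of
a Gaussian peak's area; this loss is uniform across orders, and since
the Fourier synthesis is homogeneous in the intensities it cancels in
every shape-derived quantity (phases, d_HH, normalized profiles).
Sub-grid peak positions come from a quadratic through the three points
around each maximum.

**Spacing and form factors.**  d_z = 2π/s with s the through-origin
regression slope of qₙ on n over nonzero orders.  Form-factor magnitudes
use the plain product |Fₙ| = Iₙ·qₙ by default; the Lorentz-style
√(Iₙ·qₙ) is selectable (`ff_convention="sqrt"`), and the choice is
recorded in output metadata.  No absorption or polarization corrections
are applied.

**Phase determination.**  With only one sample (one set of |Fₙ|), sign
assignment is underdetermined without physical input: for any candidate
signs, a band-limited interpolant through the signed values exists, and
smoothness-type objectives on that interpolant in fact prefer all-equal
signs.  The package therefore phases by structural-model fitting, the
standard route for single-humidity bilayer data: every sign assignment
(exhaustive, N ≤ 12) is scored by the least-squares residual of a
constrained bilayer-stack model — head-pair Gaussian at ±h, central core
trough, and a narrow low-density feature at the cell edge z = ±d/2 —
fitted to the signed form factors.  For fixed geometry the model is
linear in its three amplitudes, so each score is a projection; geometry
is scanned over h/d ∈ [0.20, 0.44] (25 steps) and widths
head 2.5–6.5 Å (0.5 Å steps), core {4, 6, 8} Å, edge 1.5–3.5 Å
(0.5 Å steps).  The residual cannot distinguish a global sign flip; the
overall sign is fixed by requiring the reconstructed head-group density
to exceed the density at the bilayer center, with ties broken toward a
negative first order.  On the default model bilayer the correct
assignment wins with a ~1.8× residual margin over the runner-up at 11
orders; below ~6 orders the margin erodes and the result should be
checked against the reconstructed profile's plausibility.

**Reconstruction and geometry.**  ρ(z) is evaluated on a symmetric grid
over [−d_z/2, d_z/2] on the non-negative half and mirrored, making
centro-symmetry exact in floating point; the output is linear in the
signed form factors (an optional flag rescales to max |ρ| = 1 for
display, off by default precisely to preserve linearity).  d_HH is the
distance between the two head maxima flanking the central minimum, each
refined by a local quadratic; d_w = d_z − d_HH exactly.

## In-plane analysis

Azimuthal profiles integrate map cells with |q| in the chosen radial
band into φ bins (default 1°), φ measured from the q_∥ axis.  ⟨cos²φ⟩
weights intensity uniformly in φ — no sin φ Jacobian — which is the
convention under which a uniform profile over [0°, 90°] gives exactly
H = 0.25 and a δ at 0° gives H = 1.  The default integration band
(0.8–2.6 Å⁻¹, 10°–34°) matches common practice for the tail peak of
oriented stacks; analyses of synthetic maps use the full 0–90° range.
Area per chain uses a_L = 8π²/(√3 q_T²) (hexagonal dense packing);
a variant with 3 instead of √3 is selectable for comparison with texts
that typeset the relation without the radical.  At q_T = 1.5 Å⁻¹ the
exact value is 20.2603 Å² (≈ 20.25 with rounded constants).

## Trajectory structural metrics

All pair distances are minimum-image in orthorhombic periodic boxes.
Lipid "distance from glucose" uses the lipid center of mass (unweighted
atom mean) by default, the phosphate as an alternative; a radius of
`None` selects all lipids, which makes the largest-radius point of a
distance-resolved series equal the whole-membrane average by
construction.

* Gauche classification: a 4-carbon dihedral is gauche when it deviates
  from trans (±180°) by more than 60°, i.e. |φ| < 120°; the window is
  configurable.  Dihedral sampling defaults to every 25th frame,
  H-bond sampling to every 50th (both configurable).
* Hydrogen bonds: donor–acceptor distance ≤ 3.5 Å and
  hydrogen–donor–acceptor angle ≤ 30°, counted between water donors
  (optionally glucose) and head-group acceptor oxygens, normalized per
  selected lipid per frame.  Cutoff boundaries are inclusive.
* RDF: 0.02 Å shells up to half the minimum box length, normalized by
  ideal-gas shell counts (self-pairs excluded), so g → 1 for
  uncorrelated particles.  The hydration score is
  g(5.5 Å) − g(4.5 Å) at the nearest bins, positive meaning
  hydrated-like packing; its uncertainty is the quadrature sum of half
  the max–min spread over a six-point window about each position.
* Density profiles: each frame is recentered so the lipid center of
  mass sits at z = 0 (stability against slow drift), electron weights
  (CH₂ 8, terminal CH₃ 9, lumped head beads) are histogrammed in z with
  an odd bin count so one bin is centered exactly on the midplane, and
  normalized by box area × bin width.  The profile integral equals the
  component's total electron weight per box area per frame.
  Interdigitation is the symmetrized core (terminal-methyl) density at
  z = 0.
* Distance fluctuation: per lipid, the standard deviation over frames
  of the phosphate-to-target distance; reported normalized by the mean
  distance (default display) and raw, since the normalization choice is
  a convention.
* Block errors: five contiguous, near-equal blocks; standard error =
  population std of block means / √5.

## Trajectory dynamics

* MSD: coordinates are unwrapped by accumulating minimum-image
  frame-to-frame displacements (valid while nothing moves more than half
  a box per frame), head-group centers are tracked in xy, and the MSD is
  averaged over all time origins via an FFT identity (exactly equal to
  the direct sum).  D_xy = slope/4 by unweighted linear regression.  The
  default window is 20–160 ns when available, else the [10%, 80%] span
  of lags; recovery tests instead fit an early window (10–300 ps at
  1 ps frames) because origin-averaged MSD estimates at lags approaching
  the trajectory length carry few effective samples and dominate the
  variance of a long-window fit.
* Rotational ACF: for carbon window k (1–12, counted from the
  carbonyl-proximal carbon), u(t) is the unit cross product of the two
  bonds around carbon k+1; C(t) = ⟨u(ξ)·u(ξ+t)⟩ is the per-molecule
  (incoherent) P1 correlator averaged over origins, lipids and both
  tails.  Mid-tail windows 4–7 give the most stable fits.  A direct
  origin-sum estimator is used up to 4096 frames and an FFT estimator
  above; they agree to 10⁻¹⁰.  Collinear-bond frames are dropped.
* Integral correlation time: trapezoidal ∫C dt over the sampled span.
  For exp(−t/τ) this converges to τ; for a KWW component to
  (τ/β)Γ(1/β).
* Double-KWW fit: bounded least squares of
  B + A₁exp[−(t/τ₁)^β₁] + A₂exp[−(t/τ₂)^β₂] with τ₁ ∈ [1, 100] ps,
  τ₂ ∈ [0.1, 10] ns, β ∈ (0.05, 1], the baseline tied by
  B = C(0) − A₁ − A₂ (a soft penalty keeps B ≥ 0; an unconstrained
  variant is available).  Exponents are decaying by construction.
  Residuals carry √(Δlog t) point weights so the ps and ns decades
  contribute comparably regardless of grid; R² is reported unweighted.
  Fits multi-start from a log-spaced τ₁×τ₂ grid (9 starts, fixed seed)
  and the best residual wins; τ's are optimized in log space.

## The synthetic generator

The generator matches *statistics*, not physics: no force field, no
energetics, no thermodynamic realism.  Defaults describe a 128-lipid
patch at low hydration (7 waters per lipid, 57.4 Å repeat, lateral
pitch 7.8 Å), a gauche fraction of 0.245 (the fluid plateau of a
hydrated bilayer), D_xy = 10⁻³ Å²/ps (≈10⁻⁷ cm²/s, typical for DMPC),
3 planted H-bonds per lipid, and a double-KWW rotational ground truth
(B = 0.1, A₁ = 0.5, τ₁ = 10 ps, β₁ = 0.6, A₂ = 0.4, τ₂ = 2 ns,
β₂ = 0.9).

* The model density profile is a periodized Gaussian mixture: head pair
  at ±17 Å (width 5 Å), core trough (−0.3, width 6 Å) and a narrow
  low-density inter-bilayer feature at the cell edge (−1.0, width 2 Å).
  The edge feature is what gives a dehydrated stack its alternating
  high-order sign pattern; a heads+core-only profile mathematically
  cannot produce alternating signs beyond the fourth order at this
  geometry (the head term's cosine and a single-signed core term cannot
  change sign order-to-order), which is why the model includes it.
* Reflectivity curves place Gaussian peaks (σ = 0.004 Å⁻¹) of
  integrated area Iₙ = |Fₙ|/qₙ at qₙ, with Fₙ from direct cosine
  integration of the profile — the same product convention the analysis
  applies, so generator and pipeline round-trip by construction.
* In-plane maps paint a Gaussian ring at q_T whose azimuthal mass is a
  uniform + aligned mixture with aligned weight w = (H − 0.25)/0.75,
  deposited per 0.5° bin normalized by the ring cell count of that bin,
  making the analyzed H insensitive to grid pixelation (recovery within
  0.01).
* Trajectories: tail dihedrals are planted by exact count
  (round(target·n_dihedrals) gauche placements, shuffled) and held
  static, so tails are rigid bodies and the time-averaged gauche
  fraction equals the target to within 1/(2·n_dihedrals).  Tail
  orientations perform stationary isotropic rotational diffusion; each
  tail draws a rate λ so the ensemble P1 ACF equals the planted
  double-KWW exactly in expectation: a fraction B of tails is frozen,
  and components A₁/A₂ draw λ = X/τ with X one-sided β-stable sampled
  by Kanter's method (E[e^{−sX}] = e^{−s^β}).  Per-frame rotation
  magnitudes are calibrated through E[cos(s·χ₃)] = (1 − s²)e^{−s²/2};
  rates too fast for a single random rotation per frame (per-step decay
  < 1/3) fall back to full orientation resampling.  Head groups ride a
  planted 2-D Brownian walk; planted H-bond waters (donor–acceptor
  3.2 Å, angle 10°, comfortably inside the cutoffs) and attached
  glucose ride their lipid, so planted geometries hold in every frame.
  Bulk waters sit statically in the slab beyond |z| = 24 Å.  Identical
  specs (including the seed) produce bit-identical output.

What the generator does **not** emulate — and what passing tests
therefore do not show about real membranes: conformational coupling
between dihedral dynamics and rotation (tails are rigid), undulations
and collective modes, realistic head-group chemistry, water dynamics,
glucose exchange between bound and free states, and any
temperature/composition dependence.  Estimator correctness and planted
-parameter recovery are what the tests establish.

## Problem sizes in tests

The suite runs on small instances chosen for seconds-scale runtime:
32-lipid/100-frame trajectories for structural metrics, a
64-lipid/2000-frame (10 ns at 5 ps) trajectory for the rotational
route, 100 walkers × 10⁴ steps for diffusion, and 200-point log-spaced
grids for KWW fits.  Tolerances follow the estimator statistics at
those sizes: gauche ±0.01, D_xy ±5%, curve-route KWW parameters ±10%
(median < 15% over 20 random draws at noise 0.01), trajectory-route
KWW parameters ±25–30% (the finite ensemble of 128 tails and 10 ns span
limit the identifiability of β₂ in particular).

## Known limitations

* Phase determination assumes a "physical" bilayer-stack profile; exotic
  profiles (asymmetric leaflets, strong additive layers) can defeat the
  structural-model scoring, and below ~6 orders the sign assignment is
  weakly determined.
* The product form-factor convention |F| = I·q is the package default;
  where data were reduced with the √(I·q) convention the relative
  profile shape differs, so the convention is echoed into metadata and
  must match between datasets being compared.
* Absolute electron densities (e⁻/Å³ on an absolute scale) are out of
  scope; profiles are relative.
* The H-bond counter is geometric only (no energetic criterion) and
  expects explicit hydrogen coordinates for donors.
* `membrane_geometry` requires a profile with two head maxima flanking
  a central minimum; interdigitated or inverted profiles raise an
  explicit error rather than returning a number.
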