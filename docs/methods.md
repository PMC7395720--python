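# Methods

This note records the model assumptions, the numerical choices behind each
stage, what the synthetic data emulate (and do not), and known
limitations. Nothing here asserts an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Constitutive model

A NITI (nearly-incompressible transversely isotropic) solid has one
isotropy plane (x–y; the lamellar plane) and symmetry axis z. Its Voigt
stiffness has a formally isotropic longitudinal block built from λ and μ,
and a shear diagonal (G, G, μ). Parameters, with defaults used throughout:

| parameter | meaning | default / range |
|---|---|---|
| μ | in-plane shear modulus; E = 3μ in the incompressible limit | fit target, ~10 kPa–1 MPa |
| G | out-of-plane shear modulus; governs surface/guided speeds | fit target, ~5–200 kPa |
| ρ | density | 1000 kg/m³ |
| c_L | longitudinal speed fixing λ = ρc_L² − 2μ | 1540 m/s |
| h | layer thickness | user input (0.55 mm in examples) |
| ρ_f, c_f | bounding water density / sound speed | 1000 kg/m³, 1480 m/s |

λ is never fitted: longitudinal terms barely affect guided-wave behavior
in the nearly-incompressible regime (the acceptance suite verifies the
angular variation of the quasi-longitudinal speed stays ≪ 5%). The
constructor warns below λ/μ = 100 and for G > μ (legal but outside the
layered-tissue regime the model targets).

Young's modulus is computed by inverting the full 6×6 stiffness
(E = 1/S₁₁) rather than assuming 3μ; the closed form
E = μ(3λ+2μ)/(λ+μ) is the test oracle.

## Bulk and surface waves

Bulk speeds come from the 2×2 sagittal Christoffel matrix plus the
explicit SH expression. The Rayleigh problem uses two downward-decaying
partial waves whose vertical slowness ratios q solve the biquadratic

αβq⁴ + (α² + β² − X(α+β) − γ²)q² + (α−X)(β−X) = 0,
α = λ+2μ, β = G, γ = λ+G, X = ρc².

A numerically critical detail: with amplitude vectors (γq, −(α+βq²−X))
the traction rows reduce *exactly* to
σ_zz ∝ q[λ(G−4μ) − 4μ² − αβq² + αX] and σ_xz ∝ λ(q²−1) − 2μ + X.
Without this cancellation, done in exact algebra, the O(λ²) terms destroy
the root at λ/μ ~ 10⁶ in double precision. The root search brackets sign
changes of the (purely imaginary) determinant on a 2000-point grid with a
geometric tail approaching √(G/ρ) (at μ/G = 10⁴ the root sits within
10⁻⁷ of the bound) and refines by bisection.

## Guided-wave dispersion

Four layer partial waves (±q₁, ±q₂) and one downgoing acoustic wave in
the water half-space satisfy five boundary conditions: zero traction on
top, zero shear traction, normal-stress/pressure balance, and vertical
displacement continuity at the bottom. Exponentials are referenced to the
surface each wave decays from, so entries stay bounded at any kh (column
scaling only rescales the determinant). Air above is modeled as vacuum —
its impedance is negligible against tissue.

Roots are sought on the real-k axis as minima of the row-normalized
|determinant| (water-loaded modes are only weakly leaky, and experimental
ridge fitting happens on real (f, k) anyway). Two guards matter:

* **Background-relative acceptance.** At λ/μ ~ 10⁶ the determinant's
  background magnitude is itself ~10⁻¹⁰ (the λ-dominated rows are nearly
  parallel), so an absolute threshold admits noise dips. A refined
  minimum counts as a root only when it is < 10⁻⁶ absolutely *and*
  < 10⁻⁴ × the local scan background.
* **Branch-point rejection.** Where a partial-wave q² vanishes (e.g. the
  whole line c = √(G/ρ)) or the two q² merge, two matrix columns coincide
  and the determinant vanishes without a mode. These points are detected
  from the quartic and discarded.

Tracing scans 800 log-spaced phase velocities per frequency up to just
below min(c_f, c_qL), links roots across frequency by
nearest-velocity continuation with linear extrapolation, and labels the
branch with the lowest low-frequency velocity A0, the next S0 (the
asymmetric water loading makes symmetry labels only "quasi"). A batched
fast path (`_trace_a0_fast`) capped below √(G/ρ) — where A0 is the only
branch — drives the inversion loop at ~10 ms per curve; it agrees with
the robust tracer to < 10⁻⁴ relative.

**A0 plateau and the Scholte speed.** The water-loaded A0 branch
asymptotes to the *Scholte* speed of the tissue–water interface
(0.839·√(G/ρ) at G = μ, rising toward √(G/ρ) at high μ/G), not to the
free-surface Rayleigh speed — verified here against an independently
derived isotropic potential formulation and a direct 3×3 half-space
solve. Consequence: the μ-dependence of the A0 phase velocity at 4 kHz
for the water-backed layer (G = 20 kPa, h = 0.55 mm) is ~10%, larger
than the < 5% spread of the free-surface Rayleigh limits (0.9553 → 1).
The acceptance suite states the < 5% claim for the water-backed
configuration and accordingly reports it as failed; the package computes
and reports the honest value rather than adopting the free-plate setting
that would satisfy it.

## Finite-difference forward model

2D plane-strain staggered-grid velocity–stress scheme; water is an
isotropic "solid" with zero shear modulus, the standard trick that yields
correct acoustic coupling on this grid. Choices:

* **Free surface** on the normal-stress row, with the source's normal
  stress imposed there, the antisymmetric shear-stress image, and the
  surface constitutive update eliminating ∂v_z/∂z through the traction
  condition. A naive one-sided surface update is weakly unstable.
* **Sponge boundaries** (Cerjan-style, 20% of the domain per side,
  bottom only in z) with the damping profile evaluated at *each staggered
  field's own position* — sampling all fields at integer nodes damps the
  half-node fields asymmetrically by half a cell, which seeds a slowly
  growing antisymmetric parasitic mode (found and fixed via a mirror-
  symmetry test; the suite keeps that test).
* **Reduced longitudinal speed.** The explicit time step scales with
  c_L, whereas guided behavior barely depends on λ. The simulation
  stiffness uses c_L = 100 m/s by default (auto-raised to keep
  λ/μ ≥ 100; the fluid bulk modulus is matched to the same speed). The
  grid-convergence test and the FD-vs-analytic ridge test bound the
  resulting bias: the A0 ridge stays within one wavenumber bin of the
  full-c_L analytic branch across 0.5–3 kHz.
* **Resolution.** 20 cells per shortest guided wavelength (40 by
  default for production runs), never coarser than h/8 across the layer;
  CFL fraction 0.5. Default runs use a 16 mm domain for 9 ms — sizes
  chosen so a three-simulation study completes in a few minutes on one
  core; halving the step changes in-band ridge wavenumbers by < 1%
  (tested).
* The temporal super-Gaussian order is 4 (the push is specified only as
  "super-Gaussian"); spatial FWHM 600 μm, temporal FWHM 100 μs.

## Synthetic wavefields (what they emulate, what they do not)

`synthesize_modal` places energy exactly on prescribed dispersion
branches with the source's temporal spectrum and the spatial footprint's
wavenumber response, on OCE-like grids (512 samples at 46.5 kHz × 256
positions at 54.7 μm), with optional additive white Gaussian noise and a
Tukey taper over the outer 15% of the aperture (a hard truncation would
smear ~9% of ridge energy into sidelobes). It reproduces ridge geometry,
bandwidth and SNR — the features the inversion consumes. It does *not*
reproduce near-field effects, mode-conversion amplitude ratios,
geometric spreading, speckle-correlated OCT phase noise, or layer
curvature; passing recovery tests therefore demonstrate correctness of
the estimator given the model, not robustness to every experimental
artifact. The FD solver covers the near-field and multi-mode energy
partition independently.

## Inversion

The objective is the mean normalized spectral power in a 7-bin Gaussian
window (HWHM 1.75 bins, a choice made where only "7-point Gaussian
window" is specified) along the A0 curve traced for the current iterate,
minus reg_weight·(μ/λ) which walls off the degenerate λ → 0 corner
(reg_weight default 10⁻²; its contribution at the optimum is reported in
the fit diagnostics because the μ estimate is known to be
regularization-sensitive). Nelder–Mead runs in (log G, log μ), initial
G₀ = ρc² from the high-band ridge velocity and μ₀ = 3G₀; parameter
tolerance 10⁻³, objective tolerance 10⁻⁴, max 400 iterations. The
isotropic fit is the same machinery with G ≡ μ.

GOF compares the windowed power on the fitted curve with the same window
centered on each column's energy maximum (the best any curve could do),
averaged over columns and clipped to [0, 1] — a perfect fit scores ~1.
A plain windowed-mean/column-max ratio cannot approach 1 for a ridge a
few bins wide, which is why the reference-window form is used.

Estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
utilities such as `clone`.

## Display and visibility conventions

Spectra are column-normalized (max 1 per frequency column above a 10⁻³
noise floor) and viewed on a 20 dB log scale. "A clear second ridge"
means median column-normalized S0 power within 10 dB of the A0 maximum;
"essentially vanished" means below −13 dB. Under these conventions the
finite-difference study at G = 20 kPa gives S0 visibilities of −3.7 dB
(μ = G), −11 dB (μ = 2G) and −19 dB (μ = 5G): a two-ridge spectrum only
in the isotropic case, with S0 effectively gone at μ = 5G.

## Degenerate inputs and numerical edges

* Zero or all-noise spectra raise domain errors before optimization.
* Tracing failures at a simplex iterate score −∞; the simplex retreats.
* Near-degenerate quartics during determinant evaluation re-evaluate at
  k(1 + 10⁻⁶).
* Wavenumbers are cycles/m in every file and spectrum axis, rad/m inside
  the solvers; containers expose both to keep 2π factors explicit.

## Known limitations

* Real-k root finding ignores leaky-mode attenuation; attenuation-based
  fitting is out of scope.
* The layer is flat; corneal curvature (h/R ≈ 5% effects) is not
  modeled.
* Moduli are strain-independent: at high intraocular pressure real
  cornea turns nonlinear/orthotropic, which this model signals only
  through a degraded GOF.
* μ estimates degrade quickly with noise at high anisotropy (tested:
  at 30% noise the μ error distribution dominates G's); confidence in μ
  requires high SNR, and the reported reg-term diagnostic should be
  checked before interpreting μ differences.
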