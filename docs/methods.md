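# Methods

This note records the model, the numerical choices and their rationale, and
what the synthetic phantoms do and do not establish about real MRE data.

## Constitutive model

All materials are Zener (standard linear solid) viscoelastic solids with
shear relaxation `G(t) = μ0 + μ1 exp(−t/τ1)` and a bulk modulus tied to the
shear response through the Poisson ratio, `K(t) = (2/3)(1+ν)/(1−2ν) G(t)`,
i.e. shear and bulk share one loss tangent. Under harmonic excitation at
`ω = 2πf` the complex shear modulus is

    G*(ω) = G′ + iG″,   G′ = μ0 + μ1(ωη1)²/(μ1²+(ωη1)²),
                        G″ = μ1²(ωη1)/(μ1²+(ωη1)²),   η1 = μ1 τ1.

`G′` rises monotonically from μ0 to μ0+μ1; `G″` peaks at μ1/2 at ω = 1/τ1.
The dashpot viscosity is stored implicitly (η1 = μ1τ1) so the parameter set
is minimal and the τ1 = η1/μ1 identity cannot be violated.

Reference materials (the package defaults, used by every shipped study):

| material | μ0 = μ1 | τ1 | ν | ρ | G′(250 Hz) |
|---|---|---|---|---|---|
| gel (background) | 7.5 kPa | 25 ms | 0.499 | 1000 kg/m³ | 15.0 kPa |
| stiff (inclusion) | 15 kPa | 25 ms | 0.499 | 1000 kg/m³ | 30.0 kPa |

These are agarose-gel-like values; ν = 0.499 models near-incompressibility
(K′/G′ ≈ 500). At 62.5 Hz the closed form gives 14.92 kPa for the gel.

## Phantom geometry and excitation

The full-size block is 100 × 70 × 55 mm at 1.25 mm cubic elements (80×56×44
= 197,120 elements). The **default** geometry is a scaled-down
50 × 35 × 27.5 mm block (40×28×22 = 24,640 elements) at the same 1.25 mm
spacing: it preserves the local wave physics (≥ 12 elements per shear
wavelength at 250 Hz for the gel) while one harmonic solve stays below two
minutes and 4 GB on a single core. The full-size block is a one-line config
change (`phantom.size_mm`).

Boundary conditions: all displacement components of the bottom face (z = 0)
are clamped; the nodes of a circular 8 mm patch centered on the x = 0 face
are prescribed the complex displacement (a, 0, 0) with a = 0.5 mm (a
Dirichlet drive, modeling a rigid indenter); every other boundary node is
traction-free. Heterogeneous variants embed a z-spanning circular cylinder
(10/15/20 mm diameter) of the stiff material, elements assigned by the
centroid rule — deterministic and grid-aligned; a body-fitted mesher would
count boundary elements differently, so published element counts for
cylindrical inserts are treated as descriptive, not as a target.

## Forward solver

Trilinear 8-node hexahedra with **selective reduced integration**: the
deviatoric stiffness (weight 2G*) is integrated at 2×2×2 Gauss points, the
volumetric stiffness (weight K*) at the single centroid point. Full
integration locks volumetrically at ν = 0.499; with SRI the 1-D rod
benchmark stays below 2% (ν = 0.3) and 5% (ν = 0.499) error at 20 elements
per wavelength, converging at observed order ≈ 2. The consistent mass matrix
is exact for the tensor-product element (per-axis row sums lump to ρh³/8 per
node). Damping enters only through the imaginary parts of G*, K*; the
dynamic operator K − ω²M is complex-symmetric.

The linear system is reduced by eliminating prescribed DOFs and solved by
sparse LU (SuperLU, MMD_AT_PLUS_A ordering). Factorization runs in
complex64 with complex128 iterative refinement of the residual — two to
three sweeps reach ~1e-11 relative, at roughly half the time and memory of a
double-precision factorization; a double factorization is the automatic
fallback if refinement stalls. Systems beyond ~300k free DOFs fall back to
ILU-preconditioned GMRES (relative residual 1e-8, configurable). A zero
drive short-circuits to the exact zero field. Solves are rejected when the
grid resolves fewer than 8 elements per shear wavelength (configurable; ten
is the usual rule of thumb and the default geometries satisfy it).

## Motion encoding

The MEG is a sinusoid `G(t) = G0 d cos(ωt)` synchronized with the vibration;
over N whole cycles the spin phase is exactly
`θ = γG0N/(2F)·|U·d|·cos(arg(U·d)+φ)`, where φ is the motion phase offset.
A trapezoid quadrature of the defining integral is kept as an independent
cross-check (they agree to 1e-8). Decoding fits
`θ_k = a cos φ_k + b sin φ_k + c` over K ≥ 2 offsets (default K = 4, equally
spaced); the intercept rejects motion-free background phase and is included
when K ≥ 3. The pipeline's "meg" mode encodes/decodes three orthogonal
gradient axes to reassemble the full displacement vector, as multi-direction
MRE acquisitions do; without noise the round trip is the identity to 1e-10.
Phase wrapping is off by default (a wrap option exists; unwrapping is out of
scope), as is any Bloch/sequence-level simulation.

## Inversion (modified integral method)

In a homogeneous region the curl w = ∇×u of any solution of the harmonic
Navier equation satisfies `G*Δw + ρω²w = 0` exactly — the curl annihilates
the pressure/longitudinal term, which is what makes the method insensitive
to the poorly known bulk behavior. The implementation:

1. optional Gaussian mollification of u (σ in meters, truncated at 3σ,
   reflective boundaries) — **off by default**: on noiseless simulated
   fields smoothing only biases the wavenumber. σ = 1 voxel is the
   suggested setting when noise is added;
2. curl by second-order central differences (one-node rim masked);
3. optional mollification of w;
4. 7-point (3-D) or 5-point (2-D) Laplacian (mask grows by one node);
5. per-voxel ratio of Simpson-quadrature integrals over a sliding 3-point-
   per-axis window (3×3×3 in 3-D, 3×3×1 on a slice), points one grid step
   apart by default; a `stride` option spaces them wider to grow the test
   domain toward the half-wavelength guidance without adding points;
6. `G′ = −ρω²Re(num/den)`, `G″ = +ρω²Im(num/den)` — the sign convention
   makes G″ ≥ 0 for decaying waves.

Voxels are masked (not thrown) when a window touches the differentiation
rim, when |den| falls below 1e-8 of the volume maximum (the denominator
cannot vanish in exact arithmetic, but numerics can get arbitrarily close),
or when the recovered storage modulus is nonpositive. A field whose curl is
pure differencing roundoff (e.g. a gradient field) is rejected outright.

Accuracy is limited by the (kh)²/12 bias of the second-order Laplacian: at
exactly 12 nodes per wavelength a plane-wave inversion overestimates G′ by
2.3%, at 16 nodes by 1.3%, converging at second order. The same bias —
partially offset by the opposite-signed FEM dispersion error — sets the
~3% closed-loop error at 250 Hz on the 1.25 mm grid.

Statistics are reported over a region of interest: valid voxels at least 5
voxels from every volume boundary, and (heterogeneous case) attributed to a
material only when all adjacent elements share its label, then eroded 2
voxels away from the interface, where the homogeneity assumption of the
window fails.

## Wavelength estimation

`dominant_wavelength` Hann-windows a 2-D slice, zero-pads ×4, and
peak-picks the radially binned power spectrum (DC excluded) with quadratic
sub-bin interpolation — rotation-invariant by construction. On synthetic
plane waves (e.g. 19.5 mm on a 288 mm field of view) the estimate is
accurate to one refined frequency bin. On the scaled-down default block the
mid-depth slice holds only ~3 wavelengths at 250 Hz and includes the
near-field of the drive patch, so the estimate is biased high by tens of
percent there; treat it as a qualitative check on small windows and size
the field of view to several wavelengths when the number matters.

## What the synthetic studies do and do not show

The phantoms share the solver's discretization with the inversion input:
closed-loop errors therefore quantify the inversion's consistency with the
wave model plus discretization effects, not robustness to acquisition
physics. Not emulated: measurement noise beyond additive complex Gaussian
(`add_noise`, SNR-calibrated, seeded), phase wrapping artifacts, partial
volume effects, body-fitted anatomy, or transient (non-steady-state)
excitation. The 2-D-vs-3-D comparison and the inclusion-contrast results
depend on the specific drive geometry; the qualitative conclusions (2-D
overestimates under oblique propagation, exactly by 1/cos²α for a plane
wave; contrast recovered away from interfaces) are geometry-independent.

## Determinism and seeds

All randomness (field noise, phase noise) flows from the single config seed
through `numpy.random.default_rng`; identical configs and seeds produce
bit-identical reports and artifacts. Noise-free stages are deterministic
regardless of seed.
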