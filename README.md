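# mresim

Closed-loop simulation of **magnetic resonance elastography (MRE)**: forward
time-harmonic viscoelastic wave propagation in voxelized tissue phantoms,
MRI motion-encoding, and recovery of storage/loss modulus elastograms by the
curl-based **modified integral method** — so that inversion accuracy can be
quantified against known ground truth.

MRE measures the displacement field of a shear wave driven into tissue at a
known frequency and infers stiffness from the wave pattern. Validating an
inversion algorithm on in-vivo data is hard because the truth is unknown;
this package closes the loop instead: it *simulates* the experiment on a
phantom whose mechanical parameters are set exactly, then *inverts* the
simulated field and reports the recovery error. It is aimed at researchers
developing or stress-testing MRE inversion schemes.

## Model

Materials follow the **Zener (standard linear solid)** rheology: a spring
μ₀ in parallel with a Maxwell branch (spring μ₁, dashpot η₁ = μ₁τ₁),

```
G(t)  = μ₀ + μ₁ exp(−t/τ₁)                      (shear relaxation)
G′(ω) = μ₀ + μ₁(ωη₁)² / (μ₁² + (ωη₁)²)          (storage modulus)
G″(ω) =      μ₁²(ωη₁) / (μ₁² + (ωη₁)²)          (loss modulus)
K(t)  = (2/3)(1+ν)/(1−2ν) · G(t)                 (bulk, via Poisson ratio ν)
```

The forward solver computes the steady-state complex displacement field
u(x) of `(K(G*, K*) − ω²M) u = 0` on a structured grid of 8-node hexahedra
(selective reduced integration, so ν = 0.499 does not lock), with the bottom
face fixed and a circular patch on one side face driven harmonically.

The inversion exploits that w = ∇×u satisfies `(G′+iG″)Δw + ρω²w = 0` in any
locally homogeneous region — the curl eliminates the pressure term of the
nearly incompressible (modified Stokes) description. Integrating over a
small test domain R gives the **modified integral method**:

```
G′ − iG″ = −ρω² ·  ∫_R |w|² dx  /  ∫_R w·conj(Δw) dx
```

evaluated with 3×3×3-point Simpson windows swept over the volume (3-D), or
with the in-plane scalar curl on a single slice (2-D). The MEG module maps
displacement to spin phase, `θ = γ∫u·G dt`, and back.

## Worked example

```python
from mresim import default_config, run_experiment

report = run_experiment(default_config(seed=1))
for r in report.rows:
    print(f"{r.frequency_hz:6.1f} Hz  true {r.true_storage_kpa:6.3f} kPa  "
          f"3D {r.mean3d_kpa:6.3f} ± {r.sd3d_kpa:.3f} ({r.err3d_pct:.2f}%)  "
          f"2D {r.mean2d_kpa:6.3f} ± {r.sd2d_kpa:.3f} ({r.err2d_pct:.2f}%)")
```

prints (scaled-down 50 × 35 × 27.5 mm gel block, 1.25 mm elements):

```
  62.5 Hz  true 14.923 kPa  3D 14.494 ± 2.215 (2.87%)  2D 23.826 ± 16.130 (59.66%)
 125.0 Hz  true 14.981 kPa  3D 15.245 ± 0.513 (1.76%)  2D 19.822 ± 11.422 (32.32%)
 250.0 Hz  true 14.995 kPa  3D 15.425 ± 0.131 (2.86%)  2D 19.511 ± 7.105 (30.11%)
```

The *true* column is the Zener closed form G′(f) for the reference gel
(μ₀ = μ₁ = 7.5 kPa, τ₁ = 25 ms, ν = 0.499, ρ = 1000 kg/m³). The 3-D
inversion recovers it to within ~3% at every frequency; the single-slice 2-D
inversion systematically overestimates, because out-of-plane propagation
stretches the apparent in-plane wavelength. Embedding a 20 mm cylinder with
doubled spring constants (G′ ≈ 30 kPa) yields an inclusion/background median
contrast of 1.97 (true 2.0).

The same chain is scriptable from the shell:

```
mre report --config run.yaml --seed 1 --out results/
```

with `mre phantom / simulate / encode / invert` exposing the individual
stages (NIfTI label volumes and elastograms, HDF5 complex fields).

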