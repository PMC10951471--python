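# Methods

## The model

A vitrified cryoEM specimen is a liquid film, typically 10–1000 nm
thick, spanning a grid hole and bounded above and below by air–water
interfaces (AWIs). Because creating liquid–gas surface is expensive
(γ_lg = 72 mJ/m² for water), the system lowers its total energy when a
suspended particle replaces liquid–gas area with particle–gas area.
The package books this with three states for the particle population:

| state | total energy Ω |
|---|---|
| bulk | 2 A₁ γ_lg + 2 A₂ γ_ls |
| single adsorption | 2 A₁ γ_lg + A₂ γ_ls + A₂ γ_sg − A₂ γ_lg |
| double adsorption | 2 A₁ γ_lg + 2 A₂ γ_sg − 2 A₂ γ_lg |

A₁ is the liquid surface area of the hole (µm²), A₂ the combined
top-or-bottom area of all particles, and γ_lg/γ_ls/γ_sg the liquid–gas,
liquid–solid and solid–gas surface energies (mJ/m²; energies come out
in fJ since 1 mJ/m²·µm² = 1 fJ). Young's equation
γ_sg = γ_ls + γ_lg cos θ closes the system; at θ = 180° (particle
completely dewetted by the receding surface) γ_sg = γ_ls − γ_lg and
every transition gain collapses to a multiple of A₂ γ_lg:
bulk→single = single→double = 2 A₂ γ_lg, bulk→double = 4 A₂ γ_lg.

Transition gains are computed **only** by subtracting state energies,
never from separately simplified closed forms; the 2 A₂ γ_lg identity
is then a theorem of the implementation and is property-tested over
randomized systems. Favorability is reported as a signed gain; the
package does not assert a sign when γ_lg < γ_ls at θ = 180°.

### Surfactant isotherm

Surfactants depress γ_lg monotonically down to a plateau at the
critical micelle concentration (CMC). The exact functional form between
the endpoints is not constrained by the physics above, so a
Szyszkowski/Langmuir-type curve was chosen:

γ(c) = γ_water − (γ_water − γ_min) · log(1 + c/k) / log(1 + cmc/k),
k = s·cmc, clamped to γ_min for c ≥ cmc.

It is smooth, monotone and hits both stated endpoints exactly; the
shape parameter s (default 0.1) only moves the knee. Shipped surfactant
constants: FFC8 CMC 3.0 mmol/L, DDM 0.17, NP-40 0.3. The plateau values
γ_min (20–30 mJ/m²) are representative of micellar solutions, not
measured constants, and are user-overridable.

## Interface force and screening

Each residue of a chain near the AWI feels a Gaussian-localised force
F_i = q_i A exp(−z_i²/2W²)/(√(2π) W), with q_i its Kyte–Doolittle
hydropathy (−4.5 for Arg to +4.5 for Ile; full 20-residue table
bundled), A the pinning amplitude (model units — no physical unit is
fixed for it) and W the interface width in nm. Positive force pulls
toward the plane z = 0, so hydrophobic residues are drawn to the
surface and hydrophilic ones to the bulk. The kernel is a normalised
Gaussian: the depth-integrated force equals q·A exactly, which is the
tested invariant.

The Debye–Hückel length λ_D = √(ε ε₀ k_B T / Σ n_j q_j²) uses SI
constants with mmol/L → m⁻³ conversion and default T = 298.15 K,
ε_r = 78.4. For standard 1× PBS (137 NaCl / 2.7 KCl / 10 Na₂HPO₄ /
1.8 KH₂PO₄ mM, phosphates at nominal charges, no speciation) it gives
0.73 nm — smaller than a folded domain, which is why the migration
simulator carries no electrostatic term.

## Migration simulator

Particle migration along the film normal is overdamped Langevin
dynamics: z ← z + (D/k_BT) F(z) dt + √(2D dt) ξ, reflecting boundaries
at ±h/2, D from Stokes–Einstein (kT/6πηr; defaults T = 298.15 K,
η = 0.89 mPa·s, r = 2 nm → D ≈ 0.12 nm²/ns). Each interface carries an
attractive well of width w whose depth is the per-particle single-side
adsorption gain, ΔE = 2 a₂ γ_lg,eff(c), with a₂ the per-particle
contact area in nm² (1 mJ/m²·nm² = 10⁻²¹ J ≈ 0.24 k_BT at room
temperature). Surfactant competition enters solely through
γ_lg,eff(c); explicit surfactant particles are not co-simulated.

Numerical choices:

- **Well shape.** The well is flat at −ΔE with a cosine smoothstep ramp
  of half-width w/10 centred on the well edge, so forces are bounded
  and the Boltzmann occupancy of |z| ≥ h/2 − w stays within a fraction
  of a percent of the ideal two-slab partition
  f = 2w e^ΔE / (2w e^ΔE + h − 2w), which serves as the closed-form
  oracle.
- **Integrator.** The Leimkuhler–Matthews averaged-noise update
  (consecutive Gaussian increments shared between steps) replaces plain
  Euler–Maruyama: at the same time step its configurational sampling
  bias is far smaller, keeping equilibrium occupancies within ~1.5
  binomial SE of the oracle at n = 2000 even for 5 k_BT wells.
- **Time step.** dt defaults to the tighter of the noise bound
  √(2D dt) ≤ w/5 and the drift bound D·F_max·dt ≤ r_ramp/2; a
  user-supplied dt whose drift per step exceeds w/2 is rejected.
- **Problem sizes.** Equilibrium checks use n = 2000 particles and a
  60 µs horizon (several box-diffusion times for h = 100 nm), with the
  adsorbed fraction tail-averaged over the last quarter of recorded
  frames.

Seeds are mandatory; a fixed (system, config) pair reproduces the
trajectory stream bitwise.

## CryoET depth analysis

Interface planes are fitted from picked points — exactly through three
points, total least squares (SVD) for more, with the residual RMS
recorded. Coordinates are converted once from voxels to nm via the
pixel size (Å/voxel); point files are 0-based. For a particle between
planes the deviation is 100·|d_top − d_bot|/(d_top + d_bot) with signed
distances along the interior-pointing normals: 0% at the mid-surface,
100% on either interface. This local normalisation handles tilted,
non-parallel planes and is rigid-motion invariant (tested to 1e-9).
Deviations are folded to magnitude; the nearer side is kept as
metadata, ties going to "top" deterministically. Histograms use five
20% bins plus an explicit overflow bin (> 100%) so counts are
conserved; fractions are primary, counts also emitted. ~5-nm slabs at
either interface or the mid-plane are selected by distance along the
plane normal.

`recover_adsorbed_fractions` inverts a profile to adsorbed fractions by
counting the outer band (deviation ≥ 80%, overflow included) and
subtracting the share a uniform bulk population would contribute to
that band; it is exact in expectation when jitter keeps adsorbed
particles inside the band.

## Synthetic scenes

`generate_film_scene` places round(n·f_top) particles at the top plane
and round(n·f_bottom) at the bottom — each displaced into the film by
half-normal jitter so nothing starts beyond an interface — and the rest
uniform in the bulk, optionally rigidly tilting points and planes
together. Defaults: n = 1000, h = 150 nm, lateral extent 800 nm,
jitter 2 nm. Presets mirror a surfactant titration: no_surfactant
(0.55/0.30, broad 33-nm jitter emulating the spread, top-biased film),
ffc8_1to100 (0.30/0.20), ffc8_1to10 (0.10/0.10), ffc8_cmc (uniform),
all with monotonically falling adsorbed totals.

What the generator does **not** emulate: missing-wedge anisotropy,
fiducial markers, picking noise or false positives, particle–particle
exclusion, or meniscus curvature (planes are flat). A passing
round-trip therefore shows the analyzer's geometry and counting are
correct, not that real tomograms meet its assumptions. One known shape
limitation: half-normal jitter is monotone in depth, so no preset can
put more mass in the [60,80) bin than in [80,100]; the no-surfactant
preset lands ≈32%/28% in those bins rather than an inverted ordering.

## Degenerate inputs and tie-breaks

Collinear points (second singular value ≤ 1e-12 of the first) are
rejected in plane fitting; coincident top/bottom planes are rejected in
deviation; zero ionic strength raises rather than returning an infinite
screening length; empty chains, empty models and empty reports are
errors, never silently empty output.

## Limitations

- The three-state energy model is flat-interface, isothermal
  bookkeeping; no meniscus curvature, line tension or temperature
  dependence of γ.
- The simulator is 1-D in the film normal: no lateral dynamics,
  inter-particle interactions, orientation or denaturation kinetics;
  blotting is representable only as a thickness change between runs.
- γ_ls and γ_sg for proteins are not known constants; worked examples
  use illustrative values and all defaults are user-overridable.
- Binary tomography model files are not parsed; convert to ASCII point
  dumps (e.g. with `model2point`) or CSV first.
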