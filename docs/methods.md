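# Methods

This note records the model equations as implemented, the numerical and
design choices that were genuinely open, and what the synthetic test systems
do and do not demonstrate.

## Mean-field non-bonded model

The non-bonded energy is the Helfand functional over normalized species
densities ϕ_K (units: dimensionless, ϕ = 1 at the average density ρ₀ = N/V):

    W[ϕ] = Σ_cells V_cell ρ₀ k_BT [ ½ Σ_KK' χ_KK' ϕ_K ϕ_K'
                                    + ½ κ⁻¹ (Σ_K ϕ_K − 1)² ]

a midpoint discretization of the continuum integral. Two bookkeeping
choices deserve a note:

- **ρ₀ prefactor.** The integrand is written per unit volume of *particle*
  density, so a ρ₀ factor converts the normalized-density expression into an
  energy density. With it, the functional derivative of W with respect to
  the particle density reproduces the external potential with the right
  dimensions; without it the force and energy scales would disagree by ρ₀.
- **kT placement on the incompressibility term.** Published forms of the
  potential differ on whether k_BT multiplies only the χ term or the whole
  bracket. Here κ⁻¹ is dimensionless in k_BT units and one k_BT scales the
  whole potential:  V_K = k_BT[Σ χ_KK' ϕ_K' + κ⁻¹(Σϕ − 1)].  A model file
  wanting the other convention simply rescales κ⁻¹ by 1/k_BT; nothing else
  changes.

Typical values used by the builders: χ of order 10–40 between incompatible
species (positive = repulsive, demixing above roughly χ ≈ 2–4 at this
density), κ⁻¹ = 5 k_BT, which keeps total density fluctuations at the few-%
level (⟨(Σϕ−1)²⟩ ≈ 1/(ρ₀ V_cell κ⁻¹)).

## PIC assignment and the staggered-lattice gradient

Each particle distributes unit weight over the 8 lattice points of its cell
with trilinear (cloud-in-cell) volume-fraction weights — the unique 3D
extension of the 2D area rule. Weights sum to 1 per particle by
construction, so per-species lattice sums equal particle counts to
round-off for any configuration (this is asserted, not assumed).

Density derivatives live on the staggered lattice: the difference
(ϕ_{i+1}−ϕ_i)/h is the natural derivative on the cell face between lattice
points i and i+1. The gradient interpolated at a particle position uses,
for each of the 8 bounding lattice points, the one-sided difference
pointing *into* the particle's cell (forward difference at the low corner
of the derivative axis, backward at the high corner — the same six
forward/backward difference values a stored-gradient table would hold),
blended per axis by the fractional offset with trilinear transverse
weights.

This orientation was the one genuinely open stencil choice, and it was made
for thermodynamic consistency: with it, the interpolated force is *exactly*
the negative partial derivative of the discretized energy W with respect to
the particle coordinate (the two one-sided differences across a cell refer
to the same face value, so the per-axis blend collapses to the in-cell face
difference — the exact gradient of the trilinear interpolant). A centered
or smoothed blend would leave an O(h) inconsistency between force and
energy on rough fields. The consistency is verified against central finite
differences of W; the finite-difference oracle draws probe positions more
than the FD step away from cell faces, because W is only piecewise smooth
in a coordinate and a central difference across a weight-derivative kink is
not a valid derivative estimate.

Two implementations of the gradient are kept deliberately: the production
path computes the six differences on the fly (no gradient array is ever
allocated), and `StoredGradientReference` precomputes all six difference
grids. Both consume identical values in identical accumulation order, so
they agree bitwise — the memory-saving path costs nothing numerically.

Mesh resolution guidance (not enforced): choose cells holding roughly 4–10
particles; the builders and tests use ~8 per cell.

## Parallel contract without parallel hardware

The molecular decomposition scheme is implemented as a deterministic
in-process contract rather than over a message-passing runtime:

- whole molecules are assigned to ranks by greedy longest-processing-time
  balancing on particle counts (molecule index as tie-break), and never
  split — bonded terms therefore never need cross-rank data;
- each rank accumulates a *partial* density field from its own molecules;
  the global field is the sum of partials in fixed rank order;
- scatter/accumulate operations run in particle- or list-order, standing in
  for conflict-safe atomic accumulation: repeated calls are bit-identical,
  and any rank count reproduces the serial field to per-lattice-point
  round-off (≤1e−12, asserted for 1/2/4/8 ranks).

Global observables can be reduced by ordered sequential summation (the
atomic-accumulation analogue) or balanced pairwise tree reduction; the two
agree to ≤1e−12 relative on 1e5-term energy lists, and the pairwise error
bound grows as O(log n) vs O(n), which the suite measures on an
ill-conditioned alternating series.

## Integration, thermostat, units

Velocity Verlet in NVT. Units are GROMACS-like: nm, ps, K, kJ/mol, amu
(so 1 kJ mol⁻¹ nm⁻¹ / 1 amu = 1 nm ps⁻²). Bonded forces are recomputed
every step. Field forces are re-interpolated every step at the new
positions from the *frozen* lattice; the lattice itself is rebuilt only
every `field_update_every` steps (default 100, the low end of the method's
usual 100–500 range). A comparison mode that also freezes the per-particle
field forces between updates is available behind
`freeze_forces_between_updates`.

The thermostat is Andersen: each particle's velocity is resampled from the
Maxwell–Boltzmann distribution with probability ν·dt per step (default
ν = 7 ps⁻¹, dt = 0.03 ps). Andersen was chosen over alternatives because it
samples the canonical ensemble exactly, needs one parameter, and is trivially
seedable; the price — it destroys momentum transport — is irrelevant to the
static/thermodynamic properties tested here. Initial velocities are drawn
Maxwell–Boltzmann when the configuration file carries none. Temperature is
2·KE/(3N k_B) with no constraint or COM correction.

`ForceField` defaults bead masses to 1 amu when a model gives none, but the
builder models set 72 amu per bead (a 4-to-1 mapped coarse-grained bead,
four heavy atoms per bead). This matters: with 72 amu beads, a thermal bead
at 300 K crosses a ~1 nm cell in about 180 steps of 0.03 ps, so a 100-step
field-update cadence genuinely satisfies the quasi-instantaneous
approximation; 1 amu beads at the same dt would cross several cells between
updates and the approximation (and the 0.03 ps step) would be inappropriate.

Degenerate geometry guards: zero-length bonds raise; collinear angles and
dihedrals cap the 1/sinθ (resp. plane-normal) factors at 1e−8 and log a
warning rather than emitting non-finite forces. Non-finite positions or
velocities abort the run with a blow-up diagnostic.

## Bonded forms and parameters

Harmonic bonds ½k_b(r−r0)², harmonic angles ½k_a(θ−θ0)², cosine dihedrals
k_d(1+cos(nφ−δ)); minimum-image displacements throughout, so molecules may
span the periodic seam. These are the common coarse-grained choices; the
builder defaults (k_b = 1250 kJ mol⁻¹ nm⁻², r0 = 0.47 nm, k_a = 25 kJ mol⁻¹
rad⁻², θ0 = π) are generic self-consistent chain parameters, not a
parameterization of any specific lipid. Angle and dihedral lists are
auto-enumerated from the bond graph (all 2-bond paths through a vertex, all
simple 3-bond paths, canonical orientation, lexicographic order); explicit
lists may be supplied instead and override enumeration. Improper dihedrals
are not generated.

## Synthetic systems: what they show and what they do not

The builders produce a monoatomic single-species fluid (uniform random
positions) and a bead-spring lipid/water mixture (default 10-bead lipids,
2 head + 8 tail beads, optionally pre-arranged as a bilayer slab with
waters in the remaining slabs). They emulate the *compositional structure*
of benchmark lipid-water and CG-water systems at desk scale — they are not
equilibrated ensembles and carry no claim of force-field fidelity. Passing
tests therefore demonstrate the correctness of the machinery (assignment,
gradients, forces, integration, decomposition) and the qualitative
mean-field physics (demixing under repulsive χ, density-fluctuation
suppression by κ⁻¹), not quantitative agreement with any real lipid
system.

## Validation experiment sizes

The self-validation measurements (`hpfmd.diagnostics`, exercised by the
acceptance tests and `scripts/acceptance.py`) use: 100 random systems for
mass conservation; a 1900-particle lipid/water system for partition
invariance over 1/2/4/8 ranks; 1e5 bond-energy terms for summation
equivalence; 1000 random probes for the gradient-path identity; 100 random
40-particle configurations for force/energy consistency; 1e4-step harmonic
dimer runs at dt = 0.03/0.015 ps for the dt² drift ratio; a 1000-particle
incompressible fluid over 1e4 steps for the thermostat; an 8000-particle
fluid for the field-cadence KS test (625 decorrelated cell-density samples
per cadence: stride-2 sublattice cells — the CIC kernel spans two lattice
points, so stride-2 cells share no particle — from frames 500 steps apart,
several density relaxation times) and for the demixing experiment (χ_AB =
40 vs 0, 5000 steps at cadence 100, plateau = mean over the final fifth).
These sizes were fixed once as the package's study conditions.

## Known limitations

- Periodic boundaries only; no NPT, pressure/virial, or electrostatics.
- First-order (CIC) assignment only; no TSC or adaptive meshes.
- The Andersen thermostat destroys hydrodynamics; transport properties are
  out of scope.
- Ranks are an in-process contract; no distributed transport layer is
  provided, and scaling/timing behaviour is explicitly not a claim.
- Field forces between updates come from a stale lattice by design; the KS
  validation covers the default cadence (100) for fluids near equilibrium,
  not arbitrarily fast-evolving systems.
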