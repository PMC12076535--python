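"""Self-validation measurements for the hPF-MD machinery.

Each function sets up a seeded scenario, runs the relevant part of the
package, and returns ``(value, n)`` where ``value`` is the measured quantity
and ``n`` the problem size used.  The scenarios mirror the method's core
claims: exact PIC mass conservation, invariance of the global density field
under molecular decomposition, double-precision equivalence of the two
summation strategies, identity of the stored-grid and on-the-fly gradient
paths, thermodynamic consistency of field forces with the Helfand energy,
second-order integrator convergence, canonical sampling by the Andersen
thermostat, validity of the quasi-instantaneous field approximation, and
end-to-end demixing driven by a repulsive χ.

These are exercised both by the acceptance test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from hpfmd.bonded_forces import BondParam, bond_forces
from hpfmd.builders import CG_BEAD_MASS, build_fluid, build_lipid_water
from hpfmd.density_mesh import (
    MeshSpec,
    StoredGradientReference,
    assign_density,
    field_from_system,
    gradient_at,
    reduce_partials,
)
from hpfmd.field_forces import ForceField, field_force, total_field_energy
from hpfmd.integrator import Simulation
from hpfmd.model_io import RunSettings, SystemConfig
from hpfmd.reduction import pairwise_sum, sequential_sum
from hpfmd.topology import partition_molecules


def _subseed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31 - 1)


def _binary_fluid(n: int, box, chi_ab: float, seed: int, kappa_inv: float = 5.0):
    """Monoatomic two-species fluid, alternating species, 72 amu beads."""
    base = build_fluid(n, box, seed)
    types = np.arange(n, dtype=np.int64) % 2
    system = SystemConfig(
        box=np.asarray(box, dtype=float),
        labels=["A" if t == 0 else "B" for t in types],
        type_ids=types,
        positions=base.positions.copy(),
        velocities=None,
        connectivity=[[] for _ in range(n)],
        molecules=[np.array([i]) for i in range(n)],
    )
    chi = np.array([[0.0, chi_ab], [chi_ab, 0.0]])
    ff = ForceField(
        species=["A", "B"],
        chi=chi,
        kappa_inv=kappa_inv,
        temperature=300.0,
        masses=np.array([CG_BEAD_MASS, CG_BEAD_MASS]),
    )
    return system, ff


def measure_mass_conservation(seed: int, n_systems: int = 100) -> tuple[float, int]:
    """Max relative error of per-species raw PIC weight sums vs counts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        n = int(rng.integers(50, 2000))
        cells = tuple(int(c) for c in rng.integers(4, 13, size=3))
        box = tuple(float(b) for b in rng.uniform(5.0, 15.0, size=3))
        n_species = int(rng.integers(1, 4))
        mesh = MeshSpec(cells=cells, box=box)
        pos = rng.random((n, 3)) * np.array(box)
        sp = rng.integers(0, n_species, size=n)
        raw = assign_density(pos, sp, mesh, n_species).grids
        for k in range(n_species):
            count = int((sp == k).sum())
            if count:
                worst = max(worst, abs(raw[k].sum() - count) / count)
    return worst, n_systems


def measure_partition_invariance(seed: int) -> tuple[float, int]:
    """Max per-lattice-point deviation of 1/2/4/8-rank fields vs serial."""
    system = build_lipid_water(40, 1500, (8.0, 8.0, 12.0), seed)
    mesh = MeshSpec(cells=(8, 8, 12), box=tuple(system.box))
    serial = field_from_system(system, mesh, 3)
    worst = 0.0
    for n_ranks in (1, 2, 4, 8):
        part = partition_molecules(system, n_ranks)
        field = field_from_system(system, mesh, 3, partition=part)
        worst = max(worst, float(np.abs(field.phi - serial.phi).max()))
    return worst, system.n_particles


def measure_summation_equivalence(seed: int, n_terms: int = 100_000) -> tuple[float, int]:
    """Relative disagreement of sequential vs pairwise sums of bond energies."""
    n_beads = 18  # 17 bonds per chain
    n_chains = math.ceil(n_terms / (n_beads - 1))
    rng = np.random.default_rng(seed)
    n_particles = n_chains * n_beads
    positions = rng.random((n_particles, 3)) * 50.0
    # chains laid out contiguously; bonds between consecutive beads
    starts = np.arange(n_chains) * n_beads
    i = (starts[:, None] + np.arange(n_beads - 1)).ravel()
    bonds = np.column_stack([i, i + 1])[:n_terms]
    _, terms = bond_forces(
        positions, bonds, BondParam(k=1250.0, r0=0.47), np.array([50.0] * 3), return_terms=True
    )
    s_seq = sequential_sum(terms)
    s_pair = pairwise_sum(terms)
    rel = abs(s_seq - s_pair) / max(abs(s_seq), 1e-300)
    return rel, len(terms)


def measure_gradient_paths(seed: int, n_probes: int = 1000) -> tuple[float, int]:
    """Max abs difference between on-the-fly and stored-grid gradients."""
    rng = np.random.default_rng(seed)
    mesh = MeshSpec(cells=(9, 7, 11), box=(9.0, 7.0, 11.0))
    n, n_species = 600, 2
    pos = rng.random((n, 3)) * mesh.box_array
    sp = rng.integers(0, n_species, size=n)
    rho0 = n / float(np.prod(mesh.box_array))
    field = reduce_partials([assign_density(pos, sp, mesh, n_species)], rho0)
    probes = rng.random((n_probes, 3)) * mesh.box_array
    probe_sp = rng.integers(0, n_species, size=n_probes)
    on_the_fly = gradient_at(probes, probe_sp, field)
    stored = StoredGradientReference(field).gradient_at(probes, probe_sp)
    return float(np.abs(on_the_fly - stored).max()), n_probes


def measure_force_energy_consistency(
    seed: int, n_configs: int = 100, n_check: int = 5, step: float = 1e-5
) -> tuple[float, int]:
    """Max relative error of field forces vs central differences of the energy.

    The energy is re-accumulated through the same assignment stencil after
    displacing one coordinate by ±step.  Probe particles are kept more than
    the step away from cell faces, where the piecewise-polynomial energy has
    a kink and a central difference is not a valid derivative estimate.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        mesh = MeshSpec(cells=(6, 5, 7), box=(6.0, 5.0, 7.0))
        n, n_species = 40, 2
        margin = 50 * step
        frac = rng.uniform(margin, 1.0 - margin, size=(n, 3))
        cell = rng.integers(0, mesh.cells_array, size=(n, 3))
        pos = (cell + frac) * mesh.cell_size
        sp = rng.integers(0, n_species, size=n)
        rho0 = n / float(np.prod(mesh.box_array))
        chi_ab = float(rng.uniform(0.0, 20.0))
        ff = ForceField(
            species=["A", "B"],
            chi=np.array([[1.0, chi_ab], [chi_ab, 0.5]]),
            kappa_inv=float(rng.uniform(1.0, 8.0)),
            temperature=300.0,
        )

        def energy(p):
            f = reduce_partials([assign_density(p, sp, mesh, n_species)], rho0)
            return total_field_energy(f, mesh, ff, rho0)

        field = reduce_partials([assign_density(pos, sp, mesh, n_species)], rho0)
        forces = field_force(pos, sp, field, ff)
        scale = max(float(np.abs(forces).max()), 1e-12)
        for _ in range(n_check):
            p_idx = int(rng.integers(0, n))
            axis = int(rng.integers(0, 3))
            plus = pos.copy()
            plus[p_idx, axis] += step
            minus = pos.copy()
            minus[p_idx, axis] -= step
            fd = -(energy(plus) - energy(minus)) / (2 * step)
            denom = max(abs(fd), 1e-3 * scale)
            worst = max(worst, abs(fd - forces[p_idx, axis]) / denom)
    return worst, n_configs


def _harmonic_dimer(dt: float, n_steps: int, seed: int, k: float = 1250.0,
                    r0: float = 0.47, stretch: float = 0.05):
    box = (4.0, 4.0, 4.0)
    positions = np.array([[1.0, 2.0, 2.0], [1.0 + r0 + stretch, 2.0, 2.0]])
    system = SystemConfig(
        box=np.array(box),
        labels=["A", "A"],
        type_ids=np.zeros(2, dtype=np.int64),
        positions=positions,
        velocities=np.zeros((2, 3)),
        connectivity=[[1], [0]],
        molecules=[np.array([0, 1])],
    )
    ff = ForceField(
        species=["A"],
        chi=np.zeros((1, 1)),
        kappa_inv=0.0,
        temperature=300.0,
        masses=np.array([CG_BEAD_MASS]),
        bond_params={"*": BondParam(k=k, r0=r0)},
    )
    settings = RunSettings(
        timestep=dt,
        n_steps=n_steps,
        field_update_every=max(n_steps, 1),
        temperature=300.0,
        thermostat_nu=0.0,
        seed=seed,
        mesh=(4, 4, 4),
        output_every=max(n_steps, 1),
    )
    return Simulation(system, ff, settings)


def _dimer_drift(dt: float, n_steps: int, seed: int) -> float:
    sim = _harmonic_dimer(dt, n_steps, seed)
    e0 = sim.kinetic_energy() + sim.state.energies["bond"]
    worst = 0.0
    for _ in range(n_steps):
        sim.step()
        e = sim.kinetic_energy() + sim.state.energies["bond"]
        worst = max(worst, abs(e - e0))
    return worst


def measure_integrator_order(seed: int, n_steps: int = 10_000, dt: float = 0.03) -> tuple[float, int]:
    """Ratio of NVE energy drift at dt vs dt/2 for a harmonic dimer (~4 for dt²)."""
    drift_full = _dimer_drift(dt, n_steps, seed)
    drift_half = _dimer_drift(dt / 2, n_steps, seed)
    return drift_full / drift_half, n_steps


def measure_thermostat(seed: int, n: int = 1000, n_steps: int = 10_000) -> tuple[float, int]:
    """Time-mean temperature (K) of an ideal+incompressible fluid at 300 K."""
    system, ff = _binary_fluid(n, (8.0, 8.0, 8.0), 0.0, _subseed(seed, 7))
    settings = RunSettings(
        timestep=0.03,
        n_steps=n_steps,
        field_update_every=100,
        temperature=300.0,
        thermostat_nu=7.0,
        seed=seed,
        mesh=(8, 8, 8),
        output_every=n_steps,
    )
    sim = Simulation(system, ff, settings)
    acc = 0.0
    for _ in range(n_steps):
        sim.step()
        acc += sim.temperature()
    return acc / n_steps, n


def _cell_density_samples(cadence: int, seed: int, n: int, n_steps: int,
                          burn_in: int, sample_every: int) -> np.ndarray:
    """Approximately independent equilibrium cell-density samples.

    KS needs close-to-iid draws, so sampling is decorrelated in space and
    time: only a stride-2 sublattice of cells (the CIC kernel spans two
    lattice points per axis, so stride-2 cells share no particle) and frames
    several density relaxation times apart (a thermal bead crosses a cell in
    roughly 180 steps here).
    """
    system, ff = _binary_fluid(n, (10.0, 10.0, 10.0), 0.0, _subseed(seed, 11))
    settings = RunSettings(
        timestep=0.03,
        n_steps=n_steps,
        field_update_every=cadence,
        temperature=300.0,
        thermostat_nu=7.0,
        seed=_subseed(seed, 13 + cadence),
        mesh=(10, 10, 10),
        output_every=n_steps,
    )
    sim = Simulation(system, ff, settings)
    samples = []
    for step in range(1, n_steps + 1):
        sim.step()
        if step > burn_in and step % sample_every == 0:
            # instantaneous field from current positions, without touching
            # the simulation's own (possibly stale) lattice
            partial = assign_density(
                sim.state.positions, sim.state.species, sim.mesh, sim.ff.n_species
            )
            total = reduce_partials([partial], sim.rho0).total()
            samples.append(total[::2, ::2, ::2].ravel().copy())
    return np.concatenate(samples)


def measure_field_cadence_ks(seed: int, n: int = 8000, n_steps: int = 3500,
                             burn_in: int = 1000, sample_every: int = 500) -> tuple[float, int]:
    """Two-sample KS p-value: equilibrium cell densities at cadence 100 vs 1.

    Both runs sample the instantaneous field (an extra assignment at the
    sampling step) so the compared distributions differ only through the
    dynamics' field staleness.
    """
    a = _cell_density_samples(1, seed, n, n_steps, burn_in, sample_every)
    b = _cell_density_samples(100, seed, n, n_steps, burn_in, sample_every)
    return float(stats.ks_2samp(a, b).pvalue), len(a)


def _segregation(sim: Simulation) -> float:
    a, b = sim.state.field.phi
    total = a + b
    mask = total > 1e-9
    return float(np.mean(np.abs(a - b)[mask] / total[mask]))


def measure_demixing(seed: int, n: int = 8000, n_steps: int = 5000,
                     chi_ab: float = 40.0) -> tuple[dict, int]:
    """Segregation order parameter ⟨|ϕ_A−ϕ_B|/(ϕ_A+ϕ_B)⟩: χ=40 vs χ=0 baseline.

    Returns a dict with the plateau value (mean over the last fifth of the
    run), the χ=0 baseline over the same window, and the starting value.
    """
    out = {}
    for label, chi in (("baseline", 0.0), ("demixed", chi_ab)):
        system, ff = _binary_fluid(n, (10.0, 10.0, 10.0), chi, _subseed(seed, 17))
        settings = RunSettings(
            timestep=0.03,
            n_steps=n_steps,
            field_update_every=100,
            temperature=300.0,
            thermostat_nu=7.0,
            seed=_subseed(seed, 19),
            mesh=(10, 10, 10),
            output_every=n_steps,
        )
        sim = Simulation(system, ff, settings)
        if label == "demixed":
            out["start"] = _segregation(sim)
        values = []
        window_start = n_steps - n_steps // 5
        while sim.state.step < n_steps:
            sim.run(100)
            if sim.state.step > window_start:
                values.append(_segregation(sim))
        out[label] = float(np.mean(values))
    return out, n
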