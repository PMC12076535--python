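"""NVT velocity-Verlet driver for hybrid particle-field dynamics.

The loop alternates velocity-Verlet updates with density-field refreshes at
a fixed cadence (the quasi-instantaneous field approximation: fields evolve
much more slowly than single-particle motion, so refreshing them every
100-500 steps loses no accuracy).  Bonded forces are recomputed every step;
field forces are re-interpolated every step at the new positions from the
frozen lattice, which itself is rebuilt only on update steps.  The field
refresh is the only cross-rank exchange in the loop: each rank assigns the
partial density of its own molecules and the partials are summed in fixed
rank order.

Temperature control is an Andersen thermostat: each particle's velocity is
resampled from the Maxwell-Boltzmann distribution with probability ν·dt per
step, from a seeded generator, so trajectories are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from hpfmd.bonded_forces import angle_forces, bond_forces, dihedral_forces
from hpfmd.constants import BOLTZMANN_KJ_MOL_K
from hpfmd.density_mesh import (
    DensityField,
    MeshSpec,
    assign_density,
    reduce_partials,
    wrap_positions,
)
from hpfmd.errors import ModelError, SimulationError
from hpfmd.field_forces import ForceField, field_force, total_field_energy
from hpfmd.model_io import RunSettings, SystemConfig, write_trajectory_frame
from hpfmd.reduction import reduce_values
from hpfmd.topology import BondedLists, Partition, build_bonded_lists, partition_molecules


@dataclass
class SimState:
    """Mutable integration state."""

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    masses: np.ndarray  # per particle, amu
    step: int = 0
    field: DensityField | None = None
    field_forces: np.ndarray | None = None
    bonded_forces: np.ndarray | None = None
    energies: dict = dataclass_field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.positions)


class Simulation:
    """Orchestrates one hPF-MD run from a system, force field and settings.

    ``n_ranks`` selects the molecular decomposition used for density
    assembly; any rank count gives the same global field to round-off, and
    the trajectory is fully determined by (seed, inputs, rank count).
    """

    def __init__(
        self,
        system: SystemConfig,
        ff: ForceField,
        settings: RunSettings,
        mesh: MeshSpec | None = None,
        n_ranks: int = 1,
        lists: BondedLists | None = None,
    ):
        self.system = system
        self.ff = ff
        self.settings = settings
        self.mesh = mesh or MeshSpec(cells=settings.mesh, box=tuple(system.box))
        if tuple(self.mesh.box) != tuple(float(b) for b in system.box):
            raise ModelError("mesh box does not match the system box")
        self.lists = lists if lists is not None else build_bonded_lists(
            system, ff if (ff.bond_params or ff.angle_params or ff.dihedral_params) else None
        )
        self.partition: Partition = partition_molecules(system, n_ranks)
        self.rng = np.random.default_rng(settings.seed)
        self.rho0 = system.n_particles / float(np.prod(system.box))
        self.n_field_updates = 0

        species = system.type_ids.copy()
        masses = ff.masses[species]
        velocities = (
            system.velocities.copy()
            if system.velocities is not None
            else self._maxwell_boltzmann(masses)
        )
        self.state = SimState(
            positions=wrap_positions(system.positions.copy(), system.box),
            velocities=velocities,
            species=species,
            masses=masses,
        )
        # molecule membership per particle row, for per-rank density assembly
        self._rank_rows = []
        mol_of = system.molecule_of()
        for rank in range(self.partition.n_ranks):
            rows = np.flatnonzero(np.isin(mol_of, np.flatnonzero(self.partition.rank_of == rank)))
            self._rank_rows.append(rows)
        # a bonded term is active only when the model defines parameters for it
        self._bond_params = (
            self._resolve(self.lists.bond_types, ff.bond_param) if ff.bond_params else None
        )
        self._angle_params = (
            self._resolve(self.lists.ang_types, ff.angle_param) if ff.angle_params else None
        )
        self._dihedral_params = (
            self._resolve(self.lists.dih_types, ff.dihedral_param) if ff.dihedral_params else None
        )
        self.update_field()
        self._compute_forces()

    @staticmethod
    def _resolve(type_rows: np.ndarray, lookup):
        if len(type_rows) == 0:
            return None
        return [lookup(*(int(t) for t in row)) for row in type_rows]

    def _maxwell_boltzmann(self, masses: np.ndarray) -> np.ndarray:
        sigma = np.sqrt(BOLTZMANN_KJ_MOL_K * self.settings.temperature / masses)
        return self.rng.normal(size=(len(masses), 3)) * sigma[:, None]

    # -- field handling ----------------------------------------------------

    def update_field(self) -> DensityField:
        """Rebuild the density field from current positions (per-rank partials,
        reduced in fixed rank order — the loop's only cross-rank exchange)."""
        partials = [
            assign_density(
                self.state.positions[rows],
                self.state.species[rows],
                self.mesh,
                self.ff.n_species,
                rank=rank,
            )
            for rank, rows in enumerate(self._rank_rows)
        ]
        self.state.field = reduce_partials(partials, self.rho0)
        self.n_field_updates += 1
        self.state.energies["field"] = total_field_energy(
            self.state.field, self.mesh, self.ff, self.rho0
        )
        return self.state.field

    def _field_forces(self) -> np.ndarray:
        return field_force(self.state.positions, self.state.species, self.state.field, self.ff)

    def _bonded(self, return_terms: bool = False):
        pos, box = self.state.positions, self.system.box
        total = np.zeros_like(pos)
        terms = {}
        for name, idx_list, params, fn in (
            ("bond", self.lists.bond_list, self._bond_params, bond_forces),
            ("angle", self.lists.ang_list, self._angle_params, angle_forces),
            ("dihedral", self.lists.dih_list, self._dihedral_params, dihedral_forces),
        ):
            if params is None:
                terms[name] = np.zeros(0)
                continue
            f, e = fn(pos, idx_list, params, box, return_terms=True)
            total += f
            terms[name] = e
        if return_terms:
            return total, terms
        return total, {k: float(v.sum()) for k, v in terms.items()}

    def _compute_forces(self) -> None:
        self.state.bonded_forces, energies = self._bonded()
        self.state.field_forces = self._field_forces()
        self.state.energies.update(
            {"bond": energies["bond"], "angle": energies["angle"], "dihedral": energies["dihedral"]}
        )

    # -- integration -------------------------------------------------------

    def step(self) -> SimState:
        """One velocity-Verlet step with field refresh at the set cadence."""
        st = self.state
        if not (np.all(np.isfinite(st.positions)) and np.all(np.isfinite(st.velocities))):
            raise SimulationError(f"non-finite state entering step {st.step} (blow-up)")
        dt = self.settings.timestep
        inv_m = 1.0 / st.masses[:, None]
        forces = st.bonded_forces + st.field_forces
        st.velocities += 0.5 * dt * forces * inv_m
        st.positions += dt * st.velocities
        st.positions = wrap_positions(st.positions, self.system.box)
        st.step += 1
        if st.step % self.settings.field_update_every == 0:
            self.update_field()
            self._compute_forces()
        elif self.settings.freeze_forces_between_updates:
            # comparison mode: per-particle field forces also frozen
            st.bonded_forces, energies = self._bonded()
            st.energies.update({k: energies[k] for k in ("bond", "angle", "dihedral")})
        else:
            # default: field lattice frozen, forces re-interpolated at new positions
            self._compute_forces()
        forces = st.bonded_forces + st.field_forces
        st.velocities += 0.5 * dt * forces * inv_m
        self._thermostat()
        if not (np.all(np.isfinite(st.positions)) and np.all(np.isfinite(st.velocities))):
            raise SimulationError(f"non-finite state at step {st.step} (blow-up)")
        return st

    def _thermostat(self) -> None:
        nu = self.settings.thermostat_nu
        if nu <= 0:
            return
        p = nu * self.settings.timestep
        hit = self.rng.random(self.state.n_particles) < p
        n_hit = int(hit.sum())
        if n_hit:
            sigma = np.sqrt(
                BOLTZMANN_KJ_MOL_K * self.settings.temperature / self.state.masses[hit]
            )
            self.state.velocities[hit] = self.rng.normal(size=(n_hit, 3)) * sigma[:, None]

    def run(self, n_steps: int | None = None, traj_sink=None, log_sink=None) -> SimState:
        """Advance ``n_steps`` (default from settings), optionally logging.

        The observable log is a tab-separated table of step, temperature,
        kinetic energy, bonded energies and field energy per output cadence.
        """
        n_steps = self.settings.n_steps if n_steps is None else n_steps
        if log_sink is not None and self.state.step == 0:
            log_sink.write("step\tT\tKE\tE_bond\tE_angle\tE_dihedral\tW_field\n")
            self._log_line(log_sink)
        if traj_sink is not None and self.state.step == 0:
            self._write_frame(traj_sink)
        for _ in range(n_steps):
            self.step()
            if self.state.step % self.settings.output_every == 0:
                if log_sink is not None:
                    self._log_line(log_sink)
                if traj_sink is not None:
                    self._write_frame(traj_sink)
        return self.state

    def _write_frame(self, sink) -> None:
        write_trajectory_frame(
            self.state.positions,
            self.system.labels,
            self.system.box,
            sink,
            step=self.state.step,
            time=self.state.step * self.settings.timestep,
        )

    def _log_line(self, sink) -> None:
        obs = self.observables()
        sink.write(
            f"{self.state.step}\t{obs['temperature']:.6f}\t{obs['kinetic']:.6f}\t"
            f"{obs['bond']:.6f}\t{obs['angle']:.6f}\t{obs['dihedral']:.6f}\t"
            f"{obs['field']:.6f}\n"
        )

    # -- observables -------------------------------------------------------

    def kinetic_energy(self, strategy: str | None = None) -> float:
        terms = 0.5 * self.state.masses * np.einsum("na,na->n", self.state.velocities, self.state.velocities)
        return reduce_values(terms, strategy or self.settings.reduction)

    def temperature(self) -> float:
        n = self.state.n_particles
        return 2.0 * self.kinetic_energy() / (3.0 * n * BOLTZMANN_KJ_MOL_K)

    def observables(self, strategy: str | None = None) -> dict:
        """Global scalars via the selected summation strategy.

        The field energy is the one computed at the most recent field update
        (the lattice is frozen between updates).
        """
        strategy = strategy or self.settings.reduction
        _, terms = self._bonded(return_terms=True)
        ke = self.kinetic_energy(strategy)
        return {
            "step": self.state.step,
            "kinetic": ke,
            "temperature": 2.0 * ke / (3.0 * self.state.n_particles * BOLTZMANN_KJ_MOL_K),
            "bond": reduce_values(terms["bond"], strategy),
            "angle": reduce_values(terms["angle"], strategy),
            "dihedral": reduce_values(terms["dihedral"], strategy),
            "field": self.state.energies.get("field", 0.0),
        }

    def total_momentum(self) -> np.ndarray:
        return (self.state.masses[:, None] * self.state.velocities).sum(axis=0)
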