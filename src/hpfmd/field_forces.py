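"""Mean-field (density-functional) non-bonded potential, forces and energy.

The non-bonded energy is the Helfand functional

    W = ∫ dr ρ0 [ (kT/2) Σ_KK' χ_KK' ϕ_K(r) ϕ_K'(r)
                  + (kT κ⁻¹ / 2) (Σ_K ϕ_K(r) − 1)² ]

with ϕ_K the species densities normalized by the average number density ρ0.
Its functional derivative gives the external potential felt by a particle of
species K,

    V_K(r) = kT [ Σ_K' χ_KK' ϕ_K'(r) + κ⁻¹ (Σ_K' ϕ_K'(r) − 1) ]

and the force is the negative interpolated gradient,

    F_K(r) = −kT [ Σ_K' χ_KK' ∇ϕ_K'(r) + κ⁻¹ Σ_K' ∇ϕ_K'(r) ].

χ is dimensionless (kT units, Flory–Huggins-like) and κ⁻¹ is the
incompressibility strength, also in kT units; one kT factor scales the whole
potential.  The per-particle force needs no inter-particle communication:
each evaluation reads only the (shared, possibly stale) density lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hpfmd.bonded_forces import AngleParam, BondParam, DihedralParam
from hpfmd.constants import BOLTZMANN_KJ_MOL_K
from hpfmd.density_mesh import DensityField, MeshSpec, density_at, gradient_at
from hpfmd.errors import ModelError, ValidationError


@dataclass
class ForceField:
    """Mean-field and bonded interaction parameters plus the species table.

    ``chi`` is the symmetric species×species Flory–Huggins matrix (kT units);
    ``kappa_inv`` the incompressibility strength (kT units); ``masses`` the
    per-type bead masses in amu (default 1 CG unit).  Bonded parameter sets
    are keyed by canonical type tuples, with ``"*"`` as a wildcard set.
    """

    species: list[str]
    chi: np.ndarray
    kappa_inv: float = 0.0
    temperature: float = 300.0
    masses: np.ndarray | None = None
    bond_params: dict = field(default_factory=dict)
    angle_params: dict = field(default_factory=dict)
    dihedral_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        n = len(self.species)
        if self.chi.shape != (n, n):
            raise ModelError(f"chi must be {n}x{n} for {n} species")
        if not np.allclose(self.chi, self.chi.T, rtol=0, atol=0):
            raise ModelError("chi matrix must be symmetric")
        if self.kappa_inv < 0:
            raise ModelError("kappa_inv must be >= 0")
        if self.temperature <= 0:
            raise ModelError("temperature must be > 0")
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ModelError("masses must be positive, one per species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kJ/mol at the run temperature."""
        return BOLTZMANN_KJ_MOL_K * self.temperature

    def _lookup(self, table: dict, key: tuple, kind: str):
        if key in table:
            return table[key]
        if key[::-1] in table:
            return table[key[::-1]]
        if "*" in table:
            return table["*"]
        wild = tuple(-1 for _ in key)
        if wild in table:
            return table[wild]
        raise ModelError(f"no {kind} parameters for type tuple {key}")

    def bond_param(self, ti: int, tj: int) -> BondParam:
        return self._lookup(self.bond_params, (min(ti, tj), max(ti, tj)), "bond")

    def angle_param(self, ti: int, tj: int, tk: int) -> AngleParam:
        i, k = sorted((ti, tk))
        return self._lookup(self.angle_params, (i, tj, k), "angle")

    def dihedral_param(self, ti: int, tj: int, tk: int, tl: int) -> DihedralParam:
        key = (ti, tj, tk, tl)
        if key[0] > key[3] or (key[0] == key[3] and key[1] > key[2]):
            key = key[::-1]
        return self._lookup(self.dihedral_params, key, "dihedral")


def _check_species(species, n_species: int) -> None:
    sp = np.atleast_1d(np.asarray(species, dtype=np.int64))
    if sp.size and (sp.min() < 0 or sp.max() >= n_species):
        raise ValidationError("unknown species index")


def external_potential_at(positions, species, field: DensityField, ff: ForceField):
    """External potential V_K(r) in kT units at the given position(s).

    The incompressibility term is positive where total normalized density
    exceeds 1 and negative below 1.
    """
    _check_species(species, ff.n_species)
    single = np.asarray(positions).ndim == 1
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    sp = np.broadcast_to(np.atleast_1d(np.asarray(species, dtype=np.int64)), (pos.shape[0],))
    phi = np.stack([density_at(pos, k, field) for k in range(ff.n_species)], axis=1)
    chi_term = np.einsum("nk,nk->n", ff.chi[sp], phi)
    incompress = ff.kappa_inv * (phi.sum(axis=1) - 1.0)
    v = chi_term + incompress
    return float(v[0]) if single else v


def field_force(positions, species, field: DensityField, ff: ForceField):
    """Density-field force in kJ mol⁻¹ nm⁻¹ on the given particle(s).

    Evaluated independently per particle from the shared lattice; no
    inter-particle communication is involved.
    """
    _check_species(species, ff.n_species)
    single = np.asarray(positions).ndim == 1
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    sp = np.broadcast_to(np.atleast_1d(np.asarray(species, dtype=np.int64)), (pos.shape[0],))
    # contract χ_KK' + κ⁻¹ into one lattice potential per species K (in kT),
    # then interpolate a single gradient per particle; linear in ϕ, so this
    # equals the per-species gradient sum
    coeff = ff.chi + ff.kappa_inv  # (S, S)
    potential = DensityField(
        phi=np.einsum("ks,sxyz->kxyz", coeff, field.phi),
        mesh=field.mesh,
        rho0=field.rho0,
    )
    force = -ff.kT * gradient_at(pos, sp, potential)
    return force[0] if single else force


def total_field_energy(field: DensityField, mesh: MeshSpec, ff: ForceField, rho0: float) -> float:
    """Discretized Helfand energy W in kJ/mol (midpoint rule over the lattice).

    The ρ0 prefactor converts the normalized-density integrand to an energy
    density, so that the functional derivative with respect to the particle
    density reproduces the external potential dimensionally.
    """
    if field.phi.shape[1:] != tuple(mesh.cells):
        raise ValidationError("field and mesh disagree on lattice shape")
    phi = field.phi
    chi_energy = 0.5 * np.einsum("kl,kxyz,lxyz->", ff.chi, phi, phi)
    excess = phi.sum(axis=0) - 1.0
    incompress = 0.5 * ff.kappa_inv * float(np.sum(excess * excess))
    return mesh.cell_volume * rho0 * ff.kT * (chi_energy + incompress)
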