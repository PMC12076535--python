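"""Seeded synthetic system builders.

Two system families mirror the benchmark compositions at desk scale: a
monoatomic coarse-grained fluid (water-like single species, no bonds) and a
bead-spring lipid/water mixture, optionally pre-arranged as a bilayer slab
mid-box.  The default lipid architecture is a 10-bead chain with 2 head and
8 tail beads; bead counts and typing are configurable, and no claim of
fidelity to any published lipid parameterization is made.

All builders are deterministic under their seed and every emitted system
passes full SystemConfig validation.
"""

from __future__ import annotations

import numpy as np

from hpfmd.bonded_forces import AngleParam, BondParam, DihedralParam
from hpfmd.density_mesh import wrap_positions
from hpfmd.errors import ValidationError
from hpfmd.field_forces import ForceField
from hpfmd.model_io import RunSettings, SystemConfig, validate_system

#: refuse builds denser than this many beads per nm^3 (a CG water box sits
#: near 8-9 nm^-3; anything several-fold above that is a mis-specified box)
DEFAULT_DENSITY_CAP = 50.0

#: default bead mass (amu) for builder models: a 4-to-1 mapped CG bead
#: (four heavy atoms per bead, MARTINI-style), so the 0.03 ps timestep and
#: the 100-step field-update cadence resolve thermal motion across a ~1 nm
#: cell.  ForceField itself defaults to 1 amu when no masses are given.
CG_BEAD_MASS = 72.0

FLUID_SPECIES = ["W"]
LIPID_SPECIES = ["W", "H", "T"]  # water, lipid head, lipid tail


def build_fluid(n: int, box, seed: int, label: str = "W") -> SystemConfig:
    """Uniform random monoatomic single-species fluid; each bead one molecule."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValidationError("box must be 3 positive lengths")
    rng = np.random.default_rng(seed)
    positions = rng.random((n, 3)) * box
    system = SystemConfig(
        box=box,
        labels=[label] * n,
        type_ids=np.zeros(n, dtype=np.int64),
        positions=positions,
        velocities=None,
        connectivity=[[] for _ in range(n)],
        molecules=[np.array([i]) for i in range(n)],
    )
    validate_system(system)
    return system


def build_lipid_water(
    n_lipids: int,
    n_water: int,
    box,
    seed: int,
    n_beads: int = 10,
    n_head: int = 2,
    arrangement: str = "bilayer",
    bond_length: float = 0.47,
    density_cap: float = DEFAULT_DENSITY_CAP,
) -> SystemConfig:
    """Bead-spring lipids plus water beads.

    ``arrangement="bilayer"`` places the lipids as two leaflets in a slab at
    mid-box (heads outward, tails meeting at the midplane, chains along z)
    with waters filling the two remaining slabs; ``"random"`` scatters both.
    Species: water type 0, head type 1, tail type 2.
    """
    if n_lipids < 0 or n_water < 0 or n_lipids + n_water == 0:
        raise ValidationError("need a non-negative, non-empty composition")
    if not 1 <= n_head < n_beads:
        raise ValidationError("need 1 <= n_head < n_beads")
    if arrangement not in ("bilayer", "random"):
        raise ValidationError(f"unknown arrangement {arrangement!r}")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValidationError("box must be 3 positive lengths")
    n_total = n_lipids * n_beads + n_water
    if n_total / float(np.prod(box)) > density_cap:
        raise ValidationError(
            f"overfilled box: {n_total / float(np.prod(box)):.1f} beads/nm^3 "
            f"exceeds the cap of {density_cap}"
        )
    rng = np.random.default_rng(seed)

    labels: list[str] = []
    type_ids: list[int] = []
    positions: list[np.ndarray] = []
    connectivity: list[list[int]] = []
    molecules: list[np.ndarray] = []

    half_chain = n_beads * bond_length  # leaflet thickness along z
    z_mid = box[2] / 2.0

    for m in range(n_lipids):
        first = len(labels)
        if arrangement == "bilayer":
            leaflet = 1 if m % 2 == 0 else -1  # alternate leaflets
            xy = rng.random(2) * box[:2]
            # bead 0 = outermost head; chain runs toward the midplane
            z0 = z_mid + leaflet * half_chain
            axis = np.array([0.0, 0.0, -leaflet])
            base = np.array([xy[0], xy[1], z0])
            jitter = rng.normal(scale=0.02, size=(n_beads, 3))
        else:
            base = rng.random(3) * box
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            jitter = rng.normal(scale=0.02, size=(n_beads, 3))
        members = []
        for b in range(n_beads):
            g = first + b
            labels.append("H" if b < n_head else "T")
            type_ids.append(1 if b < n_head else 2)
            positions.append(base + axis * (b * bond_length) + jitter[b])
            partners = []
            if b > 0:
                partners.append(g - 1)
            if b < n_beads - 1:
                partners.append(g + 1)
            connectivity.append(partners)
            members.append(g)
        molecules.append(np.array(members))

    for _ in range(n_water):
        g = len(labels)
        labels.append("W")
        type_ids.append(0)
        if arrangement == "bilayer" and n_lipids > 0:
            # waters in the two slabs outside the membrane
            margin = half_chain + 0.2
            free = box[2] - 2 * margin
            if free <= 0:
                raise ValidationError("box too thin for the bilayer plus water slabs")
            z = rng.random() * free
            z = z + z_mid + margin if z < free / 2 else z - free / 2
            positions.append(np.array([rng.random() * box[0], rng.random() * box[1], z]))
        else:
            positions.append(rng.random(3) * box)
        connectivity.append([])
        molecules.append(np.array([g]))

    system = SystemConfig(
        box=box,
        labels=labels,
        type_ids=np.array(type_ids, dtype=np.int64),
        positions=wrap_positions(np.array(positions), box),
        velocities=None,
        connectivity=connectivity,
        molecules=molecules,
    )
    validate_system(system)
    return system


def perturb_uniform(system: SystemConfig, amplitude: float, seed: int) -> SystemConfig:
    """Seeded uniform jitter in [-amplitude, amplitude] per coordinate, wrapped."""
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if amplitude == 0:
        positions = system.positions.copy()
    else:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-amplitude, amplitude, size=system.positions.shape)
        positions = wrap_positions(system.positions + jitter, system.box)
    out = SystemConfig(
        box=system.box.copy(),
        labels=list(system.labels),
        type_ids=system.type_ids.copy(),
        positions=positions,
        velocities=None if system.velocities is None else system.velocities.copy(),
        connectivity=[list(c) for c in system.connectivity],
        molecules=[m.copy() for m in system.molecules],
        molecule_ids=list(system.molecule_ids),
        global_indices=system.global_indices.copy(),
    )
    validate_system(out)
    return out


def fluid_model(
    temperature: float = 300.0, kappa_inv: float = 5.0, mesh=(8, 8, 8), seed: int = 0
) -> tuple[ForceField, RunSettings]:
    """Generic single-species fluid model (ideal + incompressibility only)."""
    ff = ForceField(
        species=list(FLUID_SPECIES),
        chi=np.zeros((1, 1)),
        kappa_inv=kappa_inv,
        temperature=temperature,
        masses=np.array([CG_BEAD_MASS]),
    )
    settings = RunSettings(temperature=temperature, mesh=tuple(mesh), seed=seed)
    return ff, settings


def lipid_water_model(
    temperature: float = 300.0,
    kappa_inv: float = 5.0,
    chi_wt: float = 30.0,
    chi_wh: float = -5.0,
    chi_ht: float = 15.0,
    mesh=(8, 8, 8),
    seed: int = 0,
) -> tuple[ForceField, RunSettings]:
    """Generic 3-species lipid/water mean-field model with chain bonded terms.

    χ values follow the usual qualitative pattern: tails strongly repel
    water, heads are mildly hydrophilic, heads and tails dislike mixing.
    """
    chi = np.zeros((3, 3))
    chi[0, 2] = chi[2, 0] = chi_wt
    chi[0, 1] = chi[1, 0] = chi_wh
    chi[1, 2] = chi[2, 1] = chi_ht
    ff = ForceField(
        species=list(LIPID_SPECIES),
        chi=chi,
        kappa_inv=kappa_inv,
        temperature=temperature,
        masses=np.array([CG_BEAD_MASS] * 3),
        bond_params={"*": BondParam(k=1250.0, r0=0.47)},
        angle_params={"*": AngleParam(k=25.0, theta0=np.pi)},
        dihedral_params={},
    )
    settings = RunSettings(temperature=temperature, mesh=tuple(mesh), seed=seed)
    return ff, settings
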