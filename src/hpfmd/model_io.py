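"""Configuration, model-file and trajectory I/O.

The configuration dialect is a whitespace-separated text format carrying,
per particle: global index (1-based), label, type id (1-based), number of
bonds, Cartesian coordinates in nm, optional velocities in nm/ps, and the
1-based indices of bonded partners.  Particles are grouped into per-molecule
blocks.  Indices are converted to 0-based at the parse boundary; nothing
outside this module sees 1-based indices.

The model/parameter file is a YAML key-value document naming species, the
χ interaction entries, the incompressibility strength κ⁻¹ (in kT units),
bonded parameter sets keyed by species names, and the run settings.

Trajectories are written as plain XYZ frames with the box lengths and step
number on the comment line, so any standard viewer can read them.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence

import numpy as np
import yaml

from hpfmd.bonded_forces import AngleParam, BondParam, DihedralParam
from hpfmd.errors import (
    ConfigParseError,
    ModelError,
    PartitionError,
    TopologyError,
    ValidationError,
)
from hpfmd.field_forces import ForceField

logger = logging.getLogger(__name__)

_FLOAT_FMT = "{:.17g}"


@dataclass
class SystemConfig:
    """Particle system as read from a configuration file.

    Arrays are indexed by local row; ``global_indices`` maps rows to global
    0-based particle indices (the identity for a full system, a subset for a
    chunked-read fragment).  ``connectivity`` and ``molecules`` always hold
    global indices.
    """

    box: np.ndarray
    labels: list[str]
    type_ids: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None
    connectivity: list[list[int]]
    molecules: list[np.ndarray]
    molecule_ids: list[int] = field(default_factory=list)
    global_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.type_ids = np.asarray(self.type_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        self.molecules = [np.asarray(m, dtype=np.int64) for m in self.molecules]
        if not self.molecule_ids:
            self.molecule_ids = list(range(len(self.molecules)))
        if self.global_indices is None:
            self.global_indices = np.arange(self.n_particles, dtype=np.int64)
        else:
            self.global_indices = np.asarray(self.global_indices, dtype=np.int64)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    def local_index(self, global_index: int) -> int:
        """Map a global particle index to the local row holding it."""
        if self._g2l is None:
            self._g2l = {int(g): i for i, g in enumerate(self.global_indices)}
        return self._g2l[int(global_index)]

    _g2l: dict | None = field(default=None, repr=False, compare=False)

    def molecule_of(self) -> np.ndarray:
        """Molecule row index for each local particle row."""
        out = np.empty(self.n_particles, dtype=np.int64)
        for m, members in enumerate(self.molecules):
            for g in members:
                out[self.local_index(g)] = m
        return out


def validate_system(system: SystemConfig) -> None:
    """Check every SystemConfig invariant; raise on the first violation.

    Connectivity symmetry is verified by an exhaustive pairwise scan, and
    every bond partner must belong to the same molecule as the particle.
    """
    if system.box.shape != (3,) or not np.all(np.isfinite(system.box)) or np.any(system.box <= 0):
        raise ValidationError(f"box must be 3 positive finite lengths, got {system.box}")
    n = system.n_particles
    if not (len(system.labels) == len(system.connectivity) == len(system.type_ids) == n):
        raise ValidationError("per-particle arrays have inconsistent lengths")
    if not np.all(np.isfinite(system.positions)):
        raise ValidationError("non-finite particle position")
    if system.velocities is not None and not np.all(np.isfinite(system.velocities)):
        raise ValidationError("non-finite particle velocity")

    known = set(int(g) for g in system.global_indices)
    if len(known) != n:
        raise ValidationError("duplicate global particle indices")
    mol_of: dict[int, int] = {}
    seen: set[int] = set()
    for m, members in enumerate(system.molecules):
        for g in members:
            g = int(g)
            if g not in known:
                raise TopologyError(f"molecule {m} lists unknown particle {g}")
            if g in seen:
                raise TopologyError(f"particle {g} appears in more than one molecule")
            seen.add(g)
            mol_of[g] = m
    if seen != known:
        raise TopologyError("some particles belong to no molecule")

    neighbor_sets = {}
    for row, partners in enumerate(system.connectivity):
        g = int(system.global_indices[row])
        if len(set(partners)) != len(partners):
            raise TopologyError(f"particle {g} lists a duplicate bond partner")
        neighbor_sets[g] = set(int(p) for p in partners)
    for g, partners in neighbor_sets.items():
        for p in partners:
            if p not in known:
                raise TopologyError(f"particle {g} bonded to out-of-range index {p}")
            if p == g:
                raise TopologyError(f"particle {g} bonded to itself")
            if mol_of[p] != mol_of[g]:
                raise TopologyError(
                    f"bond {g}-{p} crosses molecules {mol_of[g]} and {mol_of[p]}"
                )
            if g not in neighbor_sets[p]:
                raise TopologyError(f"asymmetric connectivity: {g} lists {p} but not vice versa")


def _tokenize(stream: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        yield lineno, text.split()


def read_configuration(source: IO[str] | str) -> SystemConfig:
    """Parse a configuration file into a validated :class:`SystemConfig`.

    Raises :class:`ConfigParseError` (with line number) on malformed input and
    :class:`TopologyError` on connectivity violations.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = _tokenize(source)

    def next_line(what: str) -> tuple[int, list[str]]:
        try:
            return next(lines)
        except StopIteration:
            raise ConfigParseError(f"unexpected end of file, expected {what}") from None

    lineno, tok = next_line("header counts")
    if len(tok) != 3:
        raise ConfigParseError("header must be 'n_particles n_molecules has_velocities'", lineno)
    try:
        n_particles, n_molecules, vel_flag = (int(t) for t in tok)
    except ValueError:
        raise ConfigParseError("header counts must be integers", lineno) from None
    if vel_flag not in (0, 1):
        raise ConfigParseError("velocity flag must be 0 or 1", lineno)

    lineno, tok = next_line("box lengths")
    if len(tok) != 3:
        raise ConfigParseError("box line must hold 3 lengths", lineno)
    try:
        box = np.array([float(t) for t in tok])
    except ValueError:
        raise ConfigParseError("box lengths must be numbers", lineno) from None

    labels: list[str] = [""] * n_particles
    type_ids = np.zeros(n_particles, dtype=np.int64)
    positions = np.zeros((n_particles, 3))
    velocities = np.zeros((n_particles, 3)) if vel_flag else None
    connectivity: list[list[int]] = [[] for _ in range(n_particles)]
    molecules: list[np.ndarray] = []

    n_read = 0
    for _ in range(n_molecules):
        lineno, tok = next_line("molecule header")
        if len(tok) != 3 or tok[0] != "molecule":
            raise ConfigParseError("expected 'molecule <id> <n_particles>'", lineno)
        try:
            n_in_mol = int(tok[2])
        except ValueError:
            raise ConfigParseError("molecule particle count must be an integer", lineno) from None
        members = []
        for _ in range(n_in_mol):
            lineno, tok = next_line("particle record")
            base = 7 + (3 if vel_flag else 0)
            if len(tok) < base:
                raise ConfigParseError(
                    f"particle record needs at least {base} fields, got {len(tok)}", lineno
                )
            try:
                gid = int(tok[0]) - 1
                type_id = int(tok[2]) - 1
                n_bonds = int(tok[3])
                coords = [float(t) for t in tok[4:7]]
                vel = [float(t) for t in tok[7:10]] if vel_flag else None
                partners = [int(t) - 1 for t in tok[base:]]
            except ValueError:
                raise ConfigParseError("malformed numeric field in particle record", lineno) from None
            if not 0 <= gid < n_particles:
                raise TopologyError(f"line {lineno}: particle index {gid + 1} out of range")
            if len(partners) != n_bonds:
                raise TopologyError(
                    f"line {lineno}: particle {gid + 1} declares {n_bonds} bonds "
                    f"but lists {len(partners)}"
                )
            if type_id < 0:
                raise ConfigParseError("type id must be >= 1", lineno)
            labels[gid] = tok[1]
            type_ids[gid] = type_id
            positions[gid] = coords
            if velocities is not None:
                velocities[gid] = vel
            connectivity[gid] = partners
            members.append(gid)
            n_read += 1
        molecules.append(np.array(members, dtype=np.int64))

    if n_read != n_particles:
        raise ConfigParseError(
            f"header promised {n_particles} particles but molecule blocks held {n_read}"
        )
    system = SystemConfig(
        box=box,
        labels=labels,
        type_ids=type_ids,
        positions=positions,
        velocities=velocities,
        connectivity=connectivity,
        molecules=molecules,
    )
    validate_system(system)
    return system


def write_configuration(system: SystemConfig, sink: IO[str]) -> None:
    """Emit ``system`` in the canonical dialect; refuses invalid systems."""
    validate_system(system)
    f = _FLOAT_FMT.format
    sink.write(f"{system.n_particles} {system.n_molecules} {1 if system.has_velocities else 0}\n")
    sink.write(" ".join(f(b) for b in system.box) + "\n")
    for m, members in enumerate(system.molecules):
        sink.write(f"molecule {system.molecule_ids[m] + 1} {len(members)}\n")
        for g in members:
            row = system.local_index(g)
            parts = [
                str(int(g) + 1),
                system.labels[row],
                str(int(system.type_ids[row]) + 1),
                str(len(system.connectivity[row])),
                *(f(x) for x in system.positions[row]),
            ]
            if system.velocities is not None:
                parts.extend(f(v) for v in system.velocities[row])
            parts.extend(str(int(p) + 1) for p in system.connectivity[row])
            sink.write(" ".join(parts) + "\n")


def read_configuration_chunk(source: IO[str] | str, rank: int, n_ranks: int, partition) -> SystemConfig:
    """Read only the molecules that ``partition`` assigns to ``rank``.

    The union of all ranks' fragments equals the serial read; each fragment
    holds whole molecules only.  ``n_ranks == 1`` degenerates to
    :func:`read_configuration`.
    """
    if not 0 <= rank < n_ranks:
        raise PartitionError(f"rank {rank} outside 0..{n_ranks - 1}")
    if partition.n_ranks != n_ranks:
        raise PartitionError(
            f"partition built for {partition.n_ranks} ranks, asked for {n_ranks}"
        )
    full = read_configuration(source)
    if len(partition.rank_of) != full.n_molecules:
        raise PartitionError("partition does not match the molecule count of the file")
    keep = [m for m in range(full.n_molecules) if partition.rank_of[m] == rank]
    return extract_molecules(full, keep)


def extract_molecules(system: SystemConfig, molecule_rows: Sequence[int]) -> SystemConfig:
    """Fragment holding the given molecules, preserving global indices."""
    rows = []
    molecules = []
    mol_ids = []
    for m in molecule_rows:
        members = system.molecules[m]
        molecules.append(members.copy())
        mol_ids.append(system.molecule_ids[m])
        rows.extend(system.local_index(g) for g in members)
    rows = np.asarray(rows, dtype=np.int64)
    return SystemConfig(
        box=system.box.copy(),
        labels=[system.labels[r] for r in rows],
        type_ids=system.type_ids[rows],
        positions=system.positions[rows].copy(),
        velocities=None if system.velocities is None else system.velocities[rows].copy(),
        connectivity=[list(system.connectivity[r]) for r in rows],
        molecules=molecules,
        molecule_ids=mol_ids,
        global_indices=system.global_indices[rows],
    )


@dataclass
class RunSettings:
    """Run control parameters (timestep in ps, temperature in K)."""

    timestep: float = 0.03
    n_steps: int = 1000
    field_update_every: int = 100
    temperature: float = 300.0
    thermostat_nu: float = 7.0  # Andersen collision frequency, ps^-1
    seed: int = 0
    mesh: tuple[int, int, int] = (8, 8, 8)
    output_every: int = 100
    reduction: str = "pairwise"
    freeze_forces_between_updates: bool = False

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ModelError("timestep must be > 0")
        if self.field_update_every < 1:
            raise ModelError("field_update_every must be >= 1")
        if any(m < 2 for m in self.mesh):
            raise ModelError("mesh must have at least 2 cells per axis")
        if self.reduction not in ("sequential", "pairwise"):
            raise ModelError(f"unknown reduction strategy {self.reduction!r}")
        if self.thermostat_nu * self.timestep > 1:
            raise ModelError("thermostat collision probability nu*dt exceeds 1")


_RUN_KEYS = {
    "timestep",
    "n_steps",
    "field_update_every",
    "temperature",
    "thermostat_nu",
    "seed",
    "mesh",
    "output_every",
    "reduction",
    "freeze_forces_between_updates",
}


def read_model(source: IO[str] | str) -> tuple[ForceField, RunSettings]:
    """Parse the YAML model/parameter document.

    Returns a :class:`ForceField` (symmetric χ matrix with missing pairs
    defaulting to 0, κ⁻¹ in kT units, bonded parameter sets bound to species
    tuples) and a :class:`RunSettings`; omitted run settings fall back to
    defaults with a logged notice.
    """
    doc = yaml.safe_load(source if isinstance(source, str) else source.read())
    if not isinstance(doc, dict):
        raise ModelError("model file must be a key-value document")

    species = doc.get("species")
    if not species or not isinstance(species, list):
        raise ModelError("model file must list species names")
    species = [str(s) for s in species]
    index = {name: k for k, name in enumerate(species)}
    n = len(species)

    chi = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for entry in doc.get("chi", []) or []:
        try:
            a, b, value = entry
        except (TypeError, ValueError):
            raise ModelError(f"chi entry must be [species, species, value], got {entry!r}") from None
        for name in (a, b):
            if name not in index:
                raise ModelError(f"unknown species {name!r} in chi entry")
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        value = float(value)
        if key in seen and seen[key] != value:
            raise ModelError(
                f"conflicting chi values for pair {a}-{b}: {seen[key]} vs {value}"
            )
        seen[key] = value
        chi[i, j] = chi[j, i] = value

    if "kappa_inv" in doc:
        kappa_inv = float(doc["kappa_inv"])
        if kappa_inv < 0:
            raise ModelError("kappa_inv must be >= 0")
    elif "kappa" in doc:
        kappa = float(doc["kappa"])
        if kappa <= 0:
            raise ModelError("compressibility kappa must be > 0")
        kappa_inv = 1.0 / kappa
    else:
        kappa_inv = 0.0
        logger.info("no kappa/kappa_inv given; incompressibility term disabled")

    masses = np.ones(n)
    for name, m in (doc.get("masses") or {}).items():
        if name not in index:
            raise ModelError(f"unknown species {name!r} in masses")
        masses[index[name]] = float(m)

    def _types(names, width, kind):
        if names in ("*", ["*"]):
            return "*"
        if not isinstance(names, list) or len(names) != width:
            raise ModelError(f"{kind} entry needs {width} species names, got {names!r}")
        for nm in names:
            if nm != "*" and nm not in index:
                raise ModelError(f"unknown species {nm!r} in {kind} entry")
        return tuple(index[nm] if nm != "*" else -1 for nm in names)

    bond_params = {}
    for entry in doc.get("bonds", []) or []:
        key = _types(entry.get("types", "*"), 2, "bond")
        bond_params[key] = BondParam(k=float(entry["k"]), r0=float(entry["r0"]))
    angle_params = {}
    for entry in doc.get("angles", []) or []:
        key = _types(entry.get("types", "*"), 3, "angle")
        angle_params[key] = AngleParam(k=float(entry["k"]), theta0=float(entry["theta0"]))
    dihedral_params = {}
    for entry in doc.get("dihedrals", []) or []:
        key = _types(entry.get("types", "*"), 4, "dihedral")
        dihedral_params[key] = DihedralParam(
            k=float(entry["k"]), n=int(entry.get("n", 1)), delta=float(entry.get("delta", 0.0))
        )

    temperature = float(doc.get("temperature", 300.0))
    ff = ForceField(
        species=species,
        chi=chi,
        kappa_inv=kappa_inv,
        temperature=temperature,
        masses=masses,
        bond_params=bond_params,
        angle_params=angle_params,
        dihedral_params=dihedral_params,
    )

    kwargs = {}
    for key in _RUN_KEYS:
        if key in doc:
            kwargs[key] = doc[key]
        elif key != "temperature":
            logger.info("run setting %r not in model file; using default", key)
    kwargs["temperature"] = temperature
    if "mesh" in kwargs:
        mesh = kwargs["mesh"]
        if not (isinstance(mesh, list) and len(mesh) == 3):
            raise ModelError("mesh must be a list of 3 cell counts")
        kwargs["mesh"] = tuple(int(m) for m in mesh)
    settings = RunSettings(**kwargs)

    unknown = set(doc) - _RUN_KEYS - {
        "species", "chi", "kappa", "kappa_inv", "masses", "bonds", "angles", "dihedrals",
    }
    if unknown:
        logger.warning("ignoring unknown model keys: %s", sorted(unknown))
    return ff, settings


def write_model(ff: ForceField, settings: RunSettings, sink: IO[str]) -> None:
    """Emit a model document that :func:`read_model` parses back."""
    doc: dict = {
        "species": list(ff.species),
        "chi": [
            [ff.species[i], ff.species[j], float(ff.chi[i, j])]
            for i in range(len(ff.species))
            for j in range(i, len(ff.species))
            if ff.chi[i, j] != 0.0
        ],
        "kappa_inv": float(ff.kappa_inv),
        "masses": {ff.species[k]: float(m) for k, m in enumerate(ff.masses)},
        "temperature": settings.temperature,
        "timestep": settings.timestep,
        "n_steps": settings.n_steps,
        "field_update_every": settings.field_update_every,
        "thermostat_nu": settings.thermostat_nu,
        "seed": settings.seed,
        "mesh": list(settings.mesh),
        "output_every": settings.output_every,
        "reduction": settings.reduction,
    }

    def name(t: int) -> str:
        return "*" if t < 0 else ff.species[t]

    if ff.bond_params:
        doc["bonds"] = [
            {"types": "*" if k == "*" else [name(t) for t in k], "k": p.k, "r0": p.r0}
            for k, p in ff.bond_params.items()
        ]
    if ff.angle_params:
        doc["angles"] = [
            {"types": "*" if k == "*" else [name(t) for t in k], "k": p.k, "theta0": p.theta0}
            for k, p in ff.angle_params.items()
        ]
    if ff.dihedral_params:
        doc["dihedrals"] = [
            {"types": "*" if k == "*" else [name(t) for t in k], "k": p.k, "n": p.n, "delta": p.delta}
            for k, p in ff.dihedral_params.items()
        ]
    yaml.safe_dump(doc, sink, sort_keys=False)


def write_trajectory_frame(
    positions: np.ndarray,
    labels: Sequence[str],
    box: np.ndarray,
    sink: IO[str],
    step: int = 0,
    time: float = 0.0,
) -> None:
    """Append one XYZ frame; the comment line carries box lengths and step."""
    n = len(positions)
    if len(labels) != n:
        raise ValidationError("labels and positions length mismatch")
    sink.write(f"{n}\n")
    f = _FLOAT_FMT.format
    sink.write(f"box {f(box[0])} {f(box[1])} {f(box[2])} step {step} time {f(time)}\n")
    for lab, p in zip(labels, positions):
        sink.write(f"{lab} {f(p[0])} {f(p[1])} {f(p[2])}\n")


def read_trajectory(source: IO[str] | str) -> list[dict]:
    """Parse an XYZ trajectory written by :func:`write_trajectory_frame`."""
    if isinstance(source, str):
        source = io.StringIO(source)
    frames = []
    while True:
        header = source.readline()
        if not header.strip():
            break
        n = int(header)
        comment = source.readline().split()
        box = np.array([float(x) for x in comment[1:4]])
        step = int(comment[5]) if len(comment) > 5 else 0
        labels, pos = [], np.zeros((n, 3))
        for i in range(n):
            tok = source.readline().split()
            labels[len(labels):] = [tok[0]]
            pos[i] = [float(t) for t in tok[1:4]]
        frames.append({"labels": labels, "positions": pos, "box": box, "step": step})
    return frames
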