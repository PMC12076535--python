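"""Bonded interaction lists and whole-molecule partitioning.

Angles and dihedrals are enumerated from the bond graph (every 2-bond path
through a central vertex, every simple 3-bond path) in canonical orientation
and lexicographic order, so identical inputs always yield byte-identical
lists.  Explicit lists may be supplied instead and override generation.

Molecules are assigned whole to ranks — never split — by greedy
longest-processing-time balancing on per-molecule particle counts, with the
molecule index as tie-break.  Bonded terms therefore never cross ranks and
need no communication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hpfmd.errors import ModelError, PartitionError, TopologyError


@dataclass
class BondedLists:
    """Canonical bond/angle/dihedral index tables with per-row type tuples."""

    bond_list: np.ndarray  # (nb, 2)
    ang_list: np.ndarray  # (na, 3)
    dih_list: np.ndarray  # (nd, 4)
    bond_types: np.ndarray  # (nb, 2) species ids
    ang_types: np.ndarray  # (na, 3)
    dih_types: np.ndarray  # (nd, 4)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_list)

    @property
    def n_angles(self) -> int:
        return len(self.ang_list)

    @property
    def n_dihedrals(self) -> int:
        return len(self.dih_list)


@dataclass
class Partition:
    """Whole-molecule assignment of a system to worker ranks."""

    rank_of: np.ndarray  # (n_molecules,)
    n_ranks: int
    particle_counts: np.ndarray  # (n_ranks,)

    def molecules_of(self, rank: int) -> list[int]:
        return [int(m) for m in np.flatnonzero(self.rank_of == rank)]


def _neighbor_map(system) -> dict[int, list[int]]:
    nbrs: dict[int, list[int]] = {}
    for row, partners in enumerate(system.connectivity):
        g = int(system.global_indices[row])
        nbrs[g] = sorted(int(p) for p in partners)
    return nbrs


def build_bonded_lists(system, ff=None, generate_angles: bool = True,
                       generate_dihedrals: bool = True, explicit: dict | None = None) -> BondedLists:
    """Derive bond, angle and dihedral tables from connectivity.

    ``explicit`` may carry pre-built ``"angles"``/``"dihedrals"`` index tables
    (global indices) that override graph enumeration.  When ``ff`` provides
    bonded parameter tables, every generated row must resolve to a parameter
    set, otherwise a :class:`ModelError` is raised.
    """
    nbrs = _neighbor_map(system)
    type_of = {
        int(system.global_indices[row]): int(system.type_ids[row])
        for row in range(system.n_particles)
    }

    bonds = sorted(
        (g, p) for g, partners in nbrs.items() for p in partners if g < p
    )
    bond_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)

    if explicit and "angles" in explicit:
        angles = [tuple(int(x) for x in row) for row in explicit["angles"]]
    elif generate_angles:
        angles = []
        for j, partners in nbrs.items():
            for a in range(len(partners)):
                for b in range(a + 1, len(partners)):
                    i, k = partners[a], partners[b]
                    angles.append((i, j, k) if i < k else (k, j, i))
        angles.sort()
    else:
        angles = []
    ang_arr = np.array(angles, dtype=np.int64).reshape(-1, 3)

    if explicit and "dihedrals" in explicit:
        dihedrals = sorted({tuple(int(x) for x in row) for row in explicit["dihedrals"]})
    elif generate_dihedrals:
        found = set()
        for j, k in bonds:
            for i in nbrs[j]:
                if i == k:
                    continue
                for l in nbrs[k]:
                    if l == j or l == i:
                        continue
                    quad = (i, j, k, l) if i < l else (l, k, j, i)
                    found.add(quad)
        dihedrals = sorted(found)
    else:
        dihedrals = []
    dih_arr = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    def types_for(arr: np.ndarray) -> np.ndarray:
        return np.array(
            [[type_of[int(g)] for g in row] for row in arr], dtype=np.int64
        ).reshape(arr.shape)

    lists = BondedLists(
        bond_list=bond_arr,
        ang_list=ang_arr,
        dih_list=dih_arr,
        bond_types=types_for(bond_arr),
        ang_types=types_for(ang_arr),
        dih_types=types_for(dih_arr),
    )

    mol_of = {}
    for m, members in enumerate(system.molecules):
        for g in members:
            mol_of[int(g)] = m
    for arr, kind in ((bond_arr, "bond"), (ang_arr, "angle"), (dih_arr, "dihedral")):
        for row in arr:
            mols = {mol_of[int(g)] for g in row}
            if len(mols) != 1:
                raise TopologyError(f"{kind} row {row.tolist()} spans molecules {sorted(mols)}")

    if ff is not None:
        if ff.bond_params:
            for ti, tj in lists.bond_types:
                ff.bond_param(int(ti), int(tj))
        if ff.angle_params:
            for ti, tj, tk in lists.ang_types:
                ff.angle_param(int(ti), int(tj), int(tk))
        if ff.dihedral_params:
            for ti, tj, tk, tl in lists.dih_types:
                ff.dihedral_param(int(ti), int(tj), int(tk), int(tl))
        if bond_arr.size and not ff.bond_params:
            raise ModelError("system has bonds but the model defines no bond parameters")
    return lists


def partition_molecules(system, n_ranks: int) -> Partition:
    """Greedy LPT assignment of whole molecules to ranks by particle count.

    Deterministic: molecules are taken largest-first (index as tie-break) and
    placed on the currently lightest rank (lowest rank id on ties).
    """
    if n_ranks < 1:
        raise PartitionError("n_ranks must be >= 1")
    n_mol = system.n_molecules
    if n_ranks > n_mol:
        raise PartitionError(
            f"cannot spread {n_mol} molecules over {n_ranks} ranks without an empty rank"
        )
    sizes = np.array([len(m) for m in system.molecules], dtype=np.int64)
    order = sorted(range(n_mol), key=lambda m: (-sizes[m], m))
    rank_of = np.empty(n_mol, dtype=np.int64)
    loads = np.zeros(n_ranks, dtype=np.int64)
    for m in order:
        r = int(np.argmin(loads))  # argmin takes the lowest index on ties
        rank_of[m] = r
        loads[r] += sizes[m]
    return Partition(rank_of=rank_of, n_ranks=n_ranks, particle_counts=loads)


def validate_partition(partition: Partition, n_molecules: int) -> None:
    """Reject overlapping/incomplete assignments."""
    if len(partition.rank_of) != n_molecules:
        raise PartitionError("partition covers a different number of molecules")
    if np.any(partition.rank_of < 0) or np.any(partition.rank_of >= partition.n_ranks):
        raise PartitionError("molecule assigned to an out-of-range rank")
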