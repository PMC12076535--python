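"""Intramolecular forces: harmonic bonds and angles, cosine dihedrals.

All distances use the minimum-image convention, so molecules may span the
periodic seam.  Contributions to shared atoms are accumulated in
deterministic list order — the serial contract standing in for conflict-safe
atomic accumulation in the parallel setting.  Every term obeys Newton's
third law exactly: per-bond forces are equal and opposite, per-angle and
per-dihedral forces sum to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hpfmd.errors import SimulationError

logger = logging.getLogger(__name__)

_SIN_GUARD = 1e-8  # collinear-angle derivative guard


@dataclass(frozen=True)
class BondParam:
    """Harmonic bond ½ k (r − r0)²; k in kJ mol⁻¹ nm⁻², r0 in nm."""

    k: float
    r0: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.r0 <= 0:
            raise ValueError("bond requires k >= 0 and r0 > 0")


@dataclass(frozen=True)
class AngleParam:
    """Harmonic angle ½ k (θ − θ0)²; k in kJ mol⁻¹ rad⁻², θ0 in rad."""

    k: float
    theta0: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("angle requires k >= 0")


@dataclass(frozen=True)
class DihedralParam:
    """Cosine dihedral k (1 + cos(nφ − δ)); k in kJ/mol, integer n ≥ 1."""

    k: float
    n: int
    delta: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.n < 1:
            raise ValueError("dihedral requires k >= 0 and n >= 1")


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Nearest periodic image of displacement(s) d."""
    box = np.asarray(box, dtype=float)
    return d - np.round(d / box) * box


def _per_row(params, rows: int, fields: tuple[str, ...]):
    """Broadcast a single param set or a list of per-row sets to arrays."""
    if isinstance(params, (list, tuple, np.ndarray)):
        return tuple(np.array([getattr(p, f) for p in params], dtype=float) for f in fields)
    return tuple(np.full(rows, float(getattr(params, f))) for f in fields)


def bond_forces(positions, bond_list, params, box, return_terms: bool = False):
    """Harmonic bond forces and energy over ``bond_list``.

    ``params`` is a single :class:`BondParam` or a per-row sequence.  Returns
    ``(forces, energy)``; with ``return_terms`` the per-bond energy array is
    returned instead of its sum.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    bond_list = np.asarray(bond_list, dtype=np.int64).reshape(-1, 2)
    if bond_list.size == 0:
        terms = np.zeros(0)
        return (forces, terms) if return_terms else (forces, 0.0)
    k, r0 = _per_row(params, len(bond_list), ("k", "r0"))
    i, j = bond_list[:, 0], bond_list[:, 1]
    d = minimum_image(positions[j] - positions[i], box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise SimulationError("zero-length bond vector")
    terms = 0.5 * k * (r - r0) ** 2
    fmag = -k * (r - r0) / r  # force on j along +d
    fvec = fmag[:, None] * d
    np.add.at(forces, j, fvec)
    np.add.at(forces, i, -fvec)
    return (forces, terms) if return_terms else (forces, float(terms.sum()))


def angle_forces(positions, ang_list, params, box, return_terms: bool = False):
    """Harmonic angle forces and energy; the middle index of each row is the vertex.

    Collinear geometries (θ → 0 or π) are handled by capping the 1/sinθ
    derivative factor; the cap is logged once per call.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    ang_list = np.asarray(ang_list, dtype=np.int64).reshape(-1, 3)
    if ang_list.size == 0:
        terms = np.zeros(0)
        return (forces, terms) if return_terms else (forces, 0.0)
    k, theta0 = _per_row(params, len(ang_list), ("k", "theta0"))
    i, j, m = ang_list[:, 0], ang_list[:, 1], ang_list[:, 2]
    u = minimum_image(positions[i] - positions[j], box)
    v = minimum_image(positions[m] - positions[j], box)
    lu = np.linalg.norm(u, axis=1)
    lv = np.linalg.norm(v, axis=1)
    if np.any(lu == 0) or np.any(lv == 0):
        raise SimulationError("zero-length angle arm")
    cos_t = np.clip(np.einsum("na,na->n", u, v) / (lu * lv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 0.0))
    degenerate = sin_t < _SIN_GUARD
    if np.any(degenerate):
        logger.warning("capping %d collinear angle term(s)", int(degenerate.sum()))
        sin_t = np.maximum(sin_t, _SIN_GUARD)
    terms = 0.5 * k * (theta - theta0) ** 2
    # F = -dU/dθ · dθ/dr with dθ/dr = -(1/sinθ) dcosθ/dr
    coef = k * (theta - theta0) / sin_t
    fi = coef[:, None] * (v / (lu * lv)[:, None] - cos_t[:, None] * u / (lu * lu)[:, None])
    fm = coef[:, None] * (u / (lu * lv)[:, None] - cos_t[:, None] * v / (lv * lv)[:, None])
    np.add.at(forces, i, fi)
    np.add.at(forces, m, fm)
    np.add.at(forces, j, -(fi + fm))
    return (forces, terms) if return_terms else (forces, float(terms.sum()))


def dihedral_forces(positions, dih_list, params, box, return_terms: bool = False):
    """Cosine dihedral forces and energy over (i, j, k, l) quadruplets.

    φ is the angle between the (i,j,k) and (j,k,l) planes, signed by the
    right-hand rule about the central j→k bond.  Degenerate (collinear)
    central geometry is guarded by capping the plane-normal norms.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    dih_list = np.asarray(dih_list, dtype=np.int64).reshape(-1, 4)
    if dih_list.size == 0:
        terms = np.zeros(0)
        return (forces, terms) if return_terms else (forces, 0.0)
    kd, mult, delta = _per_row(params, len(dih_list), ("k", "n", "delta"))
    ia, ja, ka, la = (dih_list[:, c] for c in range(4))
    b1 = minimum_image(positions[ja] - positions[ia], box)
    b2 = minimum_image(positions[ka] - positions[ja], box)
    b3 = minimum_image(positions[la] - positions[ka], box)
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2, axis=1)
    m2 = np.maximum(np.einsum("na,na->n", m, m), _SIN_GUARD**2)
    n2 = np.maximum(np.einsum("na,na->n", n, n), _SIN_GUARD**2)
    if np.any(lb2 == 0):
        raise SimulationError("zero-length central dihedral bond")
    phi = np.arctan2(
        np.einsum("na,na->n", np.cross(m, n), b2) / lb2,
        np.einsum("na,na->n", m, n),
    )
    terms = kd * (1.0 + np.cos(mult * phi - delta))
    dU = -kd * mult * np.sin(mult * phi - delta)  # dU/dφ
    dphi_di = -(lb2 / m2)[:, None] * m
    dphi_dl = (lb2 / n2)[:, None] * n
    s = (np.einsum("na,na->n", b1, b2) / (lb2 * lb2))[:, None]
    t = (np.einsum("na,na->n", b3, b2) / (lb2 * lb2))[:, None]
    dphi_dj = -(1.0 + s) * dphi_di + t * dphi_dl
    dphi_dk = s * dphi_di - (1.0 + t) * dphi_dl
    np.add.at(forces, ia, -dU[:, None] * dphi_di)
    np.add.at(forces, ja, -dU[:, None] * dphi_dj)
    np.add.at(forces, ka, -dU[:, None] * dphi_dk)
    np.add.at(forces, la, -dU[:, None] * dphi_dl)
    return (forces, terms) if return_terms else (forces, float(terms.sum()))
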