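import io

import numpy as np
import pytest

from hpfmd.bonded_forces import AngleParam, BondParam
from hpfmd.density_mesh import MeshSpec
from hpfmd.field_forces import ForceField
from hpfmd.model_io import SystemConfig


CHAIN3_TEXT = """\
# three-bead chain, one molecule
3 1 0
10.0 10.0 10.0
molecule 1 3
1 CA 1 1 1.0 1.0 1.0 2
2 CB 1 2 1.5 1.0 1.0 1 3
3 CA 1 1 2.0 1.0 1.0 2
"""


@pytest.fixture
def chain3_text():
    return CHAIN3_TEXT


@pytest.fixture
def chain3_stream():
    return io.StringIO(CHAIN3_TEXT)


def make_chain(n_beads: int, box=(10.0, 10.0, 10.0), spacing: float = 0.47) -> SystemConfig:
    """Single linear bead-spring chain along x."""
    positions = np.zeros((n_beads, 3))
    positions[:, 0] = 1.0 + spacing * np.arange(n_beads)
    positions[:, 1] = positions[:, 2] = 5.0
    connectivity = []
    for b in range(n_beads):
        partners = []
        if b > 0:
            partners.append(b - 1)
        if b < n_beads - 1:
            partners.append(b + 1)
        connectivity.append(partners)
    return SystemConfig(
        box=np.asarray(box, dtype=float),
        labels=["B"] * n_beads,
        type_ids=np.zeros(n_beads, dtype=np.int64),
        positions=positions,
        velocities=None,
        connectivity=connectivity,
        molecules=[np.arange(n_beads)],
    )


@pytest.fixture
def mesh10():
    return MeshSpec(cells=(10, 10, 10), box=(10.0, 10.0, 10.0))


@pytest.fixture
def simple_ff():
    """One-species force field with generic chain bonded terms."""
    return ForceField(
        species=["B"],
        chi=np.zeros((1, 1)),
        kappa_inv=5.0,
        temperature=300.0,
        masses=np.array([72.0]),
        bond_params={"*": BondParam(k=1250.0, r0=0.47)},
        angle_params={"*": AngleParam(k=25.0, theta0=np.pi)},
    )
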