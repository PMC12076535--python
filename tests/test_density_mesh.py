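import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from hpfmd.density_mesh import (
    DensityField,
    MeshSpec,
    StoredGradientReference,
    assign_density,
    density_at,
    field_from_system,
    gradient_at,
    locate,
    reduce_partials,
)
from hpfmd.builders import build_lipid_water
from hpfmd.errors import ValidationError
from hpfmd.topology import partition_molecules


MESH = MeshSpec(cells=(10, 10, 10), box=(10.0, 10.0, 10.0))


def brute_force_weights(position, mesh):
    """Independent per-particle CIC weight formula."""
    pos = np.asarray(position, dtype=float) % mesh.box_array
    scaled = pos / mesh.cell_size
    base = np.floor(scaled).astype(int)
    f = scaled - base
    weights = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[0] if dx else 1 - f[0])
                    * (f[1] if dy else 1 - f[1])
                    * (f[2] if dz else 1 - f[2])
                )
                pt = tuple((base + [dx, dy, dz]) % mesh.cells_array)
                weights[pt] = weights.get(pt, 0.0) + w
    return weights


class TestLocate:
    def test_lattice_point_has_zero_offset(self):
        idx, frac = locate(np.array([0.0, 0.0, 0.0]), MESH)
        assert idx.tolist() == [0, 0, 0]
        assert frac.tolist() == [0.0, 0.0, 0.0]

    def test_periodic_wrap(self):
        idx, frac = locate(np.array([25.0, 0.0, 0.0]), MESH)
        assert idx[0] == 5
        assert frac[0] == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-20, 30, size=(10_000, 3))
        idx, frac = locate(pos, MESH)
        rebuilt = (idx + frac) * MESH.cell_size
        wrapped = pos - np.floor(pos / MESH.box_array) * MESH.box_array
        assert np.abs(rebuilt - wrapped).max() < 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            locate(np.array([np.nan, 0.0, 0.0]), MESH)

    @hsettings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=3))
    def test_offsets_in_unit_cube(self, coords):
        idx, frac = locate(np.array(coords), MESH)
        assert np.all(idx >= 0) and np.all(idx < 10)
        assert np.all(frac >= 0.0) and np.all(frac < 1.0)


class TestAssignDensity:
    def test_particle_on_lattice_point(self):
        raw = assign_density(np.array([[3.0, 4.0, 5.0]]), np.array([0]), MESH, 1).grids
        assert raw[0, 3, 4, 5] == 1.0
        assert raw.sum() == 1.0

    def test_cell_center_splits_eightfold(self):
        raw = assign_density(np.array([[0.5, 0.5, 0.5]]), np.array([0]), MESH, 1).grids
        occupied = raw[raw > 0]
        assert len(occupied) == 8
        assert np.allclose(occupied, 0.125)

    def test_conservation_random(self):
        rng = np.random.default_rng(1)
        pos = rng.random((1000, 3)) * MESH.box_array
        sp = rng.integers(0, 2, size=1000)
        raw = assign_density(pos, sp, MESH, 2).grids
        for k in range(2):
            count = (sp == k).sum()
            assert abs(raw[k].sum() - count) / count < 1e-12

    def test_matches_brute_force_weights(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pos = rng.random(3) * MESH.box_array
            raw = assign_density(pos[None, :], np.array([0]), MESH, 1).grids[0]
            for pt, w in brute_force_weights(pos, MESH).items():
                assert raw[pt] == pytest.approx(w, abs=1e-14)

    def test_species_out_of_range(self):
        with pytest.raises(ValidationError):
            assign_density(np.zeros((1, 3)), np.array([5]), MESH, 2)

    def test_repeated_calls_bit_identical(self):
        rng = np.random.default_rng(3)
        pos = rng.random((500, 3)) * MESH.box_array
        sp = rng.integers(0, 3, size=500)
        a = assign_density(pos, sp, MESH, 3).grids
        b = assign_density(pos, sp, MESH, 3).grids
        assert a.tobytes() == b.tobytes()

    def test_periodicity_exact_on_representable_shift(self):
        # dyadic coordinates in a power-of-two box make x + L exactly
        # representable, so the shifted field must be bit-identical
        mesh = MeshSpec(cells=(8, 8, 8), box=(8.0, 8.0, 8.0))
        rng = np.random.default_rng(4)
        pos = rng.integers(0, 512, size=(200, 3)) / 64.0
        sp = np.zeros(200, dtype=np.int64)
        a = assign_density(pos, sp, mesh, 1).grids
        b = assign_density(pos + mesh.box_array, sp, mesh, 1).grids
        assert a.tobytes() == b.tobytes()


def random_field(seed, mesh=MESH, n_species=2, n=500):
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3)) * mesh.box_array
    sp = rng.integers(0, n_species, size=n)
    rho0 = n / float(np.prod(mesh.box_array))
    return reduce_partials([assign_density(pos, sp, mesh, n_species)], rho0)


class TestReducePartials:
    def test_single_partial_is_normalized_serial(self):
        rng = np.random.default_rng(5)
        pos = rng.random((100, 3)) * MESH.box_array
        sp = np.zeros(100, dtype=np.int64)
        partial = assign_density(pos, sp, MESH, 1)
        field = reduce_partials([partial], rho0=0.1)
        assert np.allclose(field.phi, partial.grids / (0.1 * MESH.cell_volume))

    def test_partitioned_equals_serial(self):
        system = build_lipid_water(8, 200, (6.0, 6.0, 12.0), seed=6)
        mesh = MeshSpec(cells=(6, 6, 12), box=(6.0, 6.0, 12.0))
        serial = field_from_system(system, mesh, 3)
        for n_ranks in (2, 4):
            part = partition_molecules(system, n_ranks)
            split = field_from_system(system, mesh, 3, partition=part)
            assert np.abs(split.phi - serial.phi).max() < 1e-12

    def test_empty_partial_contributes_zero(self):
        a = assign_density(np.array([[1.0, 1.0, 1.0]]), np.array([0]), MESH, 2)
        empty = assign_density(np.zeros((0, 3)), np.zeros(0, dtype=int), MESH, 2)
        with_empty = reduce_partials([a, empty], 1.0)
        alone = reduce_partials([a], 1.0)
        assert np.array_equal(with_empty.phi, alone.phi)

    def test_mismatched_mesh_rejected(self):
        other = MeshSpec(cells=(5, 5, 5), box=(10.0, 10.0, 10.0))
        a = assign_density(np.zeros((1, 3)), np.array([0]), MESH, 1)
        b = assign_density(np.zeros((1, 3)), np.array([0]), other, 1)
        with pytest.raises(ValidationError):
            reduce_partials([a, b], 1.0)


class TestDensityAt:
    def test_uniform_field_constant(self):
        field = DensityField(phi=np.full((1, *MESH.cells), 0.7), mesh=MESH, rho0=1.0)
        rng = np.random.default_rng(7)
        for pos in rng.random((20, 3)) * MESH.box_array:
            assert density_at(pos, 0, field) == pytest.approx(0.7, abs=1e-14)

    def test_lattice_point_value_exact(self):
        field = random_field(8)
        assert density_at(np.array([3.0, 4.0, 5.0]), 1, field) == field.phi[1, 3, 4, 5]

    def test_matches_brute_force_interpolation(self):
        field = random_field(9)
        rng = np.random.default_rng(10)
        for pos in rng.random((100, 3)) * MESH.box_array:
            expected = sum(
                w * field.phi[0][pt]
                for pt, w in brute_force_weights(pos, MESH).items()
            )
            assert density_at(pos, 0, field) == pytest.approx(expected, rel=1e-12, abs=1e-14)


class TestGradientAt:
    def test_uniform_field_zero_gradient(self):
        field = DensityField(phi=np.full((1, *MESH.cells), 0.3), mesh=MESH, rho0=1.0)
        rng = np.random.default_rng(11)
        g = gradient_at(rng.random((50, 3)) * MESH.box_array, 0, field)
        assert np.abs(g).max() < 1e-13

    def test_linear_ramp_recovers_slope(self):
        # ϕ(x) = b·x on the lattice; away from the wrap seam the staggered
        # stencil must return exactly (b, 0, 0)
        b = 0.25
        x = np.arange(10) * MESH.cell_size[0]
        phi = np.tile(b * x[:, None, None], (1, 10, 10))[None, ...]
        field = DensityField(phi=phi, mesh=MESH, rho0=1.0)
        rng = np.random.default_rng(12)
        probes = rng.random((200, 3)) * np.array([6.0, 10.0, 10.0]) + np.array([2.0, 0, 0])
        g = gradient_at(probes, 0, field)
        assert np.abs(g[:, 0] - b).max() < 1e-10
        assert np.abs(g[:, 1:]).max() < 1e-10

    def test_on_the_fly_equals_stored_reference(self):
        field = random_field(13)
        rng = np.random.default_rng(14)
        probes = rng.random((1000, 3)) * MESH.box_array
        sp = rng.integers(0, 2, size=1000)
        a = gradient_at(probes, sp, field)
        b = StoredGradientReference(field).gradient_at(probes, sp)
        assert np.array_equal(a, b)
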