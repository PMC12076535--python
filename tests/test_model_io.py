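import io

import numpy as np
import pytest

from hpfmd.builders import build_fluid, build_lipid_water
from hpfmd.errors import ConfigParseError, ModelError, TopologyError, ValidationError
from hpfmd.model_io import (
    read_configuration,
    read_configuration_chunk,
    read_model,
    read_trajectory,
    write_configuration,
    write_trajectory_frame,
)
from hpfmd.topology import partition_molecules


def systems_equal(a, b):
    assert a.n_particles == b.n_particles
    assert a.n_molecules == b.n_molecules
    assert np.array_equal(a.box, b.box)
    assert a.labels == b.labels
    assert np.array_equal(a.type_ids, b.type_ids)
    assert np.array_equal(a.positions, b.positions)
    if a.velocities is None:
        assert b.velocities is None
    else:
        assert np.array_equal(a.velocities, b.velocities)
    assert [sorted(c) for c in a.connectivity] == [sorted(c) for c in b.connectivity]
    assert all(np.array_equal(x, y) for x, y in zip(a.molecules, b.molecules))


class TestReadConfiguration:
    def test_minimal_chain(self, chain3_stream):
        system = read_configuration(chain3_stream)
        assert system.n_particles == 3
        assert system.n_molecules == 1
        assert system.connectivity == [[1], [0, 2], [1]]
        assert system.labels == ["CA", "CB", "CA"]
        assert system.velocities is None  # to be drawn by the thermostat

    def test_asymmetric_connectivity_rejected(self):
        text = (
            "3 1 0\n10 10 10\nmolecule 1 3\n"
            "1 A 1 0 0 0 0\n"
            "2 A 1 1 1 0 0 3\n"
            "3 A 1 0 2 0 0\n"
        )
        with pytest.raises(TopologyError, match="asymmetric"):
            read_configuration(text)

    def test_out_of_range_index_rejected(self):
        text = (
            "2 1 0\n10 10 10\nmolecule 1 2\n"
            "1 A 1 1 0 0 0 9\n"
            "2 A 1 1 1 0 0 1\n"
        )
        with pytest.raises(TopologyError):
            read_configuration(text)

    def test_malformed_line_names_line_number(self):
        text = "2 1 0\n10 10 oops\nmolecule 1 2\n1 A 1 0 0 0 0\n2 A 1 0 1 0 0\n"
        with pytest.raises(ConfigParseError, match="line 2"):
            read_configuration(text)

    def test_bond_count_mismatch_rejected(self):
        text = "1 1 0\n10 10 10\nmolecule 1 1\n1 A 1 2 0 0 0 1\n"
        with pytest.raises(TopologyError, match="declares 2 bonds"):
            read_configuration(text)


class TestWriteConfiguration:
    def test_round_trip_identity(self):
        system = build_fluid(1000, (12.0, 9.0, 7.5), seed=3)
        buf = io.StringIO()
        write_configuration(system, buf)
        again = read_configuration(buf.getvalue())
        systems_equal(system, again)

    def test_canonical_byte_round_trip(self, chain3_text):
        once = io.StringIO()
        write_configuration(read_configuration(chain3_text), once)
        twice = io.StringIO()
        write_configuration(read_configuration(once.getvalue()), twice)
        assert once.getvalue() == twice.getvalue()

    def test_velocity_columns_only_when_present(self):
        system = build_fluid(5, (5.0, 5.0, 5.0), seed=0)
        buf = io.StringIO()
        write_configuration(system, buf)
        header = buf.getvalue().splitlines()[0]
        assert header.split()[2] == "0"
        system.velocities = np.zeros((5, 3))
        buf2 = io.StringIO()
        write_configuration(system, buf2)
        assert buf2.getvalue().splitlines()[0].split()[2] == "1"
        systems_equal(system, read_configuration(buf2.getvalue()))

    def test_invalid_system_refused(self):
        system = build_fluid(4, (5.0, 5.0, 5.0), seed=0)
        system.connectivity[0] = [1]  # asymmetric on purpose
        with pytest.raises(TopologyError):
            write_configuration(system, io.StringIO())


class TestReadModel:
    def test_symmetry_completion(self):
        ff, _ = read_model("species: [A, B]\nchi:\n  - [A, B, 10.0]\nkappa_inv: 5\n")
        assert np.array_equal(ff.chi, [[0.0, 10.0], [10.0, 0.0]])

    def test_zero_kappa_rejected(self):
        with pytest.raises(ModelError):
            read_model("species: [A]\nkappa: 0.0\n")

    def test_conflicting_chi_rejected(self):
        doc = "species: [A, B]\nchi:\n  - [A, B, 10.0]\n  - [B, A, 11.0]\n"
        with pytest.raises(ModelError, match="conflicting"):
            read_model(doc)

    def test_unknown_species_rejected(self):
        with pytest.raises(ModelError, match="unknown species"):
            read_model("species: [A]\nchi:\n  - [A, Z, 1.0]\n")

    def test_full_lipid_model_binds_everything(self):
        doc = """
species: [W, H, T, C, N]
chi:
  - [W, T, 30.0]
  - [W, H, -5.0]
  - [H, T, 15.0]
  - [C, N, 2.5]
kappa_inv: 5.0
temperature: 325.0
timestep: 0.03
field_update_every: 100
mesh: [8, 8, 8]
bonds:
  - {types: [H, T], k: 1250.0, r0: 0.47}
  - {types: [T, T], k: 1250.0, r0: 0.47}
angles:
  - {types: [T, T, T], k: 25.0, theta0: 3.14159}
"""
        ff, settings = read_model(doc)
        assert ff.chi.shape == (5, 5)
        # exhaustive symmetry scan
        for i in range(5):
            for j in range(5):
                assert ff.chi[i, j] == ff.chi[j, i]
        h, t = ff.species.index("H"), ff.species.index("T")
        assert ff.bond_param(t, h).r0 == 0.47
        assert ff.angle_param(t, t, t).k == 25.0
        assert settings.temperature == 325.0
        assert settings.field_update_every == 100

    def test_defaults_are_filled(self):
        ff, settings = read_model("species: [A]\nkappa_inv: 1.0\n")
        assert settings.timestep > 0
        assert settings.field_update_every >= 1


class TestChunkedRead:
    def _text(self, system):
        buf = io.StringIO()
        write_configuration(system, buf)
        return buf.getvalue()

    def test_single_rank_is_serial_read(self):
        system = build_lipid_water(4, 40, (6.0, 6.0, 12.0), seed=1)
        text = self._text(system)
        part = partition_molecules(system, 1)
        frag = read_configuration_chunk(text, 0, 1, part)
        systems_equal(system, frag)

    def test_two_ranks_cover_disjointly(self):
        system = build_lipid_water(10, 0, (6.0, 6.0, 12.0), seed=2)
        text = self._text(system)
        part = partition_molecules(system, 2)
        frags = [read_configuration_chunk(text, r, 2, part) for r in range(2)]
        ids = [set(f.molecule_ids) for f in frags]
        assert ids[0] & ids[1] == set()
        assert ids[0] | ids[1] == set(range(10))

    def test_fragments_union_equals_serial(self):
        system = build_lipid_water(10, 40, (6.0, 6.0, 12.0), seed=3)
        text = self._text(system)
        part = partition_molecules(system, 4)
        seen = {}
        for r in range(4):
            frag = read_configuration_chunk(text, r, 4, part)
            for m, members in zip(frag.molecule_ids, frag.molecules):
                rows = [frag.local_index(g) for g in members]
                seen[m] = (
                    tuple(int(g) for g in members),
                    frag.positions[rows].tobytes(),
                )
        assert set(seen) == set(range(system.n_molecules))
        for m in range(system.n_molecules):
            members = system.molecules[m]
            rows = [system.local_index(g) for g in members]
            assert seen[m] == (
                tuple(int(g) for g in members),
                system.positions[rows].tobytes(),
            )


class TestTrajectory:
    def test_frame_labels_and_round_trip(self):
        buf = io.StringIO()
        pos = np.array([[1.2345678901234, 2.0, 3.0], [4.0, 5.0, 6.0]])
        write_trajectory_frame(pos, ["W", "H"], np.array([10.0, 10.0, 10.0]), buf, step=7)
        frames = read_trajectory(buf.getvalue())
        assert len(frames) == 1
        assert frames[0]["labels"] == ["W", "H"]
        assert frames[0]["step"] == 7
        assert np.array_equal(frames[0]["positions"], pos)

    def test_many_frames_self_delimiting(self):
        buf = io.StringIO()
        box = np.array([5.0, 5.0, 5.0])
        for s in range(100):
            write_trajectory_frame(np.full((3, 3), float(s)), ["A"] * 3, box, buf, step=s)
        frames = read_trajectory(buf.getvalue())
        assert len(frames) == 100
        assert [f["step"] for f in frames] == list(range(100))
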