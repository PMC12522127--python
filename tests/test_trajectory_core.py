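"""Data model, file round-trips, selections, and the PBC distance kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrion as fb
from fibrion.errors import (
    EmptySelectionError,
    TopologyMismatchError,
    UnsupportedBoxError,
)

from conftest import make_tiny_random_trajectory
from oracles import brute_min_image_distance


class TestMinImageDistance:
    def test_coincident_points(self):
        assert fb.min_image_distance((1, 2, 3), (1, 2, 3), (10, 10, 10)) == 0.0

    def test_wraps_across_boundary(self):
        assert fb.min_image_distance((1, 0, 0), (9, 0, 0), (10, 10, 10)) == pytest.approx(2.0)
        assert fb.min_image_distance((1, 1, 1), (9, 9, 9), (10, 10, 10)) == pytest.approx(
            np.sqrt(12.0)
        )

    def test_matches_27_image_enumeration_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            box = rng.uniform(5.0, 30.0, size=3)
            p = rng.random(3) * box
            q = rng.random(3) * box
            assert fb.min_image_distance(p, q, box) == pytest.approx(
                brute_min_image_distance(p, q, box), abs=1e-9
            )

    def test_invariant_under_whole_box_translations(self):
        rng = np.random.default_rng(7)
        box = np.array([10.0, 12.0, 14.0])
        for _ in range(50):
            p, q = rng.random(3) * box, rng.random(3) * box
            shift = rng.integers(-2, 3, size=3) * box
            assert fb.min_image_distance(p + shift, q, box) == pytest.approx(
                fb.min_image_distance(p, q, box), abs=1e-9
            )

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        q=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        box=st.lists(st.floats(1.0, 40.0), min_size=3, max_size=3),
    )
    def test_symmetric_and_bounded_by_half_diagonal(self, p, q, box):
        d_pq = fb.min_image_distance(p, q, box)
        d_qp = fb.min_image_distance(q, p, box)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert d_pq <= np.linalg.norm(np.asarray(box) / 2.0) + 1e-9

    def test_rejects_non_finite_and_bad_box(self):
        with pytest.raises(ValueError):
            fb.min_image_distance((np.nan, 0, 0), (0, 0, 0), (10, 10, 10))
        with pytest.raises(UnsupportedBoxError):
            fb.min_image_distance((0, 0, 0), (1, 1, 1), (10, -1, 10))


class TestReaders:
    def test_three_atom_pdb_identity_readback(self, tmp_path):
        pdb = tmp_path / "tiny.pdb"
        pdb.write_text(
            "CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1\n"
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  O   GLY A   1       2.500   2.000   3.000  1.00  0.00           O\n"
            "ATOM      3  NA  NA  B   2       5.000   5.000   5.000  1.00  0.00          NA\n"
            "END\n"
        )
        traj = fb.load_system(pdb)
        assert traj.n_frames == 1
        assert traj.n_atoms == 3
        np.testing.assert_allclose(traj.frames[0].positions[0], [1.0, 2.0, 3.0])
        assert list(traj.topology.groups) == ["protein", "protein", "ion:NA"]

    def test_gro_nanometre_to_angstrom(self, tmp_path):
        gro = tmp_path / "one.gro"
        gro.write_text(
            "one sodium\n"
            "    1\n"
            "    1NA      NA    1   1.000   0.500   0.250\n"
            "   2.00000   2.00000   2.00000\n"
        )
        traj = fb.load_system(gro)
        np.testing.assert_allclose(traj.frames[0].positions[0], [10.0, 5.0, 2.5])
        np.testing.assert_allclose(traj.frames[0].box, [20.0, 20.0, 20.0])

    def test_pdb_roundtrip_preserves_positions(self, tmp_path):
        traj = make_tiny_random_trajectory(n_frames=5, seed=3)
        out = tmp_path / "rt.pdb"
        fb.write_pdb(traj, out)
        back = fb.load_system(out)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.coords(), traj.coords(), atol=2e-3)
        # idempotence: a second write/read changes nothing further
        out2 = tmp_path / "rt2.pdb"
        fb.write_pdb(back, out2)
        again = fb.load_system(out2)
        np.testing.assert_allclose(again.coords(), back.coords(), atol=1e-9)

    def test_xtc_trajectory_roundtrip(self, tmp_path):
        import MDAnalysis as mda

        traj = make_tiny_random_trajectory(n_frames=4, seed=5)
        top = tmp_path / "top.pdb"
        fb.write_pdb(fb.Trajectory(traj.topology, traj.frames[:1]), top)
        xtc = tmp_path / "t.xtc"
        u = mda.Universe(str(top))
        with mda.Writer(str(xtc), traj.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.positions
                u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)
        back = fb.load_system(top, xtc)
        assert back.n_frames == 4
        # XTC stores coordinates at 0.001 nm precision
        np.testing.assert_allclose(back.coords(), traj.coords(), atol=6e-3)

    def test_atom_count_mismatch_raises(self, tmp_path):
        small = make_tiny_random_trajectory(n_prot=3, n_ions=1, n_frames=1, seed=1)
        big = make_tiny_random_trajectory(n_prot=5, n_ions=1, n_frames=2, seed=2)
        fb.write_pdb(small, tmp_path / "s.pdb")
        fb.write_pdb(big, tmp_path / "b.pdb")
        with pytest.raises(TopologyMismatchError):
            fb.load_system(tmp_path / "s.pdb", tmp_path / "b.pdb")

    def test_triclinic_box_rejected(self, tmp_path):
        pdb = tmp_path / "tri.pdb"
        pdb.write_text(
            "CRYST1   20.000   20.000   20.000  60.00  90.00  90.00 P 1           1\n"
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(UnsupportedBoxError):
            fb.load_system(pdb)

    def test_tsv_dump_matches_trajectory(self, tmp_path):
        import pandas as pd

        traj = make_tiny_random_trajectory(n_frames=3, seed=8)
        out = tmp_path / "dump.tsv"
        fb.write_tsv(traj, out)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == traj.n_frames * traj.n_atoms
        got = df[["x", "y", "z"]].to_numpy().reshape(traj.n_frames, traj.n_atoms, 3)
        np.testing.assert_allclose(got, traj.coords(), atol=1e-6)


class TestSelections:
    def test_water_oxygen_count(self, shell_fixture):
        _, traj, truth = shell_fixture
        sel = fb.select_group(traj, "water_O")
        assert len(sel) == int(truth.shell_occupancy.sum())

    def test_protein_heavy_excludes_hydrogens(self):
        # two GLY residues, one carrying four explicit hydrogens
        names = ["N", "CA", "C", "O", "N", "CA", "C", "O", "H", "HA2", "HA3", "H2"]
        elements = ["N", "C", "C", "O", "N", "C", "C", "O", "H", "H", "H", "H"]
        resids = [1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2]
        topo = fb.SystemTopology(
            atom_names=np.array(names, dtype=object),
            elements=np.array(elements, dtype=object),
            residue_indices=np.array(resids),
            residue_names=np.array(["GLY"] * 12, dtype=object),
            chain_ids=np.array(["A"] * 12, dtype=object),
            groups=np.array(["protein"] * 12, dtype=object),
        )
        traj = fb.Trajectory(topo, [fb.Frame(0.0, np.zeros((12, 3)) + 1.0, np.array([10.0] * 3))])
        heavy = fb.select_group(traj, "protein_heavy")
        full = fb.select_group(traj, "protein")
        assert len(full) - len(heavy) == 4
        assert not np.any(traj.topology.elements[heavy.atom_indices] == "H")

    def test_missing_ion_species_raises(self, binding_fixture):
        _, traj, _ = binding_fixture
        with pytest.raises(EmptySelectionError):
            fb.select_group(traj, "ion:XX")

    def test_selections_are_pairwise_disjoint(self, binding_fixture, shell_fixture):
        for traj in (binding_fixture[1], shell_fixture[1]):
            sels = []
            for spec in ("protein_heavy", "water_O", "ion:NA"):
                try:
                    sels.append(set(fb.select_group(traj, spec).atom_indices.tolist()))
                except EmptySelectionError:
                    pass
            for a in range(len(sels)):
                for b in range(a + 1, len(sels)):
                    assert not (sels[a] & sels[b])

    def test_phosphate_selection_uses_phosphorus_anchor(self):
        names = ["P", "O1", "O2", "O3", "O4", "CA"]
        elements = ["P", "O", "O", "O", "O", "C"]
        topo = fb.SystemTopology(
            atom_names=np.array(names, dtype=object),
            elements=np.array(elements, dtype=object),
            residue_indices=np.array([1, 1, 1, 1, 1, 2]),
            residue_names=np.array(["HPO4"] * 5 + ["GLY"], dtype=object),
            chain_ids=np.array(["B"] * 5 + ["A"], dtype=object),
            groups=np.array(["ion:HPO4"] * 5 + ["protein"], dtype=object),
        )
        traj = fb.Trajectory(topo, [fb.Frame(0.0, np.ones((6, 3)), np.array([10.0] * 3))])
        sel = fb.select_group(traj, "ion:HPO4")
        assert sel.anchor_rule == "single_anchor_atom"
        assert len(sel) == 1
        assert traj.topology.elements[sel.atom_indices[0]] == "P"
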