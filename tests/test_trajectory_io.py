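"""GRO parsing, the tabular frame format, and role selection."""

import numpy as np
import pytest

from conftest import make_trajectory
from fibrilsorb.fibril import ChainSpec, FibrilSpec, build_fibril, write_structure
from fibrilsorb.trajio import (
    ROLE_FIBRIL_CARBON,
    ROLE_OTHER,
    ROLE_WATER_OXYGEN,
    Frame,
    GroFormatError,
    read_frames,
    read_gro,
    select,
    write_frames,
)

def _gro_line(resid, resname, atomname, serial, x, y, z):
    return f"{resid:5d}{resname:<5s}{atomname:>5s}{serial:5d}{x:8.3f}{y:8.3f}{z:8.3f}"


GRO_3ATOMS = "\n".join(
    [
        "hand-written test frame",
        "3",
        _gro_line(1, "SOL", "OW", 1, 1.0, 2.0, 3.0),
        _gro_line(1, "SOL", "HW1", 2, 1.1, 2.0, 3.0),
        _gro_line(2, "GLC", "C1", 3, 0.5, 0.5, 0.5),
        "   5.00000   5.00000   5.00000",
        "",
    ]
)


class TestReadGro:
    def test_roles_of_handwritten_frame(self, tmp_path):
        p = tmp_path / "f.gro"
        p.write_text(GRO_3ATOMS)
        frame = read_gro(p)
        assert frame.n_atoms == 3
        assert list(frame.roles) == [ROLE_WATER_OXYGEN, ROLE_OTHER, ROLE_FIBRIL_CARBON]
        np.testing.assert_allclose(frame.positions[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(frame.box, [5.0, 5.0, 5.0])

    def test_count_mismatch_names_both_counts(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text(GRO_3ATOMS.replace("\n3\n", "\n5\n"))
        with pytest.raises(GroFormatError, match="5.*3"):
            read_gro(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text(GRO_3ATOMS.replace("   1.000   2.000   3.000", "   x.xxx   2.000   3.000"))
        with pytest.raises(GroFormatError, match="line 3"):
            read_gro(p)

    def test_against_mdanalysis_reader(self, tmp_path):
        """Independent cross-check: MDAnalysis parses our GRO identically."""
        mda = pytest.importorskip("MDAnalysis")
        s = build_fibril(ChainSpec(n_residues=4), FibrilSpec(grid_rows=2, grid_cols=2))
        path = write_structure(s, tmp_path / "x.gro")
        ours = read_gro(path)
        u = mda.Universe(str(path))
        np.testing.assert_allclose(u.atoms.positions / 10.0, ours.positions, atol=1e-3)
        np.testing.assert_allclose(u.dimensions[:3] / 10.0, ours.box, atol=1e-3)


class TestTabularFormat:
    def test_round_trip(self, tmp_path):
        traj = make_trajectory(n_frames=4, n_waters=3, n_carbons=2, seed=5)
        back = read_frames(write_frames(traj, tmp_path / "t.csv"))
        assert back.n_frames == 4
        assert back.frame_interval == traj.frame_interval
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-6)
        assert list(back.roles) == list(traj.roles)

    def test_two_frame_interval(self, tmp_path):
        traj = make_trajectory(n_frames=2, n_waters=2, dt=10.0)
        back = read_frames(write_frames(traj, tmp_path / "t.csv"))
        assert back.frame_interval == 10.0

    def test_row_order_within_frame_is_irrelevant(self, tmp_path):
        import pandas as pd

        traj = make_trajectory(n_frames=3, n_waters=4, n_carbons=2, seed=6)
        p = write_frames(traj, tmp_path / "t.csv")
        df = pd.read_csv(p)
        shuffled = df.sample(frac=1.0, random_state=3).sort_values("time_ps", kind="stable")
        p2 = tmp_path / "shuffled.csv"
        shuffled.to_csv(p2, index=False)
        a, b = read_frames(p), read_frames(p2)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert list(a.mol_index) == list(b.mol_index)

    def test_missing_molecule_is_named(self, tmp_path):
        import pandas as pd

        traj = make_trajectory(n_frames=3, n_waters=3)
        p = write_frames(traj, tmp_path / "t.csv")
        df = pd.read_csv(p)
        t1 = sorted(df["time_ps"].unique())[1]
        df = df[~((df["time_ps"] == t1) & (df["mol"] == 2) & (df["role"] != "box"))]
        p2 = tmp_path / "gap.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_frames(p2)

    def test_non_constant_spacing_rejected(self, tmp_path):
        import pandas as pd

        traj = make_trajectory(n_frames=3, n_waters=2)
        p = write_frames(traj, tmp_path / "t.csv")
        df = pd.read_csv(p)
        df.loc[df["time_ps"] == 20.0, "time_ps"] = 35.0
        p2 = tmp_path / "warp.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(ValueError, match="spacing"):
            read_frames(p2)


class TestMDAnalysisAdapter:
    def test_round_trip_through_xtc(self, tmp_path):
        """Write our waters+fibril to GRO/XTC with MDAnalysis and read the
        binary trajectory back through the optional adapter."""
        mda = pytest.importorskip("MDAnalysis")
        from fibrilsorb.trajio import from_mdanalysis

        traj = make_trajectory(n_frames=3, n_waters=4, n_carbons=0, seed=8)
        n = len(traj.roles)
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
        u.add_TopologyAttr("resname", ["SOL"] * n)
        u.add_TopologyAttr("name", ["OW"] * n)
        u.dimensions = [100.0, 100.0, 100.0, 90.0, 90.0, 90.0]
        gro = tmp_path / "top.gro"
        xtc = tmp_path / "t.xtc"
        u.atoms.positions = traj.positions[0] * 10.0
        u.atoms.write(str(gro))
        with mda.Writer(str(xtc), n) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.positions[f] * 10.0
                u.trajectory.ts.time = traj.times[f]
                w.write(u.atoms)
        back = from_mdanalysis(gro, xtc)
        assert back.n_frames == 3
        assert list(back.roles) == ["water-oxygen"] * 4
        # XTC stores single precision at 1e-3 Angstrom
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-3)


class TestSelect:
    def _frame(self):
        return Frame(
            time=0.0,
            box=np.array([5.0, 5.0, 5.0]),
            positions=np.arange(24, dtype=float).reshape(8, 3),
            roles=np.array([ROLE_WATER_OXYGEN] * 5 + [ROLE_FIBRIL_CARBON] * 2 + [ROLE_OTHER]),
            mol_index=np.array([4, 3, 2, 1, 0, 0, 1, -1]),
        )

    def test_selection_counts_and_order(self):
        f = self._frame()
        waters = select(f, ROLE_WATER_OXYGEN)
        assert waters.shape == (5, 3)
        # molecule 0 is row 4 of the frame
        np.testing.assert_array_equal(waters[0], f.positions[4])

    def test_absent_role_gives_empty_selection(self):
        f = self._frame()
        f.roles[:] = ROLE_WATER_OXYGEN
        assert select(f, ROLE_FIBRIL_CARBON).shape == (0, 3)

    def test_roles_partition_the_frame(self):
        f = self._frame()
        n = sum(len(select(f, r)) for r in (ROLE_WATER_OXYGEN, ROLE_FIBRIL_CARBON, ROLE_OTHER))
        assert n == f.n_atoms
        assert len(select(f, ROLE_WATER_OXYGEN)) + len(select(f, ROLE_FIBRIL_CARBON)) == f.n_atoms - 1

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown role"):
            select(self._frame(), "hydrogen")
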