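"""Structure I/O, leaflet assignment, probe proximity, frame selection."""

import numpy as np
import pytest

import memprobe as mp
from memprobe.errors import (
    InsufficientSpanError,
    MissingProbeError,
    MissingReferenceAtomError,
    TopologyMismatchError,
)
from memprobe.trajectory import LOWER, UPPER, Frame, Trajectory

from conftest import make_p_frame


class TestReadStructure:
    def test_counts_preserved_through_round_trip(self, tmp_path):
        spec = mp.popc_spec(seed=3, n_lipids_per_leaflet=2)
        traj, _ = mp.gen_bilayer(spec, n_frames=2)
        path = tmp_path / "tiny.pdb"
        mp.write_pdb(traj, path)
        back = mp.read_structure(path, spec.topology)
        assert back.n_frames == 2
        assert len(back[0].residues_named("POPC")) == 4

    def test_missing_unit_cell_falls_back_to_bounding_box(self, tmp_path):
        spec = mp.popc_spec(seed=3, n_lipids_per_leaflet=2)
        traj, _ = mp.gen_bilayer(spec, n_frames=1)
        path = tmp_path / "box.pdb"
        mp.write_pdb(traj, path)
        stripped = tmp_path / "nobox.pdb"
        stripped.write_text(
            "".join(l for l in path.read_text().splitlines(keepends=True)
                    if not l.startswith("CRYST1"))
        )
        back = mp.read_structure(stripped)
        coords = back[0].coordinates
        expect = coords.max(axis=0) - coords.min(axis=0)
        np.testing.assert_allclose(back[0].box, expect, atol=1e-6)

    def test_topology_mismatch_names_residue_and_atom(self, tmp_path):
        spec = mp.popc_spec(seed=3, n_lipids_per_leaflet=2)
        traj, _ = mp.gen_bilayer(spec, n_frames=1)
        path = tmp_path / "ok.pdb"
        mp.write_pdb(traj, path)
        # rename one lipid's phosphorus so the topology requirement fails
        bad = tmp_path / "bad.pdb"
        bad.write_text(path.read_text().replace(" P  ", " Q  ", 1))
        with pytest.raises(TopologyMismatchError, match="P"):
            mp.read_structure(bad, spec.topology)


class TestAssignLeaflets:
    def test_sign_of_z_minus_midplane(self, mini_topology):
        frame = make_p_frame([18.0, 19.0], [-18.0, -19.0])
        labels = mp.assign_leaflets(frame, mini_topology)
        assert [labels[r] for r in (1, 2, 3, 4)] == [UPPER, UPPER, LOWER, LOWER]

    def test_tie_goes_lower_with_warning(self, mini_topology):
        frame = make_p_frame([5.0, 5.0], [5.0])
        with pytest.warns(UserWarning, match="degenerate"):
            labels = mp.assign_leaflets(frame, mini_topology)
        assert set(labels.values()) == {LOWER}

    def test_recovers_generator_split_exactly(self, mini_topology):
        rng = np.random.default_rng(7)
        upper = 18.0 + rng.normal(0, 1, 50)
        lower = -18.0 + rng.normal(0, 1, 50)
        frame = make_p_frame(upper, lower)
        labels = mp.assign_leaflets(frame, mini_topology)
        assert all(labels[r] == UPPER for r in range(1, 51))
        assert all(labels[r] == LOWER for r in range(51, 101))

    def test_invariant_under_global_translation(self, mini_topology):
        rng = np.random.default_rng(1)
        frame = make_p_frame(18 + rng.normal(0, 1, 20), -18 + rng.normal(0, 1, 20))
        ref = mp.assign_leaflets(frame, mini_topology)
        shifted = Frame(frame.coordinates + np.array([5.0, -3.0, 111.0]),
                        frame.atom_names, frame.residue_ids, frame.residue_names,
                        frame.box)
        assert mp.assign_leaflets(shifted, mini_topology) == ref

    def test_no_phosphorus_raises(self, mini_topology):
        frame = make_p_frame([18.0], [-18.0], resname="OTHER")
        with pytest.raises(MissingReferenceAtomError):
            mp.assign_leaflets(frame, mini_topology)


def _frame_with_probe(lipid_positions, probe_positions, box=(40.0, 40.0, 60.0)):
    """Residue 1..n are single-atom lipids; last residue is the probe."""
    coords = np.vstack([lipid_positions, probe_positions])
    n_l = len(lipid_positions)
    n_p = len(probe_positions)
    return Frame(
        coordinates=coords,
        atom_names=np.array(["C1"] * n_l + ["PX"] * n_p, dtype=object),
        residue_ids=np.array(list(range(1, n_l + 1)) + [n_l + 1] * n_p),
        residue_names=np.array(["LIP"] * n_l + ["PRB"] * n_p, dtype=object),
        box=np.asarray(box, float),
    )


class TestSelectNearProbe:
    def test_threshold_is_inclusive_at_cutoff(self):
        frame = _frame_with_probe(
            np.array([[4.9, 0.0, 0.0], [5.1, 0.0, 0.0]]),
            np.array([[0.0, 0.0, 0.0]]),
        )
        assert mp.select_near_probe(frame, 3, cutoff=5.0) == {1}

    def test_coincident_atoms_selected_at_tiny_cutoff(self):
        frame = _frame_with_probe(np.array([[1.0, 1.0, 1.0]]),
                                  np.array([[1.0, 1.0, 1.0]]))
        assert mp.select_near_probe(frame, 2, cutoff=1e-9) == {1}

    def test_wraps_through_xy_boundary(self):
        frame = _frame_with_probe(np.array([[39.5, 0.0, 0.0]]),
                                  np.array([[0.5, 0.0, 0.0]]))
        assert mp.select_near_probe(frame, 2, cutoff=2.0) == {1}

    def test_missing_probe_raises(self):
        frame = _frame_with_probe(np.array([[0.0, 0.0, 0.0]]),
                                  np.array([[1.0, 0.0, 0.0]]))
        with pytest.raises(MissingProbeError):
            mp.select_near_probe(frame, 99, cutoff=5.0)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        box = np.array([30.0, 30.0, 60.0])
        lipids = rng.uniform([0, 0, -20], [30, 30, 20], size=(50 * 4, 3))
        probe = rng.uniform([0, 0, -5], [30, 30, 5], size=(6, 3))
        n_l = len(lipids)
        coords = np.vstack([lipids, probe])
        frame = Frame(
            coords,
            np.array([f"C{i % 4}" for i in range(n_l)] + ["PX"] * 6, dtype=object),
            np.array([1 + i // 4 for i in range(n_l)] + [n_l // 4 + 1] * 6),
            np.array(["LIP"] * n_l + ["PRB"] * 6, dtype=object),
            box,
        )
        cutoff = 5.0
        got = mp.select_near_probe(frame, n_l // 4 + 1, cutoff)

        # independent oracle: enumerate the 9 xy image shifts per atom pair
        expected = set()
        for rid in range(1, n_l // 4 + 1):
            latoms = lipids[(rid - 1) * 4: rid * 4]
            hit = False
            for la in latoms:
                for pa in probe:
                    for sx in (-1, 0, 1):
                        for sy in (-1, 0, 1):
                            d = la - pa + np.array([sx * box[0], sy * box[1], 0.0])
                            if np.sqrt((d ** 2).sum()) <= cutoff:
                                hit = True
            if hit:
                expected.add(rid)
        assert got == expected


class TestAnalysisFrames:
    @staticmethod
    def _traj(times):
        frames = [make_p_frame([18.0], [-18.0], time=t) for t in times]
        return Trajectory(frames)

    def test_default_window_gives_eleven_half_ns_frames(self):
        traj = self._traj(np.arange(0.0, 15.01, 0.5))
        win = mp.analysis_frames(traj)
        np.testing.assert_allclose(win.times, np.arange(10.0, 15.01, 0.5))
        assert win.n_frames == 11

    def test_full_span_identity(self):
        times = np.arange(0.0, 5.01, 0.5)
        traj = self._traj(times)
        win = mp.analysis_frames(traj, window_ns=5.0, n_frames=len(times))
        np.testing.assert_allclose(win.times, times)

    def test_fine_cadence_snaps_to_grid(self):
        traj = self._traj(np.round(np.arange(0.0, 15.001, 0.1), 10))
        win = mp.analysis_frames(traj)
        np.testing.assert_allclose(win.times, np.arange(10.0, 15.01, 0.5), atol=1e-9)

    def test_output_count_always_matches_request(self):
        traj = self._traj(np.arange(0.0, 15.01, 0.5))
        for n in (2, 5, 11, 17):
            assert mp.analysis_frames(traj, 5.0, n).n_frames == n

    def test_short_trajectory_raises(self):
        traj = self._traj([0.0, 1.0, 2.0])
        with pytest.raises(InsufficientSpanError):
            mp.analysis_frames(traj, window_ns=5.0)
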