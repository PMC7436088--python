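"""Shared fixtures: minimal frames and topologies built in memory."""

import numpy as np
import pytest

from memprobe.topology import AcylChain, LipidTopology
from memprobe.trajectory import Frame


def make_p_frame(upper_z, lower_z, box=(64.0, 64.0, 70.0), resname="LIP", time=0.0):
    """A frame of head-group-only lipids: one P atom per residue at given z."""
    zs = list(upper_z) + list(lower_z)
    n = len(zs)
    rng = np.random.default_rng(0)
    coords = np.column_stack([
        rng.uniform(0, box[0], n), rng.uniform(0, box[1], n), np.asarray(zs, float)
    ])
    return Frame(
        coordinates=coords,
        atom_names=np.array(["P"] * n, dtype=object),
        residue_ids=np.arange(1, n + 1),
        residue_names=np.array([resname] * n, dtype=object),
        box=np.asarray(box, float),
        time=time,
    )


@pytest.fixture
def mini_topology():
    """Head-group-only lipid species (thickness/leaflet tests)."""
    return LipidTopology(
        name="LIP",
        phosphorus_atom="P",
        chains={"sn1": AcylChain("sn1", ["C2A", "C3A", "C4A"], [2, 3, 4])},
    )


@pytest.fixture(scope="session")
def popc_window():
    """A small POPC-like synthetic system restricted to its analysis window."""
    import memprobe as mp

    spec = mp.popc_spec(seed=101, n_lipids_per_leaflet=36, probe_state="N*")
    traj, truth = mp.gen_bilayer(spec, n_frames=11, t0_ns=10.0)
    return mp.analysis_frames(traj), spec, truth
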