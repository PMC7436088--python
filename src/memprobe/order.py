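"""Deuterium order parameters (SCD) for acyl chains.

The order parameter of a C-D (C-H) bond is S = <(3 cos^2 theta - 1)/2>
with theta the angle between the bond and the bilayer normal (z here).
Profiles report |S_CD| per carbon — the plotting convention under which
ordered plateau carbons sit near 0.3-0.4 and the disordered tail
approaches 0 — while the signed mean is kept alongside.

When explicit hydrogens are present in the structure the bond vectors are
taken directly; otherwise they are reconstructed from the carbon skeleton:
two vectors perpendicular to the local chain span at tetrahedral geometry
for a CH2, one in-plane vector for an sp2 (double-bond) carbon, and three
vectors on the tetrahedral cone for the terminal methyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptySelectionError,
    InvalidGeometryError,
    ReconstructionError,
)
from .topology import AcylChain, LipidTopology
from .trajectory import Frame, Trajectory, select_near_probe

Z_NORMAL = np.array([0.0, 0.0, 1.0])

#: half the tetrahedral H-C-H angle
_HALF_HCH = np.deg2rad(109.471 / 2.0)
#: angle between a methyl C-H and the preceding C-C direction
_METHYL_CONE = np.deg2rad(180.0 - 109.471)


def instantaneous_scd(cd_vector, normal=Z_NORMAL) -> float:
    """(3 cos^2 theta - 1)/2 for one bond vector against the normal."""
    v = np.asarray(cd_vector, dtype=float)
    n = np.asarray(normal, dtype=float)
    v2, n2 = v @ v, n @ n
    if v2 == 0.0 or n2 == 0.0:
        raise InvalidGeometryError("zero-length vector has no orientation")
    c2 = (v @ n) ** 2 / (v2 * n2)
    return float((3.0 * c2 - 1.0) / 2.0)


def _scd_batch(vectors: np.ndarray, normal: np.ndarray = Z_NORMAL) -> np.ndarray:
    """Vectorised instantaneous SCD for an (..., 3) stack of bond vectors."""
    n = normal / np.linalg.norm(normal)
    v2 = np.einsum("...i,...i->...", vectors, vectors)
    c2 = np.einsum("...i,i->...", vectors, n) ** 2 / v2
    return (3.0 * c2 - 1.0) / 2.0


# ----------------------------------------------------------------------
# C-H reconstruction from the carbon skeleton


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to unit vectors d (..., 3)."""
    d = np.atleast_2d(d)
    e = np.where(np.abs(d[:, :1]) < 0.9,
                 np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    p1 = _normalize(e - np.einsum("ij,ij->i", e, d)[:, None] * d)
    p2 = np.cross(d, p1)
    return p1, p2


def _ch2_pair(u_prev: np.ndarray, u_next: np.ndarray) -> np.ndarray:
    """Two tetrahedral C-H unit vectors for CH2 carbons, shape (n, 2, 3).

    H vectors lie in the plane through the backbone-angle bisector and the
    backbone-plane normal; for locally straight chains (undefined bisector)
    a deterministic perpendicular pair is used instead.
    """
    s = u_prev + u_next
    cr = np.cross(u_prev, u_next)
    s_norm = np.linalg.norm(s, axis=-1)
    cr_norm = np.linalg.norm(cr, axis=-1)
    ok = (s_norm > 1e-8) & (cr_norm > 1e-8)

    b = np.empty_like(u_prev)
    nrm = np.empty_like(u_prev)
    if np.any(ok):
        b[ok] = -_normalize(s[ok])
        nrm[ok] = _normalize(cr[ok])
    if np.any(~ok):
        d = _normalize(u_next[~ok] - u_prev[~ok])
        p1, p2 = _perp_basis(d)
        b[~ok], nrm[~ok] = p1, p2
    h1 = b * np.cos(_HALF_HCH) + nrm * np.sin(_HALF_HCH)
    h2 = b * np.cos(_HALF_HCH) - nrm * np.sin(_HALF_HCH)
    return np.stack([h1, h2], axis=1)


def _sp2_single(u_prev: np.ndarray, u_next: np.ndarray) -> np.ndarray:
    """One in-plane C-H unit vector for sp2 carbons, shape (n, 1, 3)."""
    s = u_prev + u_next
    s_norm = np.linalg.norm(s, axis=-1)
    ok = s_norm > 1e-8
    h = np.empty_like(u_prev)
    if np.any(ok):
        h[ok] = -_normalize(s[ok])
    if np.any(~ok):
        d = _normalize(u_next[~ok] - u_prev[~ok])
        p1, _ = _perp_basis(d)
        h[~ok] = p1
    return h[:, None, :]


def _methyl_triplet(d: np.ndarray) -> np.ndarray:
    """Three C-H unit vectors on the tetrahedral cone around d, shape (n, 3, 3)."""
    d = _normalize(d)
    p1, p2 = _perp_basis(d)
    out = []
    for phi in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0):
        radial = p1 * np.cos(phi) + p2 * np.sin(phi)
        out.append(d * np.cos(_METHYL_CONE) + radial * np.sin(_METHYL_CONE))
    return np.stack(out, axis=1)


def _reconstruct_batch(carbons: np.ndarray, k: int, chain: AcylChain) -> np.ndarray:
    """C-H unit vectors for carbon slot ``k`` of (n_lipids, n_carbons, 3) skeletons."""
    n_c = carbons.shape[1]
    if n_c < 3:
        raise ReconstructionError("need at least 3 chain carbons to reconstruct C-H vectors")
    index = chain.carbon_indices[k]
    if k == 0:
        d = _normalize(carbons[:, 1] - carbons[:, 0])
        u_prev, u_next = -d, d  # locally straight: perpendicular pair
    elif k == n_c - 1:
        d = _normalize(carbons[:, -1] - carbons[:, -2])
        if chain.is_terminal_methyl(index):
            return _methyl_triplet(d)
        u_prev, u_next = -d, d
    else:
        u_prev = _normalize(carbons[:, k - 1] - carbons[:, k])
        u_next = _normalize(carbons[:, k + 1] - carbons[:, k])
    if index in chain.sp2_carbons:
        return _sp2_single(u_prev, u_next)
    return _ch2_pair(u_prev, u_next)


def reconstruct_ch_vectors(
    chain_positions: np.ndarray, chain: AcylChain, carbon_index: int
) -> np.ndarray:
    """C-H unit vectors for one carbon of a single chain skeleton.

    ``chain_positions`` is the (n_carbons, 3) array of the chain's carbon
    coordinates in topology order; ``carbon_index`` is the 1-based acyl
    position.  Returns an (m, 3) array (m = 1, 2 or 3 vectors).
    """
    pos = np.asarray(chain_positions, dtype=float)
    if carbon_index not in chain.carbon_indices:
        raise ReconstructionError(f"carbon {carbon_index} not in chain {chain.chain_id}")
    k = chain.carbon_indices.index(carbon_index)
    return _reconstruct_batch(pos[None, :, :], k, chain)[0]


# ----------------------------------------------------------------------
# profiles


@dataclass
class OrderProfile:
    """|S_CD| per carbon for one acyl chain, plus selection metadata."""

    chain_id: str
    carbon_indices: list[int]
    scd_values: list[float]  # |S_CD|
    scd_signed: list[float]
    n_lipids_used: int
    selection: str  # "all" or "within X A of probe"
    frame_scope: str  # "single frame" or "averaged over N frames"
    sp2_carbons: list[int] = field(default_factory=list)
    reconstructed: bool = False

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.carbon_indices, self.scd_values))


class _ChainMap:
    """Atom-index lookup tables for one chain over a fixed set of lipids."""

    def __init__(self, frame: Frame, topology: LipidTopology, chain: AcylChain,
                 resids: list[int]):
        idx = frame.residue_index()
        n = len(resids)
        self.carbon_idx = np.empty((n, len(chain.carbon_names)), dtype=int)
        name_maps = []
        for i, rid in enumerate(resids):
            aidx = idx[rid]
            names = {nm: j for nm, j in zip(frame.atom_names[aidx], aidx)}
            name_maps.append(names)
            for k, cname in enumerate(chain.carbon_names):
                self.carbon_idx[i, k] = names[cname]
        self.hydrogen_idx: list[np.ndarray | None] = []
        if chain.hydrogen_names is not None:
            for k, hnames in enumerate(chain.hydrogen_names):
                try:
                    cols = np.array(
                        [[name_maps[i][h] for h in hnames] for i in range(n)], dtype=int
                    )
                except KeyError:
                    cols = None
                self.hydrogen_idx.append(cols)
        else:
            self.hydrogen_idx = [None] * len(chain.carbon_names)


def scd_profile(
    frames: Trajectory | list[Frame],
    topology: LipidTopology,
    chain_id: str,
    *,
    probe_residue: int | None = None,
    cutoff: float = 5.0,
    mode: str = "auto",
    normal: np.ndarray = Z_NORMAL,
) -> OrderProfile:
    """Per-carbon |S_CD| averaged over bonds, selected lipids and frames.

    With ``probe_residue`` set, lipids are re-selected every frame as those
    with any atom within ``cutoff`` A of the probe (the 5 A neighbourhood
    convention); otherwise all lipids of the topology's species are used.
    ``mode`` is "explicit" (require hydrogens), "reconstruct" (ignore
    hydrogens), or "auto" (explicit when available).
    """
    frame_list = list(frames)
    if not frame_list:
        raise EmptySelectionError("no frames given")
    chain = topology.chains[chain_id]
    n_carbons = len(chain.carbon_names)
    sums = np.zeros(n_carbons)
    counts = np.zeros(n_carbons, dtype=int)
    lipids_used: set[int] = set()
    min_lipids = None
    reconstructed_any = False

    all_resids = frame_list[0].residues_named(topology.name)
    cmap = _ChainMap(frame_list[0], topology, chain, all_resids)
    pos_in_all = {rid: i for i, rid in enumerate(all_resids)}

    for fi, frame in enumerate(frame_list):
        if probe_residue is not None:
            sel = select_near_probe(frame, probe_residue, cutoff,
                                    lipid_resnames={topology.name})
            sel = sorted(sel)
        else:
            sel = all_resids
        if not sel:
            raise EmptySelectionError(
                f"no {topology.name} lipids selected in frame {fi} (t={frame.time:g} ns)"
            )
        rows = np.array([pos_in_all[r] for r in sel], dtype=int)
        lipids_used.update(sel)
        min_lipids = len(sel) if min_lipids is None else min(min_lipids, len(sel))
        coords = frame.coordinates
        carbons = coords[cmap.carbon_idx[rows]]  # (n_sel, n_carbons, 3)
        for k in range(n_carbons):
            hidx = cmap.hydrogen_idx[k]
            use_explicit = mode != "reconstruct" and hidx is not None
            if mode == "explicit" and hidx is None:
                raise ReconstructionError(
                    f"explicit hydrogens requested but absent for carbon "
                    f"{chain.carbon_indices[k]} of chain {chain_id}"
                )
            if use_explicit:
                h_pos = coords[hidx[rows]]  # (n_sel, n_h, 3)
                vecs = h_pos - carbons[:, k][:, None, :]
            else:
                reconstructed_any = True
                vecs = _reconstruct_batch(carbons, k, chain)
            vals = _scd_batch(vecs, normal)
            sums[k] += vals.sum()
            counts[k] += vals.size

    signed = sums / counts
    scope = ("single frame" if len(frame_list) == 1
             else f"averaged over {len(frame_list)} frames")
    selection = ("all" if probe_residue is None else f"within {cutoff:g} A of probe")
    return OrderProfile(
        chain_id=chain_id,
        carbon_indices=list(chain.carbon_indices),
        scd_values=[float(abs(s)) for s in signed],
        scd_signed=[float(s) for s in signed],
        n_lipids_used=int(min_lipids),
        selection=selection,
        frame_scope=scope,
        sp2_carbons=sorted(chain.sp2_carbons),
        reconstructed=reconstructed_any,
    )
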