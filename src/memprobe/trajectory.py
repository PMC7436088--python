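"""Membrane snapshot data model and structure I/O.

Frames hold plain numpy arrays (coordinates in Angstrom, names, residue
ids) plus an orthorhombic box; trajectories are ordered frame lists with
strictly increasing times in nanoseconds.  Multi-model PDB files are read
and written through MDAnalysis.  The bilayer normal is fixed as z
throughout the package: leaflets are split at the mean phosphorus z, and
periodicity is applied in x,y only (the bilayer spans z).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientSpanError,
    MissingProbeError,
    MissingReferenceAtomError,
    TopologyMismatchError,
)
from .topology import LipidTopology, SystemLabel

logger = logging.getLogger(__name__)

UPPER = "upper"
LOWER = "lower"


@dataclass
class Frame:
    """One snapshot: per-atom coordinates plus residue bookkeeping."""

    coordinates: np.ndarray  # (n_atoms, 3) Angstrom
    atom_names: np.ndarray  # (n_atoms,) str
    residue_ids: np.ndarray  # (n_atoms,) int
    residue_names: np.ndarray  # (n_atoms,) str
    box: np.ndarray  # (3,) Lx, Ly, Lz in Angstrom
    time: float = 0.0  # ns

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.coordinates)
        if n == 0 or self.residue_ids.size == 0:
            raise EmptyInputError("frame has no atoms")
        if self.coordinates.shape != (n, 3) or not np.all(np.isfinite(self.coordinates)):
            raise FormatError("coordinates must be a finite (n, 3) array")
        if len(self.atom_names) != n or len(self.residue_ids) != n or len(self.residue_names) != n:
            raise FormatError("atom annotation arrays must match the coordinate count")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise FormatError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def residue_index(self) -> dict[int, np.ndarray]:
        """Map residue id -> atom index array (cached)."""
        if not hasattr(self, "_resindex"):
            order = np.argsort(self.residue_ids, kind="stable")
            ids = self.residue_ids[order]
            bounds = np.flatnonzero(np.diff(ids)) + 1
            groups = np.split(order, bounds)
            self._resindex = {int(self.residue_ids[g[0]]): g for g in groups}
        return self._resindex

    def atoms_of(self, resid: int) -> np.ndarray:
        return self.residue_index()[resid]

    def atom_position(self, resid: int, atom_name: str) -> np.ndarray:
        idx = self.atoms_of(resid)
        hit = idx[self.atom_names[idx] == atom_name]
        if hit.size == 0:
            raise TopologyMismatchError(str(resid), atom_name)
        return self.coordinates[hit[0]]

    def residues_named(self, resname: str) -> list[int]:
        """Residue ids with the given residue name, in file order."""
        seen: dict[int, None] = {}
        for rid, rn in zip(self.residue_ids, self.residue_names):
            if rn == resname and rid not in seen:
                seen[int(rid)] = None
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom layout."""

    frames: list[Frame]
    label: SystemLabel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise EmptyInputError("trajectory has no frames")
        n0 = self.frames[0].n_atoms
        for f in self.frames[1:]:
            if f.n_atoms != n0:
                raise FormatError("all frames must share the atom count and ordering")
        times = self.times
        if np.any(np.diff(times) <= 0) and len(times) > 1:
            raise FormatError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# ----------------------------------------------------------------------
# structure I/O (MDAnalysis)


def _check_topology(frame: Frame, topology: LipidTopology) -> None:
    required = topology.required_atoms()
    idx = frame.residue_index()
    for rid in frame.residues_named(topology.name):
        names = set(frame.atom_names[idx[rid]])
        for atom in required:
            if atom not in names:
                raise TopologyMismatchError(f"{topology.name}:{rid}", atom)


def read_structure(
    path: str | Path,
    topology: LipidTopology | None = None,
    *,
    frame_spacing_ns: float = 0.5,
    t0_ns: float = 0.0,
    times_ns: list[float] | None = None,
    label: SystemLabel | None = None,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The box is taken from the CRYST1 record when present, otherwise the
    axis-aligned bounding-box extents are used.  PDB carries no time axis,
    so frame times are either given explicitly (``times_ns``) or laid out
    on an even grid ``t0_ns + i * frame_spacing_ns``.
    """
    import MDAnalysis as mda

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise FormatError(f"could not parse structure file {path}: {exc}") from exc

    if u.atoms.n_atoms == 0:
        raise EmptyInputError(f"{path}: no atoms")

    # multiframe PDB readers can drop the single header CRYST1; recover it
    header_box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    header_box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError:
                    header_box = None
                break
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break

    frames: list[Frame] = []
    names = u.atoms.names.astype(object)
    resids = u.atoms.resids.astype(int)
    resnames = u.atoms.resnames.astype(object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            coords = ts.positions.astype(float).copy()
            dims = ts.dimensions
            if dims is not None and np.all(np.asarray(dims[:3]) > 0):
                box = np.asarray(dims[:3], dtype=float)
            elif header_box is not None and np.all(header_box > 0):
                box = header_box.copy()
            else:
                box = coords.max(axis=0) - coords.min(axis=0)
                box[box <= 0] = 1.0
            t = times_ns[i] if times_ns is not None else t0_ns + i * frame_spacing_ns
            frames.append(Frame(coords, names, resids, resnames, box, time=float(t)))

    if not frames:
        raise EmptyInputError(f"{path}: zero models")
    if topology is not None:
        _check_topology(frames[0], topology)
    return Trajectory(frames, label=label, metadata={"source": str(path)})


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB with CRYST1 records."""
    import MDAnalysis as mda

    first = trajectory[0]
    n = first.n_atoms
    resids_per_atom = first.residue_ids
    unique_resids, resindex = np.unique(resids_per_atom, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(unique_resids),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(first.atom_names))
    resname_of = {}
    for rid, rn in zip(first.residue_ids, first.residue_names):
        resname_of.setdefault(int(rid), rn)
    u.add_TopologyAttr("resnames", [resname_of[int(r)] for r in unique_resids])
    u.add_TopologyAttr("resids", unique_resids)
    u.add_TopologyAttr("elements", [_guess_element(nm) for nm in first.atom_names])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for frame in trajectory:
                u.atoms.positions = frame.coordinates
                u.trajectory.ts.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def _guess_element(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "C"


# ----------------------------------------------------------------------
# leaflet assignment


def assign_leaflets(frame: Frame, topology: LipidTopology) -> dict[int, str]:
    """Split phospholipids into upper/lower leaflets at the mean P z.

    Ties (P exactly at the midplane) go to the lower leaflet; a degenerate
    bilayer (an empty leaflet) is reported as a warning, not an error, so
    callers that only need the split can proceed.
    """
    lipids = frame.residues_named(topology.name)
    p_z = {}
    for rid in lipids:
        try:
            p_z[rid] = frame.atom_position(rid, topology.phosphorus_atom)[2]
        except TopologyMismatchError:
            continue
    if not p_z:
        raise MissingReferenceAtomError(
            f"no {topology.phosphorus_atom!r} atoms in residues named {topology.name!r}"
        )
    midplane = float(np.mean(list(p_z.values())))
    labels = {rid: (UPPER if z > midplane else LOWER) for rid, z in p_z.items()}
    counts = {UPPER: 0, LOWER: 0}
    for v in labels.values():
        counts[v] += 1
    if counts[UPPER] == 0 or counts[LOWER] == 0:
        warnings.warn("degenerate bilayer: one leaflet is empty", stacklevel=2)
    return labels


# ----------------------------------------------------------------------
# probe-proximity selection


def _min_image_xy(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    delta = delta.copy()
    for ax in (0, 1):
        delta[..., ax] -= box[ax] * np.round(delta[..., ax] / box[ax])
    return delta


def select_near_probe(
    frame: Frame,
    probe_residue: int,
    cutoff: float = 5.0,
    *,
    lipid_resnames: set[str] | None = None,
) -> set[int]:
    """Lipids with any atom within ``cutoff`` A of any probe atom.

    Minimum-image convention is applied in x and y (membrane plane) only.
    ``lipid_resnames`` restricts candidates to chain-bearing phospholipids;
    by default every residue except the probe itself is a candidate.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = frame.residue_index()
    if probe_residue not in idx:
        raise MissingProbeError(f"probe residue {probe_residue} not present")
    probe_xyz = frame.coordinates[idx[probe_residue]]

    selected: set[int] = set()
    for rid, atom_idx in idx.items():
        if rid == probe_residue:
            continue
        if lipid_resnames is not None:
            if frame.residue_names[atom_idx[0]] not in lipid_resnames:
                continue
        delta = frame.coordinates[atom_idx][:, None, :] - probe_xyz[None, :, :]
        delta = _min_image_xy(delta, frame.box)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        if d2.min() <= cutoff * cutoff:
            selected.add(rid)
    return selected


# ----------------------------------------------------------------------
# analysis-window frame selection


def analysis_frames(
    trajectory: Trajectory, window_ns: float = 5.0, n_frames: int = 11
) -> Trajectory:
    """Frames nearest to an even grid over the trajectory's last window.

    The grid includes both endpoints, so the 15 ns / 0.5 ns cadence yields
    frames at 10.0, 10.5, ..., 15.0 ns.  Nearest-to-grid matching (earlier
    frame on ties) keeps the selection robust to uneven writer cadence.
    """
    times = trajectory.times
    span = times[-1] - times[0]
    if span < window_ns:
        raise InsufficientSpanError(
            f"trajectory spans {span:g} ns < requested window {window_ns:g} ns"
        )
    grid = np.linspace(times[-1] - window_ns, times[-1], n_frames)
    picks = [int(np.argmin(np.abs(times - g))) for g in grid]
    frames = [trajectory[i] for i in picks]
    if len(set(picks)) != len(picks):
        logger.warning("analysis grid finer than trajectory cadence: duplicate frames kept")
        # strictly-increasing times are required by Trajectory; nudge repeats
        out, prev = [], -np.inf
        for f in frames:
            t = f.time if f.time > prev else np.nextafter(prev, np.inf)
            out.append(Frame(f.coordinates, f.atom_names, f.residue_ids,
                             f.residue_names, f.box, time=float(t)))
            prev = out[-1].time
        frames = out
    return Trajectory(frames, label=trajectory.label,
                      metadata={**trajectory.metadata, "window_ns": window_ns})
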