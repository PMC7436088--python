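"""Synthetic inputs with known ground truth.

Generators emulate everything the pipeline consumes: planar bilayer
trajectories with prescribed P-P thickness, box area and per-carbon SCD
profiles (POPC-like fluid membranes with the carbon-9 double-bond dip,
and more ordered DPPC:cholesterol-like membranes), an optional probe
anchored below one leaflet surface, Gaussian binding-energy series,
two-Gaussian emission spectra, and ring-shaped two-channel vesicle
images.

Chains are kinematic stick models, not physical conformers: carbon
skeletons are connected random walks tilted into the membrane, while
explicit C-H hydrogen orientations are drawn from a Beta-parameterised
tilt distribution whose mean hits the target |S_CD| exactly, so measured
profiles converge to the prescription at Monte-Carlo rate.  No excluded
volume or force field is involved — ground truth, not physics, is the
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .order import _reconstruct_batch
from .photometry import Spectrum
from .stats import EnergySeries
from .topology import (
    CHOLESTEROL_RESNAME,
    PROBE_RESNAME,
    AcylChain,
    LipidTopology,
    SystemLabel,
    dppc_topology,
    popc_topology,
)
from .trajectory import Frame, Trajectory

CC_BOND = 1.25  # A, projected C-C step
CH_BOND = 1.09  # A
#: concentration of the Beta distribution behind C-H tilt sampling; sets the
#: per-bond orientation spread (sd ~0.08 in instantaneous SCD at the plateau),
#: hence the frame-to-frame wobble of encoded letters
_BETA_CONCENTRATION = 60.0


@dataclass
class ProbeSpec:
    """Probe placement: head anchored below one leaflet surface, tail inward."""

    state: str = "N*"  # tautomer label only; geometry is shared
    leaflet: str = "upper"
    anchor_depth: float = 1.5  # A below the P plane
    tail_carbons: int = 18


@dataclass
class BilayerSpec:
    """Prescription for one synthetic bilayer system."""

    topology: LipidTopology
    n_lipids_per_leaflet: int = 64
    target_thickness: float = 37.3  # A, P-P
    box_xy: float = 64.0  # A
    target_scd_profile: dict[str, dict[int, float]] = field(default_factory=dict)
    chol_fraction: float = 0.0
    probe: ProbeSpec | None = None
    sigma_z: float = 0.5  # A, P-plane roughness
    sigma_xy: float = 0.4  # A, per-frame lateral jitter
    seed: int = 0

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 1 or self.target_thickness <= 0 or self.box_xy <= 0:
            raise ConfigurationError("lipid count, thickness and box must be positive")
        if not 0.0 <= self.chol_fraction < 1.0:
            raise ConfigurationError("chol_fraction must lie in [0, 1)")
        for cid, prof in self.target_scd_profile.items():
            for c, s in prof.items():
                if not 0.0 <= s <= 0.5:
                    raise ConfigurationError(
                        f"target SCD {s} at carbon {c} of {cid} outside the feasible [0, 0.5]"
                    )


# ----------------------------------------------------------------------
# preset profiles (plateau + tail decay; C9 dip for the oleoyl chain)


def _profile(indices: list[int], values: list[float]) -> dict[int, float]:
    if len(indices) != len(values):
        raise ConfigurationError("profile values must align with carbon indices")
    return dict(zip(indices, values))


def popc_profile() -> dict[str, dict[int, float]]:
    """Fluid (Ld-like) profile: ~0.2 plateau, sharp dip at the C9=C10 bond,
    decay toward ~0.03 at the terminal methyl.

    Values are prescribed at two decimals, centred in the default 0.02-wide
    letter bins, so the encoding of the prescription itself is unambiguous.
    """
    sn1 = _profile(
        list(range(2, 17)),
        [0.21] * 7 + [0.19, 0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05],
    )
    sn2 = _profile(
        list(range(2, 19)),
        [0.19] * 7  # C2-C8 plateau
        + [0.09, 0.09]  # C9-C10 double-bond dip
        + [0.13, 0.11, 0.11, 0.09, 0.07, 0.05, 0.05, 0.03],
    )
    return {"sn1": sn1, "sn2": sn2}


def dppc_chol_profile() -> dict[str, dict[int, float]]:
    """Ordered (Lo-like) profile: cholesterol-condensed ~0.37 plateau."""
    prof = _profile(
        list(range(2, 17)),
        [0.37] * 9 + [0.33, 0.29, 0.23, 0.17, 0.13, 0.09],
    )
    return {"sn1": dict(prof), "sn2": dict(prof)}


def popc_spec(seed: int = 0, n_lipids_per_leaflet: int = 64,
              probe_state: str | None = None) -> BilayerSpec:
    """POPC-like preset: 37.3 A P-P thickness, 64 A box, A_l = 64 A^2."""
    return BilayerSpec(
        topology=popc_topology(),
        n_lipids_per_leaflet=n_lipids_per_leaflet,
        target_thickness=37.3,
        box_xy=64.0 * np.sqrt(n_lipids_per_leaflet / 64.0),
        target_scd_profile=popc_profile(),
        chol_fraction=0.0,
        probe=ProbeSpec(state=probe_state) if probe_state else None,
        seed=seed,
    )


def dppc_chol_spec(seed: int = 0, n_lipids_per_leaflet: int = 64,
                   probe_state: str | None = None) -> BilayerSpec:
    """DPPC:Chol-like preset: 45.9 A thickness, 30% cholesterol."""
    return BilayerSpec(
        topology=dppc_topology(),
        n_lipids_per_leaflet=n_lipids_per_leaflet,
        target_thickness=45.9,
        box_xy=64.0 * np.sqrt(n_lipids_per_leaflet / 64.0),
        target_scd_profile=dppc_chol_profile(),
        chol_fraction=0.30,
        probe=ProbeSpec(state=probe_state) if probe_state else None,
        seed=seed,
    )


def preset_spec(membrane: str, seed: int = 0, n_lipids_per_leaflet: int = 64,
                probe_state: str | None = None) -> BilayerSpec:
    if membrane == "POPC":
        return popc_spec(seed, n_lipids_per_leaflet, probe_state)
    if membrane == "DPPC-Chol":
        return dppc_chol_spec(seed, n_lipids_per_leaflet, probe_state)
    raise ConfigurationError(f"unknown preset {membrane!r}")


# ----------------------------------------------------------------------
# bilayer generator


def _sample_ch_vectors(rng: np.random.Generator, target_scd: float, n: int) -> np.ndarray:
    """n unit C-H vectors whose expected SCD against z is exactly -target_scd.

    cos^2(theta) is Beta-distributed with mean (1 - 2S)/3, so
    E[(3 cos^2 - 1)/2] = -S by construction; azimuth and the sign of
    cos(theta) are uniform.
    """
    m = (1.0 - 2.0 * target_scd) / 3.0
    if m <= 1e-12:
        u = np.zeros(n)
    else:
        a = m * _BETA_CONCENTRATION
        b = (1.0 - m) * _BETA_CONCENTRATION
        u = rng.beta(a, b, size=n)
    cos_t = np.sqrt(u) * rng.choice([-1.0, 1.0], size=n)
    sin_t = np.sqrt(1.0 - u)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _grid_sites(n: int, box_xy: float, rng: np.random.Generator) -> np.ndarray:
    m = int(np.ceil(np.sqrt(n)))
    spacing = box_xy / m
    xs, ys = np.meshgrid(np.arange(m), np.arange(m))
    sites = (np.column_stack([xs.ravel(), ys.ravel()]) + 0.5) * spacing
    order = rng.permutation(len(sites))[:n]
    return sites[order]


class _Layout:
    """Static atom layout (names/resids/resnames + index maps) for one system."""

    def __init__(self, spec: BilayerSpec):
        self.names: list[str] = []
        self.resids: list[int] = []
        self.resnames: list[str] = []
        self.p_idx: dict[str, list[int]] = {"upper": [], "lower": []}
        self.n4_idx: dict[str, list[int]] = {"upper": [], "lower": []}
        # per leaflet, per chain: carbon index grid and hydrogen grids
        self.chain_c: dict[tuple[str, str], list[list[int]]] = {}
        self.chain_h: dict[tuple[str, str], list[list[list[int]]]] = {}
        self.chol_idx: list[list[int]] = []
        self.chol_leaflet: list[str] = []
        self.probe_idx: list[int] = []
        self.leaflet_truth: dict[int, str] = {}

        rid = 0
        for leaflet in ("upper", "lower"):
            for cid, chain in spec.topology.chains.items():
                self.chain_c[(leaflet, cid)] = []
                self.chain_h[(leaflet, cid)] = []
            for _ in range(spec.n_lipids_per_leaflet):
                rid += 1
                self.leaflet_truth[rid] = leaflet
                self.p_idx[leaflet].append(self._add(rid, spec.topology.name, "P"))
                self.n4_idx[leaflet].append(self._add(rid, spec.topology.name, "N4"))
                for cid, chain in spec.topology.chains.items():
                    c_row, h_row = [], []
                    for k, cname in enumerate(chain.carbon_names):
                        c_row.append(self._add(rid, spec.topology.name, cname))
                        h_row.append([
                            self._add(rid, spec.topology.name, h)
                            for h in chain.hydrogen_names[k]
                        ] if chain.hydrogen_names else [])
                    self.chain_c[(leaflet, cid)].append(c_row)
                    self.chain_h[(leaflet, cid)].append(h_row)
        n_pl = 2 * spec.n_lipids_per_leaflet
        n_chol = int(round(n_pl * spec.chol_fraction / (1.0 - spec.chol_fraction))) \
            if spec.chol_fraction > 0 else 0
        for j in range(n_chol):
            rid += 1
            leaflet = "upper" if j % 2 == 0 else "lower"
            self.chol_leaflet.append(leaflet)
            self.chol_idx.append([
                self._add(rid, CHOLESTEROL_RESNAME, nm)
                for nm in ("O3", "C3", "C10", "C13", "C17")
            ])
        self.n_chol = n_chol
        if spec.probe is not None:
            rid += 1
            self.probe_resid = rid
            self.probe_idx = [self._add(rid, PROBE_RESNAME, "NP"),
                              self._add(rid, PROBE_RESNAME, "OP")]
            self.probe_idx += [
                self._add(rid, PROBE_RESNAME, f"T{i}")
                for i in range(1, spec.probe.tail_carbons + 1)
            ]
        else:
            self.probe_resid = None
        self.n_atoms = len(self.names)

    def _add(self, rid: int, resname: str, name: str) -> int:
        self.names.append(name)
        self.resids.append(rid)
        self.resnames.append(resname)
        return len(self.names) - 1


def gen_bilayer(
    spec: BilayerSpec,
    n_frames: int = 31,
    frame_spacing_ns: float = 0.5,
    t0_ns: float = 0.0,
) -> tuple[Trajectory, dict]:
    """Generate a synthetic bilayer trajectory plus its ground-truth record.

    Default cadence (31 frames at 0.5 ns from 0) spans 15 ns so that the
    default analysis window — last 5 ns, 11 frames — falls at
    10.0, 10.5, ..., 15.0 ns.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _Layout(spec)
    box = np.array([spec.box_xy, spec.box_xy, spec.target_thickness + 30.0])
    half = spec.target_thickness / 2.0
    zsign = {"upper": 1.0, "lower": -1.0}

    n_sites = spec.n_lipids_per_leaflet + (layout.n_chol + 1) // 2
    sites = {leaflet: _grid_sites(n_sites, spec.box_xy, rng)
             for leaflet in ("upper", "lower")}

    frames = []
    names = np.array(layout.names, dtype=object)
    resids = np.array(layout.resids, dtype=int)
    resnames = np.array(layout.resnames, dtype=object)

    chol_cursor = {"upper": spec.n_lipids_per_leaflet, "lower": spec.n_lipids_per_leaflet}
    chol_site = []
    for leaflet in layout.chol_leaflet:
        chol_site.append((leaflet, chol_cursor[leaflet]))
        chol_cursor[leaflet] += 1

    for fi in range(n_frames):
        coords = np.zeros((layout.n_atoms, 3))
        for leaflet in ("upper", "lower"):
            n = spec.n_lipids_per_leaflet
            s = zsign[leaflet]
            xy = sites[leaflet][:n] + rng.normal(0.0, spec.sigma_xy, size=(n, 2))
            z_p = s * half + rng.normal(0.0, spec.sigma_z, size=n)
            p_i = np.array(layout.p_idx[leaflet])
            coords[p_i, 0], coords[p_i, 1], coords[p_i, 2] = xy[:, 0], xy[:, 1], z_p
            n4_i = np.array(layout.n4_idx[leaflet])
            coords[n4_i] = coords[p_i] + np.array([0.3, 0.3, s * 1.0])
            for ci, (cid, chain) in enumerate(spec.topology.chains.items()):
                c_idx = np.array(layout.chain_c[(leaflet, cid)])  # (n, n_carbons)
                h_idx = layout.chain_h[(leaflet, cid)]
                pos = np.column_stack([
                    xy[:, 0] + (ci - 0.5) * 1.6, xy[:, 1], z_p - s * 2.0
                ])
                phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
                prof = spec.target_scd_profile.get(cid, {})
                for k, cindex in enumerate(chain.carbon_indices):
                    tilt = np.clip(rng.normal(0.45, 0.15, size=n), 0.05, 1.0)
                    phi = phi + rng.normal(0.0, 0.5, size=n)
                    step = np.column_stack([
                        CC_BOND * np.sin(tilt) * np.cos(phi),
                        CC_BOND * np.sin(tilt) * np.sin(phi),
                        -s * CC_BOND * np.cos(tilt),
                    ])
                    pos = pos + step
                    coords[c_idx[:, k]] = pos
                    target = prof.get(cindex, 0.1)
                    n_h = len(h_idx[0][k]) if h_idx and h_idx[0][k] else 0
                    if n_h:
                        vecs = _sample_ch_vectors(rng, target, n * n_h).reshape(n, n_h, 3)
                        hvec = pos[:, None, :] + CH_BOND * vecs
                        flat = np.array([h_idx[i][k] for i in range(n)])
                        coords[flat.ravel()] = hvec.reshape(-1, 3)
        for j, idxs in enumerate(layout.chol_idx):
            leaflet, site_i = chol_site[j]
            s = zsign[leaflet]
            cx, cy = sites[leaflet][site_i] + rng.normal(0.0, spec.sigma_xy, size=2)
            z0 = s * (half - 1.5)
            for a, idx in enumerate(idxs):
                coords[idx] = [cx, cy, z0 - s * 1.5 * a]
        if layout.probe_idx:
            pr = spec.probe
            cx = cy = spec.box_xy / 2.0
            s = zsign[pr.leaflet]
            z_head = s * (half - pr.anchor_depth)
            coords[layout.probe_idx[0]] = [cx, cy, z_head]
            coords[layout.probe_idx[1]] = [cx + 1.2, cy, z_head + s * 0.5]
            phi = rng.uniform(0.0, 2.0 * np.pi)
            pos = np.array([cx, cy - 0.8, z_head - s * 1.2])
            for idx in layout.probe_idx[2:]:
                tilt = float(np.clip(rng.normal(0.35, 0.12), 0.05, 0.9))
                phi += rng.normal(0.0, 0.5)
                pos = pos + np.array([
                    CC_BOND * np.sin(tilt) * np.cos(phi),
                    CC_BOND * np.sin(tilt) * np.sin(phi),
                    -s * CC_BOND * np.cos(tilt),
                ])
                coords[idx] = pos
        frames.append(Frame(coords, names, resids, resnames, box.copy(),
                            time=t0_ns + fi * frame_spacing_ns))

    membrane = "POPC" if spec.topology.name == "POPC" else "DPPC-Chol"
    label = SystemLabel(membrane, spec.probe.state if spec.probe else "none")
    traj = Trajectory(frames, label=label, metadata={"seed": spec.seed})
    truth = {
        "thickness_A": spec.target_thickness,
        "apl_A2": spec.box_xy ** 2 / spec.n_lipids_per_leaflet,
        "box_A": box.tolist(),
        "scd_profile": {cid: dict(prof) for cid, prof in spec.target_scd_profile.items()},
        "chol_fraction": spec.chol_fraction,
        "leaflets": dict(layout.leaflet_truth),
        "probe_resid": layout.probe_resid,
        "seed": spec.seed,
    }
    return traj, truth


# ----------------------------------------------------------------------
# conformer chains for cross-validating C-H reconstruction


def gen_chain_conformers(
    chain: AcylChain, n_chains: int = 50, seed: int = 0
) -> tuple[Frame, LipidTopology]:
    """Standalone wobbly acyl chains with hydrogens placed by the ideal
    tetrahedral rule, for comparing explicit-H and reconstructed SCD paths."""
    rng = np.random.default_rng(seed)
    n_c = len(chain.carbon_names)
    carbons = np.zeros((n_chains, n_c, 3))
    pos = np.column_stack([rng.uniform(0, 100, n_chains),
                           rng.uniform(0, 100, n_chains),
                           np.full(n_chains, 20.0)])
    phi = rng.uniform(0, 2 * np.pi, n_chains)
    carbons[:, 0] = pos
    for k in range(1, n_c):
        tilt = np.clip(rng.normal(0.5, 0.2, n_chains), 0.05, 1.2)
        phi = phi + rng.normal(0.0, 0.6, n_chains)
        pos = pos + np.column_stack([
            CC_BOND * np.sin(tilt) * np.cos(phi),
            CC_BOND * np.sin(tilt) * np.sin(phi),
            -CC_BOND * np.cos(tilt),
        ])
        carbons[:, k] = pos

    names, resids, resnames, coords = [], [], [], []
    for i in range(n_chains):
        for k, cname in enumerate(chain.carbon_names):
            names.append(cname)
            resids.append(i + 1)
            resnames.append("CHN")
            coords.append(carbons[i, k])
        for k in range(n_c):
            hvecs = _reconstruct_batch(carbons[i][None], k, chain)[0]
            hnames = chain.hydrogen_names[k] if chain.hydrogen_names else []
            for j, h in enumerate(hnames[: len(hvecs)]):
                names.append(h)
                resids.append(i + 1)
                resnames.append("CHN")
                coords.append(carbons[i, k] + CH_BOND * hvecs[j])
    frame = Frame(np.array(coords), np.array(names, dtype=object),
                  np.array(resids), np.array(resnames, dtype=object),
                  box=np.array([120.0, 120.0, 60.0]))
    topo = LipidTopology(name="CHN", phosphorus_atom="P",
                         chains={chain.chain_id: chain})
    return frame, topo


# ----------------------------------------------------------------------
# energy series, spectra, vesicle images


def gen_energy_series(
    mean: float, sd: float, n: int = 11, seed: int = 0,
    t0_ns: float = 10.0, spacing_ns: float = 0.5, label=None,
) -> EnergySeries:
    """Gaussian per-frame binding energies (kcal/mol), reproducible per seed."""
    if sd < 0 or n < 2:
        raise ConfigurationError("need sd >= 0 and n >= 2")
    rng = np.random.default_rng(seed)
    values = mean + sd * rng.standard_normal(n)
    times = t0_ns + spacing_ns * np.arange(n)
    return EnergySeries(values, times, label=label)


def gen_spectrum(
    peaks: list[tuple[float, float, float]],
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Sum-of-Gaussians emission spectrum; peaks are (center nm, amplitude, sigma nm)."""
    if grid is None:
        grid = np.arange(420.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    inten = np.zeros_like(grid)
    for center, amp, width in peaks:
        if amp <= 0 or width <= 0:
            raise ConfigurationError("peak amplitudes and widths must be positive")
        inten += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return Spectrum(grid, inten)


def gen_guv_images(
    shape: tuple[int, int] = (128, 128),
    radius: float = 40.0,
    ring_width: float = 6.0,
    true_ratio: float = 1.5,
    noise_sigma: float = 0.01,
    seed: int = 0,
    base_intensity: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel annulus (equatorial GUV section) with a uniform true
    N/T ratio on the ring; additive Gaussian noise relative to the ring
    amplitude."""
    if radius <= ring_width:
        raise ConfigurationError("radius must exceed the ring width")
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    profile = np.exp(-0.5 * ((r - radius) / (ring_width / 2.0)) ** 2)
    ch_T = base_intensity * profile
    ch_N = true_ratio * base_intensity * profile
    ch_T = ch_T + noise_sigma * base_intensity * rng.standard_normal(shape)
    ch_N = ch_N + noise_sigma * true_ratio * base_intensity * rng.standard_normal(shape)
    return np.clip(ch_N, 0.0, None), np.clip(ch_T, 0.0, None)
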