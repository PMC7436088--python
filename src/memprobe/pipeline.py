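"""End-to-end comparison of membrane systems.

One run takes a list of systems (PDB trajectories or synthetic presets),
restricts each to the analysis window (last 5 ns, 11 frames by default),
computes bilayer metrics and SCD profiles (near the probe when one is
present), encodes one letter string per frame, builds the k-mer overlap
distance matrix across all systems, embeds it in 2-D, scores the
membrane-composition grouping with a silhouette, and runs pairwise Welch
tests on any binding-energy series.  Outputs are plain CSV/TSV/JSON files
plus a manifest holding every parameter, seed and output hash, so a run
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MemprobeError
from .metrics import aggregate
from .order import scd_profile
from .semantic import (
    EncodingConfig,
    KmerConfig,
    cluster_quality,
    distance_matrix,
    embed_2d,
    encode_profile,
)
from .stats import EnergySeries, compare_energies
from .synth import gen_bilayer, gen_energy_series, preset_spec
from .topology import LipidTopology, SystemLabel
from .trajectory import analysis_frames, assign_leaflets, read_structure

logger = logging.getLogger(__name__)

#: synthetic stand-ins for per-system probe binding energies (kcal/mol):
#: N* binds POPC better, T* binds DPPC-Chol better
DEFAULT_ENERGY_MEANS = {
    ("POPC", "N*"): -52.0,
    ("POPC", "T*"): -45.0,
    ("DPPC-Chol", "N*"): -47.0,
    ("DPPC-Chol", "T*"): -54.0,
}
DEFAULT_ENERGY_SD = 2.5


@dataclass
class SystemConfig:
    """One membrane system: synthetic preset or a trajectory file on disk."""

    membrane: str
    probe_state: str = "none"
    trajectory: str | None = None  # multi-model PDB; None -> synthetic preset
    topology: str | None = None  # lipid topology file (required with trajectory)
    probe_residue: int | None = None  # required with trajectory + probe_state
    chol_fraction: float | None = None  # default: 0.30 for DPPC-Chol, else 0
    n_lipids_per_leaflet: int = 64
    energy_csv: str | None = None
    energy_mean: float | None = None  # synth energies when no CSV
    energy_sd: float = DEFAULT_ENERGY_SD

    @property
    def label(self) -> SystemLabel:
        return SystemLabel(self.membrane, self.probe_state)

    def resolved_chol_fraction(self) -> float:
        if self.chol_fraction is not None:
            return self.chol_fraction
        return 0.30 if self.membrane == "DPPC-Chol" else 0.0


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    outdir: str = "memprobe_out"
    seed: int = 42
    cutoff: float = 5.0
    window_ns: float = 5.0
    n_frames: int = 11
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    kmer: KmerConfig = field(default_factory=KmerConfig)
    tsne_seed: int = 42
    perplexity: float = 10.0
    keep_going: bool = False
    with_energies: bool = True

    def __post_init__(self):
        if not self.systems:
            raise ConfigurationError("at least one system is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        systems = [SystemConfig(**s) for s in raw.pop("systems")]
        enc = EncodingConfig(**raw.pop("encoding", {}))
        km = KmerConfig(**raw.pop("kmer", {}))
        emb = raw.pop("embedding", {})
        raw.setdefault("tsne_seed", emb.get("seed", 42))
        raw.setdefault("perplexity", emb.get("perplexity", 10.0))
        raw.update(overrides)
        return cls(systems=systems, encoding=enc, kmer=km, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoding"] = {"scd_low": self.encoding.scd_low,
                         "scd_high": self.encoding.scd_high,
                         "alphabet": self.encoding.alphabet}
        d["kmer"] = asdict(self.kmer)
        return d


def six_system_config(outdir: str = "memprobe_out", seed: int = 42,
                      n_lipids_per_leaflet: int = 64) -> RunConfig:
    """The canonical six-system comparison: each membrane bare and with the
    probe in its two excited tautomer states (6 systems x 11 frames = 66
    strings)."""
    systems = [
        SystemConfig(m, p, n_lipids_per_leaflet=n_lipids_per_leaflet)
        for m in ("POPC", "DPPC-Chol")
        for p in ("none", "N*", "T*")
    ]
    return RunConfig(systems=systems, outdir=outdir, seed=seed)


# ----------------------------------------------------------------------


def _load_system(sys_cfg: SystemConfig, config: RunConfig, index: int):
    """Returns (trajectory restricted to the analysis window, topology, probe_resid)."""
    if sys_cfg.trajectory is not None:
        if sys_cfg.topology is None:
            raise ConfigurationError(
                f"system {sys_cfg.label}: trajectory input needs a topology file"
            )
        topo = LipidTopology.load(sys_cfg.topology)
        traj = read_structure(sys_cfg.trajectory, topo, label=sys_cfg.label)
        probe_resid = sys_cfg.probe_residue
    else:
        spec = preset_spec(
            sys_cfg.membrane,
            seed=config.seed + 97 * index,
            n_lipids_per_leaflet=sys_cfg.n_lipids_per_leaflet,
            probe_state=sys_cfg.probe_state if sys_cfg.probe_state != "none" else None,
        )
        traj, truth = gen_bilayer(spec)
        topo = spec.topology
        probe_resid = truth["probe_resid"]
    window = analysis_frames(traj, config.window_ns, config.n_frames)
    return window, topo, probe_resid


def _energy_series(sys_cfg: SystemConfig, config: RunConfig, index: int):
    if sys_cfg.energy_csv is not None:
        return EnergySeries.from_csv(sys_cfg.energy_csv, label=sys_cfg.label)
    mean = sys_cfg.energy_mean
    if mean is None:
        mean = DEFAULT_ENERGY_MEANS.get((sys_cfg.membrane, sys_cfg.probe_state))
    if mean is None:
        return None  # probe-free systems have no probe binding energy
    return gen_energy_series(mean, sys_cfg.energy_sd, n=config.n_frames,
                             seed=config.seed + 131 * index + 7,
                             label=sys_cfg.label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also saved as manifest.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    metrics_rows, scd_rows, strings, energies = [], [], [], {}
    errors: list[str] = []

    for i, sys_cfg in enumerate(config.systems):
        label = str(sys_cfg.label)
        try:
            logger.info("system %s: loading", label)
            window, topo, probe_resid = _load_system(sys_cfg, config, i)
            chol = sys_cfg.resolved_chol_fraction()

            leaflets = [assign_leaflets(f, topo) for f in window]
            bm = aggregate(window, leaflets, topo, chol)
            for t, th, ap in zip(bm.frame_times_ns, bm.per_frame_thickness,
                                 bm.per_frame_apl):
                metrics_rows.append({"system": label, "frame_time_ns": t,
                                     "thickness_A": th, "apl_A2": ap})
            summary = bm.summary()

            probe_kw = {}
            if sys_cfg.probe_state != "none":
                if probe_resid is None:
                    raise ConfigurationError(
                        f"system {label}: probe_state set but no probe residue"
                    )
                probe_kw = {"probe_residue": probe_resid, "cutoff": config.cutoff}

            for cid in topo.chains:
                prof = scd_profile(window, topo, cid, **probe_kw)
                for c, v, sv in zip(prof.carbon_indices, prof.scd_values,
                                    prof.scd_signed):
                    scd_rows.append({"system": label, "chain": cid,
                                     "carbon_index": c, "scd": v, "scd_signed": sv,
                                     "n_lipids": prof.n_lipids_used,
                                     "selection": prof.selection})

            logger.info("system %s: encoding %d frames", label, window.n_frames)
            for frame in window:
                profs = [scd_profile([frame], topo, cid, **probe_kw)
                         for cid in topo.chains]
                s = encode_profile(profs, config.encoding)
                strings.append({"system": label, "time_ns": frame.time, "string": s})

            es = _energy_series(sys_cfg, config, i) if config.with_energies else None
            if es is not None:
                energies[label] = es
            summary["system"] = label
            logger.info("system %s: done (thickness %.2f A)", label,
                        summary["thickness_mean_A"])
        except MemprobeError as exc:
            msg = f"system {label}: {type(exc).__name__}: {exc}"
            if not config.keep_going:
                raise
            logger.error(msg)
            errors.append(msg)

    pd.DataFrame(metrics_rows).to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame(scd_rows).to_csv(outdir / "scd.csv", index=False)
    strings_df = pd.DataFrame(strings)
    strings_df.to_csv(outdir / "strings.tsv", sep="\t", index=False)

    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "n_systems": len(config.systems),
        "n_strings": len(strings),
        "errors": errors,
    }

    n_systems_ok = strings_df["system"].nunique() if len(strings) else 0
    if n_systems_ok >= 2:
        labeled = [(f"{r.system}@{r.time_ns:g}", r.string)
                   for r in strings_df.itertuples()]
        dm = distance_matrix(labeled, config.kmer)
        pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
            outdir / "distances.csv")
        emb = embed_2d(dm, seed=config.tsne_seed, perplexity=config.perplexity)
        pd.DataFrame({"label": emb.labels,
                      "x": emb.coordinates[:, 0],
                      "y": emb.coordinates[:, 1]}).to_csv(
            outdir / "embedding.csv", index=False)
        groups = [lab.split("@")[0].split("+")[0] for lab in dm.labels]
        sil = None
        if len(set(groups)) >= 2:
            sil = cluster_quality(dm, groups)
        sil_payload = {"grouping": "membrane composition", "groups": groups,
                       "silhouette": sil}
        (outdir / "silhouette.json").write_text(json.dumps(sil_payload, indent=2))
        report["silhouette"] = sil
    else:
        logger.info("fewer than two systems produced strings; clustering skipped")

    if len(energies) >= 2:
        ttests = {}
        for (la, ea), (lb, eb) in combinations(energies.items(), 2):
            ttests[f"{la} vs {lb}"] = compare_energies(ea, eb).to_dict()
        (outdir / "ttests.json").write_text(json.dumps(ttests, indent=2))
        report["ttests"] = ttests
        for label, es in energies.items():
            es.to_csv(outdir / f"energies_{label.replace('*', 'star').replace('+', '_')}.csv")

    hashes = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
              if p.is_file() and p.name != "manifest.json"}
    report["output_sha256"] = hashes
    (outdir / "manifest.json").write_text(json.dumps(report, indent=2))
    return report
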