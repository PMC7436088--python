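"""Lipid topology descriptions and system labels.

A :class:`LipidTopology` tells the analysis code which atoms of a lipid
residue form each acyl chain (1-based numbering from the carbonyl carbon,
so the oleoyl double bond sits at carbon 9), which atom is the phosphorus
used for leaflet assignment and thickness, and — optionally — the names of
the explicit hydrogens attached to each chain carbon.  When hydrogen names
are absent the order-parameter code falls back to geometric C-H
reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: membranes and probe tautomer states used for system labelling
MEMBRANES = ("POPC", "DPPC-Chol")
PROBE_STATES = ("none", "N", "N*", "T*")


@dataclass(frozen=True)
class SystemLabel:
    """Identity of a simulated system: membrane composition + probe state."""

    membrane: str
    probe_state: str = "none"

    def __post_init__(self):
        if self.membrane not in MEMBRANES:
            raise ConfigurationError(
                f"unknown membrane {self.membrane!r}; expected one of {MEMBRANES}"
            )
        if self.probe_state not in PROBE_STATES:
            raise ConfigurationError(
                f"unknown probe state {self.probe_state!r}; expected one of {PROBE_STATES}"
            )

    def __str__(self) -> str:
        return self.membrane if self.probe_state == "none" else f"{self.membrane}+{self.probe_state}"


@dataclass
class AcylChain:
    """One acyl chain of a phospholipid.

    ``carbon_indices`` are 1-based acyl positions (carbonyl carbon = 1);
    ``double_bond_positions`` holds the first carbon of each C=C bond, so a
    value of 9 marks carbons 9 and 10 as sp2.
    """

    chain_id: str  # "sn1" | "sn2"
    carbon_names: list[str]
    carbon_indices: list[int]
    double_bond_positions: list[int] = field(default_factory=list)
    hydrogen_names: list[list[str]] | None = None

    def __post_init__(self):
        if not self.carbon_names:
            raise ConfigurationError(f"chain {self.chain_id}: empty carbon list")
        if len(self.carbon_names) != len(self.carbon_indices):
            raise ConfigurationError(
                f"chain {self.chain_id}: carbon names and indices differ in length"
            )
        if list(self.carbon_indices) != sorted(set(self.carbon_indices)):
            raise ConfigurationError(
                f"chain {self.chain_id}: carbon indices must be strictly increasing"
            )
        top = max(self.carbon_indices)
        for pos in self.double_bond_positions:
            if pos not in self.carbon_indices or pos + 1 > top:
                raise ConfigurationError(
                    f"chain {self.chain_id}: double bond at carbon {pos} outside chain"
                )
        if self.hydrogen_names is not None and len(self.hydrogen_names) != len(self.carbon_names):
            raise ConfigurationError(
                f"chain {self.chain_id}: hydrogen list must align with carbon list"
            )

    @property
    def sp2_carbons(self) -> set[int]:
        """Carbon indices that are part of a C=C bond (one hydrogen each)."""
        out: set[int] = set()
        for pos in self.double_bond_positions:
            out.update((pos, pos + 1))
        return out

    def is_terminal_methyl(self, index: int) -> bool:
        return index == self.carbon_indices[-1]


@dataclass
class LipidTopology:
    """Per-species atom naming: phosphorus + acyl chain carbons."""

    name: str
    phosphorus_atom: str
    chains: dict[str, AcylChain]

    def __post_init__(self):
        if not self.chains:
            raise ConfigurationError(f"topology {self.name}: no chains defined")
        for cid, chain in self.chains.items():
            if chain.chain_id != cid:
                raise ConfigurationError(
                    f"topology {self.name}: chain key {cid!r} != chain id {chain.chain_id!r}"
                )

    def required_atoms(self) -> list[str]:
        atoms = [self.phosphorus_atom]
        for chain in self.chains.values():
            atoms.extend(chain.carbon_names)
        return atoms

    # ------------------------------------------------------------------
    # serialisation (JSON or YAML, keyed by file suffix)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "phosphorus_atom": self.phosphorus_atom,
            "chains": {
                cid: {
                    "carbon_names": c.carbon_names,
                    "carbon_indices": c.carbon_indices,
                    "double_bond_positions": c.double_bond_positions,
                    "hydrogen_names": c.hydrogen_names,
                }
                for cid, c in self.chains.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LipidTopology":
        chains = {
            cid: AcylChain(
                chain_id=cid,
                carbon_names=list(spec["carbon_names"]),
                carbon_indices=list(spec["carbon_indices"]),
                double_bond_positions=list(spec.get("double_bond_positions") or []),
                hydrogen_names=spec.get("hydrogen_names"),
            )
            for cid, spec in d["chains"].items()
        }
        return cls(name=d["name"], phosphorus_atom=d["phosphorus_atom"], chains=chains)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "LipidTopology":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


def _hydrogens(index: int, last: int, sp2: set[int], tags: tuple[str, str, str]) -> list[str]:
    a, b, c = tags
    if index in sp2:
        return [f"{index}{a}"]
    if index == last:
        return [f"{index}{a}", f"{index}{b}", f"{index}{c}"]
    return [f"{index}{a}", f"{index}{b}"]


def _make_chain(chain_id: str, suffix: str, n_carbons: int,
                double_bonds: list[int], htags: tuple[str, str, str]) -> AcylChain:
    # carbons 2..n carry hydrogens; the carbonyl carbon (1) is excluded
    indices = list(range(2, n_carbons + 1))
    names = [f"C{i}{suffix}" for i in indices]
    sp2 = set()
    for p in double_bonds:
        sp2.update((p, p + 1))
    hyd = [_hydrogens(i, indices[-1], sp2, htags) for i in indices]
    return AcylChain(chain_id, names, indices, double_bonds, hyd)


def popc_topology() -> LipidTopology:
    """POPC: sn-1 palmitoyl (C16, saturated), sn-2 oleoyl (C18, 9-cis double bond)."""
    return LipidTopology(
        name="POPC",
        phosphorus_atom="P",
        chains={
            "sn1": _make_chain("sn1", "A", 16, [], ("HA", "HB", "HC")),
            "sn2": _make_chain("sn2", "B", 18, [9], ("HD", "HE", "HF")),
        },
    )


def dppc_topology() -> LipidTopology:
    """DPPC: two saturated palmitoyl chains (C16)."""
    return LipidTopology(
        name="DPPC",
        phosphorus_atom="P",
        chains={
            "sn1": _make_chain("sn1", "A", 16, [], ("HA", "HB", "HC")),
            "sn2": _make_chain("sn2", "B", 16, [], ("HD", "HE", "HF")),
        },
    )


#: residue names used by the synthetic generator for non-phospholipids
CHOLESTEROL_RESNAME = "CHL"
PROBE_RESNAME = "PRB"
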