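"""Benchmark protein presets: conformer pairs with two solved states.

Each preset names an initial and a target PDB entry together with the chain
and model conventions under which their Cα traces are compared: first protein
chain for the crystal structures, model 1 of the deposited bundle for NMR
entries, and for the bound carboxypeptidase-inhibitor complex the inhibitor
chain (the 77-residue chain matching the free-inhibitor NMR structure).

Structures are looked up in a local directory of PDB files (``<ID>.pdb``,
lower- or upper-case) and, if absent and allowed, downloaded from RCSB.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .structures import Ensemble, Structure, read_structure

__all__ = ["ConformerPreset", "PRESETS", "fetch_pdb", "load_structure", "load_bundle", "load_preset_pair"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


@dataclass(frozen=True)
class ConformerPreset:
    name: str
    initial_id: str
    target_id: str
    n_residues: int
    initial_chains: tuple[str, ...] | None = None
    target_chains: tuple[str, ...] | None = None
    initial_model: int = 1
    target_model: int = 1
    initial_is_bundle: bool = False
    target_is_bundle: bool = False


#: The five benchmark conformer pairs (initial -> target).
PRESETS: dict[str, ConformerPreset] = {
    "T4L": ConformerPreset("T4L", "172L", "1L69", 162, ("A",), ("A",)),
    # target 2X15 per the tabulated comparison; 2Y3I is an alternative
    # closed-state deposition of the same protein
    "PGK": ConformerPreset("PGK", "2XE6", "2X15", 413, ("A",), ("A",)),
    "PGK-2Y3I": ConformerPreset("PGK-2Y3I", "2XE6", "2Y3I", 413, ("A",), ("A",)),
    "AK": ConformerPreset("AK", "4AKE", "1AKE", 214, ("A",), ("A",)),
    "GB1": ConformerPreset(
        "GB1", "2N9K", "7QTS", 57,
        initial_is_bundle=True, target_is_bundle=True,
    ),
    # 1ZLI is the bound complex; the inhibitor is its 77-residue chain (I)
    "TCI": ConformerPreset(
        "TCI", "1ZLI", "2JTO", 77, initial_chains=("I",), target_is_bundle=True
    ),
}

CRYSTAL_PRESETS = ("T4L", "PGK", "AK")


def fetch_pdb(pdb_id: str, directory: Path | str, timeout: float = 30.0) -> Path:
    """Download a PDB entry into ``directory`` (skipped if already present)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for candidate in (directory / f"{pdb_id.lower()}.pdb", directory / f"{pdb_id.upper()}.pdb"):
        if candidate.exists():
            return candidate
    dest = directory / f"{pdb_id.lower()}.pdb"
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp, open(dest, "wb") as fh:
        fh.write(resp.read())
    return dest


def _resolve(pdb_id: str, directory, download: bool) -> Path:
    directory = Path(directory)
    for candidate in (directory / f"{pdb_id.lower()}.pdb", directory / f"{pdb_id.upper()}.pdb"):
        if candidate.exists():
            return candidate
    if download:
        return fetch_pdb(pdb_id, directory)
    raise FileNotFoundError(
        f"{pdb_id}.pdb not found in {directory} and downloading is disabled"
    )


def load_structure(
    pdb_id: str, directory, model: int = 1, chains=None, download: bool = True
) -> Structure:
    path = _resolve(pdb_id, directory, download)
    return read_structure(path, model=model, chains=chains, identifier=pdb_id)


def load_bundle(pdb_id: str, directory, chains=None, download: bool = True) -> Ensemble:
    """All models of a (typically NMR) entry as an Ensemble."""
    path = _resolve(pdb_id, directory, download)
    members = []
    model = 1
    while True:
        try:
            members.append(
                read_structure(path, model=model, chains=chains, identifier=f"{pdb_id}:m{model}")
            )
        except (ValueError, IndexError):
            break
        model += 1
    if not members:
        raise ValueError(f"no models readable from {path}")
    return Ensemble(structures=members)


def load_preset_pair(
    name: str, directory, download: bool = True
) -> tuple[Structure, Structure]:
    """Initial and target structures of a named preset under its conventions."""
    p = PRESETS[name]
    initial = load_structure(
        p.initial_id, directory, model=p.initial_model,
        chains=p.initial_chains, download=download,
    )
    target = load_structure(
        p.target_id, directory, model=p.target_model,
        chains=p.target_chains, download=download,
    )
    return initial, target
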