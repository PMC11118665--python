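"""Structure containers, PDB I/O, geometry and Cα-RMSD machinery.

Everything downstream (restraint selection, elastic-network sampling,
restrained dynamics) operates on Cα traces.  A :class:`Structure` keeps one
Cα per residue; heavy atoms are retained only so that relative solvent
accessibility can be computed for the FRET-labelling filter.

All coordinates are in Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueInfo",
    "Structure",
    "Ensemble",
    "DistanceMatrix",
    "Superposition",
    "read_structure",
    "write_pdb",
    "distance_matrix",
    "kabsch_superpose",
    "ca_rmsd",
    "per_residue_rmsd",
    "relative_sasa",
    "radius_of_gyration",
    "central_structure",
    "reference_rmsd_bundle",
    "shared_residues",
    "MAX_SASA",
]


class ResidueInfo(NamedTuple):
    resid: int
    chain: str
    resname: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.resid)


@dataclass
class Structure:
    """One protein conformation represented by its Cα trace.

    Parameters
    ----------
    identifier:
        Free-form label (e.g. a PDB id plus model number).
    residues:
        Ordered :class:`ResidueInfo` records, one per Cα.
    ca_coords:
        ``(N, 3)`` float array of Cα positions in Å.
    heavy_atoms:
        Optional per-residue list of ``(element, xyz)`` heavy atoms used for
        solvent-accessibility calculations.
    rsasa:
        Optional per-residue relative solvent-accessible surface area.
    source_model:
        1-based model index in the source file (PDB convention).
    """

    identifier: str
    residues: list[ResidueInfo]
    ca_coords: np.ndarray
    heavy_atoms: list[list[tuple[str, np.ndarray]]] | None = None
    rsasa: np.ndarray | None = None
    source_model: int = 1

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must have shape (N, 3)")
        if len(self.residues) != len(self.ca_coords):
            raise ValueError("residues and ca_coords length mismatch")
        if self.n_residues < 1:
            raise ValueError("a Structure needs at least one residue")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resid) keys")
        if self.rsasa is not None:
            self.rsasa = np.asarray(self.rsasa, dtype=float)
            if self.rsasa.shape != (self.n_residues,):
                raise ValueError("rsasa must be one value per residue")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return [r.key for r in self.residues]

    def index_of(self, key: tuple[str, int]) -> int:
        try:
            return self.residue_keys.index(tuple(key))
        except ValueError as exc:
            raise KeyError(f"residue {key!r} not in structure") from exc

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "Structure":
        """Copy of this structure with replaced Cα coordinates."""
        return replace(
            self,
            ca_coords=np.array(coords, dtype=float),
            identifier=identifier or self.identifier,
            heavy_atoms=self.heavy_atoms,
        )


@dataclass
class Ensemble:
    """Ordered collection of conformations sharing one residue index."""

    structures: list[Structure]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.structures) < 1:
            raise ValueError("an Ensemble needs at least one member")
        keys0 = self.structures[0].residue_keys
        for s in self.structures[1:]:
            if s.residue_keys != keys0:
                raise ValueError("all ensemble members must share residue ids")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.structures),):
                raise ValueError("one weight per structure required")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.structures)

    def __getitem__(self, i):
        return self.structures[i]

    def __iter__(self):
        return iter(self.structures)

    @property
    def coords(self) -> np.ndarray:
        """Stacked ``(Ns, N, 3)`` coordinate array."""
        return np.stack([s.ca_coords for s in self.structures])

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return self.structures[0].residue_keys


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Cα pair separations R_bd in Å."""

    values: np.ndarray
    residue_keys: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_keys)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def __getitem__(self, idx):
        return self.values[idx]

    @property
    def n(self) -> int:
        return len(self.residue_keys)


@dataclass
class Superposition:
    """Proper rigid motion ``x -> rotation @ x + translation`` with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _highest_occupancy(atom):
    if atom.is_disordered():
        children = sorted(atom, key=lambda a: a.get_occupancy() or 0.0, reverse=True)
        return children[0]
    return atom


def read_structure(
    path,
    model: int = 1,
    chains: Sequence[str] | None = None,
    identifier: str | None = None,
) -> Structure:
    """Read one model from a PDB file into a :class:`Structure`.

    Parameters
    ----------
    model:
        1-based model index (PDB ``MODEL`` record convention).
    chains:
        Optional iterable of chain ids to keep; default keeps all chains.

    Residues lacking a Cα (waters, ligands, incomplete residues) are skipped
    with a logged warning.  Altloc atoms are resolved to the highest-occupancy
    conformer.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    name = identifier or str(path)
    structure = parser.get_structure(name, path)
    models = list(structure)
    wanted = None
    for m in models:
        # Biopython serial_num carries the PDB MODEL number (1-based)
        if m.serial_num == model or (m.serial_num == 0 and model == 1):
            wanted = m
            break
    if wanted is None:
        if 1 <= model <= len(models):
            wanted = models[model - 1]
        else:
            raise ValueError(
                f"model {model} not present in {path} ({len(models)} model(s))"
            )

    residues: list[ResidueInfo] = []
    coords: list[np.ndarray] = []
    heavy: list[list[tuple[str, np.ndarray]]] = []
    for chain in wanted:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetflag, resid, icode = res.id
            if hetflag.strip():
                continue
            if "CA" not in res:
                logger.warning(
                    "residue %s %s%s in %s has no CA atom; skipped",
                    res.get_resname(), chain.id, resid, name,
                )
                continue
            ca = _highest_occupancy(res["CA"])
            residues.append(ResidueInfo(int(resid), str(chain.id), res.get_resname()))
            coords.append(np.asarray(ca.get_coord(), dtype=float))
            atoms = []
            for atom in res:
                a = _highest_occupancy(atom)
                el = (a.element or "C").strip() or "C"
                if el == "H" or el == "D":
                    continue
                atoms.append((el, np.asarray(a.get_coord(), dtype=float)))
            heavy.append(atoms)
    if not residues:
        raise ValueError(f"no CA atoms found in {path} (model {model})")
    return Structure(
        identifier=identifier or f"{path}:model{model}",
        residues=residues,
        ca_coords=np.array(coords),
        heavy_atoms=heavy,
        source_model=model,
    )


def write_pdb(path, obj: Structure | Ensemble) -> None:
    """Write a Cα trace (or multi-model ensemble) as a PDB file."""
    from Bio.PDB import PDBIO, StructureBuilder

    members = obj.structures if isinstance(obj, Ensemble) else [obj]
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("fretrest")
    for m_i, s in enumerate(members):
        builder.init_model(m_i, m_i + 1)
        seen_chains: set[str] = set()
        for info, xyz in zip(s.residues, s.ca_coords):
            if info.chain not in seen_chains:
                builder.init_chain(info.chain)
                seen_chains.add(info.chain)
            else:
                builder.structure[m_i][info.chain]
            builder.init_seg("    ")
            builder.init_residue(info.resname, " ", info.resid, " ")
            builder.init_atom("CA", np.asarray(xyz, float), 0.0, 1.0, " ", " CA ", None, "C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def distance_matrix(s: Structure) -> DistanceMatrix:
    """Symmetric N×N matrix of Cα–Cα separations."""
    vals = squareform(pdist(s.ca_coords)) if s.n_residues > 1 else np.zeros((1, 1))
    return DistanceMatrix(values=vals, residue_keys=s.residue_keys)


def radius_of_gyration(s: Structure) -> float:
    """Unweighted root-mean-square Cα distance from the Cα centroid."""
    centered = s.ca_coords - s.ca_coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def shared_residues(si: Structure, sj: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays into ``si`` and ``sj`` for their common (chain, resid) keys.

    Order follows ``si``'s residue order.  Same-sequence conformers are the
    expected use case, so no sequence alignment is attempted.
    """
    keys_j = {k: idx for idx, k in enumerate(sj.residue_keys)}
    ii, jj = [], []
    for idx, k in enumerate(si.residue_keys):
        if k in keys_j:
            ii.append(idx)
            jj.append(keys_j[k])
    return np.array(ii, dtype=int), np.array(jj, dtype=int)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid motion mapping ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1, reflections
    corrected via the SVD sign trick).
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    P = mobile - mob_c
    Q = reference - ref_c
    H = P.T @ Q
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    diff = P @ R.T - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    subset: Sequence[tuple[str, int]] | None = None,
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The returned RMSD is the global minimum of the Cα RMSD over all proper
    rigid motions applied to ``mobile``, computed over the shared residues
    (optionally restricted to ``subset``).
    """
    ii, jj = shared_residues(mobile, reference)
    if subset is not None:
        keep = {tuple(k) for k in subset}
        mask = [mobile.residues[a].key in keep for a in ii]
        ii, jj = ii[mask], jj[mask]
    if len(ii) == 0:
        raise ValueError("no shared residues between structures")
    if len(ii) < 3:
        raise ValueError(
            f"only {len(ii)} shared residue(s); at least 3 are needed for a "
            "unique rigid superposition"
        )
    R, t, rmsd = _kabsch(mobile.ca_coords[ii], reference.ca_coords[jj])
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def ca_rmsd(
    si: Structure,
    sj: Structure,
    align: bool = True,
    subset: Sequence[tuple[str, int]] | None = None,
) -> float:
    """Cα root-mean-square deviation between two conformations.

    With ``align`` the structures are first optimally superposed (the usual
    convention); without it the RMSD is evaluated on the coordinates as given.
    Unlike :func:`kabsch_superpose`, fewer than 3 shared residues are accepted:
    the minimum RMSD is well-defined even where the optimal rotation is not
    unique.
    """
    ii, jj = shared_residues(si, sj)
    if subset is not None:
        keep = {tuple(k) for k in subset}
        mask = [si.residues[a].key in keep for a in ii]
        ii, jj = ii[mask], jj[mask]
    if len(ii) == 0:
        raise ValueError("no shared residues between structures")
    if align:
        return _kabsch(si.ca_coords[ii], sj.ca_coords[jj])[2]
    diff = si.ca_coords[ii] - sj.ca_coords[jj]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def per_residue_rmsd(ensemble: Ensemble, target: Structure, align: bool = True) -> np.ndarray:
    """Per-residue Cα RMSD profile of an ensemble against a target.

    ``profile[b]`` is the root-mean-square, over ensemble members, of the Cα
    deviation of residue ``b`` after (optional) per-member superposition onto
    the target.
    """
    ii, jj = shared_residues(ensemble.structures[0], target)
    if len(ii) == 0:
        raise ValueError("ensemble and target share no residues")
    acc = np.zeros(len(ii))
    for s in ensemble:
        mob = s.ca_coords[ii]
        ref = target.ca_coords[jj]
        if align:
            R, t, _ = _kabsch(mob, ref)
            mob = mob @ R.T + t
        acc += np.sum((mob - ref) ** 2, axis=1)
    return np.sqrt(acc / len(ensemble))


def central_structure(ensemble: Ensemble, cutoff: float = 1.0) -> int:
    """Index of the member with the most neighbours within ``cutoff`` aligned RMSD.

    Ties are broken in favour of the lowest index, so an ensemble of identical
    members returns 0.
    """
    ns = len(ensemble)
    counts = np.zeros(ns, dtype=int)
    for i in range(ns):
        for j in range(i + 1, ns):
            if ca_rmsd(ensemble[i], ensemble[j], align=True) < cutoff:
                counts[i] += 1
                counts[j] += 1
    return int(np.argmax(counts))


def reference_rmsd_bundle(bundle: Ensemble) -> float:
    """Mean pairwise aligned Cα RMSD over all distinct model pairs of a bundle."""
    ns = len(bundle)
    if ns < 2:
        raise ValueError("bundle variant needs at least 2 models")
    vals = [
        ca_rmsd(bundle[i], bundle[j], align=True)
        for i in range(ns)
        for j in range(i + 1, ns)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

#: Theoretical maximum per-residue SASA (Å²), Tien-style normalisation.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_DEFAULT_MAX_SASA = 200.0

# Atomic radii (Å) for the Shrake–Rupley calculation, matching the common
# protein heavy-atom set.
_ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}


def _shrake_rupley(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling."""
    # Fibonacci sphere: near-uniform unit directions
    k = np.arange(n_points)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * k + 1) / n_points
    theta = 2 * np.pi * k / phi
    r_xy = np.sqrt(np.maximum(0.0, 1 - z**2))
    sphere = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])

    n = len(coords)
    extended = radii + probe
    areas = np.zeros(n)
    # neighbour lists via one distance matrix (desk-scale systems)
    dmat = cdist(coords, coords)
    for i in range(n):
        pts = coords[i] + extended[i] * sphere
        nbrs = np.where((dmat[i] < extended[i] + extended.max()) & (np.arange(n) != i))[0]
        nbrs = nbrs[dmat[i, nbrs] < extended[i] + extended[nbrs]]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= extended[j]
        areas[i] = 4 * np.pi * extended[i] ** 2 * accessible.mean()
    return areas


def relative_sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-residue relative solvent-accessible surface area.

    Shrake–Rupley SASA (probe 1.4 Å) of each residue's heavy atoms divided by
    a fixed per-residue-type maximum-exposure value.  Values are not clamped
    and may slightly exceed 1 for terminal or unusually exposed residues.
    """
    if s.heavy_atoms is None:
        raise ValueError(
            "structure has no heavy atoms; provide a pre-annotated rsasa field "
            "(e.g. via a 2-column TSV) instead"
        )
    coords, radii, owner = [], [], []
    for r_idx, atoms in enumerate(s.heavy_atoms):
        for el, xyz in atoms:
            coords.append(xyz)
            radii.append(_ATOM_RADII.get(el.upper(), 1.70))
            owner.append(r_idx)
    areas = _shrake_rupley(np.array(coords), np.array(radii), probe=probe, n_points=n_points)
    per_res = np.zeros(s.n_residues)
    np.add.at(per_res, np.array(owner), areas)
    norm = np.array([MAX_SASA.get(r.resname, _DEFAULT_MAX_SASA) for r in s.residues])
    return per_res / norm


def get_rsasa(s: Structure) -> np.ndarray:
    """Annotated rSASA if present, else computed from heavy atoms."""
    if s.rsasa is not None:
        return s.rsasa
    return relative_sasa(s)


def read_rsasa_tsv(path) -> dict[int, float]:
    """Read a 2-column (residue-id, rSASA) TSV annotation."""
    out: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            resid, val = line.split("\t")[:2]
            out[int(resid)] = float(val)
    return out
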