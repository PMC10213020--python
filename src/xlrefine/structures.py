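"""Coordinate model and geometry primitives for multimeric structures.

The in-memory model is deliberately light: chains of residues, each residue a
list of (atom_name, element, xyz) records in Å, addressed by 1-based author
numbering.  Everything downstream (restraints, refinement, scoring) works on
Cα coordinates; full-atom structures are supported for SASA and mass-weighted
radius-of-gyration calculations on real PDB/mmCIF inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "StructureError",
    "read_structure",
    "write_pdb",
    "truncate_region",
    "ca_distance",
    "radius_of_gyration",
]

# Average atomic masses (u) for mass-weighted Rg on full-atom inputs.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "NA": 22.990, "CL": 35.45, "X": 12.011,
}


class StructureError(ValueError):
    """Raised for unreadable files, missing atoms, or empty selections."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not all(np.isfinite(self.xyz)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    residue_number: int
    amino_acid: str  # one-letter code; 'X' for unknown
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        nums = [r.residue_number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )

    @property
    def has_gaps(self) -> bool:
        nums = [r.residue_number for r in self.residues]
        return any(b - a > 1 for a, b in zip(nums, nums[1:]))

    def residue(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.residue_number == number:
                return r
        return None

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        out = []
        for r in self.residues:
            ca = r.ca
            if ca is None:
                raise StructureError(
                    f"residue {self.chain_id}/{r.residue_number} has no CA atom"
                )
            out.append(ca.xyz)
        return np.asarray(out, dtype=float)


@dataclass
class StructureModel:
    model_id: str
    chains: list[Chain]
    source: str = "synthetic"

    def __post_init__(self):
        if not self.chains:
            raise StructureError("a structure needs at least one chain")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"no chain {chain_id!r} in model {self.model_id}")

    def iter_atoms(self) -> Iterable[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy copy (ties keep
    the first encountered).  HETATM records are ignored.  A chain without any
    Cα atoms is retained with a warning.
    """
    import gemmi

    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    gmodel = st[0]

    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag == "H":
                continue
            # resolve altLocs: per atom name keep highest occupancy, tie -> first
            best: dict[str, "gemmi.Atom"] = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            atoms = [
                Atom(ga.name, ga.element.name.upper() or "X",
                     (ga.pos.x, ga.pos.y, ga.pos.z))
                for ga in best.values()
            ]
            if not atoms:
                continue
            residues.append(Residue(
                residue_number=gres.seqid.num,
                amino_acid=THREE_TO_ONE.get(gres.name.upper(), "X"),
                atoms=atoms,
            ))
        if not residues:
            continue
        if not any(r.ca for r in residues):
            warnings.warn(f"chain {gchain.name} has no CA atoms; retained")
        chains.append(Chain(chain_id=gchain.name[:1] or "A", residues=residues))

    if not chains:
        raise StructureError(f"{path}: no polymer chains with atoms")
    return StructureModel(model_id=str(path), chains=chains, source=str(path))


def write_pdb(model: StructureModel, path: str,
              bfactors: dict[tuple[str, int], float] | None = None) -> None:
    """Write ATOM records; B-factor column optionally carries per-residue scores."""
    lines = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.amino_acid, "UNK")
            b = 0.0
            if bfactors is not None:
                b = bfactors.get((chain.chain_id, res.residue_number), 0.0)
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} "
                    f"{chain.chain_id}{res.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def truncate_region(model: StructureModel, start: int, end: int) -> StructureModel:
    """Restrict every chain to residues in [start, end]; drop emptied chains."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    chains = []
    for c in model.chains:
        kept = [r for r in c.residues if start <= r.residue_number <= end]
        if kept:
            chains.append(Chain(chain_id=c.chain_id, residues=kept))
    if not chains:
        raise StructureError(
            f"no residue of {model.model_id} falls in [{start}, {end}]"
        )
    return StructureModel(model_id=model.model_id, chains=chains,
                          source=model.source)


def _ca_xyz(model: StructureModel, site: tuple[str, int]) -> np.ndarray:
    chain_id, resnum = site
    res = model.chain(chain_id).residue(resnum)
    if res is None:
        raise StructureError(f"no residue {resnum} in chain {chain_id}")
    if res.ca is None:
        raise StructureError(f"residue {chain_id}/{resnum} has no CA atom")
    return np.asarray(res.ca.xyz, dtype=float)


def ca_distance(model: StructureModel, site_a: tuple[str, int],
                site_b: tuple[str, int]) -> float:
    """Euclidean Cα–Cα distance (Å) between two (chain_id, residue_number) sites."""
    return float(np.linalg.norm(_ca_xyz(model, site_a) - _ca_xyz(model, site_b)))


def radius_of_gyration(model: StructureModel, mode: str = "ca_only") -> float:
    """Radius of gyration in Å.

    Rg = sqrt(Σ wᵢ‖rᵢ − r̄‖² / Σ wᵢ); weights are 1 for ``ca_only`` and
    average atomic masses for ``all_atom_mass_weighted``.
    """
    coords: list[Sequence[float]] = []
    weights: list[float] = []
    if mode == "ca_only":
        for c in model.chains:
            for r in c.residues:
                if r.ca is not None:
                    coords.append(r.ca.xyz)
                    weights.append(1.0)
    elif mode == "all_atom_mass_weighted":
        for _, _, a in model.iter_atoms():
            coords.append(a.xyz)
            weights.append(ATOMIC_MASSES.get(a.element.upper(), 12.011))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not coords:
        raise StructureError("no points selected for radius of gyration")
    x = np.asarray(coords, dtype=float)
    w = np.asarray(weights, dtype=float)
    center = np.average(x, axis=0, weights=w)
    sq = np.sum((x - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))
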