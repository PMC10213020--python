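"""Shrake–Rupley solvent-accessible surface area with a deterministic point set.

Each atom is expanded by the probe radius and covered with a fixed
golden-spiral lattice of test points; points falling inside any neighbouring
expanded sphere are occluded.  The point set is identical between runs and
platforms, so SASA values are exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structures import StructureModel

__all__ = ["SasaResult", "sasa", "VDW_RADII", "MAX_SIDE_CHAIN_AREA"]

# Van-der-Waals radii (Å) for the elements that occur in protein structures.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "D": 1.2,
             "P": 1.8, "SE": 1.9}
DEFAULT_RADIUS = 1.8

# Pseudo-side-chain sphere used by the synthetic Cα-only models (see
# synthetic.add_pseudo_side_chains): a single 2.3 Å sphere standing in for
# the whole side chain.
PSEUDO_SIDE_CHAIN_ATOM = "PSC"
PSEUDO_SIDE_CHAIN_RADIUS = 2.3

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

# Approximate maximum side-chain SASA (Å²) in an extended Gly-X-Gly context,
# used to normalise side-chain areas to relative accessibilities.
MAX_SIDE_CHAIN_AREA = {
    "A": 69.0, "R": 201.0, "N": 114.0, "D": 111.0, "C": 104.0,
    "Q": 146.0, "E": 140.0, "G": 1.0, "H": 152.0, "I": 139.0,
    "L": 141.0, "K": 164.0, "M": 160.0, "F": 176.0, "P": 106.0,
    "S": 81.0, "T": 102.0, "W": 218.0, "Y": 187.0, "V": 114.0,
    "X": 160.0,
}


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (Å²)."""
    per_atom: dict[tuple[str, int, str], float]
    per_residue_total: dict[tuple[str, int], float] = field(default_factory=dict)
    per_residue_side_chain: dict[tuple[str, int], float] = field(default_factory=dict)
    relative_side_chain: dict[tuple[str, int], float] = field(default_factory=dict)
    clamped: bool = False  # True if any relative value exceeded 1 and was capped


def _golden_spiral(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(model: StructureModel, probe_radius: float = 1.4,
         n_sphere_points: int = 960,
         atom_radii: dict[str, float] | None = None,
         unknown_element: str = "default") -> SasaResult:
    """Shrake–Rupley SASA of every atom in the model.

    Parameters
    ----------
    probe_radius : solvent probe radius in Å (water: 1.4).
    n_sphere_points : size of the golden-spiral test lattice per atom.
    atom_radii : optional per-atom-NAME radius overrides; takes precedence
        over the element table.  The pseudo-side-chain atom used by synthetic
        models is included by default.
    unknown_element : "default" assigns 1.8 Å with a warning; "error" raises.
    """
    names: list[tuple[str, int, str]] = []
    keys_res: list[tuple[str, int]] = []
    aa: dict[tuple[str, int], str] = {}
    coords = []
    radii = []
    side_chain = []
    overrides = {PSEUDO_SIDE_CHAIN_ATOM: PSEUDO_SIDE_CHAIN_RADIUS}
    if atom_radii:
        overrides.update(atom_radii)

    for chain, res, atom in model.iter_atoms():
        el = atom.element.upper()
        if atom.name in overrides:
            r = overrides[atom.name]
        elif el in VDW_RADII:
            r = VDW_RADII[el]
        elif unknown_element == "error":
            raise ValueError(f"no van-der-Waals radius for element {el!r}")
        else:
            warnings.warn(f"element {el!r} unknown; using {DEFAULT_RADIUS} Å")
            r = DEFAULT_RADIUS
        if el in ("H", "D") and atom.name not in overrides:
            # hydrogens are typically absent from X-ray models; when present
            # they still contribute area, so they are kept.
            pass
        names.append((chain.chain_id, res.residue_number, atom.name))
        keys_res.append((chain.chain_id, res.residue_number))
        aa[(chain.chain_id, res.residue_number)] = res.amino_acid
        coords.append(atom.xyz)
        radii.append(r + probe_radius)
        side_chain.append(atom.name not in BACKBONE_ATOMS)

    if not coords:
        raise ValueError("model has no atoms")

    xyz = np.asarray(coords, dtype=float)
    rad = np.asarray(radii, dtype=float)
    points = _golden_spiral(n_sphere_points)
    n = len(xyz)

    per_atom: dict[tuple[str, int, str], float] = {}
    # neighbour lists via a coarse distance cut
    max_rad = rad.max()
    for i in range(n):
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        nb = np.where((d < rad[i] + max_rad) & (d > 0))[0]
        nb = nb[d[nb] < rad[i] + rad[nb]]
        surf = xyz[i] + rad[i] * points
        if nb.size:
            d2 = ((surf[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 > (rad[nb] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[names[i]] = float(4.0 * np.pi * rad[i] ** 2 * frac)

    result = SasaResult(per_atom=per_atom)
    for key, name_key, is_sc in zip(keys_res, names, side_chain):
        area = per_atom[name_key]
        result.per_residue_total[key] = result.per_residue_total.get(key, 0.0) + area
        if is_sc:
            result.per_residue_side_chain[key] = (
                result.per_residue_side_chain.get(key, 0.0) + area)

    pseudo_ref = 4.0 * np.pi * (PSEUDO_SIDE_CHAIN_RADIUS + probe_radius) ** 2
    for key in result.per_residue_total:
        sc = result.per_residue_side_chain.get(key, 0.0)
        # synthetic residues carry a single pseudo-side-chain sphere and are
        # normalised to its isolated area; real residues use the reference table
        has_pseudo = (key[0], key[1], PSEUDO_SIDE_CHAIN_ATOM) in per_atom
        ref = pseudo_ref if has_pseudo else MAX_SIDE_CHAIN_AREA.get(
            aa[key], MAX_SIDE_CHAIN_AREA["X"])
        rel = sc / ref
        if rel > 1.0:
            result.clamped = True
            rel = min(rel, 1.2)
        result.relative_side_chain[key] = rel
    return result
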