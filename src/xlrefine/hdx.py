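"""HDX-MS uptake computation, back-exchange correction, and SASA correlation.

Deuterium uptake of a peptic peptide is read from the centroid-mass shift of
its isotope envelope.  Rather than converting to absolute deuterons, uptake
is expressed relative to a fully-equilibrated control (the same protein
stored in 80 % D₂O), which cancels back-exchange during handling:

    corrected_fraction = (m_t − m_undeut) / (m_full_control − m_undeut)

Peptides whose backbone is solvent-exposed and free of hydrogen bonding
exchange fast (fraction → control level within seconds); structured regions
exchange slowly.  The Spearman correlation between corrected uptake and the
mean relative side-chain SASA over each peptide span is the model-validation
statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sasa import SasaResult
from .structures import StructureModel

__all__ = ["HdxPeptide", "UptakeResult", "max_exchangeable",
           "back_exchange_correct", "compute_uptake",
           "residue_level_sasa_profile", "hdx_sasa_correlation"]

DEFAULT_TIME_POINTS = (30, 60, 120)  # seconds


def max_exchangeable(sequence: str) -> int:
    """Number of exchanging backbone amides: length − 1 − prolines after
    the first position (the N-terminal amine and prolyl nitrogens do not
    report)."""
    if not sequence:
        return 0
    return len(sequence) - 1 - sequence[1:].count("P")


@dataclass
class HdxPeptide:
    start: int
    end: int
    sequence: str
    centroid_mass: dict[int, float]   # time (s) -> Da
    m_undeuterated: float
    m_full_control: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("peptide end before start")
        if self.m_full_control < self.m_undeuterated:
            raise ValueError("full-exchange control below undeuterated mass")

    @property
    def max_exchangeable(self) -> int:
        return max_exchangeable(self.sequence)


@dataclass
class UptakeResult:
    """corrected_fraction per (peptide span, time); raw uptake in Da."""
    raw_uptake: dict[tuple[tuple[int, int], int], float] = field(default_factory=dict)
    corrected_fraction: dict[tuple[tuple[int, int], int], float] = field(default_factory=dict)
    clamped: bool = False


def back_exchange_correct(peptide: HdxPeptide, time_s: int) -> float:
    """Control-relative exchanged fraction at one time point, clamped to
    [0, 1.05]."""
    span = peptide.m_full_control - peptide.m_undeuterated
    if span <= 0:
        raise ValueError(
            f"peptide {peptide.start}-{peptide.end}: degenerate control "
            "(full-exchange mass equals undeuterated mass)")
    if time_s not in peptide.centroid_mass:
        raise KeyError(f"no centroid mass at t={time_s}s")
    frac = (peptide.centroid_mass[time_s] - peptide.m_undeuterated) / span
    return float(np.clip(frac, 0.0, 1.05))


def compute_uptake(peptides: list[HdxPeptide],
                   time_points=DEFAULT_TIME_POINTS) -> UptakeResult:
    """Raw and corrected uptake for every peptide and time point."""
    result = UptakeResult()
    for pep in peptides:
        if pep.m_full_control <= pep.m_undeuterated:
            warnings.warn(
                f"peptide {pep.start}-{pep.end} excluded: degenerate control")
            continue
        for t in time_points:
            if t not in pep.centroid_mass:
                continue
            key = ((pep.start, pep.end), t)
            raw = pep.centroid_mass[t] - pep.m_undeuterated
            frac = (raw / (pep.m_full_control - pep.m_undeuterated))
            if frac < 0 or frac > 1.05:
                result.clamped = True
            result.raw_uptake[key] = float(raw)
            result.corrected_fraction[key] = float(np.clip(frac, 0.0, 1.05))
    return result


def residue_level_sasa_profile(model: StructureModel,
                               peptides: list[HdxPeptide],
                               sasa: SasaResult,
                               ) -> dict[tuple[int, int], float]:
    """Mean per-residue relative side-chain SASA over each peptide span.

    Peptides fully outside the modelled region are excluded with a warning;
    partially covered spans use the covered residues.
    """
    by_residue: dict[int, list[float]] = {}
    for (cid, num), rel in sasa.relative_side_chain.items():
        by_residue.setdefault(num, []).append(rel)

    profile: dict[tuple[int, int], float] = {}
    for pep in peptides:
        vals = [np.mean(by_residue[n])
                for n in range(pep.start, pep.end + 1) if n in by_residue]
        if not vals:
            warnings.warn(
                f"peptide {pep.start}-{pep.end} outside model; excluded")
            continue
        profile[(pep.start, pep.end)] = float(np.mean(vals))
    return profile


def hdx_sasa_correlation(uptake: UptakeResult,
                         profile: dict[tuple[int, int], float],
                         time_s: int) -> float:
    """Spearman correlation of corrected uptake vs mean relative SASA at one
    labeling time.  Needs ≥3 overlapping peptides; constant vectors → NaN."""
    pairs = [(frac, profile[span])
             for (span, t), frac in uptake.corrected_fraction.items()
             if t == time_s and span in profile]
    if len(pairs) < 3:
        raise ValueError("need at least three overlapping peptides")
    u = [p[0] for p in pairs]
    s = [p[1] for p in pairs]
    if len(set(u)) == 1 or len(set(s)) == 1:
        warnings.warn("constant input; correlation undefined")
        return math.nan
    rho, _ = stats.spearmanr(u, s)
    return float(rho)
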