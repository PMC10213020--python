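"""Tab-separated external interfaces for every evidence and result type.

All tables are plain TSV read and written with pandas; the ensemble manifest
additionally echoes its plan configuration as JSON for provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict

import pandas as pd

from .hdx import HdxPeptide
from .quantxl import DifferentialResult, LabelingSite, QuantRecord
from .restraints import (CrossLink, DistanceRestraint, EnsembleManifest,
                         Linker, ManifestEntry, PlanConfig)
from .sasa import SasaResult
from .scoring import ScoreCard

__all__ = [
    "write_crosslinks_tsv", "read_crosslinks_tsv",
    "write_restraints_tsv", "read_restraints_tsv",
    "write_manifest", "read_manifest",
    "write_quant_tsv", "read_quant_tsv",
    "write_differential_tsv",
    "write_sites_tsv", "read_sites_tsv",
    "write_hdx_tsv", "read_hdx_tsv",
    "write_scorecards_tsv", "write_sasa_tsv", "write_rg_tsv",
    "write_modeller_style_restraints",
]


def write_crosslinks_tsv(xls: list[CrossLink], path: str) -> None:
    pd.DataFrame([{
        "protein": x.protein, "res_a": x.res_a, "res_b": x.res_b,
        "linker": x.linker.value, "link_class": x.link_class,
        "replicate_ids": ";".join(x.replicate_ids),
    } for x in xls]).to_csv(path, sep="\t", index=False)


def read_crosslinks_tsv(path: str) -> list[CrossLink]:
    df = pd.read_csv(path, sep="\t", dtype={"replicate_ids": str})
    out = []
    for row in df.itertuples():
        reps = tuple(str(row.replicate_ids).split(";")) \
            if isinstance(row.replicate_ids, str) and row.replicate_ids else ()
        out.append(CrossLink(
            protein=row.protein, res_a=int(row.res_a), res_b=int(row.res_b),
            linker=Linker(row.linker), replicate_ids=reps,
            link_class=row.link_class))
    return out


def write_restraints_tsv(restraints: list[DistanceRestraint], path: str) -> None:
    pd.DataFrame([asdict(r) for r in restraints]).to_csv(
        path, sep="\t", index=False)


def read_restraints_tsv(path: str) -> list[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    return [DistanceRestraint(res_a=int(r.res_a), res_b=int(r.res_b),
                              mean=float(r.mean), sd=float(r.sd),
                              form=str(r.form))
            for r in df.itertuples()]


def write_modeller_style_restraints(restraints: list[DistanceRestraint],
                                    path: str, chain_ids=("A", "B", "C", "D"),
                                    ) -> None:
    """Plain-text upper-bound restraint listing for users of external
    refiners (one line per restraint per chain)."""
    lines = []
    for cid in chain_ids:
        for r in restraints:
            lines.append(
                f"UPPER_BOUND CA {r.res_a}:{cid} CA {r.res_b}:{cid} "
                f"mean {r.mean:.1f} sd {r.sd:.1f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_manifest(manifest: EnsembleManifest, tsv_path: str,
                   json_path: str | None = None) -> None:
    pd.DataFrame([asdict(e) for e in manifest.entries]).to_csv(
        tsv_path, sep="\t", index=False)
    if json_path and manifest.config is not None:
        with open(json_path, "w") as fh:
            json.dump(asdict(manifest.config), fh, indent=1)


def read_manifest(tsv_path: str, json_path: str | None = None) -> EnsembleManifest:
    df = pd.read_csv(tsv_path, sep="\t")
    entries = [ManifestEntry(
        strategy=r.strategy, restraint_set_id=r.restraint_set_id,
        seed=int(r.seed), n_models=int(r.n_models), done=bool(r.done))
        for r in df.itertuples()]
    config = None
    if json_path:
        with open(json_path) as fh:
            config = PlanConfig(**json.load(fh))
    return EnsembleManifest(entries=entries, config=config)


def write_quant_tsv(records: list[QuantRecord], path: str) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_quant_tsv(path: str) -> list[QuantRecord]:
    df = pd.read_csv(path, sep="\t")
    return [QuantRecord(link_id=str(r.link_id), replicate=str(r.replicate),
                        label_orientation=r.label_orientation,
                        intensity_d0=float(r.intensity_d0),
                        intensity_d4=float(r.intensity_d4), state=r.state)
            for r in df.itertuples()]


def write_differential_tsv(results: dict[str, DifferentialResult],
                           path: str) -> None:
    pd.DataFrame([asdict(r) for r in results.values()]).to_csv(
        path, sep="\t", index=False)


def write_sites_tsv(sites: list[LabelingSite], path: str) -> None:
    rows = []
    for s in sites:
        for (state, rep), y in sorted(s.yields.items()):
            rows.append({"residue": s.residue, "state": state,
                         "replicate": rep, "yield_percent": y,
                         "normalized_ratio": s.normalized_ratio,
                         "accessibility_class": s.accessibility_class or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> list[LabelingSite]:
    df = pd.read_csv(path, sep="\t")
    sites: dict[int, LabelingSite] = {}
    for r in df.itertuples():
        site = sites.setdefault(int(r.residue), LabelingSite(residue=int(r.residue)))
        site.yields[(str(r.state), str(r.replicate))] = float(r.yield_percent)
        if isinstance(r.accessibility_class, str) and r.accessibility_class:
            site.accessibility_class = r.accessibility_class
        if not math.isnan(float(r.normalized_ratio)):
            site.normalized_ratio = float(r.normalized_ratio)
    return list(sites.values())


def write_hdx_tsv(peptides: list[HdxPeptide], path: str) -> None:
    rows = []
    for p in peptides:
        for t, m in sorted(p.centroid_mass.items()):
            rows.append({"start": p.start, "end": p.end, "sequence": p.sequence,
                         "m_undeuterated": p.m_undeuterated,
                         "m_full_control": p.m_full_control,
                         "time_s": t, "centroid_mass": m})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hdx_tsv(path: str) -> list[HdxPeptide]:
    df = pd.read_csv(path, sep="\t")
    peptides: dict[tuple[int, int], HdxPeptide] = {}
    for r in df.itertuples():
        key = (int(r.start), int(r.end))
        if key not in peptides:
            peptides[key] = HdxPeptide(
                start=key[0], end=key[1], sequence=str(r.sequence),
                centroid_mass={}, m_undeuterated=float(r.m_undeuterated),
                m_full_control=float(r.m_full_control))
        peptides[key].centroid_mass[int(r.time_s)] = float(r.centroid_mass)
    return list(peptides.values())


def write_scorecards_tsv(cards: list[ScoreCard], path: str) -> None:
    ordered = sorted(cards, key=lambda c: (-c.combined, -c.xl_score, c.model_id))
    pd.DataFrame([{
        "model_id": c.model_id, "xl_score": c.xl_score,
        "footprint_score": c.footprint_score, "combined": c.combined,
        "rg": c.rg, "rank": i + 1,
    } for i, c in enumerate(ordered)]).to_csv(path, sep="\t", index=False)


def write_sasa_tsv(model_id: str, result: SasaResult, path: str) -> None:
    rows = [{
        "model_id": model_id, "chain": cid, "residue": num,
        "area": result.per_residue_total[(cid, num)],
        "side_chain_area": result.per_residue_side_chain.get((cid, num), 0.0),
        "relative_area": result.relative_side_chain.get((cid, num), 0.0),
    } for (cid, num) in sorted(result.per_residue_total)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rg_tsv(values: dict[str, float], path: str) -> None:
    pd.DataFrame([{"model_id": k, "rg_angstrom": v}
                  for k, v in values.items()]).to_csv(path, sep="\t", index=False)
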