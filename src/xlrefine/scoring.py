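"""Model validation and ranking against cross-link and footprinting evidence.

Cross-links are judged by Cα–Cα distance against linker-specific thresholds
(25 Å for BS²G, 30 Å for DSBU) with a 10 Å flexibility band for tolerated
links; footprinting sites by agreement between the accessibility class
predicted from relative side-chain SASA and the experimentally observed
class.  Both scores are means of per-item stepwise points, so each lies in
[0, 1]; models are ranked by their sum or by the Pareto front in the two
score axes.  Compaction is tracked through the radius of gyration and its
rank correlation with the combined score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantxl import classify_accessibility
from .restraints import CrossLink, Linker
from .sasa import SasaResult
from .structures import StructureModel, ca_distance, radius_of_gyration

__all__ = ["ScoringMatrix", "ScoreCard", "LysinePka", "categorize_crosslink",
           "score_crosslinks", "score_footprinting", "estimate_lysine_pka",
           "rank_models", "rg_score_correlation", "build_scorecard"]

ACCESSIBILITY_CLASSES = ("buried", "partial", "accessible")


@dataclass
class ScoringMatrix:
    """Stepwise rating: full points when the evidence is satisfied, half when
    within one step (flexibility band / adjacent class), none for clear
    outliers."""
    xl_thresholds: dict[Linker, float] = field(default_factory=lambda: {
        Linker.BS2G: 25.0, Linker.DSBU: 30.0})
    flexibility_band: float = 10.0
    xl_points: dict[str, float] = field(default_factory=lambda: {
        "satisfied": 1.0, "tolerated": 0.5, "violated": 0.0})
    footprint_points: dict[str, float] = field(default_factory=lambda: {
        "match": 1.0, "adjacent": 0.5, "opposite": 0.0})
    rel_sasa_class_bounds: tuple[float, float] = (0.2, 0.4)  # buried_max, partial_max

    def __post_init__(self):
        if any(t <= 0 for t in self.xl_thresholds.values()):
            raise ValueError("thresholds must be positive")
        p = self.xl_points
        if not p["satisfied"] >= p["tolerated"] >= p["violated"]:
            raise ValueError("points must be monotone satisfied>=tolerated>=violated")


@dataclass
class ScoreCard:
    model_id: str
    xl_score: float
    footprint_score: float
    rg: float
    per_link_distances: list[tuple[CrossLink, float, str]] = field(default_factory=list)
    per_site_classes: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def combined(self) -> float:
        return self.xl_score + self.footprint_score


@dataclass(frozen=True)
class LysinePka:
    residue: int
    pka: float
    source: str  # heuristic | external_table


def categorize_crosslink(distance: float, linker: Linker,
                         matrix: ScoringMatrix | None = None) -> str:
    """satisfied / tolerated / violated for a Cα–Cα distance and linker."""
    matrix = matrix or ScoringMatrix()
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    linker = Linker(linker)
    if linker not in matrix.xl_thresholds:
        raise ValueError(f"no threshold configured for linker {linker}")
    t = matrix.xl_thresholds[linker]
    if distance <= t:
        return "satisfied"
    if distance <= t + matrix.flexibility_band:
        return "tolerated"
    return "violated"


def _link_distance(model: StructureModel, xl: CrossLink,
                   chain_policy: str) -> float | None:
    dists = []
    for chain in model.chains:
        ra = chain.residue(xl.res_a)
        rb = chain.residue(xl.res_b)
        if ra is None or rb is None or ra.ca is None or rb.ca is None:
            continue
        dists.append(ca_distance(model, (chain.chain_id, xl.res_a),
                                 (chain.chain_id, xl.res_b)))
    if not dists:
        return None
    if chain_policy == "min_over_chains":
        return min(dists)
    if chain_policy == "per_chain_mean":
        return float(np.mean(dists))
    raise ValueError(f"unknown chain_policy {chain_policy!r}")


def score_crosslinks(model: StructureModel, xls: list[CrossLink],
                     matrix: ScoringMatrix | None = None,
                     chain_policy: str = "min_over_chains",
                     ) -> tuple[float, list[tuple[CrossLink, float, str]]]:
    """Mean stepwise points over all resolvable links.

    With identical chains an intramolecular link is counted satisfied if any
    protomer satisfies it (``min_over_chains``).
    """
    matrix = matrix or ScoringMatrix()
    detail: list[tuple[CrossLink, float, str]] = []
    points: list[float] = []
    for xl in xls:
        d = _link_distance(model, xl, chain_policy)
        if d is None:
            warnings.warn(f"link ({xl.res_a},{xl.res_b}) outside model; skipped")
            detail.append((xl, math.nan, "skipped"))
            continue
        cat = categorize_crosslink(d, xl.linker, matrix)
        detail.append((xl, d, cat))
        points.append(matrix.xl_points[cat])
    score = float(np.mean(points)) if points else math.nan
    return score, detail


def predicted_class(rel_sasa: float, matrix: ScoringMatrix | None = None) -> str:
    matrix = matrix or ScoringMatrix()
    buried_max, partial_max = matrix.rel_sasa_class_bounds
    if rel_sasa <= buried_max:
        return "buried"
    if rel_sasa <= partial_max:
        return "partial"
    return "accessible"


def score_footprinting(model: StructureModel, sites, sasa: SasaResult,
                       matrix: ScoringMatrix | None = None,
                       include_non_lysine: bool = False,
                       ) -> tuple[float, list[tuple[int, str, str]]]:
    """Agreement between SASA-predicted and observed accessibility classes.

    ``sites`` is a sequence of LabelingSite records (see quantxl); the
    observed class comes from each site's labeling yields, the predicted
    class from the model's relative side-chain SASA of that lysine.
    """
    matrix = matrix or ScoringMatrix()
    detail: list[tuple[int, str, str]] = []
    points: list[float] = []
    class_index = {c: i for i, c in enumerate(ACCESSIBILITY_CLASSES)}

    # relative side-chain SASA per residue number, min over chains means the
    # most buried copy; use the mean over chains as the model-level estimate
    by_residue: dict[int, list[float]] = {}
    for (cid, num), rel in sasa.relative_side_chain.items():
        by_residue.setdefault(num, []).append(rel)

    for site in sites:
        aa = None
        for chain in model.chains:
            r = chain.residue(site.residue)
            if r is not None:
                aa = r.amino_acid
                break
        if aa is None:
            warnings.warn(f"site {site.residue} not in model; skipped")
            continue
        if aa != "K" and not include_non_lysine:
            warnings.warn(f"site {site.residue} is {aa}, not lysine; skipped")
            continue
        rel = float(np.mean(by_residue[site.residue]))
        pred = predicted_class(rel, matrix)
        obs = site.accessibility_class or classify_accessibility(
            float(np.mean(list(site.yields.values()))))
        gap = abs(class_index[pred] - class_index[obs])
        cat = ("match", "adjacent", "opposite")[gap]
        detail.append((site.residue, pred, obs))
        points.append(matrix.footprint_points[cat])
    score = float(np.mean(points)) if points else math.nan
    return score, detail


def estimate_lysine_pka(model: StructureModel, residue: int, sasa: SasaResult,
                        external_table: dict[int, float] | None = None,
                        ) -> LysinePka:
    """Burial-shift heuristic for lysine side-chain pKa.

    Fully exposed lysine keeps its intrinsic pKa of 10.4; full burial lowers
    it by up to 2 units (pka = 10.4 − 2·(1 − rel SASA), clamped to
    [8.4, 10.4]).  An external per-residue table (e.g. from a dedicated pKa
    predictor) overrides the heuristic.
    """
    if external_table and residue in external_table:
        return LysinePka(residue, external_table[residue], "external_table")
    found = None
    for chain in model.chains:
        r = chain.residue(residue)
        if r is not None:
            found = r
            break
    if found is None:
        raise KeyError(f"residue {residue} not in model")
    if found.amino_acid != "K":
        raise TypeError(f"residue {residue} is {found.amino_acid}, not lysine")
    rels = [rel for (cid, num), rel in sasa.relative_side_chain.items()
            if num == residue]
    rel = float(np.clip(np.mean(rels), 0.0, 1.0))
    pka = 10.4 - 2.0 * (1.0 - rel)
    return LysinePka(residue, float(np.clip(pka, 8.4, 10.4)), "heuristic")


def rank_models(cards: list[ScoreCard], selection: str = "sum_rank",
                ) -> tuple[list[ScoreCard], list[ScoreCard]]:
    """Order models by combined score; return (ordered list, selected set).

    ``sum_rank`` sorts by xl_score + footprint_score (ties: higher xl_score,
    then model_id); ``pareto_top`` selects the non-dominated front in the
    (xl_score, footprint_score) plane.
    """
    if not cards:
        raise ValueError("need at least one score card")
    ordered = sorted(
        cards, key=lambda c: (-c.combined, -c.xl_score, c.model_id))
    if selection == "sum_rank":
        return ordered, [ordered[0]]
    if selection == "pareto_top":
        front = []
        for c in cards:
            dominated = any(
                (o.xl_score >= c.xl_score and o.footprint_score >= c.footprint_score
                 and (o.xl_score > c.xl_score or o.footprint_score > c.footprint_score))
                for o in cards)
            if not dominated:
                front.append(c)
        return ordered, front
    raise ValueError(f"unknown selection {selection!r}")


def rg_score_correlation(cards: list[ScoreCard]) -> float:
    """Spearman rank correlation between combined score and Rg.

    A negative value is the compaction signature: more compact models
    (smaller Rg) score better.  Constant inputs give NaN.
    """
    finite = [c for c in cards if np.isfinite(c.rg) and np.isfinite(c.combined)]
    if len(finite) < 3:
        raise ValueError("need at least three models with finite Rg and score")
    rg = [c.rg for c in finite]
    sc = [c.combined for c in finite]
    if len(set(rg)) == 1 or len(set(sc)) == 1:
        warnings.warn("constant input; correlation undefined")
        return math.nan
    rho, _ = stats.spearmanr(sc, rg)
    return float(rho)


def build_scorecard(model: StructureModel, xls: list[CrossLink], sites,
                    sasa: SasaResult, matrix: ScoringMatrix | None = None,
                    rg_mode: str = "ca_only") -> ScoreCard:
    """Convenience: score one model against all evidence in one call."""
    matrix = matrix or ScoringMatrix()
    xl_score, link_detail = score_crosslinks(model, xls, matrix)
    fp_score, site_detail = score_footprinting(model, sites, sasa, matrix)
    return ScoreCard(
        model_id=model.model_id,
        xl_score=xl_score,
        footprint_score=fp_score,
        rg=radius_of_gyration(model, mode=rg_mode),
        per_link_distances=link_detail,
        per_site_classes=site_detail,
    )
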