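import math

import numpy as np
import pytest

import xlrefine as xr
from xlrefine.quantxl import LabelingSite
from xlrefine.restraints import CrossLink, Linker
from xlrefine.scoring import (ScoreCard, ScoringMatrix, categorize_crosslink,
                              estimate_lysine_pka, predicted_class,
                              rank_models, rg_score_correlation,
                              score_crosslinks, score_footprinting)
from xlrefine.structures import Atom, Chain, Residue, StructureModel


def ruler(distances, chain_id="A"):
    """Chain with residue 1 at origin and residue k+1 at distances[k] on x."""
    res = [Residue(1, "K", [Atom("CA", "C", (0.0, 0.0, 0.0))])]
    for i, d in enumerate(distances):
        res.append(Residue(i + 2, "K", [Atom("CA", "C", (d, 0.0, 0.0))]))
    return StructureModel("ruler", [Chain(chain_id, res)])


class TestCategorize:
    @pytest.mark.parametrize("d,linker,expected", [
        (10.0, Linker.BS2G, "satisfied"),
        (25.0, Linker.BS2G, "satisfied"),
        (28.0, Linker.BS2G, "tolerated"),
        (35.0, Linker.BS2G, "tolerated"),
        (35.1, Linker.BS2G, "violated"),
        (30.0, Linker.DSBU, "satisfied"),
        (39.0, Linker.DSBU, "tolerated"),
        (40.1, Linker.DSBU, "violated"),
    ])
    def test_distance_bands(self, d, linker, expected):
        assert categorize_crosslink(d, linker) == expected

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            categorize_crosslink(-1.0, Linker.BS2G)

    def test_unknown_linker_raises(self):
        m = ScoringMatrix(xl_thresholds={Linker.BS2G: 25.0})
        with pytest.raises(ValueError):
            categorize_crosslink(10.0, Linker.DSBU, m)


class TestScoreCrosslinks:
    def test_all_satisfied_and_all_violated_bounds(self):
        m = ruler([10.0, 20.0])
        sat = [CrossLink("p", 1, 2, Linker.BS2G),
               CrossLink("p", 1, 3, Linker.BS2G)]
        assert score_crosslinks(m, sat)[0] == 1.0
        m2 = ruler([50.0, 60.0])
        assert score_crosslinks(m2, sat)[0] == 0.0

    def test_mixed_two_satisfied_two_tolerated(self):
        m = ruler([10.0, 20.0, 28.0, 30.0])
        links = [CrossLink("p", 1, k, Linker.BS2G) for k in (2, 3, 4, 5)]
        score, detail = score_crosslinks(m, links)
        assert score == pytest.approx(0.75)
        cats = [c for _, _, c in detail]
        assert cats == ["satisfied", "satisfied", "tolerated", "tolerated"]

    def test_min_over_chains_policy(self):
        # chain A violates, chain B satisfies -> satisfied under min policy
        chains = [
            Chain("A", [Residue(1, "K", [Atom("CA", "C", (0.0, 0.0, 0.0))]),
                        Residue(2, "K", [Atom("CA", "C", (50.0, 0.0, 0.0))])]),
            Chain("B", [Residue(1, "K", [Atom("CA", "C", (0.0, 30.0, 0.0))]),
                        Residue(2, "K", [Atom("CA", "C", (10.0, 30.0, 0.0))])]),
        ]
        m = StructureModel("two", chains)
        links = [CrossLink("p", 1, 2, Linker.BS2G)]
        assert score_crosslinks(m, links, chain_policy="min_over_chains")[0] == 1.0
        mean_score, _ = score_crosslinks(m, links, chain_policy="per_chain_mean")
        assert mean_score == 0.5  # mean distance 30 Å falls in the 25–35 band

    def test_out_of_region_link_skipped_with_warning(self):
        m = ruler([10.0])
        links = [CrossLink("p", 1, 2, Linker.BS2G),
                 CrossLink("p", 1, 99, Linker.BS2G)]
        with pytest.warns(UserWarning, match="outside model"):
            score, detail = score_crosslinks(m, links)
        assert score == 1.0
        assert detail[1][2] == "skipped"

    def test_monotone_in_distance(self):
        """Shrinking any link distance never lowers the score."""
        links = [CrossLink("p", 1, 2, Linker.BS2G)]
        scores = [score_crosslinks(ruler([d]), links)[0]
                  for d in (50.0, 30.0, 10.0)]
        assert scores == sorted(scores)

    def test_rigid_transform_invariance(self, compact_model, evidence):
        bs2g, dsbu = evidence
        s0, _ = score_crosslinks(compact_model, bs2g + dsbu)
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=100.0, size=3)
        chains = []
        for c in compact_model.chains:
            res = [Residue(r.residue_number, r.amino_acid,
                           [Atom("CA", "C",
                                 tuple(np.asarray(r.ca.xyz) @ q.T + t))])
                   for r in c.residues]
            chains.append(Chain(c.chain_id, res))
        s1, _ = score_crosslinks(StructureModel("m", chains), bs2g + dsbu)
        assert s1 == pytest.approx(s0, abs=1e-9)


class TestFootprinting:
    def site(self, residue, yield_pct):
        return LabelingSite(residue=residue,
                            yields={("minusDNA", "rep1"): yield_pct})

    def model_with_rel(self):
        return None

    @pytest.mark.parametrize("obs_yield,rel,points", [
        (15.0, 0.6, 1.0),   # observed accessible, predicted accessible
        (3.0, 0.3, 0.5),    # observed buried, predicted partial: adjacent
        (3.0, 0.8, 0.0),    # observed buried, predicted accessible: opposite
    ])
    def test_class_agreement_points(self, obs_yield, rel, points,
                                    monkeypatch):
        # single lysine with a pseudo side chain whose rel SASA we control
        from xlrefine.sasa import SasaResult
        m = ruler([])
        sr = SasaResult(per_atom={}, per_residue_total={("A", 1): 100.0},
                        per_residue_side_chain={("A", 1): 50.0},
                        relative_side_chain={("A", 1): rel})
        score, detail = score_footprinting(m, [self.site(1, obs_yield)], sr)
        assert score == pytest.approx(points)

    def test_predicted_class_bounds(self):
        assert predicted_class(0.1) == "buried"
        assert predicted_class(0.2) == "buried"
        assert predicted_class(0.3) == "partial"
        assert predicted_class(0.4) == "partial"
        assert predicted_class(0.5) == "accessible"

    def test_non_lysine_site_warns(self):
        from xlrefine.sasa import SasaResult
        res = [Residue(1, "A", [Atom("CA", "C", (0.0, 0.0, 0.0))])]
        m = StructureModel("m", [Chain("A", res)])
        sr = SasaResult(per_atom={}, per_residue_total={("A", 1): 10.0},
                        relative_side_chain={("A", 1): 0.5})
        with pytest.warns(UserWarning, match="not lysine"):
            score, detail = score_footprinting(m, [self.site(1, 15.0)], sr)
        assert math.isnan(score) and detail == []


class TestPka:
    def make(self, rel):
        from xlrefine.sasa import SasaResult
        m = ruler([])
        sr = SasaResult(per_atom={}, per_residue_total={("A", 1): 1.0},
                        relative_side_chain={("A", 1): rel})
        return m, sr

    def test_exposed_keeps_intrinsic(self):
        m, sr = self.make(1.0)
        assert estimate_lysine_pka(m, 1, sr).pka == pytest.approx(10.4)

    def test_buried_maximal_shift(self):
        m, sr = self.make(0.0)
        assert estimate_lysine_pka(m, 1, sr).pka == pytest.approx(8.4)

    def test_monotone_nonincreasing_in_burial(self):
        pkas = []
        for rel in (1.0, 0.7, 0.4, 0.1, 0.0):
            m, sr = self.make(rel)
            pkas.append(estimate_lysine_pka(m, 1, sr).pka)
        assert all(b <= a for a, b in zip(pkas, pkas[1:]))

    def test_external_table_passthrough(self):
        m, sr = self.make(0.5)
        out = estimate_lysine_pka(m, 1, sr, external_table={1: 11.3})
        assert out.pka == 11.3 and out.source == "external_table"

    def test_non_lysine_raises(self):
        from xlrefine.sasa import SasaResult
        res = [Residue(1, "A", [Atom("CA", "C", (0.0, 0.0, 0.0))])]
        m = StructureModel("m", [Chain("A", res)])
        sr = SasaResult(per_atom={}, per_residue_total={("A", 1): 1.0},
                        relative_side_chain={("A", 1): 0.5})
        with pytest.raises(TypeError):
            estimate_lysine_pka(m, 1, sr)


def card(mid, xl, fp, rg=20.0):
    return ScoreCard(model_id=mid, xl_score=xl, footprint_score=fp, rg=rg)


class TestRanking:
    def test_single_card_selected(self):
        c = card("only", 0.5, 0.5)
        ordered, selected = rank_models([c])
        assert ordered == [c] and selected == [c]

    def test_dominating_card_is_first_under_both_modes(self):
        cards = [card("a", 0.9, 0.9), card("b", 0.5, 0.8), card("c", 0.8, 0.4)]
        for mode in ("sum_rank", "pareto_top"):
            ordered, selected = rank_models(cards, selection=mode)
            assert ordered[0].model_id == "a"
            assert cards[0] in selected

    def test_pareto_front_excludes_dominated(self):
        cards = [card("a", 0.9, 0.2), card("b", 0.2, 0.9), card("c", 0.3, 0.1)]
        _, front = rank_models(cards, selection="pareto_top")
        assert {c.model_id for c in front} == {"a", "b"}

    def test_tie_break_stable(self):
        cards = [card("m1", 0.5, 0.5), card("m2", 0.5, 0.5)]
        ordered, _ = rank_models(cards)
        assert [c.model_id for c in ordered] == ["m1", "m2"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestRgScoreCorrelation:
    def test_perfectly_anti_monotone(self):
        cards = [card(f"m{i}", 0.1 * i, 0.1 * i, rg=50.0 - i) for i in range(5)]
        assert rg_score_correlation(cards) == pytest.approx(-1.0)

    def test_perfectly_monotone(self):
        cards = [card(f"m{i}", 0.1 * i, 0.1 * i, rg=20.0 + i) for i in range(5)]
        assert rg_score_correlation(cards) == pytest.approx(1.0)

    def test_constant_input_flagged_nan(self):
        cards = [card(f"m{i}", 0.5, 0.5, rg=20.0 + i) for i in range(4)]
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(rg_score_correlation(cards))

    def test_too_few_models_raises(self):
        with pytest.raises(ValueError):
            rg_score_correlation([card("a", 1, 1), card("b", 0, 0)])
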