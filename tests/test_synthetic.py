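import math
import warnings

import numpy as np
import pytest

import xlrefine as xr
from xlrefine.quantxl import aggregate_differential, classify_accessibility, pair_ratio
from xlrefine.restraints import Linker
from xlrefine.sasa import PSEUDO_SIDE_CHAIN_ATOM
from xlrefine.scoring import predicted_class


def quiet_tetramer(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xr.make_toy_tetramer(xr.SyntheticSpec(**kw))


class TestToyTetramer:
    def test_default_construction(self, compact_model):
        assert len(compact_model.chains) == 4
        assert all(len(c.residues) == 93 for c in compact_model.chains)
        for c in compact_model.chains:
            d = np.linalg.norm(np.diff(c.ca_coords(), axis=0), axis=1)
            assert np.all(np.abs(d - 3.8) < 0.01)

    def test_compact_more_compact_than_extended(self):
        for seed in (0, 5, 9):
            rgc = xr.radius_of_gyration(quiet_tetramer(seed=seed))
            rge = xr.radius_of_gyration(
                quiet_tetramer(tail_mode="extended", seed=seed))
            assert rgc < rge

    def test_deterministic_per_seed(self):
        a = quiet_tetramer(seed=4)
        b = quiet_tetramer(seed=4)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.ca_coords(), cb.ca_coords())

    def test_core_is_rigid_across_seeds(self):
        a, b = quiet_tetramer(seed=1), quiet_tetramer(seed=2)
        ta = xr.truncate_region(a, 326, 356)
        tb = xr.truncate_region(b, 326, 356)
        for ca, cb in zip(ta.chains, tb.chains):
            np.testing.assert_allclose(ca.ca_coords(), cb.ca_coords(),
                                       atol=1e-9)

    def test_lysines_in_tails(self, compact_model):
        aas = {r.residue_number: r.amino_acid
               for r in compact_model.chains[0].residues}
        lys = [n for n, a in aas.items() if a == "K"]
        assert len(lys) >= 10
        assert all(n < 326 or n > 356 for n in lys)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            xr.SyntheticSpec(core=(200, 400))
        with pytest.raises(ValueError):
            xr.SyntheticSpec(tail_mode="floppy")


class TestPseudoSideChains:
    def test_added_at_fixed_offset(self, compact_model):
        m = xr.add_pseudo_side_chains(compact_model)
        for c in m.chains:
            for r in c.residues:
                psc = r.atom(PSEUDO_SIDE_CHAIN_ATOM)
                assert psc is not None
                d = np.linalg.norm(np.asarray(psc.xyz) - np.asarray(r.ca.xyz))
                assert d == pytest.approx(2.5, abs=1e-9)

    def test_idempotent(self, compact_model):
        once = xr.add_pseudo_side_chains(compact_model)
        twice = xr.add_pseudo_side_chains(once)
        assert all(len(r.atoms) == 2 for c in twice.chains for r in c.residues)


class TestSimulatedCrosslinks:
    def test_zero_links(self, compact_model):
        assert xr.simulate_crosslinks(compact_model, Linker.BS2G, 0) == []

    def test_links_satisfied_by_construction(self, compact_model, evidence):
        bs2g, dsbu = evidence
        assert len(bs2g) == 12 and len(dsbu) == 21
        score, detail = xr.score_crosslinks(compact_model, bs2g + dsbu)
        assert score == 1.0
        assert all(cat == "satisfied" for _, _, cat in detail)

    def test_links_are_lysine_pairs(self, compact_model, evidence):
        aas = {r.residue_number: r.amino_acid
               for r in compact_model.chains[0].residues}
        for xl in evidence[0] + evidence[1]:
            assert aas[xl.res_a] == "K" and aas[xl.res_b] == "K"

    def test_compact_links_score_lower_on_extended_decoys(self, compact_model,
                                                          evidence):
        """Links drawn from a compact conformer discriminate against
        extended decoys (averaged over decoy seeds)."""
        links = evidence[0] + evidence[1]
        src, _ = xr.score_crosslinks(compact_model, links)
        decoy_scores = []
        for seed in range(20):
            decoy = quiet_tetramer(tail_mode="extended", seed=100 + seed)
            s, _ = xr.score_crosslinks(decoy, links)
            decoy_scores.append(s)
        assert float(np.mean(decoy_scores)) < src

    def test_deterministic(self, compact_model):
        a = xr.simulate_crosslinks(compact_model, Linker.BS2G, 12, seed=8)
        b = xr.simulate_crosslinks(compact_model, Linker.BS2G, 12, seed=8)
        assert a == b


class TestSimulatedFootprinting:
    def test_yields_track_accessibility_without_noise(self, compact_model,
                                                      compact_sasa):
        sites = xr.simulate_footprinting(compact_model, compact_sasa,
                                         noise_cv=0.0, seed=0)
        by_residue = {}
        for (cid, num), rel in compact_sasa.relative_side_chain.items():
            by_residue.setdefault(num, []).append(rel)
        for s in sites:
            rel = float(np.mean(by_residue[s.residue]))
            expected = 2.0 + 28.0 * min(rel, 1.0)
            for v in s.yields.values():
                assert v == pytest.approx(expected)

    def test_yield_range_matches_footprinting_scale(self, footprint_sites):
        vals = [v for s in footprint_sites for v in s.yields.values()]
        assert min(vals) >= 0.0 and max(vals) <= 60.0
        assert min(vals) < 10.0  # buried lysines exist in the compact model

    def test_noisy_classification_mostly_consistent(self, compact_model,
                                                    compact_sasa):
        clean = xr.simulate_footprinting(compact_model, compact_sasa,
                                         noise_cv=0.0, seed=0)
        noisy = xr.simulate_footprinting(compact_model, compact_sasa,
                                         noise_cv=0.2, seed=1)
        truth = {s.residue: classify_accessibility(
            float(np.mean(list(s.yields.values())))) for s in clean}
        agree = sum(
            1 for s in noisy
            if classify_accessibility(float(np.mean(list(s.yields.values()))))
            == truth[s.residue])
        assert agree / len(noisy) >= 0.8


class TestSimulatedQuant:
    def test_no_noise_recovers_unity(self):
        recs = xr.simulate_quant(true_ratio=1.0, noise_cv=0.0, seed=0)
        assert all(pair_ratio(r) == pytest.approx(1.0) for r in recs)

    def test_reversed_records_give_same_ratio(self):
        recs = xr.simulate_quant(true_ratio=3.0, noise_cv=0.0, seed=0)
        orientations = {r.label_orientation for r in recs}
        assert orientations == {"forward", "reversed"}
        assert all(pair_ratio(r) == pytest.approx(3.0) for r in recs)

    def test_fourfold_ratio_recovered(self):
        """log2FC of simulated 4x links stays near 2 across seeds."""
        fcs = []
        for seed in range(50):
            recs = xr.simulate_quant(true_ratio=4.0, noise_cv=0.1, seed=seed,
                                     link_id="L")
            res = aggregate_differential(recs)
            fcs.append(res["L"].log2_fold_change)
        assert float(np.mean(fcs)) == pytest.approx(2.0, abs=0.2)
        assert all(abs(fc - 2.0) < 0.5 for fc in fcs)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            xr.simulate_quant(true_ratio=0.0)


class TestSimulatedHdx:
    def test_core_peptides_exchange_less_than_tails(self, compact_model,
                                                    compact_sasa):
        peps = xr.simulate_hdx(compact_model, compact_sasa, peptide_length=8,
                               noise_da=0.0)
        core, tail = [], []
        for p in peps:
            frac = xr.back_exchange_correct(p, 60)
            if p.start >= 330 and p.end <= 356:
                core.append(frac)
            elif p.end < 326 or p.start > 356:
                tail.append(frac)
        assert core and tail
        assert max(core) < min(tail)

    def test_zero_noise_round_trip(self, compact_model, compact_sasa):
        peps = xr.simulate_hdx(compact_model, compact_sasa, noise_da=0.0)
        prof = xr.residue_level_sasa_profile(compact_model, peps, compact_sasa)
        from xlrefine.synthetic import HDX_SATURATION
        for p in peps:
            rel = prof[(p.start, p.end)]
            for t, sat in HDX_SATURATION.items():
                assert xr.back_exchange_correct(p, t) == pytest.approx(
                    min(rel, 1.0) * sat, abs=1e-6)
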