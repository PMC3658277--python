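"""Orthology projection, conservation statistics, rewiring classification."""

import itertools

import numpy as np
import pytest

from sh3map.conservation import (OrthologMap, best_motif_match,
                                 classify_rewiring, conservation_test,
                                 project_by_orthology, ungapped_identity,
                                 universe_size)
from sh3map.network import Edge, SH3Network
from sh3map.pwm import build_pwm
from sh3map.simulate import random_protein


class TestUniverseSize:
    def test_worked_example_with_bait_prey_overlap(self):
        assert universe_size(10, 90, 2) == 899

    def test_no_correction_without_dual_role_proteins(self):
        assert universe_size(3, 5, 0) == 15

    def test_formula_value_for_single_dual_role_protein(self):
        # n_bp = 1 contributes no correction: 4 * 23 - 0
        assert universe_size(4, 23, 1) == 92

    def test_negative_input_is_an_error(self):
        with pytest.raises(ValueError):
            universe_size(-1, 5, 0)
        with pytest.raises(ValueError):
            universe_size(2, 5, 3)


class TestConservationTest:
    def _edges(self, pairs):
        return {frozenset(p) for p in pairs}

    def test_zero_overlap_gives_p_one(self):
        proj = self._edges([("a", "b"), ("c", "d")])
        ref = self._edges([("e", "f")])
        res = conservation_test(proj, ref, universe=100)
        assert res.p_value == pytest.approx(1.0)

    def test_worm_yeast_scale_overlap_is_chance_level(self):
        from scipy.stats import hypergeom

        p = float(hypergeom.sf(2 - 1, 899, 61, 37))
        assert p > 0.5

    def test_small_case_matches_enumeration(self):
        # 3 draws from 10, all 3 reference pairs drawn: p = 1 / C(10, 3)
        universe_pairs = [frozenset((f"x{i}", f"y{i}")) for i in range(10)]
        ref = set(universe_pairs[:3])
        proj = set(universe_pairs[:3])
        res = conservation_test(proj, ref, universe=10)
        n_total = len(list(itertools.combinations(range(10), 3)))
        assert res.p_value == pytest.approx(1 / n_total)

    def test_matches_permutation_estimate_on_small_universes(self, rng):
        """Hypergeometric tail equals a draw-resampling estimate."""
        for universe_n, n_ref, n_draw in [(20, 6, 5), (50, 10, 8), (30, 4, 9)]:
            pairs = [frozenset((f"a{i}", f"b{i}")) for i in range(universe_n)]
            ref = set(pairs[:n_ref])
            proj = set(rng.choice(len(pairs), size=n_draw, replace=False)
                       .tolist())
            proj = {pairs[i] for i in proj}
            res = conservation_test(proj, ref, universe=universe_n)
            n_mc = 20_000
            hits = 0
            for _ in range(n_mc):
                draw = rng.choice(universe_n, size=n_draw, replace=False)
                overlap = sum(1 for i in draw if pairs[i] in ref)
                if overlap >= res.n_overlap:
                    hits += 1
            mc_p = hits / n_mc
            se = np.sqrt(res.p_value * (1 - res.p_value) / n_mc)
            assert abs(mc_p - res.p_value) < max(4 * se, 0.01)

    def test_universe_smaller_than_counts_is_an_error(self):
        proj = self._edges([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            conservation_test(proj, set(), universe=1)


class TestProjectByOrthology:
    def _net(self, edges):
        return SH3Network([Edge(b, p, "multi_colony", 2) for b, p in edges])

    def test_edge_without_prey_ortholog_not_projected(self):
        omap = OrthologMap({("d1", "y1")})
        proj, *_ = project_by_orthology(self._net([("d1", "p1")]), omap)
        assert proj == set()

    def test_many_to_many_expansion(self):
        omap = OrthologMap({("d1", "y1"), ("d1", "y2"), ("p1", "z1")})
        proj, baits, preys, n_bp = project_by_orthology(
            self._net([("d1", "p1")]), omap)
        assert proj == {frozenset(("y1", "z1")), frozenset(("y2", "z1"))}
        assert baits == {"y1", "y2"} and preys == {"z1"} and n_bp == 0

    def test_projected_fraction_tracks_squared_coverage(self, rng):
        coverage = 0.5
        edges = [(f"d{i}", f"p{i}") for i in range(400)]
        pairs = set()
        for name in {x for e in edges for x in e}:
            if rng.random() < coverage:
                pairs.add((name, f"y_{name}"))
        proj, *_ = project_by_orthology(self._net(edges), OrthologMap(pairs))
        assert len(proj) / len(edges) == pytest.approx(coverage ** 2, abs=0.06)


class TestMotifMatch:
    def test_verbatim_motif_scores_full_identity(self):
        ident, start = best_motif_match("PPLP", "AAAPPLPAAA")
        assert ident == 1.0 and start == 4

    def test_disjoint_alphabets_score_zero(self):
        ident, _ = best_motif_match("PPPPP", "AAAAA")
        assert ident == 0.0

    def test_constructed_half_identity_boundary(self):
        motif = "PPPPPAAAAA"
        subject = "CCCCPPPPPGGGGGCCC"  # 5 of 10 match at the best offset
        ident, _ = best_motif_match(motif, subject)
        assert ident == pytest.approx(0.5)

    def test_overhang_when_subject_shorter_than_motif(self):
        # subject "AB" can only align under an end of the motif
        ident, _ = ungapped_identity("PPLPK", "PP")
        assert ident == pytest.approx(2 / 5)


class TestClassifyRewiring:
    def _sharp(self, peptide):
        from sh3map.pwm import AlignedPeptideSet

        return build_pwm(AlignedPeptideSet("d", tuple([peptide] * 30)))

    def test_conserved_motif_lost_specificity_is_scenario_i(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        other = self._sharp("KAKAKRKAKA")
        target = random_protein(60, rng) + "PPLPPKPPLP" + random_protein(60, rng)
        call = classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=other,
            target_seq=target,
            ortholog_target_seqs=[target],  # ligand fully conserved
            T=1000)
        assert call.scenario == "i"
        assert call.motif_conserved and not call.specificity_conserved

    def test_conserved_specificity_lost_motif_is_scenario_ii(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        target = random_protein(60, rng) + "PPLPPKPPLP" + random_protein(60, rng)
        ortholog = random_protein(140, rng).replace("P", "A")
        call = classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=pwm,
            target_seq=target, ortholog_target_seqs=[ortholog], T=1000)
        assert call.scenario == "ii"

    def test_neither_conserved_is_scenario_iii(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        other = self._sharp("KAKAKRKAKA")
        target = random_protein(60, rng) + "PPLPPKPPLP" + random_protein(60, rng)
        ortholog = random_protein(140, rng).replace("P", "A")
        call = classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=other,
            target_seq=target, ortholog_target_seqs=[ortholog], T=1000)
        assert call.scenario == "iii"

    def test_missing_profile_or_motif_is_unmappable(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        bg = random_protein(100, rng).replace("P", "A")
        assert classify_rewiring(
            "d", "t", domain_pwm=None, ortholog_domain_pwm=None,
            target_seq=bg, ortholog_target_seqs=[bg]).scenario == "unmappable"
        assert classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=pwm,
            target_seq=bg, ortholog_target_seqs=[bg]).scenario == "unmappable"

    def test_missing_sh3_in_ortholog_blocks_specificity(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        target = random_protein(60, rng) + "PPLPPKPPLP" + random_protein(60, rng)
        call = classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=pwm,
            ortholog_has_sh3=False,
            target_seq=target, ortholog_target_seqs=[target], T=1000)
        assert call.scenario == "i"  # motif conserved, specificity cannot be

    def test_sequence_identity_fallback(self, rng):
        pwm = self._sharp("PPLPPKPPLP")
        dom_seq = random_protein(60, rng)
        target = random_protein(60, rng) + "PPLPPKPPLP" + random_protein(60, rng)
        call = classify_rewiring(
            "d", "t", domain_pwm=pwm, ortholog_domain_pwm=None,
            domain_seq=dom_seq, ortholog_domain_seq=dom_seq,
            target_seq=target, ortholog_target_seqs=[target], T=1000)
        assert call.specificity_conserved
        assert call.scenario == "conserved_both"

    def test_scenario_recovery_on_synthetic_world(self, world, rebuilt_pwms):
        """>= 90% of planted rewiring scenarios are recovered at defaults."""
        correct = 0
        for truth in world.rewiring_truth:
            prey_orths = sorted(world.ortholog_map.orthologs_of(truth.target_id))
            call = classify_rewiring(
                truth.domain_id, truth.target_id,
                domain_pwm=rebuilt_pwms.get(truth.domain_id),
                ortholog_domain_pwm=truth.ortholog_domain_pwm,
                ortholog_domain_seq=truth.ortholog_domain_seq,
                ortholog_has_sh3=truth.ortholog_has_sh3,
                target_seq=world.proteome[truth.target_id],
                ortholog_target_seqs=[world.proteome_b[o] for o in prey_orths],
                T=world.config.T)
            if call.scenario == truth.scenario:
                correct += 1
        assert correct / len(world.rewiring_truth) >= 0.90

    def test_scenario_counts_invariant_to_input_order(self, world, rebuilt_pwms):
        def run(rows):
            counts = {}
            for truth in rows:
                prey_orths = sorted(
                    world.ortholog_map.orthologs_of(truth.target_id))
                call = classify_rewiring(
                    truth.domain_id, truth.target_id,
                    domain_pwm=rebuilt_pwms.get(truth.domain_id),
                    ortholog_domain_pwm=truth.ortholog_domain_pwm,
                    ortholog_domain_seq=truth.ortholog_domain_seq,
                    ortholog_has_sh3=truth.ortholog_has_sh3,
                    target_seq=world.proteome[truth.target_id],
                    ortholog_target_seqs=[world.proteome_b[o]
                                          for o in prey_orths],
                    T=world.config.T)
                counts[call.scenario] = counts.get(call.scenario, 0) + 1
            return counts

        rows = world.rewiring_truth[:20]
        assert run(rows) == run(rows[::-1])
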