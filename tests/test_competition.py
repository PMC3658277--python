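"""Motif-site clustering and competition correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sh3map.competition import (build_cluster_table, cluster_motif_sites,
                                competitive_pairs, spearman_association)
from sh3map.network import Edge, SH3Network
from sh3map.pwm import AlignedPeptideSet, MotifHit, build_pwm
from sh3map.simulate import random_protein


def hit(start, score=2000.0, length=4, protein="p"):
    return MotifHit(protein_id=protein, start=start, length=length,
                    peptide="PPPP", score=score)


class TestClusterMotifSites:
    def test_close_sites_collapse(self):
        assert len(cluster_motif_sites([hit(5), hit(12)], min_sep=10)) == 1

    def test_separated_sites_are_kept(self):
        sites = cluster_motif_sites([hit(5), hit(20)], min_sep=10)
        assert [s.start for s in sites] == [5, 20]

    def test_two_distinct_regions_give_two_sites(self):
        # one proline-rich region early, one far downstream
        hits = [hit(5), hit(8, score=5000.0), hit(174), hit(179)]
        sites = cluster_motif_sites(hits, min_sep=10)
        assert len(sites) == 2
        assert sites[0].start == 8  # highest-scoring member represents

    def test_chain_measured_from_cluster_anchor(self):
        # 5, 12, 19: 12 joins 5's cluster; 19 is >= 10 from the anchor 5
        sites = cluster_motif_sites([hit(5), hit(12), hit(19)], min_sep=10)
        assert [s.start for s in sites] != []
        assert len(sites) == 2

    def test_shift_covariance(self, rng):
        starts = sorted(int(s) for s in rng.integers(1, 300, size=25))
        hits = [hit(s, score=float(rng.random())) for s in starts]
        shifted = [hit(s + 57, score=h.score) for s, h in zip(starts, hits)]
        assert len(cluster_motif_sites(hits)) == len(
            cluster_motif_sites(shifted))

    def test_empty_input(self):
        assert cluster_motif_sites([]) == []


def _sharp_pwm(peptide):
    return build_pwm(AlignedPeptideSet("d", tuple([peptide] * 30)))


class TestClusterTable:
    def _setup(self, rng, shared_site: bool):
        motif_a, motif_b = "PPLPPKPPLP", "KPLPPRPALP"
        pwms = {"dA": _sharp_pwm(motif_a), "dB": _sharp_pwm(motif_b)}
        bg = random_protein(200, rng).replace("P", "A")
        if shared_site:
            # both domains recognise the same stretch
            pwms["dB"] = pwms["dA"]
            seq = bg[:50] + motif_a + bg[50:]
        else:
            seq = bg[:50] + motif_a + bg[50:120] + motif_b + bg[120:]
        net = SH3Network([Edge("dA", "prey", "multi_colony", 2),
                          Edge("dB", "prey", "multi_colony", 2)])
        return net, pwms, {"prey": seq}

    def test_two_domains_two_disjoint_sites(self, rng):
        net, pwms, proteome = self._setup(rng, shared_site=False)
        table = build_cluster_table(net, pwms, proteome, T=1000)
        row = table.targets.iloc[0]
        assert row["n_motifs"] == 2
        assert row["n_sh3_partners"] == 2
        pairs = competitive_pairs(net, pwms, proteome, T=1000)
        assert list(pairs["relationship"]) == ["coincident"]

    def test_two_domains_one_shared_site_is_competitive(self, rng):
        net, pwms, proteome = self._setup(rng, shared_site=True)
        table = build_cluster_table(net, pwms, proteome, T=1000)
        row = table.targets.iloc[0]
        assert row["n_motifs"] == 1
        assert row["n_sh3_partners"] == 2
        pairs = competitive_pairs(net, pwms, proteome, T=1000)
        assert list(pairs["relationship"]) == ["competitive"]

    def test_generator_bookkeeping_reproduced(self, world, rebuilt_pwms):
        """Each mapped prey shows as many clustered motifs as distinct
        planted sites for its interacting domains."""
        from sh3map.network import filter_candidates

        result = filter_candidates(world.candidates, world.evidence,
                                   T=world.config.T)
        table = build_cluster_table(
            result.network, rebuilt_pwms, world.proteome,
            domain_to_protein=world.domain_protein, T=world.config.T)
        planted = {}
        net_pairs = {(e.bait_id, e.prey_id) for e in result.network}
        for prot, dom, start in world.planted_motifs:
            if (dom, prot) in net_pairs and dom in rebuilt_pwms:
                planted.setdefault(prot, set()).add(start)
        checked = 0
        for row in table.targets.itertuples():
            if row.prey_id in planted:
                # planted sites are >= 10 residues apart by construction of
                # non-overlapping placement, so counts should match closely
                assert abs(row.n_motifs - len(planted[row.prey_id])) <= 1
                checked += 1
        assert checked >= 10

    def test_bait_side_counts_domains_and_degree(self, rng):
        net = SH3Network([
            Edge("d1", "p1", "multi_colony", 2),
            Edge("d1", "p2", "multi_colony", 2),
            Edge("d2", "p1", "multi_colony", 2),
        ])
        motif = "PPLPPKPPLP"
        pwms = {"d1": _sharp_pwm(motif), "d2": _sharp_pwm(motif)}
        bg = random_protein(100, rng).replace("P", "A")
        proteome = {"p1": bg[:40] + motif + bg[40:],
                    "p2": bg[:70] + motif + bg[70:]}
        table = build_cluster_table(
            net, pwms, proteome,
            domain_to_protein={"d1": "SP1", "d2": "SP1"}, T=1000)
        assert list(table.baits["n_sh3_domains"]) == [2]
        assert list(table.baits["degree"]) == [2]


class TestSpearmanAssociation:
    def test_perfect_monotone(self):
        rho, rho2, p = spearman_association([1, 2, 3, 5, 8, 9, 12, 15, 20, 22],
                                            [2, 4, 5, 9, 11, 12, 15, 16, 21, 30])
        assert rho == pytest.approx(1.0)
        assert rho2 == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        rho, _, _ = spearman_association([1, 2, 3, 4], [9, 7, 5, 1])
        assert rho == pytest.approx(-1.0)

    def test_small_n_p_matches_independent_enumeration(self):
        x = [3, 1, 4, 1, 5, 9]
        y = [2, 7, 1, 8, 2, 8]
        rho, _, p = spearman_association(x, y)
        # independent oracle: enumerate all 720 orderings with scipy's rho
        rx = stats.rankdata(x)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = 0
        for perm in itertools.permutations(y):
            r = abs(np.corrcoef(rx, stats.rankdata(perm))[0, 1])
            if r >= obs - 1e-12:
                count += 1
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert p == pytest.approx(count / 720)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, _, p = spearman_association(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            spearman_association([1, 1, 1, 1], [1, 2, 3, 4])

    def test_planted_coupling_recovered(self, rng):
        """Rank correlation of a planted bivariate coupling is recovered."""
        r = 0.6
        n = 200
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r * r) * rng.normal(size=n)
        rho, _, _ = spearman_association(x, y)
        expected = 6 / np.pi * np.arcsin(r / 2)  # Spearman rho of a normal pair
        assert rho == pytest.approx(expected, abs=0.1)
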