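"""PWM construction, scoring, scanning and ranking."""

import numpy as np
import pytest

from sh3map.alphabet import AMINO_ACIDS, LN20, N_AA
from sh3map.pwm import (PWM, AlignedPeptideSet, build_pwm, find_binding_motifs,
                        rank_in_proteome, scan_protein, score_peptide)
from sh3map.simulate import gen_pwm, random_protein, sample_peptides

P = AMINO_ACIDS.index("P")
L = AMINO_ACIDS.index("L")


class TestAlignedPeptideSet:
    def test_rejects_empty_and_unequal_and_invalid(self):
        with pytest.raises(ValueError):
            AlignedPeptideSet("d", ())
        with pytest.raises(ValueError):
            AlignedPeptideSet("d", ("AA", "AAA"))
        with pytest.raises(ValueError):
            AlignedPeptideSet("d", ("AB",))  # B is not an amino acid

    def test_gap_is_allowed(self):
        s = AlignedPeptideSet("d", ("A-C", "AAC"))
        assert s.length == 3


class TestBuildPwm:
    def test_unanimous_peptides_give_one_hot_odds(self):
        pwm = build_pwm(AlignedPeptideSet("d", tuple(["PPLP"] * 50)))
        assert pwm.m == 4
        for j, aa_idx in enumerate([P, P, L, P]):
            assert pwm.odds[aa_idx, j] == pytest.approx(20.0)
            others = np.delete(pwm.odds[:, j], aa_idx)
            assert np.all(others == 0.0)
        assert pwm.trim_record == (0, 0)

    def test_nonspecific_flank_column_is_trimmed(self):
        # column 1: every amino acid once (no residue significant);
        # column 2: unanimous P
        peps = tuple(aa + "P" for aa in AMINO_ACIDS)
        pwm = build_pwm(AlignedPeptideSet("d", peps))
        assert pwm.m == 1
        assert pwm.trim_record == (1, 0)
        assert pwm.odds[P, 0] == pytest.approx(20.0)

    def test_interior_nonspecific_column_is_kept(self):
        peps = tuple("P" + aa + "P" for aa in AMINO_ACIDS)
        pwm = build_pwm(AlignedPeptideSet("d", peps))
        assert pwm.m == 3  # only flanks may be trimmed
        assert pwm.prob[:, 1] == pytest.approx(np.full(N_AA, 1 / 20), abs=1e-9)

    def test_all_columns_nonspecific_retains_minimum_entropy_column(self):
        rng = np.random.default_rng(5)
        peps = tuple("".join(rng.choice(list(AMINO_ACIDS), size=3))
                     for _ in range(20))
        with pytest.warns(UserWarning):
            pwm = build_pwm(AlignedPeptideSet("d", peps))
        assert pwm.m == 1

    def test_gaps_spread_fractional_counts(self):
        # half the peptides are gaps: column mass preserved, no crash
        peps = ("P-",) * 10 + ("PP",) * 10
        pwm = build_pwm(AlignedPeptideSet("d", peps))
        assert pwm.prob[:, 0].sum() == pytest.approx(1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            AlignedPeptideSet("d", ())

    def test_column_stochasticity_and_odds_identity(self, world):
        for s in world.peptide_sets[:4]:
            pwm = build_pwm(s)
            assert pwm.prob.sum(axis=0) == pytest.approx(
                np.ones(pwm.m), abs=1e-9)
            assert pwm.odds == pytest.approx(20 * pwm.prob)
            assert pwm.odds.mean(axis=0) == pytest.approx(
                np.ones(pwm.m), abs=1e-9)

    def test_consensus_monotone_in_consensus_copies(self):
        rng = np.random.default_rng(7)
        base = tuple("".join(rng.choice(list(AMINO_ACIDS), size=5))
                     for _ in range(30))
        consensus = "PPKPP"
        prev = -np.inf
        for n_extra in (0, 10, 50, 200):
            peps = base + (consensus,) * n_extra
            pwm = build_pwm(AlignedPeptideSet("d", peps), trim_threshold=1.1)
            score = score_peptide(pwm, consensus)
            assert score >= prev - 1e-9
            prev = score


class TestScorePeptide:
    def test_uniform_pwm_scores_exactly_one(self, uniform_pwm, rng):
        for _ in range(20):
            pep = random_protein(uniform_pwm.m, rng)
            assert score_peptide(uniform_pwm, pep) == 1.0

    def test_deterministic_two_column_values(self):
        prob = np.zeros((N_AA, 2))
        prob[0, :] = 1.0  # A in both columns
        pwm = PWM("d", prob)
        assert score_peptide(pwm, "AA") == pytest.approx(400.0)
        assert score_peptide(pwm, "AC") == 0.0

    def test_length_mismatch_is_an_error(self, uniform_pwm):
        with pytest.raises(ValueError):
            score_peptide(uniform_pwm, "AAAA")

    def test_unknown_residue_is_neutral(self, sharp_pwm):
        assert score_peptide(sharp_pwm, "PXLP") == pytest.approx(
            score_peptide(sharp_pwm, "PPLP") / 20)

    def test_matches_per_residue_loop_oracle(self, rng):
        """Vectorised scoring equals an explicit per-residue product."""
        for _ in range(300):
            m = int(rng.integers(1, 9))
            prob = rng.dirichlet(np.ones(N_AA), size=m).T
            pwm = PWM("d", prob)
            pep = random_protein(m, rng)
            expected = 1.0
            for j, ch in enumerate(pep):
                expected *= 20 * prob[AMINO_ACIDS.index(ch), j]
            assert score_peptide(pwm, pep) == pytest.approx(expected, rel=1e-12)


class TestScanProtein:
    def test_planted_consensus_found_by_brute_force_position(self, sharp_pwm, rng):
        background = random_protein(120, rng)
        protein = background[:49] + "PPLP" + background[49:]
        best, windows = scan_protein(sharp_pwm, protein)
        # brute-force oracle over all windows
        scores = [score_peptide(sharp_pwm, protein[i:i + 4])
                  for i in range(len(protein) - 3)]
        assert best.start == int(np.argmax(scores)) + 1 == 50
        assert best.score == pytest.approx(max(scores))
        assert len(windows) == len(protein) - 3

    def test_short_protein_scores_zero(self, sharp_pwm):
        best, windows = scan_protein(sharp_pwm, "PP")
        assert best.score == 0.0
        assert windows == []

    def test_tie_broken_by_smallest_start(self, sharp_pwm):
        protein = "PPLP" + "A" * 10 + "PPLP"
        best, _ = scan_protein(sharp_pwm, protein)
        assert best.start == 1


class TestRankInProteome:
    def test_planted_protein_ranks_first(self, sharp_pwm, rng):
        proteome = {f"p{i}": random_protein(100, rng) for i in range(3)}
        proteome["hit"] = random_protein(40, rng) + "PPLP" + random_protein(40, rng)
        table = rank_in_proteome(sharp_pwm, proteome)
        assert table.iloc[0]["protein_id"] == "hit"
        assert table.iloc[0]["rank"] == 1

    def test_identical_proteins_share_minimum_rank(self, sharp_pwm):
        proteome = {f"p{i}": "AAAPPLPAAA" for i in range(3)}
        table = rank_in_proteome(sharp_pwm, proteome)
        assert list(table["rank"]) == [1, 1, 1]

    def test_sharp_pwm_separates_planted_from_background(self, sharp_pwm, rng):
        proteome = {f"bg{i}": random_protein(200, rng) for i in range(100)}
        proteome["planted"] = (random_protein(90, rng) + "PPLP"
                               + random_protein(90, rng))
        table = rank_in_proteome(sharp_pwm, proteome)
        row = table[table["protein_id"] == "planted"].iloc[0]
        assert row["rank"] == 1


class TestFindBindingMotifs:
    def test_no_window_above_threshold_gives_empty_list(self, sharp_pwm):
        assert find_binding_motifs(sharp_pwm, "AAAAAAAA", T=1000) == []

    def test_two_planted_sites_found(self, sharp_pwm, rng):
        bg = random_protein(100, rng).replace("P", "A")
        protein = bg[:9] + "PPLP" + bg[9:55] + "PPLP" + bg[55:]
        hits = find_binding_motifs(sharp_pwm, protein, T=1000)
        assert [h.start for h in hits] == [10, 60]

    def test_uniform_pwm_yields_no_motifs(self, uniform_pwm, rng):
        assert find_binding_motifs(uniform_pwm, random_protein(200, rng),
                                   T=1000) == []


class TestParameterRecovery:
    def test_noise_free_rebuild_matches_generator(self):
        gen = gen_pwm(10, 0.9, "II", seed=3)
        peps = sample_peptides(gen, 500, noise_rate=0.0, seed=4)
        rebuilt = build_pwm(peps, trim_threshold=1.1)  # keep all columns
        assert rebuilt.m == gen.m
        tv = 0.5 * np.abs(rebuilt.prob - gen.prob).sum(axis=0)
        assert np.all(tv < 0.05)

    def test_noisy_rebuild_matches_expected_peptide_distribution(self):
        """With residue noise the estimand is the noise-convolved PWM."""
        noise = 0.1
        gen = gen_pwm(10, 0.9, "I", seed=3)
        expected = (1 - noise) * gen.prob + noise / N_AA
        peps = sample_peptides(gen, 500, noise_rate=noise, seed=4)
        rebuilt = build_pwm(peps, trim_threshold=1.1)
        tv = 0.5 * np.abs(rebuilt.prob - expected).sum(axis=0)
        assert np.all(tv < 0.05)

    def test_pure_noise_trims_to_nearly_nothing(self):
        gen = gen_pwm(10, 0.9, "I", seed=3)
        peps = sample_peptides(gen, 500, noise_rate=1.0, seed=4)
        with pytest.warns(UserWarning):
            rebuilt = build_pwm(peps)
        assert rebuilt.m == 1
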