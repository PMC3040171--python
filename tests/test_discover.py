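"""Spaced-dyad seeding, ZOOPS EM, log-E fitness, GA, masking, discovery loop."""

import numpy as np
import pytest

from chipmotif import discover, simulate
from chipmotif.annotate import align_pwms
from chipmotif.core_io import SequenceRecord
from chipmotif.discover import (UNFIT, DiscoveryConfig, SpacedDyad, dyad_to_pwm,
                                em_refine, evolve, fitness, mask,
                                seed_population, seeded_discover)
from chipmotif.pwm import PWM, reverse_complement, scan

from conftest import consensus_pwm, random_pwm


SMALL_CFG = DiscoveryConfig(n_pop=50, n_gen=3, max_motifs=2, seed=0)


class TestSeedPopulation:
    def test_repeat_only_support_restriction(self):
        recs = [SequenceRecord(f"s{i}", "ACGTAC" * 20) for i in range(20)]
        pop = seed_population(recs, n_pop=50, rng=0)
        repeat = "ACGTAC" * 4
        for ind in pop:
            assert ind.dyad.word1 in repeat and ind.dyad.word2 in repeat

    def test_determinism(self):
        recs, _ = simulate.sim_sequences(50, 100, rng=1)
        p1 = seed_population(recs, n_pop=30, rng=11)
        p2 = seed_population(recs, n_pop=30, rng=11)
        assert [i.dyad for i in p1] == [i.dyad for i in p2]

    def test_enrichment_biased_sampling(self):
        """Planted-word 4-mers dominate the sampled words."""
        planted = consensus_pwm("TGACTCA", 0.97)
        recs, _ = simulate.sim_sequences(200, 100,
                                         motifs=[(planted, 0.6, "uniform")], rng=2)
        pop = seed_population(recs, k_range=(4, 4), n_pop=200, rng=3)
        planted_kmers = {"TGACTCA"[i:i + 4] for i in range(4)}
        rc = "TGAGTCA"  # reverse complement of the plant
        planted_kmers |= {rc[i:i + 4] for i in range(4)}
        words = [i.dyad.word1 for i in pop] + [i.dyad.word2 for i in pop]
        frac = np.mean([w in planted_kmers for w in words])
        assert frac >= 0.5

    def test_short_sequences_error(self):
        with pytest.raises(ValueError):
            seed_population([SequenceRecord("s", "ACGT")], k_range=(3, 6), rng=0)


class TestDyadToPwm:
    def test_concatenation_and_spacer(self):
        pwm = dyad_to_pwm(SpacedDyad("ACG", 0, "TTT"))
        assert pwm.width == 6 and pwm.consensus() == "ACGTTT"
        spaced = dyad_to_pwm(SpacedDyad("AAA", 2, "CCC"))
        assert spaced.width == 8
        assert np.allclose(spaced.probs[:, 3:5], 0.25)

    def test_letter_probability(self):
        pwm = dyad_to_pwm(SpacedDyad("AAA", 0, "CCC"), pseudo=0.05)
        assert pwm.probs[0, 0] == pytest.approx(0.85)


class TestEmRefine:
    def test_noiseless_limit(self):
        site = "TGACTCAT"
        rng = np.random.default_rng(3)
        recs = []
        for i in range(60):
            flank = "".join(rng.choice(list("ACGT"), size=30))
            recs.append(SequenceRecord(f"s{i}", flank[:15] + site + flank[15:]))
        pwm0 = dyad_to_pwm(SpacedDyad("TGAC", 0, "TCAT"))
        res = em_refine(pwm0, recs, max_iter=50, return_details=True)
        assert res.pwm.consensus() == site
        assert res.pwm.probs.max(axis=0).min() > 0.9

    def test_loglik_trace_nondecreasing(self, planted_motif):
        recs, _ = simulate.sim_sequences(100, 120,
                                         motifs=[(planted_motif, 0.7, "uniform")], rng=4)
        pwm0 = dyad_to_pwm(SpacedDyad("TGAC", 0, "TCAT"))
        res = em_refine(pwm0, recs, max_iter=30, return_details=True)
        tr = np.asarray(res.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * (1.0 + np.abs(tr[:-1])))

    def test_planted_recovery(self, planted_motif):
        recs, _ = simulate.sim_sequences(500, 200,
                                         motifs=[(planted_motif, 0.8, "uniform")], rng=2)
        pwm0 = dyad_to_pwm(SpacedDyad("TGAC", 0, "TCAT"))
        refined = em_refine(pwm0, recs, max_iter=50)
        assert align_pwms(refined, planted_motif)[2] >= 0.9

    def test_centered_prior_converges_faster_on_centered_data(self, planted_motif):
        recs, _ = simulate.sim_sequences(
            200, 200, motifs=[(planted_motif, 0.8, ("center", 5.0))], rng=5)
        pwm0 = dyad_to_pwm(SpacedDyad("TGA", 1, "CAT"))
        res_u = em_refine(pwm0, recs, max_iter=50, prior="uniform", return_details=True)
        res_c = em_refine(pwm0, recs, max_iter=50, prior="centered", return_details=True)
        assert res_c.n_iter <= res_u.n_iter
        assert align_pwms(res_c.pwm, planted_motif)[2] >= 0.9

    def test_too_wide_pwm_errors(self):
        recs = [SequenceRecord("s", "ACGTACGT")]
        with pytest.raises(ValueError):
            em_refine(consensus_pwm("ACGTACGTACGT"), recs)


class TestFitness:
    def test_no_occurrences_is_unfit(self):
        rng = np.random.default_rng(6)
        recs = [SequenceRecord("s", "".join(rng.choice(list("ACGT"), 100)))]
        pwm = consensus_pwm("TTTTTTTTTTTT", 0.97)
        res = fitness(pwm, recs, p_threshold=1e-6)
        assert res.logE == UNFIT and res.fold_enrichment == 0.0

    def test_null_fold_enrichment_calibrated(self):
        """A weak random PWM on pure background has fold enrichment ~ 1."""
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng, 10, alpha=2.0)
        recs, _ = simulate.sim_sequences(400, 200, rng=8)
        res = fitness(pwm, recs, p_threshold=2e-4)
        W = res.n_windows
        expect = W * 2e-4
        sd = np.sqrt(expect)
        assert abs(len(res.occurrences) - expect) <= 3 * sd
        assert res.logE > 0  # background must not look significant

    def test_planted_beats_shuffled(self, planted_motif):
        rng = np.random.default_rng(9)
        wins = 0
        for rep in range(10):
            recs, _ = simulate.sim_sequences(
                300, 200, motifs=[(planted_motif, 0.6, "uniform")], rng=100 + rep)
            shuffled = PWM("shuf", planted_motif.probs[:, rng.permutation(8)][
                rng.permutation(4), :][np.argsort(rng.permutation(4)), :])
            # column-and-row scramble keeps composition but breaks the motif
            real = fitness(planted_motif, recs).logE
            shuf = fitness(shuffled, recs).logE
            wins += real < shuf
        assert wins >= 9


class TestMask:
    def test_span_replacement(self):
        recs = [SequenceRecord("s", "ACGTACGTAC")]
        from chipmotif.pwm import MotifOccurrence

        occ = MotifOccurrence("s", 5, 9, "+", 0.0, 0.5)
        (out,) = mask(recs, [occ])
        assert out.seq == "ACGTANNNNC"

    def test_identity_and_errors(self):
        recs = [SequenceRecord("s", "ACGTACGTAC")]
        assert mask(recs, [])[0].seq == recs[0].seq
        from chipmotif.pwm import MotifOccurrence

        with pytest.raises(ValueError):
            mask(recs, [MotifOccurrence("s", 8, 12, "+", 0.0, 0.5)])
        with pytest.raises(ValueError):
            mask(recs, [MotifOccurrence("zzz", 0, 4, "+", 0.0, 0.5)])

    def test_rescan_after_mask_is_empty(self, planted_motif):
        recs, _ = simulate.sim_sequences(100, 150,
                                         motifs=[(planted_motif, 0.8, "uniform")], rng=10)
        occs = scan(planted_motif, recs, p_threshold=2e-4)
        masked = mask(recs, occs)
        assert scan(planted_motif, masked, p_threshold=2e-4) == []


class TestEvolve:
    def test_zero_generations_filters_initial_population(self, planted_motif):
        recs, _ = simulate.sim_sequences(200, 150,
                                         motifs=[(planted_motif, 0.7, "uniform")], rng=11)
        cfg = DiscoveryConfig(n_pop=20, n_gen=0, seed=0)
        pop = seed_population(recs, n_pop=20, rng=0)
        winners = evolve(pop, recs, cfg, rng=0)
        assert all(w.fitness <= cfg.logE_cutoff for w in winners)
        dyads = [w.dyad for w in winners]
        assert len(set(dyads)) == len(dyads)

    def test_fixed_seed_identical_winner(self, planted_motif):
        recs, _ = simulate.sim_sequences(200, 150,
                                         motifs=[(planted_motif, 0.7, "uniform")], rng=12)
        cfg = DiscoveryConfig(n_pop=20, n_gen=2, seed=0)
        outs = []
        for _ in range(2):
            pop = seed_population(recs, n_pop=20, rng=5)
            winners = evolve(pop, recs, cfg, rng=7)
            outs.append((winners[0].dyad, winners[0].fitness,
                         winners[0].refined_pwm.probs.tobytes()))
        assert outs[0] == outs[1]


class TestDiscoveryLoop:
    def test_two_planted_motifs_recovered_in_order(self):
        a = consensus_pwm("TGACTCAT", name="a")
        b = consensus_pwm("CACGTGAC", name="b")
        recs, _ = simulate.sim_sequences(
            500, 200, motifs=[(a, 0.6, "uniform"), (b, 0.4, "uniform")], rng=4)
        cfg = DiscoveryConfig(n_pop=50, n_gen=3, max_motifs=2, seed=4)
        results = discover.discover_motifs(recs, cfg)
        assert len(results) == 2
        assert align_pwms(results[0].pwm, a)[2] >= 0.9
        assert align_pwms(results[1].pwm, b)[2] >= 0.9
        assert results[0].logE <= results[1].logE

    def test_background_only_yields_nothing(self):
        recs, _ = simulate.sim_sequences(500, 200, rng=9)
        cfg = DiscoveryConfig(n_pop=50, n_gen=3, max_motifs=2, seed=9)
        assert discover.discover_motifs(recs, cfg) == []

    def test_few_sequences_warns(self):
        recs, _ = simulate.sim_sequences(5, 60, rng=13)
        with pytest.warns(UserWarning, match="fewer than 10"):
            discover.discover_motifs(recs, DiscoveryConfig(n_pop=4, n_gen=0, seed=0,
                                                           max_motifs=1))


class TestSeededDiscover:
    def test_absent_motif_is_unfit_or_null(self):
        recs, _ = simulate.sim_sequences(300, 200, rng=14)
        seed = consensus_pwm("GTCAGTCAGTCA", 0.95, name="absent")
        res = seeded_discover(seed, recs, SMALL_CFG)
        null_sites = res.n_sites if res.logE <= 0 else 0
        W = 300 * (200 - res.pwm.width + 1) * 2
        assert res.logE > 0 or null_sites <= W * SMALL_CFG.p_threshold * 3

    def test_seed_recovers_planted(self, planted_motif):
        recs, _ = simulate.sim_sequences(
            500, 200, motifs=[(planted_motif, 0.6, "uniform")], rng=2)
        res = seeded_discover(planted_motif, recs, SMALL_CFG)
        assert align_pwms(res.pwm, planted_motif)[2] >= 0.95
        assert res.pwm.source == "seeded"
        assert res.n_sites > 100
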