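"""PWM alignment, similarity E-values, filtering/combining, distance statistics."""

import numpy as np
import pytest

from chipmotif import annotate, core_io, simulate
from chipmotif.annotate import (DistanceSummary, MotifLabel, align_pwms,
                                calibrate_null, combine, distance_to_peak,
                                export_occurrences, filter_matches,
                                match_database, pairwise_distances)
from chipmotif.discover import MotifResult
from chipmotif.pwm import (PWM, Background, MotifOccurrence, information_content,
                           reverse_complement)
from chipmotif.core_io import GenomicInterval

from conftest import consensus_pwm, random_pwm


def brute_force_align(query, target, min_overlap=4):
    """Independent exhaustive oracle over offsets x strands."""
    def col_pcc(a, b):
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(np.dot(a, b) / (na * nb))

    best = None
    for strand in ("+", "-"):
        t = target.probs if strand == "+" else target.probs[::-1, ::-1]
        wq, wt = query.width, t.shape[1]
        for off in range(-wt + min_overlap, wq - min_overlap + 1):
            cols = [(qi, qi - off) for qi in range(wq) if 0 <= qi - off < wt]
            if len(cols) < min_overlap:
                continue
            score = np.mean([col_pcc(query.probs[:, qi], t[:, ti]) for qi, ti in cols])
            key = (score, -abs(off), strand == "+")
            if best is None or key > best[0]:
                best = (key, (off, strand, score))
    return best[1]


def make_db(n, rng, width_range=(6, 13), min_ic=8.0):
    db = []
    while len(db) < n:
        w = int(rng.integers(*width_range))
        pwm = random_pwm(rng, w, alpha=0.3, name=f"M{len(db):03d}")
        if information_content(pwm).sum() >= min_ic:
            db.append(pwm)
    return db


class TestAlign:
    def test_self_alignment(self):
        pwm = consensus_pwm("TGACTCAT")
        off, strand, score = align_pwms(pwm, pwm)
        assert (off, strand) == (0, "+") and score == pytest.approx(1.0)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(rng, 9, alpha=0.3)
        off, strand, score = align_pwms(pwm, reverse_complement(pwm))
        assert strand == "-" and score == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = random_pwm(rng, int(rng.integers(4, 12)), alpha=0.4)
        t = random_pwm(rng, int(rng.integers(4, 12)), alpha=0.4)
        off, strand, score = align_pwms(q, t)
        b_off, b_strand, b_score = brute_force_align(q, t)
        assert score == pytest.approx(b_score, abs=1e-9)
        # placements must agree unless the scores are genuinely tied
        if (off, strand) != (b_off, b_strand):
            assert abs(score - b_score) < 1e-12

    def test_too_narrow_errors(self):
        with pytest.raises(ValueError):
            align_pwms(consensus_pwm("ACG"), consensus_pwm("ACGTACGT"))


class TestNullCalibration:
    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            calibrate_null([consensus_pwm("ACGTAC")], n_samples=50)

    def test_evalue_monotone_in_score(self):
        rng = np.random.default_rng(1)
        db = make_db(20, rng)
        null = calibrate_null(db, n_samples=150, rng=2)
        evs = [null.evalue(s, 8, 8, len(db)) for s in np.linspace(-0.5, 1.0, 20)]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_self_alignment_highly_significant(self):
        rng = np.random.default_rng(3)
        db = make_db(20, rng)
        null = calibrate_null(db, n_samples=150, rng=4)
        assert null.evalue(1.0, 10, 10, 100) < 1e-4

    def test_null_queries_near_database_size(self):
        """Median E of a random query over the db is ~ N_db / 2."""
        rng = np.random.default_rng(5)
        db = make_db(30, rng)
        null = calibrate_null(db, n_samples=200, rng=6)
        query = random_pwm(rng, 9, alpha=0.4, name="q")
        evs = [null.evalue(align_pwms(query, t)[2], query.width, t.width, len(db))
               for t in db]
        med = np.median(evs)
        assert len(db) / 6 <= med <= 3 * len(db)


class TestMatchDatabase:
    def test_self_retrieval_and_nbest(self):
        rng = np.random.default_rng(7)
        db = make_db(25, rng)
        null = calibrate_null(db, n_samples=150, rng=8)
        res = match_database(db, db, null)
        hits = sum(res[p.name][0].target == p.name for p in db)
        assert hits >= 24
        assert all(len(m) == 5 for m in res.values())  # top-5 by default
        for matches in res.values():
            evs = [m.evalue for m in matches]
            assert evs == sorted(evs)

    def test_uniform_query_matches_nothing_strongly(self):
        rng = np.random.default_rng(9)
        db = make_db(20, rng)
        null = calibrate_null(db, n_samples=150, rng=10)
        res = match_database([PWM("flat", np.full((4, 8), 0.25))], db, null)
        assert all(m.evalue > 1e-4 for m in res["flat"])

    def test_empty_db_errors(self):
        null = annotate.NullModel({8: (0.0, 0.1, 100)})
        with pytest.raises(ValueError):
            match_database([consensus_pwm("ACGTAC")], [], null)


class TestFilterCombine:
    def _fake_results(self):
        m = annotate.MotifMatch
        return {
            "q1": [m("q1", "STAT1", 0, "+", 0.95, 1e-6)],
            "q2": [m("q2", "GATA1", 0, "+", 0.90, 1e-5)],
            "q3": [m("q3", "STAT3", 0, "+", 0.80, 1e-2)],
        }

    def test_name_filter(self):
        res = filter_matches(self._fake_results(), name_patterns=["STAT"])
        assert set(res) == {"q1", "q3"}

    def test_evalue_filter_and_combination(self):
        res = filter_matches(self._fake_results(), name_patterns=["STAT"],
                             evalue_max=1e-4)
        assert set(res) == {"q1"}
        assert filter_matches(self._fake_results(), evalue_max=1e-12) == {}

    def test_no_filters_is_identity(self):
        res = self._fake_results()
        assert filter_matches(res) == res

    def _motif_results(self):
        occ = lambda sid: MotifOccurrence(sid, 0, 8, "+", 5.0, 1e-5)
        out = []
        for name, n in (("m5", 3), ("m10", 2), ("m25", 4)):
            pwm = consensus_pwm("TGACTCAT", name=name)
            occs = [occ(f"s{i}") for i in range(n)]
            out.append(MotifResult(pwm, occs, -10.0, 2.0, n))
        return out

    def test_combine_pools_occurrences_without_touching_pwms(self):
        motifs = self._motif_results()
        before = [m.pwm.probs.tobytes() for m in motifs]
        label = combine(motifs, "FOXA1", ["m5", "m10", "m25"])
        assert label.members == ["m5", "m10", "m25"]
        assert len(label.occurrences) == 3 + 2 + 4
        assert [m.pwm.probs.tobytes() for m in motifs] == before

    def test_single_member_and_empty_selection(self):
        motifs = self._motif_results()
        single = combine(motifs, "solo", ["m10"])
        assert single.members == ["m10"] and len(single.occurrences) == 2
        with pytest.raises(ValueError):
            combine(motifs, "none", ["zzz"])


class TestDistanceToPeak:
    def test_all_at_centers_single_spike(self):
        occs = [MotifOccurrence(f"s{i}", 96, 104, "+", 1.0, 1e-4) for i in range(50)]
        summary = distance_to_peak(occs, {f"s{i}": 100.0 for i in range(50)})
        assert summary.n_total == 50
        peak_bin = np.argmax(summary.counts)
        assert summary.bin_edges[peak_bin] <= 0 < summary.bin_edges[peak_bin + 1]
        assert summary.counts[peak_bin] == 50

    def test_mass_conservation_with_unmatched(self):
        occs = [MotifOccurrence("known", 96, 104, "+", 1.0, 1e-4),
                MotifOccurrence("unknown", 10, 18, "+", 1.0, 1e-4),
                MotifOccurrence("known", 396, 404, "+", 1.0, 1e-4)]
        s = distance_to_peak(occs, {"known": 100.0})
        assert s.n_total + s.n_unmatched + s.n_out_of_range == 3
        assert s.n_unmatched == 1 and s.n_out_of_range == 1

    def test_genomic_nearest_event_matching(self):
        occs = [MotifOccurrence("w", 0, 8, "+", 1.0, 1e-4,
                                genomic=GenomicInterval("chr1", 996, 1004, "+")),
                MotifOccurrence("w", 0, 8, "+", 1.0, 1e-4,
                                genomic=GenomicInterval("chr1", 2046, 2054, "+"))]
        s = distance_to_peak(occs, [("chr1", 1000), ("chr1", 2000)])
        assert s.n_total == 2
        assert s.counts[np.nonzero(s.counts)].tolist() == [1, 1]


class TestPairwiseDistances:
    def test_fixed_lag_spike(self):
        a = consensus_pwm("TGACTCAT", name="a")
        b = consensus_pwm("CACGTGAC", name="b")
        recs, truth = simulate.sim_sequences(
            200, 200, motifs=[(a, 1.0, ("fixed", 40)), (b, 1.0, ("lag", 0, 60))], rng=1)
        occ_a = [MotifOccurrence(sid, off, off + 8, strand, 1.0, 1e-4)
                 for sid, off, strand, name in truth.sites if name == "a"]
        occ_b = [MotifOccurrence(sid, off, off + 8, strand, 1.0, 1e-4)
                 for sid, off, strand, name in truth.sites if name == "b"]
        s = pairwise_distances(occ_a, occ_b, max_gap=150)
        spike = np.argmax(s.counts)
        assert s.bin_edges[spike] <= 60 < s.bin_edges[spike + 1]
        assert s.counts[spike] == s.n_total
        assert s.cooccurrence_fraction == pytest.approx(1.0)

    def test_cooccurrence_denominator_is_rarer_motif(self):
        occ_a = [MotifOccurrence(f"s{i}", 10, 18, "+", 1.0, 1e-4) for i in range(100)]
        occ_b = [MotifOccurrence(f"s{i}", 60, 68, "+", 1.0, 1e-4) for i in range(40)]
        s = pairwise_distances(occ_a, occ_b)
        assert s.cooccurrence_fraction == pytest.approx(1.0)  # 40 / 40

    def test_independence_null_fraction(self):
        a = consensus_pwm("TGACTCAT", name="a")
        b = consensus_pwm("CACGTGAC", name="b")
        recs, truth = simulate.sim_sequences(
            500, 200, motifs=[(a, 0.6, "uniform"), (b, 0.3, "uniform")], rng=2)
        occ = {"a": [], "b": []}
        for sid, off, strand, name in truth.sites:
            occ[name].append(MotifOccurrence(sid, off, off + 8, strand, 1.0, 1e-4))
        s = pairwise_distances(occ["a"], occ["b"], max_gap=250)
        n_b = len({o.seq_id for o in occ["b"]})
        sd = 3 * np.sqrt(0.6 * 0.4 / n_b)
        assert abs(s.cooccurrence_fraction - 0.6) <= sd

    def test_self_pair_excludes_self_comparison(self):
        occ = [MotifOccurrence("s0", 10, 18, "+", 1.0, 1e-4),
               MotifOccurrence("s0", 50, 58, "+", 1.0, 1e-4)]
        s = pairwise_distances(occ, occ)
        assert s.n_total == 2  # (+40, -40), not the zero self-distances


class TestExport:
    def test_bed_round_trip(self, tmp_path):
        occs = [MotifOccurrence("w0", 5, 13, "+", 3.2, 1e-5,
                                genomic=GenomicInterval("chr2", 105, 113, "+")),
                MotifOccurrence("w1", 7, 15, "-", 2.8, 1e-4,
                                genomic=GenomicInterval("chr1", 207, 215, "-"))]
        path = tmp_path / "occ.bed"
        export_occurrences({"myMotif": occs}, path, fmt="bed")
        back = core_io.read_intervals(path)
        assert [(iv.chrom, iv.start, iv.end, iv.strand) for iv in back] == \
               [("chr1", 207, 215, "-"), ("chr2", 105, 113, "+")]

    def test_empty_export_is_valid(self, tmp_path):
        path = tmp_path / "empty.bed"
        export_occurrences({}, path, fmt="bed")
        assert core_io.read_intervals(path) == []

    def test_mixed_provenance_error_names_label(self, tmp_path):
        occs = [MotifOccurrence("w0", 5, 13, "+", 3.2, 1e-5)]
        with pytest.raises(ValueError, match="badMotif"):
            export_occurrences({"badMotif": occs}, tmp_path / "x.bed", fmt="bed")

    def test_tsv_fallback(self, tmp_path):
        occs = [MotifOccurrence("w0", 5, 13, "+", 3.2, 1e-5)]
        path = tmp_path / "occ.tsv"
        export_occurrences({"m": occs}, path, fmt="tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("seq_id") and "w0" in lines[1]
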