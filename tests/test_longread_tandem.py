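"""Long-read hit finding, greedy dedupe, arrays, locus model, stop screen."""

import numpy as np
import pytest

from invamp import _seq
from invamp import longread_tandem as lt
from invamp import simulate as sim


def _rand(rng, n):
    return _seq.random_seq(rng, n)


class TestFindHits:
    def test_read_without_query_content_empty(self):
        rng = np.random.default_rng(1)
        read = _rand(rng, 3_000)
        unit = _rand(np.random.default_rng(2), 630)
        assert lt.find_hits(read, {"unit": unit}) == []

    def test_single_exact_copy_full_identity(self):
        rng = np.random.default_rng(3)
        unit = _rand(rng, 630)
        read = _rand(rng, 1_000) + unit + _rand(rng, 1_000)
        hits = lt.find_hits(read, {"unit": unit})
        assert len(hits) == 1
        h = hits[0]
        assert h.read_interval == (1_000, 1_630)
        assert h.identity == 1.0
        assert h.orientation == "+"

    def test_reverse_complement_copy_found_minus(self):
        rng = np.random.default_rng(4)
        unit = _rand(rng, 630)
        read = _rand(rng, 500) + _seq.revcomp(unit) + _rand(rng, 500)
        hits = lt.find_hits(read, {"unit": unit})
        assert len(hits) == 1
        assert hits[0].orientation == "-"
        assert hits[0].read_interval == (500, 1_130)

    def test_short_fragment_filtered(self):
        """A planted 150 bp unit fragment falls under the 200 bp floor."""
        rng = np.random.default_rng(5)
        unit = _rand(rng, 630)
        read = _rand(rng, 800) + unit[:150] + _rand(rng, 800)
        assert lt.find_hits(read, {"unit": unit}) == []
        assert len(lt.find_hits(read, {"unit": unit}, min_len=100)) == 1

    def test_diverged_copy_identity_below_threshold_dropped(self):
        rng = np.random.default_rng(6)
        unit = _rand(rng, 400)
        arr = _seq.encode(unit).copy()
        picks = rng.choice(400, size=120, replace=False)   # 30% divergence
        arr[picks] = (arr[picks] + 1) % 4
        read = _rand(rng, 500) + _seq.decode(arr) + _rand(rng, 500)
        assert lt.find_hits(read, {"unit": unit}, min_identity=0.80) == []

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            lt.find_hits("ACGT" * 100, {})


def _brute_force_dedupe(hits, max_overlap=0.8):
    """Independent reimplementation of the greedy acceptance rule."""
    ordered = sorted(hits, key=lambda h: (-(h.read_interval[1] - h.read_interval[0]),
                                          h.read_interval[0], h.query_id))
    accepted = []
    for h in ordered:
        s, e = h.read_interval
        covered = 0
        for p in range(s, e):
            if any(a.read_interval[0] <= p < a.read_interval[1]
                   for a in accepted):
                covered += 1
        if (e - s) > 0 and covered >= max_overlap * (e - s):
            continue
        accepted.append(h)
    return accepted


class TestDedupe:
    @staticmethod
    def _mk(iv, qid="q"):
        return lt.Hit(read_id="r", read_interval=iv, query_id=qid,
                      identity=1.0, orientation="+")

    def test_nested_hit_discarded(self):
        hits = [self._mk((0, 1_000)), self._mk((200, 500))]
        acc = lt.dedupe_hits(hits)
        assert [h.read_interval for h in acc] == [(0, 1_000)]

    def test_disjoint_hits_all_accepted(self):
        hits = [self._mk((0, 300)), self._mk((400, 900)), self._mk((1_000, 1_250))]
        assert len(lt.dedupe_hits(hits)) == 3

    def test_partial_overlap_below_threshold_kept(self):
        hits = [self._mk((0, 1_000)), self._mk((900, 1_500))]
        # overlap 100 of 600 = 17% < 80% -> kept
        assert len(lt.dedupe_hits(hits)) == 2

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            hits = []
            for i in range(n):
                s = int(rng.integers(0, 2_000))
                ln = int(rng.integers(1, 800))
                hits.append(lt.Hit(read_id="r", read_interval=(s, s + ln),
                                   query_id=f"q{int(rng.integers(0, 3))}",
                                   identity=1.0, orientation="+"))
            fast = [(h.read_interval, h.query_id)
                    for h in lt.dedupe_hits(hits)]
            brute = [(h.read_interval, h.query_id)
                     for h in _brute_force_dedupe(hits)]
            assert fast == brute

    def test_accepted_hits_never_overlap_union_80_percent(self):
        rng = np.random.default_rng(8)
        hits = [self._mk((int(s), int(s) + int(l)))
                for s, l in zip(rng.integers(0, 3_000, 40),
                                rng.integers(50, 700, 40))]
        acc = lt.dedupe_hits(hits)
        for i, h in enumerate(acc):
            union = []
            for prev in acc[:i]:
                lt._union_add(union, prev.read_interval)
            ov = lt._overlap_with_union(h.read_interval, union)
            assert ov < 0.8 * h.length


class TestArrays:
    def test_no_unit_hits_no_arrays(self):
        arrays, co = lt.annotate_arrays([], 630)
        assert arrays == []
        assert co.empty

    def test_seven_head_to_tail_units(self):
        rng = np.random.default_rng(9)
        unit = _rand(rng, 630)
        read = _rand(rng, 400) + unit * 7 + _rand(rng, 400)
        hits = lt.dedupe_hits(lt.find_hits(read, {"unit": unit}))
        arrays, _ = lt.annotate_arrays(hits, 630)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_count == 7
        assert a.span == 4_410
        assert a.head_to_tail

    def test_strand_symmetry_of_unit_count(self):
        rng = np.random.default_rng(10)
        unit = _rand(rng, 630)
        read = _rand(rng, 300) + unit * 5 + _rand(rng, 300)
        rc = _seq.revcomp(read)
        for r, orient in ((read, "+"), (rc, "-")):
            hits = lt.dedupe_hits(lt.find_hits(r, {"unit": unit}))
            arrays, _ = lt.annotate_arrays(hits, 630)
            assert len(arrays) == 1
            assert arrays[0].unit_count == 5
            assert arrays[0].orientation == orient

    def test_co_occurrence_block_structure(self):
        """Queries planted on the same reads co-occur; separate clusters
        never do (the truth clustering shows as block structure)."""
        rng = np.random.default_rng(11)
        q = {f"CNV{i}": _rand(rng, 500) for i in (1, 2, 3, 4, 7)}
        reads = []
        for _ in range(4):   # cluster A reads: CNV1+2+3 contiguous
            reads.append(_rand(rng, 200) + q["CNV1"] + q["CNV2"] + q["CNV3"]
                         + _rand(rng, 200))
        for _ in range(3):   # cluster B reads: CNV4+7
            reads.append(_rand(rng, 200) + q["CNV4"] + q["CNV7"]
                         + _rand(rng, 200))
        all_hits = []
        for i, r in enumerate(reads):
            all_hits.extend(lt.dedupe_hits(
                lt.find_hits(r, q, read_id=f"read{i}")))
        _, co = lt.annotate_arrays(all_hits, 500)
        assert co.loc["CNV1", "CNV2"] == 4
        assert co.loc["CNV2", "CNV3"] == 4
        assert co.loc["CNV4", "CNV7"] == 3
        assert co.loc["CNV1", "CNV4"] == 0
        assert co.loc["CNV3", "CNV7"] == 0


class TestLocusModel:
    def test_no_spanning_reads_warns_empty(self):
        rng = np.random.default_rng(12)
        with pytest.warns(UserWarning, match="no flank-anchored"):
            model = lt.reconstruct_locus([_rand(rng, 2_000)],
                                         _rand(rng, 800), _rand(rng, 800),
                                         _rand(rng, 630))
        assert model.unit_count_histogram == {}
        assert model.n_anchored_reads == 0

    def test_histogram_matches_planted_counts(self, locus_hap):
        _, hap, truth = locus_hap
        reads = sim.simulate_long_reads(
            hap, "S/M", coverage=0, spanning=[1, 1, 1, 1, 7, 7, 7, 35],
            truth=truth, seed=5)
        model = lt.reconstruct_locus(
            reads.sequences(), truth.locus.flank_left,
            truth.locus.flank_right, truth.locus.unit_seq)
        assert model.unit_count_histogram == {1: 4, 7: 3, 35: 1}
        # histogram conservation
        assert sum(model.unit_count_histogram.values()) == model.n_anchored_reads

    def test_consensus_byte_identical_to_planted_copy(self, locus_hap):
        _, hap, truth = locus_hap
        reads = sim.simulate_long_reads(hap, "S/M", coverage=0,
                                        spanning=[1, 1, 1], truth=truth, seed=6)
        model = lt.reconstruct_locus(
            reads.sequences(), truth.locus.flank_left,
            truth.locus.flank_right, truth.locus.unit_seq)
        planted = (truth.locus.flank_left + truth.locus.unit_seq
                   + truth.locus.flank_right)
        assert model.consensus == planted

    def test_anchoring_survives_reverse_complement(self, locus_hap):
        _, hap, truth = locus_hap
        reads = sim.simulate_long_reads(hap, "S/M", coverage=0, spanning=[7],
                                        truth=truth, seed=7)
        rc_reads = [_seq.revcomp(s) for s in reads.sequences()]
        model = lt.reconstruct_locus(
            rc_reads, truth.locus.flank_left, truth.locus.flank_right,
            truth.locus.unit_seq)
        assert model.unit_count_histogram == {7: 1}


class TestStopScreen:
    def test_no_planted_stops_zero(self):
        rng = np.random.default_rng(13)
        loc = sim.LocusSpec(position=5_000, flank_left_len=900,
                            flank_right_len=600, unit_length=630,
                            units_per_copy_wildtype=[],
                            units_per_copy_rearranged=[1] * 10)
        cfg = sim.SimConfig(chromosome_length=20_000, locus=loc, seed=14)
        hap, truth = sim.build_haplotypes(cfg)
        copies = [hap.rearranged_seq[s:e]
                  for s, e in (c.interval for c in truth.locus.copies_rearranged)]
        frac, flags = lt.screen_stop_codons(copies, truth.locus.exon2)
        assert frac == 0.0

    def test_planted_40_of_100_recovered_exactly(self):
        loc = sim.LocusSpec(position=5_000, flank_left_len=900,
                            flank_right_len=600, unit_length=630,
                            units_per_copy_wildtype=[],
                            units_per_copy_rearranged=[1] * 100,
                            stop_flags=[True] * 40 + [False] * 60)
        cfg = sim.SimConfig(chromosome_length=20_000, locus=loc, seed=15)
        hap, truth = sim.build_haplotypes(cfg)
        copies = [hap.rearranged_seq[s:e]
                  for s, e in (c.interval for c in truth.locus.copies_rearranged)]
        frac, flags = lt.screen_stop_codons(copies, truth.locus.exon2)
        assert frac == pytest.approx(0.40)
        assert [bool(f) for f in flags] == [True] * 40 + [False] * 60

    def test_out_of_frame_stop_not_flagged(self):
        # TAA straddling a codon boundary: codons CTA | AGC ...
        seq = "ATG" + "CTA" + "AGC" + "GGC"
        assert not lt.copy_has_premature_stop(seq, (0, len(seq)))
        # the same TAA in frame flags
        seq2 = "ATG" + "TAA" + "AGC"
        assert lt.copy_has_premature_stop(seq2, (0, len(seq2)))

    def test_short_exon_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            lt.copy_has_premature_stop("ACGTACGT", (2, 4))

    def test_empty_copies_rejected(self):
        with pytest.raises(ValueError):
            lt.screen_stop_codons([], (0, 9))
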