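"""Mapper exactness, depth conservation and copy-number quantification."""

import warnings

import numpy as np
import pytest

from invamp import _seq
from invamp import align_depth as ad
from invamp import simulate as sim


def _single_read_set(seq: str) -> sim.ReadSet:
    arr = _seq.encode(seq)[None, :]
    return sim.ReadSet(mode="wgs", read_len=len(seq), seqs1=arr,
                       seqs2=(3 - arr)[:, ::-1])


class TestMapReads:
    def test_unique_read_maps_at_position(self):
        rng = np.random.default_rng(1)
        ref = _seq.random_seq(rng, 5_000)
        rs = _single_read_set(ref[1000:1150])
        aln = ad.map_reads(rs, ref)
        rec = aln[0]
        assert rec.mapped and rec.ref_interval == (1000, 1150)
        assert rec.strand == "+"
        # mate 2 is the reverse complement -> '-' strand, same interval
        rec2 = aln[1]
        assert rec2.mapped and rec2.ref_interval == (1000, 1150)
        assert rec2.strand == "-"

    def test_foreign_read_unmapped(self):
        rng = np.random.default_rng(2)
        ref = _seq.random_seq(rng, 5_000)
        foreign = _seq.random_seq(np.random.default_rng(3), 150)
        aln = ad.map_reads(_single_read_set(foreign), ref)
        assert not aln[0].mapped

    def test_collapsed_repeat_read_maps_inside_reference_copy(
            self, collapsed_block_hap):
        """Reads from any of 10 wild-type copies land in the one reference
        copy; verified against brute-force substring search."""
        _, hap, truth = collapsed_block_hap
        s, e = truth.blocks[0].wildtype_interval
        unit_len = 6000
        # read wholly inside the 5th copy of the wild-type array
        rstart = s + 4 * unit_len + 100
        read = hap.wildtype_seq[rstart:rstart + 150]
        aln = ad.map_reads(_single_read_set(read), hap.reference_seq, seed=5)
        rec = aln[0]
        assert rec.mapped
        brute = []
        p = hap.reference_seq.find(read)
        while p != -1:
            brute.append(p)
            p = hap.reference_seq.find(read, p + 1)
        assert rec.ref_interval[0] in brute
        rs, re_ = truth.blocks[0].ref_interval
        assert rs <= rec.ref_interval[0] < re_

    def test_multi_placement_choice_is_seeded(self):
        rng = np.random.default_rng(7)
        unit = _seq.random_seq(rng, 400)
        ref = _seq.random_seq(rng, 2_000) + unit + _seq.random_seq(rng, 500) \
            + unit + _seq.random_seq(rng, 2_000)
        read = unit[100:250]
        rs = _single_read_set(read)
        a1 = ad.map_reads(rs, ref, seed=42)
        a2 = ad.map_reads(rs, ref, seed=42)
        assert a1[0].ref_interval == a2[0].ref_interval
        positions = {ad.map_reads(rs, ref, seed=s)[0].ref_interval[0]
                     for s in range(20)}
        assert positions == {2100, 3000}


class TestDepthTrack:
    def test_single_read_depth_and_median_baseline(self):
        # one mapped 150 bp record -> exactly 150 positions at depth 1
        aln = ad.AlignmentSet([0], [1], [200], [150], [1], [True],
                              reference_length=10_000, paired=False)
        track, baseline = ad.build_depth_track(aln)
        assert (track.depth == 1).sum() == 150
        assert track.total == 150
        assert baseline == 0.0

    def test_pair_depth_two_over_shared_interval(self):
        rng = np.random.default_rng(4)
        ref = _seq.random_seq(rng, 10_000)
        aln = ad.map_reads(_single_read_set(ref[200:350]), ref)
        track, baseline = ad.build_depth_track(aln)
        assert (track.depth == 2).sum() == 150
        assert baseline == 0.0

    def test_depth_conservation(self, collapsed_block_hap):
        _, hap, _ = collapsed_block_hap
        rs = sim.simulate_short_reads(hap, "S/S", coverage=3, seed=1)
        aln = ad.map_reads(rs, hap.reference_seq, seed=1)
        track, _ = ad.build_depth_track(aln)
        mapped_bases = int(aln.length[aln.mapped].sum())
        assert track.total == mapped_bases

    def test_uniform_coverage_baseline(self):
        cfg = sim.SimConfig(chromosome_length=400_000, seed=5)
        hap, _ = sim.build_haplotypes(cfg)
        rs = sim.simulate_short_reads(hap, "S/S", coverage=30, seed=2)
        aln = ad.map_reads(rs, hap.reference_seq, seed=2)
        _, baseline = ad.build_depth_track(aln)
        assert abs(baseline - 30) <= 0.05 * 30

    def test_masked_amplification_leaves_baseline_unchanged(self):
        blk = sim.CNVBlock(id="amp", position=100_000, unit_length=5000,
                           copies_wildtype=50, copies_rearranged=50)
        cfg = sim.SimConfig(chromosome_length=300_000, cnv_blocks=[blk],
                            seed=6)
        hap, truth = sim.build_haplotypes(cfg)
        cfg0 = sim.SimConfig(chromosome_length=300_000, seed=6)
        hap0, _ = sim.build_haplotypes(cfg0)
        rs = sim.simulate_short_reads(hap, "S/S", coverage=20, seed=3)
        rs0 = sim.simulate_short_reads(hap0, "S/S", coverage=20, seed=3)
        aln = ad.map_reads(rs, hap.reference_seq, seed=3)
        aln0 = ad.map_reads(rs0, hap0.reference_seq, seed=3)
        mask = [truth.blocks[0].ref_interval]
        _, b_masked = ad.build_depth_track(aln, mask=mask)
        _, b_clean = ad.build_depth_track(aln0)
        assert abs(b_masked - b_clean) <= 0.02 * b_clean

    def test_fully_masked_reference_errors(self):
        rng = np.random.default_rng(8)
        ref = _seq.random_seq(rng, 1_000)
        aln = ad.map_reads(_single_read_set(ref[:150]), ref)
        with pytest.raises(ValueError, match="no baseline"):
            ad.build_depth_track(aln, mask=[(0, 1_000)])


class TestCallCNV:
    def test_identical_tracks_no_calls(self):
        depth = np.full(50_000, 30, dtype=np.int64)
        t = ad.DepthTrack(depth=depth)
        assert ad.call_cnv_intervals(t, t, (30.0, 30.0)) == []

    def test_single_block_called_with_reciprocal_overlap(self):
        blk = sim.CNVBlock(id="b", position=100_000, unit_length=10_000,
                           copies_wildtype=1, copies_rearranged=9)
        cfg = sim.SimConfig(chromosome_length=300_000, cnv_blocks=[blk],
                            seed=7)
        hap, truth = sim.build_haplotypes(cfg)
        rh = sim.simulate_short_reads(hap, "S/M", coverage=30, seed=4)
        rm = sim.simulate_short_reads(hap, "S/S", coverage=30, seed=5)
        res = ad.depth_cnv_pipeline(rh, rm, hap.reference_seq)
        assert len(res.intervals) == 1
        (cs, ce), (ts, te) = res.intervals[0], truth.blocks[0].ref_interval
        inter = max(0, min(ce, te) - max(cs, ts))
        assert inter >= 0.9 * (te - ts)
        assert inter >= 0.9 * (ce - cs)

    def test_merge_gap_behavior(self):
        base = np.full(40_000, 30, dtype=np.int64)
        het = base.copy()
        het[5_000:10_000] = 90
        # gap of 3 kb > merge_gap 1 kb -> two calls
        het[13_000:18_000] = 90
        t_het, t_hom = ad.DepthTrack(het), ad.DepthTrack(base)
        two = ad.call_cnv_intervals(t_het, t_hom, (30, 30), merge_gap=1000)
        assert len(two) == 2
        one = ad.call_cnv_intervals(t_het, t_hom, (30, 30), merge_gap=3000)
        assert len(one) == 1

    def test_zero_baseline_errors(self):
        t = ad.DepthTrack(np.zeros(5_000, dtype=np.int64))
        with pytest.raises(ValueError, match="baseline"):
            ad.call_cnv_intervals(t, t, (0.0, 30.0))


class TestQuantify:
    def test_hom_depth_20x_baseline_gives_40_total_20_per_homolog(self):
        """Twenty-fold depth over baseline = 40 copies total, 20/homolog."""
        hom = np.full(20_000, 30, dtype=np.int64)
        het = hom.copy()
        hom[5_000:10_000] = 600   # 20 x baseline
        het[5_000:10_000] = 600
        calls = ad.quantify_cnvs([(5_000, 10_000)],
                                 (ad.DepthTrack(het), ad.DepthTrack(hom)),
                                 (30.0, 30.0))
        c = calls[0]
        assert c.total_copies_hom == pytest.approx(40.0)
        assert c.per_homolog_wild == pytest.approx(20.0)

    def test_baseline_depth_is_diploid_no_extra_dna(self):
        d = np.full(10_000, 30, dtype=np.int64)
        c = ad.quantify_cnvs([(2_000, 4_000)],
                             (ad.DepthTrack(d), ad.DepthTrack(d)),
                             (30.0, 30.0))[0]
        assert c.total_copies_hom == pytest.approx(2.0)
        assert c.extra_dna_hom_bp == 0.0
        assert c.extra_dna_het_bp == 0.0

    def test_extra_dna_six_copies_over_10kb(self):
        hom = np.full(30_000, 30, dtype=np.int64)
        het = hom.copy()
        het[10_000:20_000] = 90   # 6 copies total in the het sample
        c = ad.quantify_cnvs([(10_000, 20_000)],
                             (ad.DepthTrack(het), ad.DepthTrack(hom)),
                             (30.0, 30.0))[0]
        assert c.total_copies_het == pytest.approx(6.0)
        assert c.extra_dna_het_bp == pytest.approx(40_000.0)

    def test_negative_per_homolog_clipped_with_warning(self):
        hom = np.full(10_000, 30, dtype=np.int64)
        het = hom.copy()
        hom[2_000:4_000] = 300
        het[2_000:4_000] = 60
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            c = ad.quantify_cnvs([(2_000, 4_000)],
                                 (ad.DepthTrack(het), ad.DepthTrack(hom)),
                                 (30.0, 30.0))[0]
        assert c.per_homolog_rearranged == 0.0
        assert any("clipped" in str(x.message) for x in w)


def test_collapsed_depth_matches_copies(self=None):
    """Depth over a collapsed block ~ baseline * total copies / 2."""
    blk = sim.CNVBlock(id="c", position=100_000, unit_length=8000,
                       copies_wildtype=6, copies_rearranged=6)
    cfg = sim.SimConfig(chromosome_length=250_000, cnv_blocks=[blk], seed=9)
    hap, truth = sim.build_haplotypes(cfg)
    rs = sim.simulate_short_reads(hap, "S/S", coverage=25, seed=6)
    aln = ad.map_reads(rs, hap.reference_seq, seed=6)
    track, baseline = ad.build_depth_track(
        aln, mask=[truth.blocks[0].ref_interval])
    s, e = truth.blocks[0].ref_interval
    mean_block = track.depth[s:e].mean()
    assert mean_block == pytest.approx(baseline * 6, rel=0.08)
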