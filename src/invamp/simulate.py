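"""Synthetic diploid rearrangement generator.

Builds a wild-type / rearranged haplotype pair for a single chromosome
carrying a paracentric inversion and a set of amplified tandem CNV blocks,
including a multicopy gene-like locus with a nested tandem repeat unit that
can be withheld from the mapping reference (a "novel" insertion) or
represented by a single collapsed copy.  Paired short reads (shotgun or
proximity-ligation mode) and long reads are drawn from the haplotypes,
error-free by default, with full per-read provenance so that every
downstream estimator can be scored against ground truth.

Coordinates are 0-based half-open throughout.  All randomness flows through
``numpy.random.default_rng(seed)``; the same config and seed reproduce the
same bytes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import _seq

STOP_CODONS = ("TAA", "TAG", "TGA")
# codons that can fill a coding frame without creating an in-frame stop
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CNVBlock:
    """A tandem-amplified block inserted at a backbone position.

    The wild-type haplotype carries ``copies_wildtype`` head-to-tail copies
    of a ``unit_length`` bp unit at ``position``; the rearranged haplotype
    carries ``copies_rearranged``.  ``assembly`` controls the mapping
    reference: "collapsed" plants exactly one unit copy (the classic
    collapsed-repeat situation that inflates mapped depth), "absent" omits
    the block entirely (a novel, unassembled sequence).
    """

    id: str
    position: int
    unit_length: int
    copies_wildtype: int
    copies_rearranged: int
    tandem: bool = True
    assembly: str = "collapsed"  # "collapsed" | "absent"
    unit_seq: str | None = None


@dataclass
class LocusSpec:
    """A multicopy gene-like locus with a nested tandem repeat unit.

    Each locus copy is flank_left + unit * k + flank_right, where k varies
    per copy (``units_per_copy_*``).  "Exon 2" lives inside the left flank
    and may carry a planted premature stop codon (TAA substituted for one
    in-frame codon) in a per-copy Bernoulli(stop_variant_fraction) draw, or
    exactly as dictated by ``stop_flags``.  "Exon 3" lies inside the repeat
    unit.  Both exon templates are generated stop-free so that planted stops
    are the only in-frame terminators.
    """

    position: int
    flank_left_len: int
    flank_right_len: int
    unit_length: int = 630
    exon2: tuple[int, int] = (300, 600)        # within flank_left
    exon3: tuple[int, int] = (100, 324)        # within the repeat unit
    units_per_copy_wildtype: list[int] = field(default_factory=list)
    units_per_copy_rearranged: list[int] = field(default_factory=list)
    stop_variant_fraction: float = 0.0
    stop_flags: list[bool] | None = None       # overrides the Bernoulli draw
    divergent_first_unit: bool = False
    assembly: str = "absent"


@dataclass
class SimConfig:
    chromosome_length: int
    inversion: tuple[int, int] | None = None
    cnv_blocks: list[CNVBlock] = field(default_factory=list)
    locus: LocusSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        L = self.chromosome_length
        if L <= 0:
            raise ConfigError("chromosome_length must be positive")
        if self.inversion is not None:
            b1, b2 = self.inversion
            if not (0 <= b1 < b2 <= L):
                raise ConfigError(
                    f"inversion ({b1}, {b2}) outside chromosome [0, {L})"
                )
        positions = []
        for blk in self.cnv_blocks:
            if blk.copies_wildtype < 0 or blk.copies_rearranged < 0:
                raise ConfigError(f"block {blk.id}: copies must be >= 0")
            if blk.unit_length <= 0:
                raise ConfigError(f"block {blk.id}: unit_length must be > 0")
            if not 0 <= blk.position <= L:
                raise ConfigError(f"block {blk.id}: position outside chromosome")
            if blk.assembly not in ("collapsed", "absent"):
                raise ConfigError(f"block {blk.id}: unknown assembly policy")
            positions.append((blk.position, blk.id))
        if self.locus is not None:
            loc = self.locus
            if not 0.0 <= loc.stop_variant_fraction <= 1.0:
                raise ConfigError("stop_variant_fraction must be in [0, 1]")
            if not 0 <= loc.position <= L:
                raise ConfigError("locus position outside chromosome")
            e2s, e2e = loc.exon2
            if not (0 <= e2s < e2e <= loc.flank_left_len):
                raise ConfigError("exon2 interval must lie within flank_left")
            e3s, e3e = loc.exon3
            if not (0 <= e3s < e3e <= loc.unit_length):
                raise ConfigError("exon3 interval must lie within the unit")
            if loc.stop_flags is not None and len(loc.stop_flags) != len(
                loc.units_per_copy_rearranged
            ):
                raise ConfigError(
                    "stop_flags length must equal the number of rearranged "
                    "locus copies"
                )
            positions.append((loc.position, "locus"))
        seen: dict[int, str] = {}
        for pos, name in positions:
            if pos in seen:
                raise ConfigError(
                    f"insertions {seen[pos]!r} and {name!r} overlap at {pos}"
                )
            seen[pos] = name
        if self.inversion is not None:
            b1, b2 = self.inversion
            for pos, name in positions:
                if b1 < pos < b2:
                    raise ConfigError(
                        f"inversion ({b1}, {b2}) overlaps planted block {name!r}"
                    )


# ---------------------------------------------------------------------------
# truth / output types
# ---------------------------------------------------------------------------

@dataclass
class BlockTruth:
    id: str
    unit_seq: str
    copies_wildtype: int
    copies_rearranged: int
    ref_interval: tuple[int, int] | None
    wildtype_interval: tuple[int, int]
    rearranged_interval: tuple[int, int]


@dataclass
class LocusCopyTruth:
    interval: tuple[int, int]   # on its haplotype
    unit_count: int
    stop_flag: bool


@dataclass
class LocusTruth:
    flank_left: str
    flank_right: str
    unit_seq: str
    exon2: tuple[int, int]          # relative to copy start
    exon3: tuple[int, int]          # relative to unit start
    copies_wildtype: list[LocusCopyTruth]
    copies_rearranged: list[LocusCopyTruth]
    ref_interval: tuple[int, int] | None

    @property
    def stop_fraction_rearranged(self) -> float:
        c = self.copies_rearranged
        return sum(x.stop_flag for x in c) / len(c) if c else 0.0


@dataclass
class InversionTruth:
    backbone: tuple[int, int]
    reference: tuple[int, int]
    wildtype: tuple[int, int]
    rearranged: tuple[int, int]


@dataclass
class TruthTable:
    chromosome_length: int
    blocks: list[BlockTruth]
    locus: LocusTruth | None
    inversion: InversionTruth | None


@dataclass
class HaplotypePair:
    wildtype_seq: str
    rearranged_seq: str
    reference_seq: str
    features: dict[str, list[tuple[int, int, str]]]

    def seq(self, which: str) -> str:
        return {"wildtype": self.wildtype_seq,
                "rearranged": self.rearranged_seq,
                "reference": self.reference_seq}[which]


@dataclass
class ReadSet:
    """Simulated reads with full provenance.

    For paired mode, ``seqs1``/``seqs2`` are (n, read_len) uint8 code
    matrices; mate 2 is stored as sequenced (reverse-complemented off the
    source haplotype).  For long-read mode, ``long_seqs`` is a list of 1-D
    code arrays.  ``source_hap`` holds "wildtype"/"rearranged" per
    pair/read; ``start1``/``start2`` are source coordinates on that
    haplotype (forward strand).
    """

    mode: str                                   # "wgs" | "ligation" | "long"
    read_len: int | None
    seqs1: np.ndarray | None = None
    seqs2: np.ndarray | None = None
    long_seqs: list[np.ndarray] | None = None
    source_hap: list[str] = field(default_factory=list)
    start1: np.ndarray | None = None
    start2: np.ndarray | None = None

    @property
    def n(self) -> int:
        if self.mode == "long":
            return len(self.long_seqs or [])
        return 0 if self.seqs1 is None else self.seqs1.shape[0]

    @property
    def total_bases(self) -> int:
        if self.mode == "long":
            return int(sum(len(s) for s in (self.long_seqs or [])))
        if self.seqs1 is None:
            return 0
        return int(self.seqs1.size + (self.seqs2.size if self.seqs2 is not None else 0))

    def sequences(self, mate: int = 1) -> list[str]:
        """Decode reads (or mate 1/2 of pairs) to strings."""
        if self.mode == "long":
            return [_seq.decode(s) for s in self.long_seqs or []]
        mat = self.seqs1 if mate == 1 else self.seqs2
        return [] if mat is None else [_seq.decode(r) for r in mat]


# ---------------------------------------------------------------------------
# haplotype construction
# ---------------------------------------------------------------------------

def _plant_stop_free_exon(rng: np.random.Generator, length: int) -> str:
    """A coding stretch with no in-frame stop codon (frame 0 at offset 0)."""
    n_codons = length // 3
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    tail = _seq.random_seq(rng, length - 3 * n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx) + tail


def _locus_copy(loc: LocusSpec, flank_left: str, flank_right: str, unit: str,
                divergent_unit: str, n_units: int, stop: bool) -> str:
    fl = flank_left
    if stop:
        e2s, _ = loc.exon2
        # replace the middle in-frame codon of exon 2 with TAA
        n_codons = (loc.exon2[1] - loc.exon2[0]) // 3
        cod = e2s + 3 * (n_codons // 2)
        fl = fl[:cod] + "TAA" + fl[cod + 3:]
    units = []
    for i in range(n_units):
        units.append(divergent_unit if (i == 0 and loc.divergent_first_unit) else unit)
    return fl + "".join(units) + flank_right


def build_haplotypes(config: SimConfig) -> tuple[HaplotypePair, TruthTable]:
    """Materialise the wild-type / rearranged / reference sequences.

    The three sequences share a random backbone; blocks and the locus are
    inserted at their backbone positions with per-sequence copy numbers
    (reference gets 1 copy when "collapsed", 0 when "absent").  The
    inversion is applied to the rearranged haplotype last and must not
    overlap any insertion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    backbone = _seq.random_seq(rng, config.chromosome_length)

    # draw block / locus sequence material once
    block_units: dict[str, str] = {}
    for blk in config.cnv_blocks:
        block_units[blk.id] = (
            blk.unit_seq if blk.unit_seq is not None
            else _seq.random_seq(rng, blk.unit_length)
        )

    locus_parts = None
    if config.locus is not None:
        loc = config.locus
        fl = _seq.random_seq(rng, loc.flank_left_len)
        e2s, e2e = loc.exon2
        fl = fl[:e2s] + _plant_stop_free_exon(rng, e2e - e2s) + fl[e2e:]
        fr = _seq.random_seq(rng, loc.flank_right_len)
        unit = _seq.random_seq(rng, loc.unit_length)
        e3s, e3e = loc.exon3
        unit = unit[:e3s] + _plant_stop_free_exon(rng, e3e - e3s) + unit[e3e:]
        divergent = unit
        if loc.divergent_first_unit:
            # a handful of substitutions outside the exon-3 interval
            arr = _seq.encode(unit).copy()
            outside = np.array(
                [i for i in range(loc.unit_length) if not e3s <= i < e3e]
            )
            picks = rng.choice(outside, size=min(8, outside.size), replace=False)
            arr[picks] = (arr[picks] + rng.integers(1, 4, size=picks.size)) % 4
            divergent = _seq.decode(arr.astype(np.uint8))
        if loc.stop_flags is not None:
            stops_re = list(loc.stop_flags)
        else:
            stops_re = list(
                rng.random(len(loc.units_per_copy_rearranged))
                < loc.stop_variant_fraction
            )
        locus_parts = (fl, fr, unit, divergent, stops_re)

    # assemble: per-sequence list of (position, inserted_seq, label, extra)
    def _insertions(which: str):
        out = []
        for blk in config.cnv_blocks:
            copies = {"wildtype": blk.copies_wildtype,
                      "rearranged": blk.copies_rearranged,
                      "reference": 1 if blk.assembly == "collapsed" else 0}[which]
            if copies > 0:
                out.append((blk.position, block_units[blk.id] * copies,
                            f"block:{blk.id}", None))
        if config.locus is not None:
            loc = config.locus
            fl, fr, unit, divergent, stops_re = locus_parts
            if which == "reference":
                if loc.assembly == "collapsed":
                    copy = _locus_copy(loc, fl, fr, unit, divergent, 1, False)
                    out.append((loc.position, copy, "locus", [(1, False)]))
            else:
                counts = (loc.units_per_copy_wildtype if which == "wildtype"
                          else loc.units_per_copy_rearranged)
                stops = ([False] * len(counts) if which == "wildtype" else stops_re)
                copies = [
                    _locus_copy(loc, fl, fr, unit, divergent, k, s)
                    for k, s in zip(counts, stops)
                ]
                if counts:
                    out.append((loc.position, "".join(copies), "locus",
                                list(zip(counts, stops))))
        out.sort(key=lambda t: t[0])
        return out

    seqs: dict[str, str] = {}
    features: dict[str, list[tuple[int, int, str]]] = {}
    intervals: dict[str, dict[str, tuple[int, int]]] = {}
    locus_copy_intervals: dict[str, list[LocusCopyTruth]] = {}
    offset_tables: dict[str, list[tuple[int, int]]] = {}

    for which in ("wildtype", "rearranged", "reference"):
        parts = []
        feats = []
        ivs: dict[str, tuple[int, int]] = {}
        cursor = 0
        offset = 0
        offsets = []  # (backbone_pos, cumulative_inserted_before)
        for pos, ins, label, extra in _insertions(which):
            parts.append(backbone[cursor:pos])
            start = pos + offset
            parts.append(ins)
            end = start + len(ins)
            feats.append((start, end, label))
            ivs[label] = (start, end)
            if label == "locus" and extra is not None:
                copy_list = []
                cstart = start
                loc = config.locus
                for k, s in extra:
                    clen = (loc.flank_left_len + k * loc.unit_length
                            + loc.flank_right_len)
                    copy_list.append(
                        LocusCopyTruth((cstart, cstart + clen), k, bool(s))
                    )
                    cstart += clen
                locus_copy_intervals[which] = copy_list
            offset += len(ins)
            offsets.append((pos, offset))
            cursor = pos
        parts.append(backbone[cursor:])
        seqs[which] = "".join(parts)
        features[which] = feats
        intervals[which] = ivs
        offset_tables[which] = offsets

    def _map_coord(which: str, x: int) -> int:
        off = 0
        for pos, cum in offset_tables[which]:
            if pos <= x:
                off = cum
        return x + off

    inv_truth = None
    if config.inversion is not None:
        b1, b2 = config.inversion
        rb1, rb2 = _map_coord("rearranged", b1), _map_coord("rearranged", b2)
        s = seqs["rearranged"]
        seqs["rearranged"] = s[:rb1] + _seq.revcomp(s[rb1:rb2]) + s[rb2:]
        features["rearranged"].append((rb1, rb2, "inversion"))
        inv_truth = InversionTruth(
            backbone=(b1, b2),
            reference=(_map_coord("reference", b1), _map_coord("reference", b2)),
            wildtype=(_map_coord("wildtype", b1), _map_coord("wildtype", b2)),
            rearranged=(rb1, rb2),
        )

    blocks_truth = []
    for blk in config.cnv_blocks:
        label = f"block:{blk.id}"
        blocks_truth.append(BlockTruth(
            id=blk.id,
            unit_seq=block_units[blk.id],
            copies_wildtype=blk.copies_wildtype,
            copies_rearranged=blk.copies_rearranged,
            ref_interval=intervals["reference"].get(label),
            wildtype_interval=intervals["wildtype"].get(
                label, (_map_coord("wildtype", blk.position),) * 2),
            rearranged_interval=intervals["rearranged"].get(
                label, (_map_coord("rearranged", blk.position),) * 2),
        ))

    locus_truth = None
    if config.locus is not None:
        fl, fr, unit, divergent, stops_re = locus_parts
        locus_truth = LocusTruth(
            flank_left=fl, flank_right=fr, unit_seq=unit,
            exon2=config.locus.exon2, exon3=config.locus.exon3,
            copies_wildtype=locus_copy_intervals.get("wildtype", []),
            copies_rearranged=locus_copy_intervals.get("rearranged", []),
            ref_interval=intervals["reference"].get("locus"),
        )

    pair = HaplotypePair(
        wildtype_seq=seqs["wildtype"],
        rearranged_seq=seqs["rearranged"],
        reference_seq=seqs["reference"],
        features=features,
    )
    truth = TruthTable(
        chromosome_length=config.chromosome_length,
        blocks=blocks_truth,
        locus=locus_truth,
        inversion=inv_truth,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _genome_len(hap: HaplotypePair, genotype: str) -> float:
    if genotype == "S/S":
        return float(len(hap.wildtype_seq))
    if genotype == "S/M":
        return (len(hap.wildtype_seq) + len(hap.rearranged_seq)) / 2.0
    raise ValueError(f"unknown genotype {genotype!r} (expected 'S/S' or 'S/M')")


def _power_law_distances(rng, n, alpha, d_min, d_max):
    """Draw n distances with density proportional to d^-alpha on [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return (d_min * np.exp(u * math.log(d_max / d_min))).astype(np.int64)
    a = 1.0 - alpha
    lo, hi = d_min ** a, d_max ** a
    return ((lo + u * (hi - lo)) ** (1.0 / a)).astype(np.int64)


def _apply_errors(rng, mat: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    out = mat.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_short_reads(
    hap: HaplotypePair,
    genotype: str,
    coverage: float,
    read_len: int = 150,
    mode: str = "wgs",
    insert_size: int = 500,
    decay_exponent: float = 1.0,
    min_distance: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw paired 150 bp-style reads at the requested fold coverage.

    ``wgs`` mode draws fixed-insert proper pairs; ``ligation`` mode draws the
    second mate at a genomic distance d with P(d) proportional to
    d^-decay_exponent (truncated to the chromosome), emulating
    proximity-ligation contact decay.  Heterozygotes are sampled exactly
    50/50 from the two haplotypes (odd pair left with the wild type) so
    depth expectations are exact.  Pair count is
    floor(coverage * genome_len / (2 * read_len)).
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if mode not in ("wgs", "ligation"):
        raise ValueError(f"unknown mode {mode!r}")
    for name in ("wildtype", "rearranged") if genotype == "S/M" else ("wildtype",):
        if read_len > len(hap.seq(name)):
            raise ValueError(f"read_len {read_len} exceeds {name} haplotype length")
    if mode == "wgs" and insert_size < read_len:
        raise ValueError("insert_size must be >= read_len")

    gl = _genome_len(hap, genotype)
    n_pairs = int(math.floor(coverage * gl / (2 * read_len)))
    rng = np.random.default_rng(seed)

    if genotype == "S/S":
        alloc = [("wildtype", n_pairs)]
    else:
        # deterministic split proportional to haplotype length: each homolog
        # then receives exactly coverage/2 per-position depth regardless of
        # how much the rearrangement lengthened it
        lw = len(hap.wildtype_seq)
        lr = len(hap.rearranged_seq)
        n_wild = int(round(n_pairs * lw / (lw + lr)))
        alloc = [("wildtype", n_wild), ("rearranged", n_pairs - n_wild)]

    s1_all, s2_all, hap_all = [], [], []
    m1_all, m2_all = [], []
    for which, n in alloc:
        if n == 0:
            continue
        seq = _seq.encode(hap.seq(which))
        L = seq.size
        if mode == "wgs":
            frag = min(insert_size, L)
            s1 = rng.integers(0, L - frag + 1, size=n)
            s2 = s1 + frag - read_len
        else:
            s1 = rng.integers(0, L - read_len + 1, size=n)
            d_max = max(L - read_len, min_distance + 1)
            s2 = np.empty(n, dtype=np.int64)
            todo = np.arange(n)
            while todo.size:
                d = _power_law_distances(rng, todo.size, decay_exponent,
                                         min_distance, d_max)
                sign = rng.integers(0, 2, size=todo.size) * 2 - 1
                cand = s1[todo] + sign * d
                ok = (cand >= 0) & (cand <= L - read_len)
                s2[todo[ok]] = cand[ok]
                todo = todo[~ok]
        windows = np.lib.stride_tricks.sliding_window_view(seq, read_len)
        m1 = windows[s1]
        m2 = (3 - windows[s2])[:, ::-1]       # mate 2 sequenced on the - strand
        s1_all.append(s1)
        s2_all.append(s2)
        m1_all.append(m1)
        m2_all.append(m2)
        hap_all.extend([which] * n)

    if not s1_all:
        empty = np.empty((0, read_len), dtype=np.uint8)
        return ReadSet(mode=mode, read_len=read_len, seqs1=empty, seqs2=empty,
                       source_hap=[], start1=np.empty(0, dtype=np.int64),
                       start2=np.empty(0, dtype=np.int64))

    seqs1 = _apply_errors(rng, np.concatenate(m1_all), error_rate)
    seqs2 = _apply_errors(rng, np.concatenate(m2_all), error_rate)
    return ReadSet(
        mode=mode, read_len=read_len, seqs1=seqs1, seqs2=seqs2,
        source_hap=hap_all,
        start1=np.concatenate(s1_all), start2=np.concatenate(s2_all),
    )


def simulate_long_reads(
    hap: HaplotypePair,
    genotype: str,
    coverage: float,
    length_law: tuple[float, float] = (20000.0, 5000.0),
    seed: int = 0,
    spanning: list[int] | str | None = None,
    spanning_margin: int = 100,
    truth: TruthTable | None = None,
) -> ReadSet:
    """Draw error-free long reads; lengths are min + Exponential(mean - min).

    Total bases land within 2% of coverage * genome_len (the last read is
    trimmed to hit the target, never below the minimum length).  Each read
    is a forward-strand substring of one haplotype.

    ``spanning`` requests guaranteed locus-spanning reads: "all" emits one
    read per locus copy; a list of unit counts emits one read per entry,
    each taken from the next locus copy carrying that many repeat units
    (requires ``truth``).  Spanning reads come from the rearranged
    haplotype for S/M, wild type otherwise.
    """
    mean_len, min_len = length_law
    if not mean_len >= min_len > 0:
        raise ValueError("length_law requires mean >= min > 0")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    gl = _genome_len(hap, genotype)
    target = coverage * gl

    long_seqs: list[np.ndarray] = []
    source, starts = [], []

    if target > 0:
        lengths: list[int] = []
        total = 0
        while total < target:
            chunk = rng.exponential(mean_len - min_len, size=256) + min_len
            for ln in chunk.astype(np.int64):
                lengths.append(int(ln))
                total += int(ln)
                if total >= target:
                    break
        excess = total - int(target)
        if excess > 0 and lengths[-1] - excess >= min_len:
            lengths[-1] -= excess
        haps = ("wildtype",) if genotype == "S/S" else ("wildtype", "rearranged")
        enc = {h: _seq.encode(hap.seq(h)) for h in haps}
        sizes = np.array([enc[h].size for h in haps], dtype=float)
        hap_prob = sizes / sizes.sum()   # per-position depth equal per homolog
        for ln in lengths:
            which = haps[rng.choice(len(haps), p=hap_prob)]
            arr = enc[which]
            ln = min(ln, arr.size)
            s = int(rng.integers(0, arr.size - ln + 1))
            long_seqs.append(arr[s:s + ln])
            source.append(which)
            starts.append(s)

    if spanning is not None:
        if truth is None or truth.locus is None:
            raise ValueError("spanning reads require a TruthTable with a locus")
        which = "rearranged" if genotype == "S/M" else "wildtype"
        copies = (truth.locus.copies_rearranged if which == "rearranged"
                  else truth.locus.copies_wildtype)
        arr = _seq.encode(hap.seq(which))
        if spanning == "all":
            wanted = list(range(len(copies)))
        else:
            by_count: dict[int, list[int]] = {}
            for i, c in enumerate(copies):
                by_count.setdefault(c.unit_count, []).append(i)
            wanted = []
            for k in spanning:
                pool = by_count.get(k, [])
                if not pool:
                    raise ValueError(f"no remaining locus copy with {k} units")
                wanted.append(pool.pop(0))
        for i in wanted:
            s, e = copies[i].interval
            s = max(0, s - spanning_margin)
            e = min(arr.size, e + spanning_margin)
            long_seqs.append(arr[s:e])
            source.append(which)
            starts.append(s)

    return ReadSet(mode="long", read_len=None, long_seqs=long_seqs,
                   source_hap=source,
                   start1=np.asarray(starts, dtype=np.int64))


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _write_fasta(path: str, records: list[tuple[str, str]]) -> None:
    try:
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")
    except OSError as exc:
        raise OSError(f"writing FASTA {path}: {exc}") from exc


def _write_fastq(path: str, names: list[str], seqs: list[str]) -> None:
    try:
        with open(path, "w") as fh:
            for name, seq in zip(names, seqs):
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    except OSError as exc:
        raise OSError(f"writing FASTQ {path}: {exc}") from exc


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_fixtures(
    hap: HaplotypePair,
    truth: TruthTable,
    reads: ReadSet | None,
    outdir: str,
    config: SimConfig | None = None,
) -> dict[str, str]:
    """Write FASTA / FASTQ / JSON fixtures; returns {role: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    p = os.path.join(outdir, "reference.fasta")
    _write_fasta(p, [("reference", hap.reference_seq)])
    paths["reference"] = p
    p = os.path.join(outdir, "haplotypes.fasta")
    _write_fasta(p, [("wildtype", hap.wildtype_seq),
                     ("rearranged", hap.rearranged_seq)])
    paths["haplotypes"] = p

    if reads is not None:
        if reads.mode == "long":
            p = os.path.join(outdir, "long_reads.fastq")
            names = [f"read{i}" for i in range(reads.n)]
            _write_fastq(p, names, reads.sequences())
            paths["long_reads"] = p
        else:
            names = [f"pair{i}" for i in range(reads.n)]
            p1 = os.path.join(outdir, "reads_1.fastq")
            p2 = os.path.join(outdir, "reads_2.fastq")
            _write_fastq(p1, names, reads.sequences(1))
            _write_fastq(p2, names, reads.sequences(2))
            paths["reads_1"], paths["reads_2"] = p1, p2

    p = os.path.join(outdir, "truth.json")
    payload = {"truth": _jsonable(truth)}
    if config is not None:
        payload["config"] = _jsonable(config)
    try:
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"writing truth JSON {p}: {exc}") from exc
    paths["truth"] = p
    return paths


def read_fasta(path: str) -> dict[str, str]:
    """Read a (2-line or wrapped) FASTA file into {name: sequence}."""
    from Bio import SeqIO

    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    except OSError as exc:
        raise OSError(f"reading FASTA {path}: {exc}") from exc


def read_truth(path: str) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except OSError as exc:
        raise OSError(f"reading truth JSON {path}: {exc}") from exc
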