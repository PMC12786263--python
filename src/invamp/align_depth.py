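"""Short-read mapping, depth tracks and read-depth CNV quantification.

The mapper is a minimal exact-substring aligner for error-free synthetic
reads: a read is mapped iff it occurs verbatim in the reference or its
reverse complement.  Candidate placements are located through an index of
``seed_k``-mers at every reference position; reads matching several
positions (reads from a collapsed repeat) are assigned one placement
uniformly at random (seeded), so depth over the single collapsed copy
accumulates every repeat-derived read.

Copy numbers follow the classic read-depth argument: with baseline b the
per-position depth of a diploid-normal region, a region at mean depth m
carries ``2 m / b`` copies in total, and contributes
``length * max(0, copies - 2)`` bp of extra DNA beyond the diploid state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .simulate import ReadSet


@dataclass
class AlignmentRecord:
    read_id: str
    mate_index: int
    ref_interval: tuple[int, int]
    strand: str
    mapped: bool


class AlignmentSet:
    """Columnar container of per-mate alignments (array-of-records view).

    ``pair_index``/``mate`` identify the source read; ``start`` is -1 for
    unmapped mates; ``strand`` is +1/-1.
    """

    def __init__(self, pair_index, mate, start, length, strand, mapped,
                 reference_length: int, paired: bool):
        self.pair_index = np.asarray(pair_index, dtype=np.int64)
        self.mate = np.asarray(mate, dtype=np.int8)
        self.start = np.asarray(start, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.int64)
        self.strand = np.asarray(strand, dtype=np.int8)
        self.mapped = np.asarray(mapped, dtype=bool)
        self.reference_length = int(reference_length)
        self.paired = bool(paired)

    def __len__(self) -> int:
        return self.pair_index.size

    def __getitem__(self, i: int) -> AlignmentRecord:
        s = int(self.start[i])
        ln = int(self.length[i])
        return AlignmentRecord(
            read_id=f"pair{int(self.pair_index[i])}",
            mate_index=int(self.mate[i]),
            ref_interval=(s, s + ln) if self.mapped[i] else (-1, -1),
            strand="+" if self.strand[i] >= 0 else "-",
            mapped=bool(self.mapped[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


class ReferenceIndex:
    """Sorted index of the packed seed_k-mer at every reference position."""

    def __init__(self, reference: str, seed_k: int = 21):
        if seed_k > 31:
            raise ValueError("seed_k must be <= 31")
        self.seed_k = seed_k
        self.ref = _seq.encode(reference)
        if self.ref.size < seed_k:
            raise ValueError("reference shorter than seed_k")
        codes = _seq.kmer_codes(self.ref, seed_k)
        self.order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[self.order]

    def candidates(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) slice bounds into ``order`` for each query code."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi


def _map_batch(index: ReferenceIndex, reads: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Map a (n, L) matrix of equal-length reads; returns (start, strand).

    start = -1 where unmapped.  Verification compares the full read against
    the reference at each candidate placement, so only true exact
    occurrences survive; one occurrence is picked uniformly at random when
    there are several.
    """
    n, L = reads.shape
    k = index.seed_k
    if k > L:
        raise ValueError("seed_k exceeds read length")
    ref = index.ref
    starts = np.full(n, -1, dtype=np.int64)
    strands = np.ones(n, dtype=np.int8)
    if n == 0:
        return starts, strands

    sc = index.sorted_codes
    size = sc.size
    cap = size - 1

    def _probe(codes):
        """(lo, count) with count capped at 2 (2 means 'two or more')."""
        lo = np.searchsorted(sc, codes, side="left")
        loc = np.minimum(lo, cap)
        present = (lo < size) & (sc[loc] == codes)
        nxt = np.minimum(lo + 1, cap)
        dup = present & (lo + 1 < size) & (sc[nxt] == codes)
        return lo, present.astype(np.int8) + dup.astype(np.int8)

    code_f = _seq.kmer_codes(reads[:, :k], k).ravel()
    # first k bases of the reverse complement = revcomp of the last k bases
    tail = reads[:, L - k:]
    code_r = _seq.kmer_codes((3 - tail)[:, ::-1], k).ravel()
    lo_f, cnt_f = _probe(code_f)
    lo_r, cnt_r = _probe(code_r)
    ncand = cnt_f + cnt_r

    ref_windows = np.lib.stride_tricks.sliding_window_view(ref, L)

    # fast path: exactly one candidate placement over both strands
    idx = np.flatnonzero(ncand == 1)
    if idx.size:
        is_f = cnt_f[idx] == 1
        pos = np.where(is_f,
                       index.order[np.minimum(lo_f[idx], cap)],
                       index.order[np.minimum(lo_r[idx], cap)])
        ok_bounds = pos + L <= ref.size
        sel = idx[ok_bounds]
        pos = pos[ok_bounds]
        is_f = is_f[ok_bounds]
        for flag in (True, False):
            part = is_f if flag else ~is_f
            if not part.any():
                continue
            s, p = sel[part], pos[part]
            query = reads[s] if flag else (3 - reads[s])[:, ::-1]
            hit = (ref_windows[p] == query).all(axis=1)
            starts[s[hit]] = p[hit]
            strands[s[hit]] = 1 if flag else -1

    # slow path: several candidates (collapsed repeats)
    multi = np.flatnonzero(ncand > 1)
    for i in multi:
        read_f = reads[i]
        read_r = (3 - read_f)[::-1]
        placements = []
        for code, mat, st in ((code_f[i], read_f, 1), (code_r[i], read_r, -1)):
            lo = int(np.searchsorted(sc, code, side="left"))
            hi = int(np.searchsorted(sc, code, side="right"))
            for p in index.order[lo:hi]:
                p = int(p)
                if p + L <= ref.size and np.array_equal(ref[p:p + L], mat):
                    placements.append((p, st))
        if placements:
            p, st = placements[int(rng.integers(0, len(placements)))]
            starts[i] = p
            strands[i] = st
    return starts, strands


def map_reads(
    reads: ReadSet,
    reference: str,
    seed_k: int = 21,
    seed: int = 0,
    index: ReferenceIndex | None = None,
) -> AlignmentSet:
    """Map a paired short-read set against the reference (both strands)."""
    if reads.mode == "long":
        raise ValueError("map_reads handles short reads; long reads are "
                         "annotated with longread_tandem.find_hits")
    if index is None:
        index = ReferenceIndex(reference, seed_k)
    rng = np.random.default_rng(seed)
    n = reads.n
    L = reads.read_len or 0
    s1, st1 = _map_batch(index, reads.seqs1, rng)
    s2, st2 = _map_batch(index, reads.seqs2, rng)
    pair_index = np.concatenate([np.arange(n), np.arange(n)])
    mate = np.concatenate([np.ones(n, dtype=np.int8),
                           np.full(n, 2, dtype=np.int8)])
    start = np.concatenate([s1, s2])
    strand = np.concatenate([st1, st2])
    mapped = start >= 0
    length = np.full(2 * n, L, dtype=np.int64)
    return AlignmentSet(pair_index, mate, start, length, strand, mapped,
                        reference_length=len(reference), paired=True)


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    depth: np.ndarray
    bin_size: int = 1

    @property
    def total(self) -> int:
        return int(self.depth.sum())


def build_depth_track(
    alignments: AlignmentSet,
    reference_len: int | None = None,
    mask: list[tuple[int, int]] = (),
) -> tuple[DepthTrack, float]:
    """Per-position coverage plus a baseline over unmasked positions.

    Baseline is the median per-position depth outside ``mask`` (robust to
    residual CNVs; the mean is available through ``baseline_mean``).
    """
    if reference_len is None:
        reference_len = alignments.reference_length
    diff = np.zeros(reference_len + 1, dtype=np.int64)
    m = alignments.mapped
    starts = alignments.start[m]
    ends = np.minimum(starts + alignments.length[m], reference_len)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])

    keep = np.ones(reference_len, dtype=bool)
    for s, e in mask:
        if not (0 <= s <= e <= reference_len):
            raise ValueError(f"mask interval ({s}, {e}) outside reference")
        keep[s:e] = False
    if not keep.any():
        raise ValueError("no baseline region: reference fully masked")
    baseline = float(np.median(depth[keep]))
    return DepthTrack(depth=depth), baseline


def baseline_mean(track: DepthTrack, mask: list[tuple[int, int]] = ()) -> float:
    keep = np.ones(track.depth.size, dtype=bool)
    for s, e in mask:
        keep[s:e] = False
    if not keep.any():
        raise ValueError("no baseline region: reference fully masked")
    return float(track.depth[keep].mean())


# ---------------------------------------------------------------------------
# CNV calling and quantification
# ---------------------------------------------------------------------------

def _window_means(x: np.ndarray, window: int) -> np.ndarray:
    n_win = x.size // window
    if n_win == 0:
        return np.empty(0)
    return x[: n_win * window].reshape(n_win, window).mean(axis=1)


def call_cnv_intervals(
    track_het: DepthTrack,
    track_hom: DepthTrack,
    baselines: tuple[float, float],
    min_ratio: float = 1.5,
    window: int = 1000,
    merge_gap: int = 1000,
) -> list[tuple[int, int]]:
    """Maximal runs of windows with het/hom normalized-depth contrast.

    A window is flagged when normalized het depth / normalized hom depth
    >= min_ratio, or when the hom normalized depth itself is >= min_ratio
    (an amplification already present on the wild-type chromosome).
    Flagged windows closer than ``merge_gap`` are merged.
    """
    b_het, b_hom = baselines
    if b_het <= 0 or b_hom <= 0:
        raise ValueError("zero baseline")
    if track_het.depth.size != track_hom.depth.size:
        raise ValueError("tracks cover different references")
    nh = _window_means(track_het.depth / b_het, window)
    nm = _window_means(track_hom.depth / b_hom, window)
    # floor the denominator at a quarter of diploid depth so near-empty
    # windows cannot fabricate huge ratios out of noise
    ratio = nh / np.maximum(nm, 0.25)
    flag = (ratio >= min_ratio) | (nm >= min_ratio)

    out: list[tuple[int, int]] = []
    n = flag.size
    i = 0
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flag[j + 1]:
            j += 1
        out.append((i * window, (j + 1) * window))
        i = j + 1

    merged: list[tuple[int, int]] = []
    for s, e in out:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    L = track_het.depth.size
    return [(s, min(e, L)) for s, e in merged]


@dataclass
class CNVCall:
    interval: tuple[int, int]
    mean_depth_hom: float
    mean_depth_het: float
    total_copies_hom: float
    total_copies_het: float
    per_homolog_wild: float
    per_homolog_rearranged: float
    extra_dna_hom_bp: float
    extra_dna_het_bp: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def extra_dna_bp(self) -> float:
        """Extra DNA in the rearrangement-carrier (heterozygous) sample."""
        return self.extra_dna_het_bp


def quantify_cnvs(
    calls: list[tuple[int, int]],
    tracks: tuple[DepthTrack, DepthTrack],
    baselines: tuple[float, float],
    genotype_labels: tuple[str, str] = ("S/M", "S/S"),
) -> list[CNVCall]:
    """Copy numbers and extra DNA for each called interval.

    ``tracks``/``baselines`` are ordered (het, hom) as labelled by
    ``genotype_labels``.  total_copies = 2 * mean_depth / baseline per
    sample; per-homolog wild = hom total / 2; per-homolog rearranged =
    het total - per-homolog wild (clipped at 0 with a warning); extra DNA =
    length * max(0, total_copies - 2) per sample.
    """
    track_het, track_hom = tracks
    b_het, b_hom = baselines
    if b_het <= 0 or b_hom <= 0:
        raise ValueError("zero baseline")
    out = []
    L = track_het.depth.size
    for s, e in calls:
        if not 0 <= s < e <= L:
            raise ValueError(f"call ({s}, {e}) outside reference [0, {L})")
        md_het = float(track_het.depth[s:e].mean())
        md_hom = float(track_hom.depth[s:e].mean())
        tc_het = 2.0 * md_het / b_het
        tc_hom = 2.0 * md_hom / b_hom
        per_wild = tc_hom / 2.0
        per_re = tc_het - per_wild
        if per_re < 0:
            warnings.warn(
                f"interval ({s}, {e}): negative per-homolog rearranged "
                f"estimate {per_re:.3f} clipped to 0",
                stacklevel=2,
            )
            per_re = 0.0
        out.append(CNVCall(
            interval=(s, e),
            mean_depth_hom=md_hom, mean_depth_het=md_het,
            total_copies_hom=tc_hom, total_copies_het=tc_het,
            per_homolog_wild=per_wild, per_homolog_rearranged=per_re,
            extra_dna_hom_bp=(e - s) * max(0.0, tc_hom - 2.0),
            extra_dna_het_bp=(e - s) * max(0.0, tc_het - 2.0),
        ))
    return out


def cumulative_extra_dna(calls: list[CNVCall]) -> tuple[float, float]:
    """(hom, het) totals of extra DNA across calls, in bp."""
    return (sum(c.extra_dna_hom_bp for c in calls),
            sum(c.extra_dna_het_bp for c in calls))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class DepthCNVResult:
    calls: list[CNVCall]
    intervals: list[tuple[int, int]]
    track_het: DepthTrack
    track_hom: DepthTrack
    baseline_het: float
    baseline_hom: float
    alignments_het: AlignmentSet = field(repr=False, default=None)
    alignments_hom: AlignmentSet = field(repr=False, default=None)


def depth_cnv_pipeline(
    reads_het: ReadSet,
    reads_hom: ReadSet,
    reference: str,
    seed_k: int = 21,
    min_ratio: float = 1.5,
    window: int = 1000,
    merge_gap: int = 1000,
    seed: int = 0,
) -> DepthCNVResult:
    """Map, build depth, call and quantify with a two-pass baseline.

    Pass one computes baselines with no mask; candidate calls from that
    pass are masked out before the final baseline is taken, which removes
    the residual upward bias of amplified intervals.
    """
    index = ReferenceIndex(reference, seed_k)
    aln_het = map_reads(reads_het, reference, seed_k, seed=seed, index=index)
    aln_hom = map_reads(reads_hom, reference, seed_k, seed=seed + 1, index=index)
    track_het, b_het = build_depth_track(aln_het)
    track_hom, b_hom = build_depth_track(aln_hom)
    candidate = call_cnv_intervals(track_het, track_hom, (b_het, b_hom),
                                   min_ratio, window, merge_gap)
    if candidate:
        try:
            _, b_het = build_depth_track(aln_het, mask=candidate)
            _, b_hom = build_depth_track(aln_hom, mask=candidate)
        except ValueError:
            pass  # candidates covered everything; keep pass-one baselines
    intervals = call_cnv_intervals(track_het, track_hom, (b_het, b_hom),
                                   min_ratio, window, merge_gap)
    calls = quantify_cnvs(intervals, (track_het, track_hom), (b_het, b_hom))
    return DepthCNVResult(
        calls=calls, intervals=intervals,
        track_het=track_het, track_hom=track_hom,
        baseline_het=b_het, baseline_hom=b_hom,
        alignments_het=aln_het, alignments_hom=aln_hom,
    )
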