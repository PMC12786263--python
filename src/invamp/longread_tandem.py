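"""Long-read annotation of amplified sequences and the multicopy locus.

Query sequences (CNV consensus, repeat unit, locus flanks) are located on
each long read by exact-seed, ungapped extension on the seed diagonal;
short (< 200 bp) and low-identity (< 80%) fragments are discarded, and
redundant hits are removed by greedy longest-first acceptance in which a
new hit is dropped when at least 80% of its length is already covered by
accepted hits.  Consecutive same-orientation unit hits with negligible
spacing merge into head-to-tail tandem arrays; reads anchored by both
locus flanks yield the units-per-copy histogram, an anchor-offset majority
consensus, and the premature-stop screen over the annotated coding exon.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq

SEED_LEN = 15
_XDROP = 10
_MATCH = 1
_MISMATCH = -2


@dataclass(frozen=True)
class Hit:
    read_id: str
    read_interval: tuple[int, int]
    query_id: str
    identity: float
    orientation: str            # '+' | '-'
    query_interval: tuple[int, int] = (0, 0)

    @property
    def length(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


@dataclass
class TandemArray:
    read_id: str
    unit_count: int
    span: int
    head_to_tail: bool
    orientation: str
    read_interval: tuple[int, int]


@dataclass
class LocusModel:
    consensus: str
    unit_count_histogram: dict[int, int]
    stop_fraction: float | None
    exon_annotation: list[tuple[int, int, str]]
    n_anchored_reads: int = 0


# ---------------------------------------------------------------------------
# seed-and-extend hit finding
# ---------------------------------------------------------------------------

def _read_seed_index(read_arr: np.ndarray):
    codes = _seq.kmer_codes(read_arr, SEED_LEN)
    order = np.argsort(codes, kind="stable")
    return codes[order], order


def _extend_diagonal(read_arr, query_arr, diag, q_lo, q_hi):
    """Greedy ungapped extension with X-drop on one diagonal.

    (q_lo, q_hi) is the seed-covered query interval; read position of
    query index q is diag + q.  Returns (q_lo, q_hi, matches) after
    extension, counting matches over the final extent.
    """
    n_r, n_q = read_arr.size, query_arr.size
    # left extension
    best, score = q_lo, 0
    q = q_lo - 1
    while q >= 0 and diag + q >= 0:
        score += _MATCH if read_arr[diag + q] == query_arr[q] else _MISMATCH
        if score > 0:
            best, score = q, 0
        elif score < -_XDROP:
            break
        q -= 1
    q_lo = best
    # right extension
    best, score = q_hi, 0
    q = q_hi
    while q < n_q and diag + q < n_r:
        score += _MATCH if read_arr[diag + q] == query_arr[q] else _MISMATCH
        if score > 0:
            best, score = q + 1, 0
        elif score < -_XDROP:
            break
        q += 1
    q_hi = best
    matches = int((read_arr[diag + q_lo: diag + q_hi] ==
                   query_arr[q_lo:q_hi]).sum())
    return q_lo, q_hi, matches


def find_hits(
    read: str,
    queries: dict[str, str],
    min_len: int = 200,
    min_identity: float = 0.80,
    read_id: str = "read",
) -> list[Hit]:
    """Local matches of every query on both strands of the read.

    Each cluster of co-diagonal seed matches is extended independently, so
    tandem copies of a query produce one hit per copy; adjacent or
    gap-separated hits stay distinct.
    """
    if not queries:
        raise ValueError("queries must be nonempty")
    read_arr = _seq.encode(read)
    if read_arr.size < SEED_LEN:
        return []
    sorted_codes, order = _read_seed_index(read_arr)

    hits: list[Hit] = []
    for qid, qseq in queries.items():
        for orient, qs in (("+", qseq), ("-", _seq.revcomp(qseq))):
            q_arr = _seq.encode(qs)
            if q_arr.size < SEED_LEN:
                continue
            q_codes = _seq.kmer_codes(q_arr, SEED_LEN)
            lo = np.searchsorted(sorted_codes, q_codes, side="left")
            hi = np.searchsorted(sorted_codes, q_codes, side="right")
            take = np.flatnonzero(hi > lo)
            if take.size == 0:
                continue
            rpos_list, qpos_list = [], []
            for q_i in take:
                rp = order[lo[q_i]:hi[q_i]]
                rpos_list.append(rp)
                qpos_list.append(np.full(rp.size, q_i, dtype=np.int64))
            rpos = np.concatenate(rpos_list)
            qpos = np.concatenate(qpos_list)
            diags = rpos - qpos
            seen: set[tuple[int, int]] = set()
            for d in np.unique(diags):
                sel = diags == d
                q_lo = int(qpos[sel].min())
                q_hi = int(qpos[sel].max()) + SEED_LEN
                q_lo, q_hi, matches = _extend_diagonal(
                    read_arr, q_arr, int(d), q_lo, q_hi)
                length = q_hi - q_lo
                if length < min_len:
                    continue
                identity = matches / length
                if identity < min_identity:
                    continue
                r_iv = (int(d) + q_lo, int(d) + q_hi)
                if orient == "+":
                    q_iv = (q_lo, q_hi)
                else:
                    q_iv = (q_arr.size - q_hi, q_arr.size - q_lo)
                key = (r_iv[0], r_iv[1])
                if (qid, orient, key) in seen:
                    continue
                seen.add((qid, orient, key))
                hits.append(Hit(read_id=read_id, read_interval=r_iv,
                                query_id=qid, identity=identity,
                                orientation=orient, query_interval=q_iv))
    return hits


# ---------------------------------------------------------------------------
# greedy non-redundant acceptance
# ---------------------------------------------------------------------------

def _overlap_with_union(iv: tuple[int, int],
                        union: list[tuple[int, int]]) -> int:
    s, e = iv
    return sum(max(0, min(e, ue) - max(s, us)) for us, ue in union)


def _union_add(union: list[tuple[int, int]], iv: tuple[int, int]) -> None:
    union.append(iv)
    union.sort()
    merged = [union[0]]
    for s, e in union[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    union[:] = merged


def dedupe_hits(hits: list[Hit], max_overlap: float = 0.8) -> list[Hit]:
    """Greedy longest-first acceptance of hits on one read.

    Hits are taken in decreasing length (ties: read start, then query id);
    a hit is discarded when >= max_overlap of its length already lies
    inside the union of accepted hit intervals.
    """
    ordered = sorted(hits, key=lambda h: (-h.length, h.read_interval[0],
                                          h.query_id))
    accepted: list[Hit] = []
    union: list[tuple[int, int]] = []
    for h in ordered:
        ov = _overlap_with_union(h.read_interval, union)
        if h.length > 0 and ov >= max_overlap * h.length:
            continue
        accepted.append(h)
        _union_add(union, h.read_interval)
    return accepted


# ---------------------------------------------------------------------------
# tandem arrays and co-occurrence
# ---------------------------------------------------------------------------

def annotate_arrays(
    accepted_hits: list[Hit],
    unit_length: int,
    unit_query_id: str = "unit",
    max_gap_frac: float = 0.2,
) -> tuple[list[TandemArray], pd.DataFrame]:
    """Merge consecutive unit hits into head-to-tail arrays; count co-reads.

    Unit hits on one read with the same orientation and inter-hit gap
    <= max_gap_frac * unit_length form one TandemArray whose unit_count is
    the number of merged hits.  The co-occurrence matrix counts, for every
    query pair, the reads containing hits of both.
    """
    by_read: dict[str, list[Hit]] = {}
    for h in accepted_hits:
        by_read.setdefault(h.read_id, []).append(h)

    arrays: list[TandemArray] = []
    qids = sorted({h.query_id for h in accepted_hits})
    co = pd.DataFrame(0, index=qids, columns=qids, dtype=int)
    max_gap = max_gap_frac * unit_length

    for rid, rhits in by_read.items():
        present = sorted({h.query_id for h in rhits})
        for a in present:
            for b in present:
                co.loc[a, b] += 1
        unit_hits = sorted((h for h in rhits if h.query_id == unit_query_id),
                           key=lambda h: h.read_interval[0])
        run: list[Hit] = []
        for h in unit_hits + [None]:
            if h is not None and (
                not run
                or (h.orientation == run[-1].orientation
                    and h.read_interval[0] - run[-1].read_interval[1] <= max_gap)
            ):
                run.append(h)
                continue
            if run:
                s = run[0].read_interval[0]
                e = run[-1].read_interval[1]
                arrays.append(TandemArray(
                    read_id=rid, unit_count=len(run), span=e - s,
                    head_to_tail=len(run) > 1,
                    orientation=run[0].orientation,
                    read_interval=(s, e),
                ))
            run = [h] if h is not None else []
    return arrays, co


# ---------------------------------------------------------------------------
# locus reconstruction
# ---------------------------------------------------------------------------

def _anchored_segment(read: str, hits: list[Hit]):
    """(start, end, orientation, unit_count) of a flank-anchored locus copy.

    Requires one flank_left and one flank_right hit in the same orientation
    arranged consistently (left before right for '+', after for '-').
    Returns None if the read is not anchored.
    """
    lefts = [h for h in hits if h.query_id == "flank_left"]
    rights = [h for h in hits if h.query_id == "flank_right"]
    units = [h for h in hits if h.query_id == "unit"]
    for hl in sorted(lefts, key=lambda h: h.read_interval[0]):
        for hr in sorted(rights, key=lambda h: h.read_interval[0]):
            if hl.orientation != hr.orientation:
                continue
            o = hl.orientation
            if o == "+" and hl.read_interval[1] <= hr.read_interval[0]:
                s, e = hl.read_interval[0], hr.read_interval[1]
            elif o == "-" and hr.read_interval[1] <= hl.read_interval[0]:
                s, e = hr.read_interval[0], hl.read_interval[1]
            else:
                continue
            n_units = sum(1 for h in units
                          if s <= h.read_interval[0] and h.read_interval[1] <= e)
            return s, e, o, n_units
    return None


def reconstruct_locus(
    reads: list[str],
    flank_left: str,
    flank_right: str,
    unit: str,
    exon2: tuple[int, int] | None = None,
    min_len: int = 200,
    min_identity: float = 0.80,
) -> LocusModel:
    """Locus model from reads anchored by both flanks.

    The units-per-read histogram covers every anchored read; the consensus
    is a per-column majority vote over single-unit reads aligned at their
    flank_left anchor (exact for error-free reads).  When ``exon2`` (an
    interval relative to the locus copy start, frame 0) is given, each
    anchored read is screened for a premature stop codon and
    ``stop_fraction`` is the flagged fraction.
    """
    queries = {"flank_left": flank_left, "flank_right": flank_right,
               "unit": unit}
    histogram: Counter[int] = Counter()
    segments: list[str] = []
    exon_seqs: list[str] = []

    for i, read in enumerate(reads):
        hits = dedupe_hits(find_hits(read, queries, min_len, min_identity,
                                     read_id=f"read{i}"))
        anchored = _anchored_segment(read, hits)
        if anchored is None:
            continue
        s, e, o, n_units = anchored
        seg = read[s:e]
        if o == "-":
            seg = _seq.revcomp(seg)
        histogram[n_units] += 1
        if n_units == 1:
            segments.append(seg)
        if exon2 is not None:
            exon_seqs.append(seg)

    if not histogram:
        warnings.warn("no flank-anchored reads; empty locus model",
                      stacklevel=2)
        return LocusModel(consensus="", unit_count_histogram={},
                          stop_fraction=None, exon_annotation=[],
                          n_anchored_reads=0)

    consensus = ""
    if segments:
        width = min(len(s) for s in segments)
        mat = np.stack([_seq.encode(s[:width]) for s in segments])
        counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
        maj = counts.argmax(axis=0).astype(np.uint8)
        consensus = _seq.decode(maj)

    stop_fraction = None
    exon_annotation: list[tuple[int, int, str]] = []
    if exon2 is not None:
        exon_annotation = [(exon2[0], exon2[1], "exon2")]
        flags = [
            copy_has_premature_stop(s, exon2) for s in exon_seqs
            if len(s) >= exon2[1]
        ]
        stop_fraction = (sum(flags) / len(flags)) if flags else None

    return LocusModel(consensus=consensus,
                      unit_count_histogram=dict(sorted(histogram.items())),
                      stop_fraction=stop_fraction,
                      exon_annotation=exon_annotation,
                      n_anchored_reads=sum(histogram.values()))


# ---------------------------------------------------------------------------
# premature-stop screen
# ---------------------------------------------------------------------------

def copy_has_premature_stop(seq: str, exon: tuple[int, int],
                            frame: int = 0) -> bool:
    """True iff an in-frame stop codon starts before the exon's end.

    The codon walk starts at exon_start + frame and steps by 3; only full
    codons inside the exon are considered, so an out-of-frame stop
    straddling a codon boundary never flags.
    """
    s, e = exon
    if e - s < 3:
        raise ValueError(f"exon ({s}, {e}) shorter than one codon")
    for i in range(s + frame, e - 2, 3):
        if seq[i:i + 3].upper() in ("TAA", "TAG", "TGA"):
            return True
    return False


def screen_stop_codons(
    copies: list[str],
    exon_annotation: tuple[int, int],
    reference_frame: int = 0,
) -> tuple[float, list[bool]]:
    """Premature-stop fraction over locus copies (or locus-spanning reads).

    Each sequence is interpreted in locus-copy coordinates: the annotated
    exon interval indexes directly into it.
    """
    if not copies:
        raise ValueError("no copies to screen")
    flags = [copy_has_premature_stop(c, exon_annotation, reference_frame)
             for c in copies]
    return sum(flags) / len(flags), flags
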