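"""Differential k-mer discovery of unassembled amplified sequence.

Pipeline: take read pairs where exactly one mate maps to the reference
(the unmapped mate then comes from sequence adjacent to, but missing from,
the assembly), count canonical k-mers of those unmapped mates in the
heterozygous and homozygous samples, keep k-mers whose depth-normalized
abundance ratio favours the heterozygote, and chain the survivors through
their (k-1)-overlaps.  A tandem repeat unit shows up as a single simple
cycle in that graph; its length equals the number of k-mers on the cycle,
independent of k.

Canonical means the lexicographic minimum of a k-mer and its reverse
complement, so counts are strand-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from . import _seq
from .align_depth import AlignmentSet, ReferenceIndex, map_reads
from .simulate import ReadSet


class GraphBranchError(ValueError):
    """Overlap graph has no unique path/cycle; carries the branch k-mers."""

    def __init__(self, branches: list[str]):
        self.branches = branches
        super().__init__(
            "k-mer overlap graph branches at: " + ", ".join(branches[:5])
            + ("..." if len(branches) > 5 else "")
        )


class HalfMappedPairs(NamedTuple):
    sequences: np.ndarray       # (n, read_len) codes of the unmapped mates
    pair_indices: np.ndarray    # indices into the source ReadSet


def extract_half_mapped(alignments: AlignmentSet, reads: ReadSet) -> HalfMappedPairs:
    """Unmapped mates of pairs in which exactly one mate mapped.

    Pairs with both mates mapped or both unmapped are excluded.
    """
    if not alignments.paired:
        raise ValueError("extract_half_mapped requires paired alignments")
    n = reads.n
    if len(alignments) != 2 * n:
        raise ValueError("alignments do not pair up with the read set")
    mapped = np.zeros((n, 2), dtype=bool)
    mapped[alignments.pair_index, alignments.mate - 1] = alignments.mapped
    half = mapped[:, 0] ^ mapped[:, 1]
    idx = np.flatnonzero(half)
    take1 = ~mapped[idx, 0]
    seqs = np.where(take1[:, None], reads.seqs1[idx], reads.seqs2[idx])
    return HalfMappedPairs(sequences=seqs, pair_indices=idx)


# ---------------------------------------------------------------------------
# k-mer tables
# ---------------------------------------------------------------------------

@dataclass
class KmerTable:
    """Canonical k-mer counts stored as sorted packed codes.

    ``total_bases_sequenced`` is the normalization denominator for
    between-sample comparison; by default the bases actually counted, but
    callers typically override it with the full sequencing effort of the
    sample the reads were drawn from.
    """

    k: int
    codes: np.ndarray       # sorted uint64
    counts: np.ndarray      # int64, aligned with codes
    total_bases_sequenced: float

    @property
    def n_distinct(self) -> int:
        return self.codes.size

    def get(self, kmer: str) -> int:
        code = min(_seq.encode_kmer(kmer), _seq.encode_kmer(_seq.revcomp(kmer)))
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def __getitem__(self, kmer: str) -> int:
        c = self.get(kmer)
        if c == 0:
            raise KeyError(kmer)
        return c

    def as_dict(self) -> dict[str, int]:
        return {_seq.decode_kmer(int(c), self.k): int(n)
                for c, n in zip(self.codes, self.counts)}


def count_kmers(
    seqs: Iterable[str] | np.ndarray,
    k: int,
    total_bases: float | None = None,
) -> KmerTable:
    """Canonical k-mer counts over sequences (strings or a code matrix).

    Sequences shorter than k contribute nothing; k-mers containing
    non-ACGT characters are skipped.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    chunks: list[np.ndarray] = []
    nbases = 0
    if isinstance(seqs, np.ndarray) and seqs.ndim == 2:
        nbases = int(seqs.size)
        if seqs.shape[1] >= k:
            codes = _seq.canonical_kmer_codes(seqs, k)
            ok = _seq.valid_windows(seqs, k)
            chunks.append(codes[ok])
    else:
        for s in seqs:
            arr = s if isinstance(s, np.ndarray) else _seq.encode(s)
            nbases += arr.size
            if arr.size < k:
                continue
            codes = _seq.canonical_kmer_codes(arr, k)
            ok = _seq.valid_windows(arr, k)
            chunks.append(codes[ok])
    if chunks:
        allc = np.concatenate(chunks)
        uniq, counts = np.unique(allc, return_counts=True)
    else:
        uniq = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    return KmerTable(
        k=k, codes=uniq, counts=counts.astype(np.int64),
        total_bases_sequenced=float(total_bases if total_bases is not None
                                    else nbases),
    )


def select_enriched_kmers(
    table_het: KmerTable,
    table_hom: KmerTable,
    min_ratio: float = 4.0,
    min_count: int = 5,
) -> set[str]:
    """K-mers over-represented in the heterozygote after depth normalization.

    Keeps k-mers with (c_het / N_het) / ((c_hom + 1) / N_hom) >= min_ratio
    and c_het >= min_count, where N is total_bases_sequenced and the
    pseudocount 1 guards absent k-mers.
    """
    if table_het.k != table_hom.k:
        raise ValueError(
            f"k mismatch: {table_het.k} vs {table_hom.k}"
        )
    if table_het.n_distinct == 0:
        return set()
    n_het = table_het.total_bases_sequenced
    n_hom = table_hom.total_bases_sequenced
    idx = np.searchsorted(table_hom.codes, table_het.codes)
    idx_c = np.minimum(idx, max(table_hom.codes.size - 1, 0))
    if table_hom.codes.size:
        present = table_hom.codes[idx_c] == table_het.codes
        hom_counts = np.where(present, table_hom.counts[idx_c], 0)
    else:
        hom_counts = np.zeros(table_het.codes.size, dtype=np.int64)
    ratio = (table_het.counts / n_het) / ((hom_counts + 1) / n_hom)
    keep = (ratio >= min_ratio) & (table_het.counts >= min_count)
    k = table_het.k
    return {_seq.decode_kmer(int(c), k) for c in table_het.codes[keep]}


# ---------------------------------------------------------------------------
# unit reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ConsensusUnit:
    sequence: str
    circular: bool
    canonical_rotation: str

    @property
    def unit_length(self) -> int:
        return len(self.sequence)

    def equivalent(self, other_seq: str) -> bool:
        """Rotation/strand equivalence against another (circular) sequence."""
        if self.circular:
            return self.canonical_rotation == _seq.canonical_rotation(other_seq)
        return self.sequence in (other_seq, _seq.revcomp(other_seq))


def _collapse_period(seq: str, circular: bool) -> str:
    p = _seq.minimal_cyclic_period(seq) if circular else _seq.minimal_period(seq)
    return seq[:p] if p < len(seq) else seq


def reconstruct_unit(kmers: Iterable[str], k: int) -> list[ConsensusUnit]:
    """Chain k-mers by exact (k-1)-overlap into units, one per component.

    Every canonical k-mer is expanded to both orientations; walking unique
    successors yields either a simple cycle (a circular tandem-repeat unit,
    reported in canonical rotation and collapsed to its minimal period) or
    a simple path (a linear contig).  Any branch point aborts with
    ``GraphBranchError`` listing the offending k-mers.
    """
    canon = set()
    for s in kmers:
        if len(s) != k:
            raise ValueError(f"k-mer {s!r} is not of length {k}")
        canon.add(min(s, _seq.revcomp(s)))
    if not canon:
        raise ValueError("empty k-mer set")

    oriented: set[str] = set()
    for s in canon:
        oriented.add(s)
        oriented.add(_seq.revcomp(s))
    by_prefix: dict[str, list[str]] = {}
    for s in oriented:
        by_prefix.setdefault(s[: k - 1], []).append(s)

    def successors(s: str) -> list[str]:
        return [t for t in by_prefix.get(s[1:], ()) if t != s]

    def predecessors(s: str) -> list[str]:
        suf = s[: k - 1]
        return [t for t in oriented if t[1:] == suf and t != s]

    units: list[ConsensusUnit] = []
    used: set[str] = set()
    branches: list[str] = []
    for start in sorted(canon):
        if start in used:
            continue
        # walk forward
        chain = [start]
        chain_set = {start}
        circular = False
        cur = start
        while True:
            nxt = [t for t in successors(cur) if min(t, _seq.revcomp(t)) in canon]
            if len(nxt) > 1:
                branches.append(cur)
                break
            if not nxt:
                break
            t = nxt[0]
            if t == start:
                circular = True
                break
            if t in chain_set or _seq.revcomp(t) in chain_set:
                break  # self-collision (palindromic fold-back); treat as end
            chain.append(t)
            chain_set.add(t)
            cur = t
        if not circular and not branches:
            # extend backward from the start for linear contigs
            cur = start
            while True:
                prv = [t for t in predecessors(cur)
                       if min(t, _seq.revcomp(t)) in canon]
                if len(prv) > 1:
                    branches.append(cur)
                    break
                if not prv:
                    break
                t = prv[0]
                if t in chain_set or _seq.revcomp(t) in chain_set:
                    break
                chain.insert(0, t)
                chain_set.add(t)
                cur = t
        if branches:
            break
        for s in chain:
            used.add(min(s, _seq.revcomp(s)))
        if circular:
            seq = "".join(s[0] for s in chain)
            seq = _collapse_period(seq, circular=True)
            units.append(ConsensusUnit(
                sequence=seq, circular=True,
                canonical_rotation=_seq.canonical_rotation(seq),
            ))
        else:
            seq = chain[0] + "".join(s[-1] for s in chain[1:])
            seq = _collapse_period(seq, circular=False)
            units.append(ConsensusUnit(
                sequence=seq, circular=False,
                canonical_rotation=_seq.canonical_rotation(seq)
                if len(seq) else seq,
            ))
    if branches:
        raise GraphBranchError(sorted(set(branches)))
    return units


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    units: list[ConsensusUnit]          # best-supported first
    selected_kmers: set[str]
    table_het: KmerTable
    table_hom: KmerTable


def discover_repeat_unit(
    reads_het: ReadSet,
    reads_hom: ReadSet,
    reference: str,
    k: int = 31,
    seed_k: int = 21,
    min_ratio: float = 4.0,
    min_count: int = 5,
    seed: int = 0,
    index: ReferenceIndex | None = None,
) -> DiscoveryResult:
    """Half-mapped extraction -> differential k-mers -> unit reconstruction.

    Units are ordered by (circular first, then total supporting k-mer count
    in the heterozygote), so ``units[0]`` is the best candidate repeat.
    """
    if index is None:
        index = ReferenceIndex(reference, seed_k)
    aln_het = map_reads(reads_het, reference, seed_k, seed=seed, index=index)
    aln_hom = map_reads(reads_hom, reference, seed_k, seed=seed + 1, index=index)
    hm_het = extract_half_mapped(aln_het, reads_het)
    hm_hom = extract_half_mapped(aln_hom, reads_hom)
    t_het = count_kmers(hm_het.sequences, k, total_bases=reads_het.total_bases)
    t_hom = count_kmers(hm_hom.sequences, k, total_bases=reads_hom.total_bases)
    selected = select_enriched_kmers(t_het, t_hom, min_ratio, min_count)
    units: list[ConsensusUnit] = []
    if selected:
        units = reconstruct_unit(selected, k)

        def support(u: ConsensusUnit) -> int:
            s = u.sequence + (u.sequence[: k - 1] if u.circular else "")
            arr = _seq.encode(s)
            if arr.size < k:
                return 0
            codes = _seq.canonical_kmer_codes(arr, k)
            idx = np.searchsorted(t_het.codes, codes)
            idx = np.minimum(idx, max(t_het.codes.size - 1, 0))
            ok = t_het.codes.size and (t_het.codes[idx] == codes)
            return int(t_het.counts[idx][ok].sum()) if t_het.codes.size else 0

        units.sort(key=lambda u: (not u.circular, -support(u)))
    return DiscoveryResult(units=units, selected_kmers=selected,
                           table_het=t_het, table_hom=t_hom)
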