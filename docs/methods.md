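# Methods

`invamp` models and analyses a single-chromosome structural polymorphism of
the kind seen in wild bird populations: a standard haplotype (S) and a
rearranged haplotype (M) that differ by a large paracentric inversion on one
arm and by massive tandem amplification of several loci on the other,
including a multicopy gene-like locus carrying a nested ~630 bp repeat unit
that is missing from the mapping reference. The package provides (i) a
generator that plants such a rearrangement with full ground truth, and (ii)
the detection/quantification stages a sequencing study of the polymorphism
would run: read-depth copy-number analysis, differential k-mer discovery of
the unassembled repeat, long-read tandem-array and locus annotation,
contact-map inversion breakpoint detection, and the population/cytogenetic
statistics.

## Simulation model

A chromosome backbone of length `L` is drawn i.i.d. uniform over ACGT.
Uniform composition keeps accidental k-mer collisions negligible at k >= 21,
so repeat-unit identity is exact by construction. Three sequences share the
backbone:

* **wild-type haplotype** — backbone plus, at each CNV block position,
  `copies_wildtype` head-to-tail copies of a randomly drawn unit;
* **rearranged haplotype** — same with `copies_rearranged`, then the
  inversion interval reverse-complemented (the inversion may not overlap an
  insertion; configurations that try are rejected);
* **mapping reference** — backbone with each block either *collapsed* to a
  single unit copy (the classic collapsed-repeat situation) or *absent*
  entirely (novel, unassembled sequence).

The gene-like locus is a special insertion: each copy is
`flank_left + unit x k + flank_right`, with `k` varying per copy. "Exon 2"
sits inside the left flank and "exon 3" inside the unit; both are generated
from non-stop codons so that a planted premature stop (one in-frame codon of
exon 2 replaced by TAA, drawn per copy as Bernoulli(stop_variant_fraction)
or fixed via explicit flags) is the only in-frame terminator. An optional
divergent-first-unit flag substitutes a few bases of the first unit of each
copy outside exon 3.

Coordinates are 0-based half-open everywhere; all randomness flows through a
single integer seed and identical configurations reproduce identical bytes.

### Reads

Short reads are error-free 150 bp pairs by default (a uniform substitution
rate is available for robustness experiments; none of the shipped analyses
use it). Pair count is `floor(coverage * genome_len / (2 * read_len))` with
`genome_len` the mean haplotype length for heterozygotes. Heterozygote pairs
are allocated **deterministically in proportion to haplotype length**, so
each homolog receives exactly `coverage / 2` per-position depth however much
the rearrangement lengthened it; an equal *pair-count* split would dilute
the longer haplotype and systematically underestimate heterozygous copy
numbers.

* `wgs` mode draws fixed-insert (default 500 bp) proper pairs.
* `ligation` mode emulates proximity-ligation contact decay: the second
  mate lands at distance `d` with `P(d) proportional to d^-alpha`, default
  `alpha = 1` on `[1 kb, L)`, truncated by rejection at the chromosome ends.
  The decay exponent and minimum distance are not dictated by the emulated
  protocol, so the defaults are the generic power-law used throughout the
  contact-map literature.

Long reads are forward-strand substrings with lengths
`min + Exponential(mean - min)` (default 20 kb mean, 5 kb minimum); total
bases land within 2% of the coverage target. A `spanning` option plants
guaranteed locus-spanning reads (one per requested unit count, or one per
locus copy) so flank-anchored analyses can be tested exactly.

### What the generator does not emulate

GC bias, indel/chimeric errors, restriction-site-aware ligation
fragmentation, diploid SNP heterozygosity outside the planted variants, and
mapping-quality artefacts. Recovery results on this synthetic data therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to real-data noise; the error-rate knob and the identity
threshold of the long-read aligner are the entry points for stress testing.

## Read-depth copy numbers

The mapper is an exact-substring aligner appropriate for error-free reads: a
read is mapped iff it occurs verbatim in the reference or its reverse
complement, located via a sorted index of every reference `seed_k`-mer
(default 21) and verified by full comparison. Reads matching several
positions — reads from a collapsed repeat — are assigned one position
uniformly at random (seeded), mirroring the default behaviour of standard
aligners, so depth over the single collapsed copy accumulates every
repeat-derived read.

The baseline is the **median** per-position depth outside masked intervals.
The median rather than the mean is used for robustness to residual CNVs
(`baseline_mean` is available); the pipeline recomputes the baseline once
after a first calling pass, masking candidate calls — two passes suffice on
synthetic data. CNV windows (default 1 kb) are flagged when normalized
het/hom depth ratio >= `min_ratio` (default 1.5, the floor at which a
single-copy gain per homolog is detectable) or when hom normalized depth
itself exceeds `min_ratio` (amplification already present on the wild-type
chromosome); the ratio denominator is floored at 0.25x diploid so
near-empty windows cannot fabricate ratios. Flagged windows merge across
gaps <= `merge_gap` (default 1 kb).

For a called interval, `total_copies = 2 * mean_depth / baseline` per
sample; per-homolog wild = hom total / 2; per-homolog rearranged = het total
minus that (clipped at zero with a warning); extra DNA =
`length * max(0, total_copies - 2)` per sample, and cumulative extra DNA is
the sum over calls. Because the unit of a tandem block is represented once
in the reference, reads spanning copy junctions cannot map and depth is
biased low by roughly `read_len / unit_length`; with blocks >= 5 kb this is
~3%, well inside the 10% recovery tolerance the tests enforce.

## Differential k-mer discovery

Pairs in which exactly one mate maps are the signature of sequence adjacent
to unassembled loci; the unmapped mates are collected and their canonical
k-mers (lexicographic min of k-mer and reverse complement; A<C<G<T ordering
makes this integer comparison on 2-bit packed codes) counted. Default
`k = 31`: error-free synthetic data needs no longer k for specificity, and
31 is the largest k that packs into 64 bits; reconstruction itself accepts
any k, and a scan over k in {21, 31, 41, 80} is tested to give identical
units after period collapse.

Enrichment is deterministic rather than a hypothesis test (no sensible
error model exists for error-free counts): keep k-mers with

    (c_het / N_het) / ((c_hom + 1) / N_hom) >= min_ratio   and   c_het >= min_count

with `N` the total bases sequenced in the sample, pseudocount 1 for absent
k-mers, `min_ratio = 4` (half the 8-fold true abundance ratio of the
20-vs-400-copies-per-homolog scenario, leaving margin for the mate-pair
escape effect: a mate of a read inside a long array often lands inside the
array too, and such both-unmapped pairs are excluded) and `min_count = 5`
(about a sixth of the expected per-position count) to suppress sporadic
junction k-mers.

Selected k-mers are chained by exact (k-1)-overlap, walking unique
successors over both orientations. A simple cycle is a circular tandem-repeat
unit whose length equals the number of k-mers on the cycle; a simple path is
a linear contig; branching aborts with the branch k-mers listed; several
components yield one unit each, ordered circular-first then by total
supporting het count. Units are collapsed to their minimal string period
(so `k > unit_length` still returns the true unit) and circular units are
identified by their canonical rotation — the lexicographic minimum over all
rotations of both strands — making unit equality testable independent of
phase and strand. This graph-chaining consensus replaces a manual
multiple-alignment consensus; on error-free data the two agree by
construction.

## Long-read annotation

Queries (CNV consensus sequences, the repeat unit, locus flanks) are located
on reads by exact 15-mer seeds grouped by diagonal, each diagonal extended
ungapped with X-drop 10 (match +1, mismatch -2). Gapped extension is
deliberately omitted: the generator plants substitution divergence only, so
ungapped per-diagonal extension is exact here and keeps the aligner small;
hits below 200 bp or 80% identity are discarded. Tandem copies produce one
hit per copy (adjacent or gap-separated hits stay distinct).

Redundant hits are removed greedily: sort by decreasing length (ties by read
start, then query id) and discard any hit whose interval is already >= 80%
covered by the union of accepted hits. Consecutive same-orientation unit
hits with inter-hit gap <= 0.2 x unit length merge into a head-to-tail
tandem array with `unit_count` = number of merged hits; a query-pair
co-occurrence matrix counts reads containing both queries.

A read is locus-anchored when both flanks occur in consistent orientation;
the units-per-read histogram is taken over anchored reads, and the locus
consensus is a per-column majority vote over single-unit reads aligned at
their left-flank anchor (exact on error-free reads). The premature-stop
screen walks codons from the annotated exon start (frame 0 by default) and
flags a copy iff an in-frame TAA/TAG/TGA begins before the exon end —
out-of-frame stops straddling codon boundaries never flag.

## Contact-map inversion detection

Fully mapped ligation pairs increment both symmetric cells of a binned
matrix (matrix total = 2x pair count). The observed/expected normalization
divides each cell by the mean contact at its bin distance.

A heterozygous inversion with breakpoints (b1, b2) shows the butterfly
pattern: on the inverted haplotype a position just inside b2 is physically
adjacent to b1, so after mapping to the non-inverted reference the two
anti-diagonal quadrants flanking the (b1, b2) corner are enriched while the
two off-quadrants are not. Each 5x5-bin quadrant is scored by its Poisson
surprise `(O - E) / sqrt(E + 1)` against the decay expectation, and the
corner score is the contrast `z(UL) + z(LR) - z(UR) - z(LL)`. The
variance-stabilized form matters: at 1e5 pairs and 100 kb bins, long-range
cells hold ~5-20 counts and a plain mean of per-cell O/E is noise-dominated;
the subtracted off-quadrants sharpen localization, since shifting the
candidate corner by one bin moves enriched cells into a subtracted quadrant.

Detection maximizes `S = Z_het - Z_hom` over all bin pairs separated by at
least 10 bins. The call threshold is permutation-calibrated on the
homozygote map: 200 batches, each drawing one grid's worth of differences of
`Z_hom` at shuffled candidate pairs, and the threshold is the 99th
percentile of the batch *maxima* — a family-wise calibration across the
~2,000-pair grid (a per-pair percentile would false-call almost surely).
Breakpoints are reported as the argmax bin edges with one-bin tolerance;
sub-bin precision is out of scope.

## Population and cytogenetic statistics

* **Frequencies.** Heterozygote frequency over N individuals; rearranged-
  allele frequency over 2N chromosomes. The sampling error uses the
  sample-variance denominator, `sqrt(p(1-p) / (N - 1))`, the convention that
  reproduces the reference cytotype table cell-for-cell at printed
  precision (`ddof=0` gives the plain binomial form). Table reporting
  rounds half away from zero: frequencies and SEs to 2 decimals, chi-square
  and p to 1.
* **Hardy-Weinberg.** Pearson chi-square of the three genotype classes
  against `N * (p^2, 2pq, q^2)` at the estimated allele frequency, df = 1,
  no continuity correction; monomorphic samples return chi2 = 0, p = 1 by
  convention.
* **Contingency.** Pearson 2x2 chi-square, Yates correction off by default.
* **Crossover maps.** Focus positions are rescaled to the mean SC length,
  binned into `round(mean_length / target_bin)` equal intervals (default
  target 1 um, top edge inclusive), reported as per-bin focus proportions
  overall and stratified by foci-per-bivalent class (1-5); a
  centromere-centred axis is available since either axis convention is
  defensible.
* **Mann-Whitney U.** Midrank ties; exact enumeration over all
  `C(n1+n2, n1)` assignments when `n1 + n2 <= 12` (valid under ties),
  otherwise the normal approximation with tie-corrected variance and
  continuity correction, which keeps |delta p| <= 0.05 against the exact
  mode at n1 = n2 = 6.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
repeat-unit discovery on a 5 Mb chromosome (unit at 20 vs 400 copies per
homolog, 30x ligation coverage, 20 and 10 seeds respectively); copy-number
recovery over 100 planted blocks (5-8 kb units, per-homolog copies 1-5 wild
/ 1-45 rearranged, 30x) on 420 kb backbones; inversion detection on a 7 Mb
chromosome (breakpoints 350 kb and 5,687.3 kb — a tenth of the scale the
design is aimed at — 100 kb bins, 1e5 pairs per map). These sizes were
chosen as the smallest at which the statistical regime of each method
(enrichment ratios, junction-loss fraction, long-range contact sparsity) is
representative.

## Known limitations

* The exact-match mapper has no concept of partial alignment; reads
  spanning novel-insertion junctions are simply unmapped. This is the
  intended signal for half-mapped extraction but makes depth near block
  edges conservative.
* The k-mer enrichment rule is a deterministic stand-in; with sequencing
  errors it would need count-error modelling and the de Bruijn chaining
  would need tip/bubble cleaning.
* The long-read aligner is substitution-aware only (no gapped extension).
* Contact maps are unbalanced (no matrix-balancing step); the decay
  normalization alone is adequate for the uniform-composition simulations.
* One inversion per chromosome is assumed; nested or multiple inversions
  produce overlapping butterflies the grid search does not disentangle.
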