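# invamp

Simulation and analysis of complex **inversion + amplification** chromosome
rearrangements, of the kind segregating in wild bird populations: a
rearranged haplotype carrying a multi-megabase paracentric inversion on one
arm and massive tandem copy-number expansion on the other, including a
multicopy gene-like locus with a nested ~630 bp repeat unit that is absent
from the mapping reference.

The package is aimed at people developing or teaching structural-variant
methods: every analysis stage a sequencing study of such a polymorphism
would run is implemented against a ground-truth simulator, so each
estimator can be scored exactly.

## What it does

| module | analysis |
|---|---|
| `invamp.simulate` | diploid haplotype pair (inversion, tandem CNV blocks, multicopy locus with nested repeat and plantable premature stops), WGS / proximity-ligation / long reads, truth tables, FASTA/FASTQ/JSON fixtures |
| `invamp.align_depth` | exact-match short-read mapper, depth tracks, CNV calling by het/hom depth contrast, copy numbers and extra DNA |
| `invamp.kmer_discovery` | half-mapped-pair extraction, canonical k-mer counting, differential enrichment, de Bruijn reconstruction of the repeat unit |
| `invamp.longread_tandem` | seed-and-extend hits, greedy non-redundant acceptance, head-to-tail array counting, flank-anchored locus model, premature-stop screen |
| `invamp.hic_inversion` | binned contact maps, distance-decay normalization, butterfly-score inversion breakpoint detection |
| `invamp.cyto_popstats` | cytotype frequencies with sampling error, Hardy-Weinberg and 2x2 chi-square, crossover (MLH1) recombination maps, Mann-Whitney U |

Core quantities, in the field's usual notation:

* read-depth copy number: `total_copies = 2 * mean_depth / baseline`, with
  the baseline the median depth outside CNVs; extra DNA per CNV =
  `length * max(0, total_copies - 2)`;
* k-mer enrichment: keep canonical k-mers with
  `(c_het/N_het) / ((c_hom+1)/N_hom) >= 4`, then chain (k-1)-overlaps — a
  tandem-repeat unit appears as a simple cycle whose length equals the
  number of k-mers on it;
* Hardy-Weinberg: Pearson chi-square of (n_MM, n_SM, n_SS) against
  `N(p^2, 2pq, q^2)`, df = 1;
* inversion detection: quadrant contrast of Poisson surprises
  `z(UL)+z(LR)-z(UR)-z(LL)` around each candidate breakpoint corner of the
  observed/expected contact map, thresholded by permutation on the
  homozygote map.

## Worked example

Plant a novel 630 bp unit at 20 (wild-type) vs 400 (rearranged) copies per
homolog on a 5 Mb chromosome, sequence both genotypes at 30x in ligation
mode, and rediscover the unit from read data alone:

```python
from invamp import simulate as sim, kmer_discovery as kd

blk = sim.CNVBlock(id="CNV8", position=3_000_000, unit_length=630,
                   copies_wildtype=20, copies_rearranged=400,
                   assembly="absent")          # not in the reference
cfg = sim.SimConfig(chromosome_length=5_000_000, cnv_blocks=[blk], seed=7)
hap, truth = sim.build_haplotypes(cfg)

het = sim.simulate_short_reads(hap, "S/M", coverage=30, mode="ligation", seed=1)
hom = sim.simulate_short_reads(hap, "S/S", coverage=30, mode="ligation", seed=2)
res = kd.discover_repeat_unit(het, hom, hap.reference_seq)

u = res.units[0]
print(len(res.selected_kmers), u.unit_length, u.circular,
      u.equivalent(truth.blocks[0].unit_seq))
```

prints

```
630 630 True True
```

— all 630 canonical 31-mers of the unit (and nothing else) are enriched in
the heterozygote, they chain into a single 630 bp cycle, and the
reconstructed unit is rotation/strand-equivalent to the planted one.

The population statistics reproduce a field sample directly:

```python
from invamp.cyto_popstats import GenotypeCounts, cytotype_frequencies, hwe_test

het, allele = cytotype_frequencies(GenotypeCounts(0, 8, 35))
print(het.rounded(2), allele.rounded(2), round(hwe_test(GenotypeCounts(0, 8, 35)).chi2, 1))
# (0.19, 0.06) (0.09, 0.03) 0.5
```

i.e. 19% +/- 6% heterozygotes, 9% +/- 3% rearranged-chromosome frequency,
and no deviation from Hardy-Weinberg (chi-square 0.5).

A CLI mirrors the library (`invamp simulate`, `invamp depth-cnv`,
`invamp kmer-discover`, `invamp longread-annotate`, `invamp hic-inversion`,
`invamp stats ...`); see `invamp --help`.

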