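# panpav

Presence/absence variation (PAV) analysis for multi-line plant pangenomes:
coverage-based gene-loss calling, combinatorial pangenome size modelling,
mate-pair contig placement, PAV phylogeny placement, coding-SNP and
transposable-element statistics, and resistance-gene clustering — with a
synthetic-pangenome generator that gives every stage a known ground truth.

## Who this is for

Crop and population genomicists working with a reference-anchored pangenome:
several inbred lines or varieties resequenced with paired-end reads and
mapped against a common reference plus newly assembled sequence. The package
answers the standard questions of such a study — which genes are core and
which are dispensable, whether the pangenome is open or closed, where novel
contigs belong on the chromosomes, whether gene losses follow the phylogeny,
and how variable genes differ from core genes in SNP load, TE context and
gene-family structure.

## The methods at the core

**PAV calling.** A gene is called *absent* in a line when the horizontal
coverage of its exons — the fraction of exon bases covered by at least one
properly paired read — is below 5% (strict). Lines are downsampled to a
common ~25× depth at the read-pair level first, and genes on contigs
shorter than 1 kb are excluded. A gene present in every line is *core*;
absent in at least one line, *variable*; present in exactly one line, a
*singleton*.

**Pangenome modelling.** For every subset size *k* of the *N* lines, the
pangenome size (union) and core size (intersection) are averaged over all
C(*N*, *k*) subsets, and the per-*k* means are fitted by nonlinear least
squares: pangenome *y* = *Ax*<sup>*B*</sup> + *C*, core genome
*y* = *Ae*<sup>*Bx*</sup> + *C*. Extrapolation beyond *N* reports a
delta-method standard error.

**Contig placement.** Reads in the terminal 300 bp of a novel contig with
MAPQ ≥ 10, not in proper pairs, both mates mapped, not duplicates, and mates
on another sequence are placement evidence. An end places when ≥ 10 such
reads exist, ≥ 80% of mates hit one chromosome, and those mates span
≤ 1,000 bp; the coordinate is their median. Concordant ends take the lower
coordinate; conflicting ends cancel.

**Downstream statistics.** Homozygous coding SNPs are classified
synonymous / nonsynonymous / nonsense against the spliced CDS; core and
variable gene groups are compared with a two-tailed Mann–Whitney *U* test;
TE load is the TE fraction of the 2 kb windows flanking each gene; gene
PAV patterns are matched to tree clades; NB-ARC-domain (R) genes are
clustered when ≤ 10 genes separate them; ortholog families are enriched
for variable genes by Fisher's exact test (*P* < 0.001).

## Worked example

Generate a six-line synthetic pangenome (500 genes, 15% variable), call
PAV from the simulated 25× alignments, and check the calls against truth:

```python
from panpav import synthetic_data as sd, pav_caller as pc

truth = sd.generate_pangenome(6, 425, 75, seed=42)
per_line = {
    line: [r.to_alignment_record()
           for r in sd.simulate_reads(line, truth, depth=25.0, seed=i)]
    for i, line in enumerate(truth.line_ids)
}
seq_lengths = {c: len(s) for c, s in truth.reference.items()}
pav = pc.call_pav_pipeline(per_line, truth.gene_models, seq_lengths, seed=42)
want = truth.truth_pav.df.loc[pav.df.index, pav.df.columns]
print("mismatches:", int((pav.df.to_numpy() != want.to_numpy()).sum()))
```

```
mismatches: 0
```

The called matrix reproduces the planted deletions exactly: at 25× noiseless
coverage no present gene drops below 5% exon coverage and deleted genes
receive no reads at all. The report stage turns raw counts into the headline
percentages (here with a 49,895 / 11,484 core/variable split):

```bash
$ panpav report --core 49895 --variable 11484 --singleton 1322
Pangenome: 61379 genes
  core:      49895 (81.3%)
  variable:  11484 (18.7%)
  singleton: 1322 (2.2%)
```

A CLI covers the other stages too: `panpav simulate | call | place | model |
stats | phylo | annotate | report` (see `panpav --help`).

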