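# Methods

## Scope and data model

The package analyses a reference-anchored pangenome: one anchoring genome
plus novel contigs, shared gene models (GFF3), per-line read alignments
(SAM), SNP calls (VCF), TE intervals (BED), ortholog groups (OrthoMCL-style
text) and a line phylogeny (newick). All internal coordinates are 1-based
inclusive, the native convention of GFF3 and SAM; BED is converted at the
boundary. Genes use the exons of the first mRNA in file order (CDS features
override exons when present) — isoform choice is a convention, and the
first-transcript rule keeps it deterministic. Aligned reference intervals
come from CIGAR M/=/X operations only; D and N split intervals, I and S
consume no reference.

## PAV calling

Absence is a coverage statement: a gene is absent in a line when the
*horizontal* exon coverage — the fraction of exon bases under at least one
read, depth ignored — is below the absence threshold.

* **Threshold 0.05, strict.** Coverage exactly 5% counts as present.
* **Proper pairs only**, duplicates excluded, before any counting.
* **Pair-level downsampling** to a target depth (default 25×): estimated
  depth is total aligned bases over reference length; when above target,
  each *pair* is kept with probability target/depth, both mates sharing one
  decision so that proper-pair status survives. At or below target the
  input passes through unchanged.
* **Eligibility:** genes on contigs < 1,000 bp are excluded from the matrix
  (short contigs carry unreliable mappings), and no MAPQ filter is applied
  at this stage — MAPQ matters for placement, not for breadth-of-coverage
  presence.
* The anchoring line is treated like any other line.

Classification: core = present in all lines, variable = absent in ≥ 1,
singleton = present in exactly 1. A gene absent everywhere contradicts
pangenome membership and is an error, not a category.

## Pangenome modelling

For each subset size *k*, (pan, core) counts are collected over all
C(*N*, *k*) line subsets — exhaustively up to 15 lines, otherwise a seeded
sample — and fits use the per-*k* means (an all-points mode exists).
Pan-size means are fitted with the power law *y* = *Ax*^*B* + *C*, core
means with the exponential *y* = *Ae*^(*Bx*) + *C*, both by
Levenberg–Marquardt least squares. New-gene counts per added genome come
from ordered additions averaged over 200 seeded random orders.

Numerical choices: fits start from scale-aware initial values and try the
growth, saturating and decaying branches (for the power law: (range, 0.5,
min), (−range, −0.5, max), (range, −0.5, min)), keeping the lowest-SSE
solution. A closed pangenome saturates from below, which lives on the
*A* < 0, *B* < 0 branch of the power law; a single growth-branch start can
converge to a degenerate near-logarithmic solution, which is why the
mirrored starts exist. Extrapolation standard errors use the delta method
on the fit covariance; how "±" should be propagated to predictions is a
design choice of this package.

## Contig placement

Five read filters (MAPQ ≥ 10; not proper pair; mapped; mate mapped; not
duplicate), terminal windows of 300 bp, mate on a different sequence. An
end yields a candidate when ≥ 10 links agree: ≥ 80% (inclusive) of mates on
one chromosome and the majority-target mate coordinates spanning ≤ 1,000
bp. The span is computed over majority-target mates only — the 80% rule
already treats the minority as noise. Coordinate = median of those mate
positions, taking the lower middle value for even counts so coordinates
stay integral. Both ends on one chromosome → lower coordinate; different
chromosomes → no placement. On contigs shorter than two windows a read can
sit in both windows and is evaluated once per end. Contigs ≤ 200 bp are
skipped. When both ends place, the supports are summed and each end's
count is kept alongside.

## Variation statistics

Heterozygous SNPs are removed first: the material modelled is inbred or
doubled-haploid, so heterozygous calls are treated as artefacts. A SNP is
coding when it falls in an exon of the gene under test; the affected codon
is rebuilt from the spliced CDS (reverse-complemented for minus-strand
genes) and both alleles translated. Synonymous = same amino acid; nonsense
= alternate codon is a stop and the reference codon is not; everything else
(stop-loss included) is nonsynonymous, since only three effect classes are
distinguished. Exons are treated as CDS when no CDS features are annotated;
a CDS length not divisible by 3 leaves trailing bases ignored with a
warning.

Per-gene density = 1000 × coding SNPs / coding length; the normalised
variant divides by the gene's presence count (number of lines carrying it)
— the most literal reading of adjusting for the number of instances of a
gene; copy number is an alternative reading not implemented. Group
comparisons use the two-tailed Mann–Whitney *U* (normal approximation with
tie correction; all-tied input reports *p* = 1), with direction from mean
ranks. TE density is the merged-TE fraction of the 2,000 bp windows
before the gene start and after the gene end, truncated at sequence
boundaries with the denominator reduced accordingly so edge genes are not
penalised.

## Phylogeny placement

Each non-root node's branch is labelled with genes uniquely present
(presence set exactly the node's leaf set) and uniquely absent (absence set
exactly the leaf set). Leaf branches count — single-line unique genes sit
on terminal branches. The root is excluded: a pattern spanning all lines is
core, not PAV. Clade consistency counts a variable gene once when its
presence *or* absence set matches some node (complementary clades of a
rooted tree can both match); presence-only and absence-only tallies are
also reported because the aggregate alone does not say which side matched.

## Annotation analyses

R genes require an NB-ARC (PF00931) domain hit; TIR, CC and LRR hits refine
the category string in TIR/CC–NBS–LRR order. Clustering is ordinal: two R
genes link when the inclusive count of genes from one to the other is ≤ 10,
i.e. gene-order indices differ by ≤ 9 (a base-pair rule is a different
convention; an exclusive count can be had by lowering the separation
parameter). Clusters are transitive closures with ≥ 2 members, and the
clustered fraction counts genes, not clusters.

Families: core iff some member is present in every line; variable iff some
line lacks all members; anything else is labelled `unclassified` explicitly
rather than silently coerced (a `strict_binary` switch coerces to variable
for family-level accounting). The family × line presence matrix is the
element-wise OR of member rows and feeds the family-level accumulation
curves. Family enrichment in variable genes uses Fisher's exact test,
two-sided by default with a one-sided enrichment mode, flagged at
*P* < 0.001.

The identity-cutoff helper scales expected divergence by the ratio of
divergence times: cutoff = 100 − (t_wild/t_split) · (100 − q1), defaulting
to the divergence-scaled form because the literal product formula
(t_wild · q1 / t_split) yields cutoffs near 50% for plausible inputs, far
below any usable alignment threshold; the literal form is retained behind a
flag.

## Synthetic data: what it emulates and what it does not

The generator builds chromosomes of random sequence with non-overlapping
genes (CDS lengths multiples of 3, 1–4 exons, introns 60–200 bp,
intergenic gaps 800–1,500 bp), assigns each variable gene a non-empty,
non-full presence subset — a configurable fraction drawn from the clades of
a generated random rooted tree — and plants TE intervals densely
(~35% of flank bases) in the 2 kb flanks of variable genes over a ~2%
uniform background. Reads are emitted pre-aligned as proper pairs drawn
uniformly from each line's genome (reference minus its deleted genes plus
its carried novel contigs), defaulting to 25× depth, 100 bp reads and
400 ± 40 bp inserts, inside the 300–500 bp insert regime of typical
paired-end libraries. SNPs are homozygous substitutions at Poisson-spaced
positions with an optional heterozygous fraction for filter testing. Novel
contigs are carried by one line each and tied to a chromosome insertion
point by junction-straddling mate pairs, drawn per end at the local
physical-coverage rate.

Deliberately not modelled: sequencing errors (optional uniform
substitution rate only), indels, partial deletions, copy-number dosage, TE
mobilisation, mapping ambiguity and mapper-specific artefacts (reads are
emitted at their true positions). Passing tests therefore show the logic
of the calling, placement and statistics is correct under clean alignments
— not that the thresholds are robust to real mapping noise, which is a
property of the mapper and data, not of these rules.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in well under a minute of simulation per stage: PAV
recovery on 6 lines × 500 genes (~1.1 Mb, ~270k records/line), placement
of 50 contigs at 15× mate depth, model recovery on 10-point curves and a
1,000-gene closed pool. Every stochastic step takes an explicit seed; the
CLI derives per-stage seeds from one run seed by stage-name salting so
stages rerun independently yet reproducibly. Generation, simulation and
calling are deterministic given (parameters, seed); SAM output is
byte-identical across reruns.

## Known limitations

* PAV calls are binary per gene; partial losses and copy number are out of
  scope.
* Placement does not infer orientation or gap sizes.
* The exhaustive subset enumeration is refused above 15 lines; use sampled
  mode.
* The Mann–Whitney *p* is asymptotic; for very small groups (n ≤ 8) an
  exact enumeration differs by up to ~0.1 and the tests compare against
  one.
* VCF input is restricted to biallelic SNPs; indels are ignored on read.
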