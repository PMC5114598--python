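"""Coding-SNP classification, SNP/TE density measures and core-vs-variable
comparisons.

SNPs are restricted to homozygous calls (heterozygotes in inbred/doubled
haploid material are treated as artefacts), classified against the spliced
coding sequence as synonymous, nonsynonymous or nonsense, and summarised
per gene as coding SNP density per kb, optionally normalised by the number
of lines in which the gene is present.  Core and variable gene groups are
compared with a two-tailed Mann-Whitney U test; TE load around a gene is
the proportion of TE bases in the 2,000 bp windows flanking it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .io_formats import GeneModel, PavMatrix, SnpRecord

logger = logging.getLogger("panpav")

__all__ = ["SnpClassification", "GeneStats", "remove_heterozygous",
           "classify_snp", "gene_snp_stats", "compare_core_variable",
           "te_window_density", "private_snp_counts"]


@dataclass(frozen=True)
class SnpClassification:
    snp: SnpRecord
    context: str  # non_coding | coding
    effect: str   # synonymous | nonsynonymous | nonsense | none


@dataclass(frozen=True)
class GeneStats:
    gene_id: str
    label: str
    length_bp: int
    exon_count: int
    coding_snp_count: int
    coding_length: int
    presence_count: int

    @property
    def density_per_kb(self) -> float:
        return 1000.0 * self.coding_snp_count / self.coding_length

    @property
    def normalized_density(self) -> float:
        return self.density_per_kb / self.presence_count


def remove_heterozygous(snps: Iterable[SnpRecord]) -> list[SnpRecord]:
    """Drop heterozygous (and hom-ref) calls; keep homozygous alternates."""
    return [s for s in snps if s.genotype == "hom_alt"]


def _spliced_cds(gene: GeneModel, reference: str) -> str:
    cds = "".join(reference[s - 1:e] for s, e in gene.exons)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    for s, e in gene.exons:
        if s <= pos <= e:
            fwd = off + (pos - s)
            if gene.strand == "+":
                return fwd
            total = gene.total_exon_length
            return total - 1 - fwd
        off += e - s + 1
    return None


def classify_snp(snp: SnpRecord, gene: GeneModel,
                 reference: str) -> SnpClassification:
    """Classify one SNP against one gene's coding sequence.

    Coding iff the position falls in an exon; the affected codon is rebuilt
    from the spliced CDS honouring strand (alleles complemented for minus-
    strand genes).  Synonymous if the amino acid is unchanged, nonsense if
    the alternate codon is a stop while the reference codon is not,
    otherwise nonsynonymous (stop-loss included).  A CDS length not
    divisible by 3 leaves the trailing bases ignored with a warning.
    """
    if snp.seq_id != gene.seq_id:
        raise ValueError("SNP and gene are on different sequences")
    ref_base = reference[snp.pos - 1]
    if ref_base != snp.ref_allele:
        raise ValueError(
            f"reference base {ref_base} at {snp.seq_id}:{snp.pos} does not "
            f"match SNP ref allele {snp.ref_allele}")
    off = _cds_offset(gene, snp.pos)
    if off is None:
        return SnpClassification(snp, "non_coding", "none")
    cds = _spliced_cds(gene, reference)
    if len(cds) % 3:
        logger.warning("gene %s: CDS length %d not divisible by 3; trailing "
                       "bases ignored", gene.gene_id, len(cds))
    codon_i = off // 3
    if 3 * codon_i + 3 > len(cds):
        return SnpClassification(snp, "coding", "nonsynonymous")
    ref_alt = snp.alt_allele
    if gene.strand == "-":
        ref_alt = str(Seq(ref_alt).complement())
    codon = cds[3 * codon_i:3 * codon_i + 3]
    within = off % 3
    alt_codon = codon[:within] + ref_alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*" and aa_ref != "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return SnpClassification(snp, "coding", effect)


def gene_snp_stats(gene: GeneModel, snps: Sequence[SnpRecord],
                   pav: PavMatrix, label: str | None = None) -> GeneStats:
    """Per-gene coding SNP summary (SNPs assumed pre-filtered to hom-alt).

    Counts distinct (position, alt, line) coding hits inside the gene's
    exons; presence_count is the gene's row sum in the PAV matrix.
    """
    if gene.gene_id not in pav.df.index:
        raise ValueError(f"gene {gene.gene_id} not in PAV matrix")
    coding_length = gene.total_exon_length
    if coding_length == 0:
        raise ValueError(f"gene {gene.gene_id}: zero coding length")
    n_coding = sum(
        1 for s in snps
        if s.seq_id == gene.seq_id and _cds_offset(gene, s.pos) is not None)
    presence = int(pav.df.loc[gene.gene_id].sum())
    if label is None:
        label = "core" if presence == pav.shape[1] else "variable"
    span = gene.span
    return GeneStats(gene.gene_id, label, span[1] - span[0] + 1,
                     len(gene.exons), n_coding, coding_length, presence)


def compare_core_variable(values_core: Sequence[float],
                          values_variable: Sequence[float]
                          ) -> dict[str, float | str]:
    """Two-tailed Mann-Whitney U comparison of core vs variable values.

    Normal approximation with tie correction (two-tailed); the direction is
    reported from mean ranks.  All-tied input returns p = 1.
    """
    a = np.asarray(values_core, float)
    b = np.asarray(values_variable, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
    ranks = stats.rankdata(pooled)
    mean_rank_core = float(ranks[:len(a)].mean())
    mean_rank_var = float(ranks[len(a):].mean())
    if mean_rank_core > mean_rank_var:
        direction = "core_higher"
    elif mean_rank_core < mean_rank_var:
        direction = "variable_higher"
    else:
        direction = "tied"
    return {"U": float(u), "p": float(p),
            "mean_core": float(a.mean()), "mean_variable": float(b.mean()),
            "mean_rank_core": mean_rank_core,
            "mean_rank_variable": mean_rank_var,
            "direction": direction}


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def te_window_density(gene: GeneModel,
                      te_intervals: Sequence[tuple[str, int, int]],
                      seq_length: int, window: int = 2000) -> float:
    """Proportion of TE bases in the flanking windows of a gene.

    The windows are the ``window`` bp preceding the gene start and following
    the gene end, truncated at the sequence boundaries; the denominator is
    the bases actually available so edge genes are not penalised.
    Overlapping TE annotations are merged before counting.
    """
    gs, ge = gene.span
    windows = []
    lo, hi = max(1, gs - window), gs - 1
    if hi >= lo:
        windows.append((lo, hi))
    lo, hi = ge + 1, min(seq_length, ge + window)
    if hi >= lo:
        windows.append((lo, hi))
    total = sum(e - s + 1 for s, e in windows)
    if total == 0:
        return 0.0
    merged = _merge([(s, e) for c, s, e in te_intervals
                     if c == gene.seq_id])
    covered = 0
    for ws, we in windows:
        for s, e in merged:
            if e < ws or s > we:
                continue
            covered += min(we, e) - max(ws, s) + 1
    return covered / total


def private_snp_counts(snps: Iterable[SnpRecord]) -> dict[str, int]:
    """Per-line counts of SNPs seen in that line only (hom-alt records)."""
    by_site: dict[tuple[str, int, str], set[str]] = {}
    for s in snps:
        if s.genotype != "hom_alt":
            continue
        by_site.setdefault((s.seq_id, s.pos, s.alt_allele),
                           set()).add(s.line_id)
    counts: dict[str, int] = {}
    for lines in by_site.values():
        if len(lines) == 1:
            (line,) = lines
            counts[line] = counts.get(line, 0) + 1
    return counts
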