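"""Coverage-based gene presence/absence calling.

A gene is called absent in a line when the horizontal coverage of its exons
— the fraction of exon bases touched by at least one retained read — falls
below a threshold (default 5%, strict).  Reads are first restricted to
proper pairs, and lines sequenced deeper than the target depth (default
~25x) are downsampled at the pair level so that every line is called from a
comparable amount of evidence.  Genes annotated on short contigs
(< 1,000 bp by default) are excluded from the matrix entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, GeneModel, PavMatrix

logger = logging.getLogger("panpav")

__all__ = [
    "CoverageResult",
    "filter_alignments",
    "subsample_to_depth",
    "exon_horizontal_coverage",
    "coverage_for_genes",
    "call_pav",
    "classify_genes",
    "call_pav_pipeline",
]


@dataclass(frozen=True)
class CoverageResult:
    gene_id: str
    line_id: str
    covered_exon_bases: int
    total_exon_bases: int

    @property
    def horizontal_coverage(self) -> float:
        return self.covered_exon_bases / self.total_exon_bases


def filter_alignments(records: Iterable[AlignmentRecord]
                      ) -> Iterator[AlignmentRecord]:
    """Keep only reads mapped in proper pairs, excluding duplicates."""
    for r in records:
        if r.is_proper_pair and not r.is_unmapped and not r.is_duplicate:
            yield r


def subsample_to_depth(records: Sequence[AlignmentRecord],
                       reference_length: int, target_depth: float = 25.0,
                       seed: int = 0) -> list[AlignmentRecord]:
    """Downsample read pairs so estimated depth does not exceed the target.

    Depth is estimated as total aligned bases over the reference length.  If
    it is already at or below target the input is returned unchanged;
    otherwise each read *pair* is kept independently with probability
    target/depth, both mates sharing one retention decision (so proper-pair
    status survives subsampling).
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    records = list(records)
    total_bases = sum(e - s + 1 for r in records
                      for s, e in r.aligned_intervals)
    depth = total_bases / reference_length
    if depth <= target_depth:
        return records
    p_keep = target_depth / depth
    rng = np.random.default_rng(seed)
    decision: dict[str, bool] = {}
    out = []
    for r in records:
        keep = decision.get(r.read_id)
        if keep is None:
            keep = bool(rng.random() < p_keep)
            decision[r.read_id] = keep
        if keep:
            out.append(r)
    logger.info("subsampled depth %.1f -> target %.1f (kept %d/%d records)",
                depth, target_depth, len(out), len(records))
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]
                     ) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def exon_horizontal_coverage(records: Iterable[AlignmentRecord],
                             gene: GeneModel,
                             line_id: str = "") -> CoverageResult:
    """Horizontal (breadth) coverage of a gene's exons.

    Counts each exon base at most once regardless of read depth: the size of
    the union of aligned intervals intersected with the union of exons.
    """
    total = gene.total_exon_length
    if total == 0:
        raise ValueError(f"gene {gene.gene_id}: zero exon length")
    exons = _merge_intervals(gene.exons)
    read_iv = _merge_intervals(
        iv for r in records if r.seq_id == gene.seq_id
        for iv in r.aligned_intervals)
    covered = 0
    j = 0
    for es, ee in exons:
        while j < len(read_iv) and read_iv[j][1] < es:
            j += 1
        k = j
        while k < len(read_iv) and read_iv[k][0] <= ee:
            covered += min(ee, read_iv[k][1]) - max(es, read_iv[k][0]) + 1
            k += 1
        j = max(j, k - 1) if k > j else j
    return CoverageResult(gene.gene_id, line_id, covered, total)


def coverage_for_genes(records: Iterable[AlignmentRecord],
                       genes: Sequence[GeneModel],
                       seq_lengths: Mapping[str, int],
                       line_id: str = "") -> list[CoverageResult]:
    """Batch horizontal coverage via per-sequence coverage bitmaps.

    Equivalent to ``exon_horizontal_coverage`` per gene but linear in reads
    plus exon bases, which is what the pipeline uses at scale.
    """
    masks = {c: np.zeros(l + 2, dtype=bool) for c, l in seq_lengths.items()}
    for r in records:
        m = masks.get(r.seq_id)
        if m is None:
            continue
        for s, e in r.aligned_intervals:
            m[max(s, 1):min(e, len(m) - 2) + 1] = True
    out = []
    for g in genes:
        m = masks.get(g.seq_id)
        if m is None:
            raise KeyError(f"gene {g.gene_id}: unknown sequence {g.seq_id}")
        covered = int(sum(m[s:e + 1].sum() for s, e in _merge_intervals(g.exons)))
        out.append(CoverageResult(g.gene_id, line_id, covered,
                                  g.total_exon_length))
    return out


def call_pav(coverages: Iterable[CoverageResult],
             genes: Sequence[GeneModel], line_ids: Sequence[str],
             contig_lengths: Mapping[str, int],
             absence_threshold: float = 0.05,
             min_contig_len: int = 1000) -> PavMatrix:
    """Call the presence matrix from per-(gene, line) coverages.

    Absent iff horizontal coverage < ``absence_threshold`` (strict: coverage
    exactly at the threshold is present).  Genes on contigs shorter than
    ``min_contig_len`` are dropped from the matrix entirely.
    """
    eligible = [g for g in genes
                if contig_lengths.get(g.seq_id, 0) >= min_contig_len]
    skipped = len(genes) - len(eligible)
    if skipped:
        logger.info("excluded %d genes on contigs < %d bp",
                    skipped, min_contig_len)
    cov_map: dict[tuple[str, str], float] = {}
    for c in coverages:
        cov_map[(c.gene_id, c.line_id)] = c.horizontal_coverage
    gene_ids = [g.gene_id for g in eligible]
    missing = [(g, l) for g in gene_ids for l in line_ids
               if (g, l) not in cov_map]
    if missing:
        raise ValueError(f"missing coverage for {len(missing)} (gene, line) "
                         f"pairs, first: {missing[0]}")
    presence = np.array(
        [[0 if cov_map[(g, l)] < absence_threshold else 1 for l in line_ids]
         for g in gene_ids], dtype=np.int8)
    return PavMatrix(gene_ids, list(line_ids), presence)


def classify_genes(pav: PavMatrix) -> dict[str, dict[str, bool | str]]:
    """Label each gene core/variable, with a singleton flag.

    Core iff present in every line; variable iff absent in at least one.
    Singleton genes are present in exactly one line.  A gene absent
    everywhere contradicts pangenome membership and raises.
    """
    if pav.shape[0] == 0:
        raise ValueError("empty PAV matrix")
    arr = pav.presence
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        bad = [g for g, s in zip(pav.gene_ids, sums) if s == 0]
        raise ValueError(f"genes absent from every line: {bad[:5]}")
    n = arr.shape[1]
    return {g: {"label": "core" if s == n else "variable",
                "singleton": bool(s == 1)}
            for g, s in zip(pav.gene_ids, sums)}


def call_pav_pipeline(per_line_records: Mapping[str, Sequence[AlignmentRecord]],
                      genes: Sequence[GeneModel],
                      seq_lengths: Mapping[str, int],
                      target_depth: float = 25.0,
                      absence_threshold: float = 0.05,
                      min_contig_len: int = 1000,
                      seed: int = 0) -> PavMatrix:
    """Full calling pipeline: filter, subsample, coverage, call."""
    reference_length = sum(seq_lengths.values())
    line_ids = list(per_line_records)
    coverages: list[CoverageResult] = []
    for i, line in enumerate(line_ids):
        kept = list(filter_alignments(per_line_records[line]))
        kept = subsample_to_depth(kept, reference_length, target_depth,
                                  seed=seed + i)
        coverages.extend(coverage_for_genes(kept, genes, seq_lengths,
                                            line_id=line))
    return call_pav(coverages, genes, line_ids, seq_lengths,
                    absence_threshold, min_contig_len)
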