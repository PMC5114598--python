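"""Readers and writers for the formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere internally (the native
convention of GFF3 and SAM).  BED input is converted at the boundary
(0-based half-open -> 1-based inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("panpav")

__all__ = [
    "GeneModel",
    "AlignmentRecord",
    "PavMatrix",
    "SnpRecord",
    "GffParseError",
    "read_gene_models",
    "read_alignments",
    "alignment_record_from_pysam",
    "read_pav_matrix",
    "write_pav_matrix",
    "read_tree",
    "write_tree",
    "read_te_intervals",
    "read_snps",
    "write_snps",
    "read_fasta",
    "write_fasta",
    "read_ortho_groups",
    "read_domain_hits",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with exon intervals on a named sequence (1-based inclusive).

    ``source_line`` records which line's assembly the gene was annotated on;
    genes from the anchoring reference carry the reference line's id.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_line: str = "reference"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exons must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start {s} > end {e}")
            if prev is not None and s < prev:
                raise ValueError(f"gene {self.gene_id}: exons not sorted by start")
            prev = s

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], max(e for _, e in self.exons)

    @property
    def total_exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: decoded SAM flags plus reference intervals covered.

    ``aligned_intervals`` holds the 1-based inclusive reference intervals
    consumed by CIGAR M/=/X operations; D and N split intervals, I and S
    consume no reference.  Empty iff the read is unmapped.
    """

    read_id: str
    seq_id: str
    pos: int
    mapq: int
    flags: frozenset[str]
    mate_seq_id: str
    mate_pos: int
    aligned_intervals: tuple[tuple[int, int], ...]

    @property
    def is_unmapped(self) -> bool:
        return "unmapped" in self.flags

    @property
    def is_proper_pair(self) -> bool:
        return "proper_pair" in self.flags

    @property
    def is_duplicate(self) -> bool:
        return "duplicate" in self.flags


class PavMatrix:
    """Genes x lines binary presence matrix backed by a pandas DataFrame."""

    def __init__(self, gene_ids: Sequence[str], line_ids: Sequence[str],
                 presence: np.ndarray | Sequence[Sequence[int]]):
        presence = np.asarray(presence, dtype=np.int8)
        if presence.shape != (len(gene_ids), len(line_ids)):
            raise ValueError(
                f"presence shape {presence.shape} does not match "
                f"{len(gene_ids)} genes x {len(line_ids)} lines")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids")
        if not np.isin(presence, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        self.df = pd.DataFrame(presence, index=list(gene_ids),
                               columns=list(line_ids))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def presence(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def presence_set(self, gene_id: str) -> frozenset[str]:
        row = self.df.loc[gene_id]
        return frozenset(row.index[row == 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PavMatrix):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"PavMatrix({self.shape[0]} genes x {self.shape[1]} lines)"


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide substitution in one line (1-based position)."""

    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # hom_ref | het | hom_alt
    line_id: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT":
                raise ValueError(f"allele {a!r} not in ACGT")
        if self.genotype not in ("hom_ref", "het", "hom_alt"):
            raise ValueError(f"bad genotype {self.genotype!r}")


class GffParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse gene models from GFF3, taking the first mRNA per gene.

    Exons belong to a gene through their mRNA parent; for genes with several
    transcripts the exons of the first mRNA in file order define the model.
    Genes without exons are skipped with a warning.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    first_mrna: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(
                    f"{gff3_path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}") from None
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise GffParseError(f"{gff3_path}:{lineno}: gene without ID")
                genes[gid] = {"seq_id": seq_id, "strand": strand,
                              "source_line": a.get("source_line", "reference")}
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise GffParseError(
                        f"{gff3_path}:{lineno}: mRNA missing ID or Parent")
                mrna_parent[mid] = parent
                first_mrna.setdefault(parent, mid)
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent is None:
                    raise GffParseError(
                        f"{gff3_path}:{lineno}: {ftype} missing Parent")
                # CDS features override exon features for the same mRNA
                key = (parent, ftype)
                exons.setdefault(key, []).append((start, end))

    models: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        mid = first_mrna.get(gid)
        ex: list[tuple[int, int]] = []
        if mid is not None:
            # prefer CDS when annotated, else exon
            ex = exons.get((mid, "CDS")) or exons.get((mid, "exon")) or []
        if not ex:
            # exons may be direct children of the gene
            ex = exons.get((gid, "CDS")) or exons.get((gid, "exon")) or []
        if not ex:
            logger.warning("gene %s has no exons; skipped", gid)
            continue
        models.append(GeneModel(gene_id=gid, seq_id=info["seq_id"],
                                strand=info["strand"],
                                exons=tuple(sorted(ex)),
                                source_line=info["source_line"]))
    return models


def write_gene_models(models: Iterable[GeneModel], gff3_path: str) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s, e = g.span
            fh.write(f"{g.seq_id}\tpanpav\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};source_line={g.source_line}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.seq_id}\tpanpav\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(f"{g.seq_id}\tpanpav\texon\t{xs}\t{xe}\t.\t{g.strand}"
                         f"\t.\tID={mid}.exon{i};Parent={mid}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_FLAG_NAMES = (
    (0x2, "proper_pair"),
    (0x4, "unmapped"),
    (0x8, "mate_unmapped"),
    (0x10, "reverse"),
    (0x400, "duplicate"),
)


def _intervals_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference intervals covered by M/=/X ops; D/N split, I/S skipped."""
    out: list[tuple[int, int]] = []
    ref = pos
    for op, n in cigartuples:
        if op in (0, 7, 8):  # M, =, X consume reference and cover it
            if out and out[-1][1] == ref - 1:
                out[-1] = (out[-1][0], ref + n - 1)
            else:
                out.append((ref, ref + n - 1))
            ref += n
        elif op in (2, 3):  # D, N consume reference without covering it
            ref += n
        # I(1), S(4), H(5), P(6) consume no reference
    return tuple(out)


def alignment_record_from_pysam(read: pysam.AlignedSegment) -> AlignmentRecord:
    flags = frozenset(name for bit, name in _FLAG_NAMES if read.flag & bit)
    unmapped = "unmapped" in flags
    if not unmapped and read.reference_name is None:
        raise ValueError(f"mapped read {read.query_name} lacks a reference")
    intervals = ()
    if not unmapped and read.cigartuples:
        intervals = _intervals_from_cigar(read.reference_start + 1,
                                          read.cigartuples)
    return AlignmentRecord(
        read_id=read.query_name,
        seq_id=read.reference_name or "*",
        pos=(read.reference_start + 1) if read.reference_start >= 0 else 1,
        mapq=read.mapping_quality,
        flags=flags,
        mate_seq_id=read.next_reference_name or "*",
        mate_pos=(read.next_reference_start + 1)
        if read.next_reference_start is not None and read.next_reference_start >= 0
        else 0,
        aligned_intervals=intervals,
    )


def read_alignments(sam_path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file (header required)."""
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
        for read in sam:
            yield alignment_record_from_pysam(read)


# ---------------------------------------------------------------------------
# PAV TSV
# ---------------------------------------------------------------------------

def read_pav_matrix(tsv_path: str) -> PavMatrix:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{tsv_path}: non-binary cell {arr[i, j]!r} at gene "
            f"{df.index[i]!r}, line {df.columns[j]!r}")
    return PavMatrix(list(df.index), list(df.columns), arr)


def write_pav_matrix(matrix: PavMatrix, tsv_path: str) -> None:
    matrix.df.to_csv(tsv_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Trees, BED, VCF, FASTA, groups, domain hits
# ---------------------------------------------------------------------------

def read_tree(newick_path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=newick_path, schema="newick")


def write_tree(tree: dendropy.Tree, newick_path: str) -> None:
    tree.write(path=newick_path, schema="newick", suppress_rooting=True)


def read_te_intervals(bed_path: str) -> list[tuple[str, int, int]]:
    """Read TE intervals from BED, converting to 1-based inclusive."""
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 columns")
            out.append((cols[0], int(cols[1]) + 1, int(cols[2])))
    return out


def write_te_intervals(intervals: Iterable[tuple[str, int, int]],
                       bed_path: str) -> None:
    with open(bed_path, "w") as fh:
        for seq_id, start, end in intervals:
            fh.write(f"{seq_id}\t{start - 1}\t{end}\n")


def read_snps(vcf_path: str) -> list[SnpRecord]:
    """Read per-line SNPs from a multi-sample VCF (samples = line ids).

    One record per (site, sample) with a non-reference genotype.
    """
    out: list[SnpRecord] = []
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                continue  # indels out of scope
            for line_id in samples:
                gt = rec.samples[line_id]["GT"]
                if gt is None or None in gt:
                    continue
                alleles = set(gt)
                if alleles == {0}:
                    continue
                genotype = "hom_alt" if alleles == {1} else "het"
                out.append(SnpRecord(rec.chrom, rec.pos, rec.ref, alt,
                                     genotype, line_id))
    return out


def write_snps(snps: Sequence[SnpRecord], line_ids: Sequence[str],
               vcf_path: str, contigs: dict[str, int] | None = None) -> None:
    """Write SNPs as a multi-sample VCF (plain text)."""
    by_site: dict[tuple[str, int, str, str], dict[str, str]] = {}
    for s in snps:
        by_site.setdefault((s.seq_id, s.pos, s.ref_allele, s.alt_allele),
                           {})[s.line_id] = s.genotype
    gt_code = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(line_ids) + "\n")
        for (seq_id, pos, ref, alt), gts in sorted(by_site.items()):
            cells = [gt_code[gts.get(line, "hom_ref")] for line in line_ids]
            fh.write(f"{seq_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_ortho_groups(path: str) -> dict[str, list[str]]:
    """Read an OrthoMCL-style groups file: ``FAM001: geneA geneB ...``."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing ':' separator")
            fam, members = line.split(":", 1)
            out[fam.strip()] = members.split()
    return out


def read_domain_hits(path: str) -> pd.DataFrame:
    """Read a domain-hit table: gene_id, accession[, score] (TSV, # comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df
    df.columns = ["gene_id", "accession", "score"][: df.shape[1]]
    return df
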