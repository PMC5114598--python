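"""Synthetic multi-line pangenome generator with known ground truth.

Emulates the data regime of a reference-anchored crop pangenome: a set of
inbred lines sharing one reference, whole-gene deletions in subsets of lines,
uniform paired-end coverage (~25x, 300-500 bp inserts), homozygous SNPs,
TE-dense flanks around variable genes, and novel contigs tied to chromosome
insertion points by mate pairs.  Every downstream stage can be checked
against the recorded truth.

Reads are emitted pre-aligned (SAM records) rather than as FASTQ: truth
alignments make the tests hermetic, and mapping is not part of this package.
A FASTQ export exists for users who want to run a real mapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .io_formats import (AlignmentRecord, GeneModel, PavMatrix, SnpRecord,
                         write_fasta, write_gene_models, write_pav_matrix,
                         write_snps, write_te_intervals, write_tree)

__all__ = [
    "SyntheticTruth",
    "SamRead",
    "generate_pangenome",
    "simulate_reads",
    "inject_snps",
    "write_truth",
    "write_sam",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SamRead:
    """A single already-mapped read, one SAM line."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str

    def to_sam_line(self) -> str:
        return "\t".join((self.qname, str(self.flag), self.rname,
                          str(self.pos), str(self.mapq), self.cigar,
                          self.rnext, str(self.pnext), str(self.tlen),
                          self.seq, "*"))

    def to_alignment_record(self) -> AlignmentRecord:
        names = []
        if self.flag & 0x2:
            names.append("proper_pair")
        if self.flag & 0x4:
            names.append("unmapped")
        if self.flag & 0x8:
            names.append("mate_unmapped")
        if self.flag & 0x10:
            names.append("reverse")
        if self.flag & 0x400:
            names.append("duplicate")
        read_len = len(self.seq)
        intervals = () if self.flag & 0x4 else ((self.pos, self.pos + read_len - 1),)
        mate = self.rname if self.rnext == "=" else self.rnext
        return AlignmentRecord(
            read_id=self.qname, seq_id=self.rname, pos=self.pos,
            mapq=self.mapq, flags=frozenset(names), mate_seq_id=mate,
            mate_pos=self.pnext, aligned_intervals=intervals)


@dataclass
class SyntheticTruth:
    """A generated pangenome with complete ground truth."""

    reference: dict[str, str]          # seq_id -> sequence (chromosomes + contigs)
    gene_models: list[GeneModel]
    line_ids: list[str]
    deleted: dict[str, set[str]]       # line_id -> deleted gene ids
    truth_pav: PavMatrix
    truth_snps: list[SnpRecord]
    te_intervals: list[tuple[str, int, int]]
    novel_contigs: dict[str, tuple[str, int]]  # contig_id -> (chrom, insertion pos)
    contig_line: dict[str, str]        # contig_id -> carrying line
    tree: dendropy.Tree
    seed: int
    chrom_ids: list[str] = field(default_factory=list)

    @property
    def reference_length(self) -> int:
        return sum(len(s) for s in self.reference.values())

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.gene_models}


# ---------------------------------------------------------------------------
# Tree generation and clade enumeration
# ---------------------------------------------------------------------------

def _random_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary topology by recursive splitting."""
    def build(items: list[str]) -> str:
        if len(items) == 1:
            return f"{items[0]}:{rng.uniform(0.01, 0.1):.4f}"
        k = int(rng.integers(1, len(items)))
        left, right = items[:k], items[k:]
        bl = rng.uniform(0.01, 0.1)
        return f"({build(left)},{build(right)}):{bl:.4f}"

    shuffled = list(labels)
    rng.shuffle(shuffled)
    return build(shuffled) + ";"


def tree_clades(tree: dendropy.Tree, *, include_leaves: bool = True,
                exclude_root: bool = True) -> list[frozenset[str]]:
    """Leaf-label sets of tree nodes (clades), root optionally excluded."""
    out = []
    for node in tree.preorder_node_iter():
        if exclude_root and node is tree.seed_node:
            continue
        if node.is_leaf() and not include_leaves:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append(leaves)
    return out


# ---------------------------------------------------------------------------
# Pangenome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _make_gene(rng: np.random.Generator, gene_id: str, seq_id: str,
               start: int, gene_len_range: tuple[int, int],
               exons_range: tuple[int, int], source_line: str) -> GeneModel:
    total = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
    total -= total % 3
    total = max(total, 30)
    n_ex = int(rng.integers(exons_range[0], exons_range[1] + 1))
    n_ex = min(n_ex, total // 30)
    n_ex = max(n_ex, 1)
    # split CDS into n_ex pieces, each a positive multiple of 3
    codons = total // 3
    cuts = np.sort(rng.choice(np.arange(1, codons), size=n_ex - 1,
                              replace=False)) if n_ex > 1 else np.array([], int)
    lens = np.diff(np.concatenate([[0], cuts, [codons]])) * 3
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + int(ln) - 1))
        pos += int(ln)
        if i < len(lens) - 1:
            pos += int(rng.integers(60, 201))  # intron
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id=gene_id, seq_id=seq_id, strand=strand,
                     exons=tuple(exons), source_line=source_line)


def generate_pangenome(n_lines: int, n_core_genes: int, n_variable_genes: int,
                       gene_len_range: tuple[int, int] = (300, 1500),
                       exons_per_gene_range: tuple[int, int] = (1, 4),
                       seed: int = 0, *,
                       clade_fraction: float = 0.3,
                       n_chromosomes: int = 2,
                       intergenic_range: tuple[int, int] = (800, 1500),
                       n_novel_contigs: int = 0,
                       contig_len_range: tuple[int, int] = (1500, 3000),
                       te_background_density: float = 0.02,
                       te_variable_flank_density: float = 0.35,
                       te_window: int = 2000,
                       line_prefix: str = "line") -> SyntheticTruth:
    """Generate a multi-line pangenome with known deletions.

    Core genes are present in every line; each variable gene is assigned a
    random non-empty, non-full subset of lines, with a fraction
    ``clade_fraction`` drawn from the clades of the generated tree so that
    clade-consistency can be tested against truth.  TE intervals are planted
    at elevated density in the 2 kb flanks of variable genes over a uniform
    low background, emulating the association of repeats with structural
    variants.  Fully deterministic for a fixed seed.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_core_genes < 0 or n_variable_genes < 0:
        raise ValueError("gene counts must be >= 0")
    if n_core_genes + n_variable_genes == 0:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    line_ids = [f"{line_prefix}{i + 1}" for i in range(n_lines)]

    tree = dendropy.Tree.get(data=_random_newick(line_ids, rng),
                             schema="newick")
    tree.is_rooted = True
    clades = [c for c in tree_clades(tree) if 0 < len(c) < n_lines]

    n_genes = n_core_genes + n_variable_genes
    variable_idx = set(rng.choice(n_genes, size=n_variable_genes,
                                  replace=False).tolist())

    genes: list[GeneModel] = []
    chrom_ids = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chrom_len: dict[str, int] = {}
    per_chrom = int(math.ceil(n_genes / n_chromosomes))
    gi = 0
    for chrom in chrom_ids:
        pos = int(rng.integers(*intergenic_range))
        for _ in range(per_chrom):
            if gi >= n_genes:
                break
            g = _make_gene(rng, f"gene{gi + 1:05d}", chrom, pos,
                           gene_len_range, exons_per_gene_range, "reference")
            genes.append(g)
            pos = g.span[1] + int(rng.integers(*intergenic_range))
            gi += 1
        chrom_len[chrom] = pos + te_window
    reference = {c: _random_seq(rng, chrom_len[c]) for c in chrom_ids}

    # presence patterns
    presence = np.ones((n_genes, n_lines), dtype=np.int8)
    line_index = {l: i for i, l in enumerate(line_ids)}
    for idx in sorted(variable_idx):
        if clades and rng.random() < clade_fraction:
            subset = list(clades[int(rng.integers(len(clades)))])
        else:
            k = int(rng.integers(1, n_lines))
            subset = [line_ids[j] for j in
                      rng.choice(n_lines, size=k, replace=False)]
        presence[idx, :] = 0
        for l in subset:
            presence[idx, line_index[l]] = 1
    gene_ids = [g.gene_id for g in genes]
    truth_pav = PavMatrix(gene_ids, line_ids, presence)
    deleted = {l: {gene_ids[i] for i in range(n_genes)
                   if presence[i, line_index[l]] == 0}
               for l in line_ids}

    # TE intervals: low uniform background plus dense variable-gene flanks
    te: list[tuple[str, int, int]] = []
    for chrom in chrom_ids:
        n_bg = int(te_background_density * chrom_len[chrom] / 150)
        for _ in range(n_bg):
            s = int(rng.integers(1, chrom_len[chrom] - 150))
            te.append((chrom, s, s + int(rng.integers(50, 150))))
    for i, g in enumerate(genes):
        if i not in variable_idx:
            continue
        gs, ge = g.span
        for lo, hi in ((max(1, gs - te_window), gs - 1),
                       (ge + 1, min(chrom_len[g.seq_id], ge + te_window))):
            if hi <= lo:
                continue
            covered = 0
            target = te_variable_flank_density * (hi - lo + 1)
            while covered < target:
                ln = int(rng.integers(80, 250))
                s = int(rng.integers(lo, max(lo + 1, hi - ln)))
                te.append((g.seq_id, s, min(s + ln, hi)))
                covered += ln
    te.sort()

    # novel contigs, each carried by one line and tied to an insertion point
    novel: dict[str, tuple[str, int]] = {}
    contig_line: dict[str, str] = {}
    for i in range(n_novel_contigs):
        cid = f"contig{i + 1:04d}"
        ln = int(rng.integers(contig_len_range[0], contig_len_range[1] + 1))
        chrom = chrom_ids[int(rng.integers(n_chromosomes))]
        ins = int(rng.integers(te_window, chrom_len[chrom] - te_window))
        reference[cid] = _random_seq(rng, ln)
        novel[cid] = (chrom, ins)
        contig_line[cid] = line_ids[int(rng.integers(n_lines))]

    return SyntheticTruth(
        reference=reference, gene_models=genes, line_ids=line_ids,
        deleted=deleted, truth_pav=truth_pav, truth_snps=[],
        te_intervals=te, novel_contigs=novel, contig_line=contig_line,
        tree=tree, seed=seed, chrom_ids=chrom_ids)


# ---------------------------------------------------------------------------
# SNP injection
# ---------------------------------------------------------------------------

def inject_snps(line_id: str, truth: SyntheticTruth, snp_rate: float,
                seed: int = 0, *, het_fraction: float = 0.0) -> list[SnpRecord]:
    """Plant homozygous substitutions in one line at Poisson-spaced positions.

    A fraction ``het_fraction`` of records is marked heterozygous to exercise
    the heterozygote-removal artefact filter.  Appends to
    ``truth.truth_snps`` and returns the new records.
    """
    if not 0 < snp_rate < 0.1:
        raise ValueError("snp_rate must be in (0, 0.1)")
    if line_id not in truth.line_ids:
        raise ValueError(f"unknown line {line_id!r}")
    rng = np.random.default_rng(seed)
    out: list[SnpRecord] = []
    for chrom in truth.chrom_ids:
        seq = truth.reference[chrom]
        n = rng.poisson(snp_rate * len(seq))
        pos = np.sort(rng.choice(len(seq), size=min(n, len(seq)),
                                 replace=False)) + 1
        for p in pos.tolist():
            ref = seq[p - 1]
            if ref not in "ACGT":
                continue
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            gt = "het" if rng.random() < het_fraction else "hom_alt"
            out.append(SnpRecord(chrom, p, ref, alt, gt, line_id))
    truth.truth_snps.extend(out)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _retained_intervals(truth: SyntheticTruth, line_id: str,
                        chrom: str) -> list[tuple[int, int]]:
    """Chromosome intervals retained in a line (complement of deletions)."""
    length = len(truth.reference[chrom])
    spans = sorted(g.span for g in truth.gene_models
                   if g.seq_id == chrom and g.gene_id in truth.deleted[line_id])
    out = []
    cur = 1
    for s, e in spans:
        if s > cur:
            out.append((cur, s - 1))
        cur = max(cur, e + 1)
    if cur <= length:
        out.append((cur, length))
    return out


def _apply_snps(seq: str, snps: Iterable[SnpRecord]) -> str:
    buf = bytearray(seq, "ascii")
    for s in snps:
        buf[s.pos - 1] = ord(s.alt_allele)
    return buf.decode()


def simulate_reads(line_id: str, truth: SyntheticTruth, depth: float = 25.0,
                   read_len: int = 100, insert_mean: int = 400,
                   insert_sd: int = 40, seed: int = 0, *,
                   error_rate: float = 0.0,
                   bridge_depth: float | None = None) -> list[SamRead]:
    """Simulate uniform paired-end reads from one line's genome.

    Fragments are drawn uniformly from the line's genome — the reference
    minus its deleted genes, plus its carried novel contigs — so deleted
    exons receive zero coverage by construction.  Proper pairs are emitted
    with forward/reverse flags and shared insert.  For each carried novel
    contig, mate pairs straddling the insertion junctions are emitted with
    one mate on the contig end and one on the chromosome (not proper pairs),
    which is the placement evidence downstream.  Deterministic per seed.
    """
    if line_id not in truth.line_ids:
        raise ValueError(f"unknown line {line_id!r}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    min_insert = 2 * read_len
    line_snps = [s for s in truth.truth_snps if s.line_id == line_id]
    snps_by_chrom: dict[str, list[SnpRecord]] = {}
    for s in line_snps:
        snps_by_chrom.setdefault(s.seq_id, []).append(s)

    reads: list[SamRead] = []
    serial = 0

    def emit_pair(rname: str, seq: str, frag_start: int, frag_len: int) -> None:
        nonlocal serial
        serial += 1
        qname = f"{line_id}:{serial:08d}"
        p1 = frag_start
        p2 = frag_start + frag_len - read_len
        s1 = seq[p1 - 1:p1 - 1 + read_len]
        s2 = seq[p2 - 1:p2 - 1 + read_len]
        reads.append(SamRead(qname, 99, rname, p1, 60, f"{read_len}M",
                             "=", p2, frag_len, s1))
        reads.append(SamRead(qname, 147, rname, p2, 60, f"{read_len}M",
                             "=", p1, -frag_len, s2))

    # uniform proper pairs over retained chromosome intervals + carried contigs
    segments: list[tuple[str, str, int, int]] = []  # (rname, seq, start, end)
    for chrom in truth.chrom_ids:
        seq = truth.reference[chrom]
        if chrom in snps_by_chrom:
            seq = _apply_snps(seq, snps_by_chrom[chrom])
        for s, e in _retained_intervals(truth, line_id, chrom):
            if e - s + 1 >= min_insert:
                segments.append((chrom, seq, s, e))
    for cid, carrier in truth.contig_line.items():
        if carrier == line_id and len(truth.reference[cid]) >= min_insert:
            segments.append((cid, truth.reference[cid], 1,
                             len(truth.reference[cid])))

    total_len = sum(e - s + 1 for _, _, s, e in segments)
    n_pairs = int(round(depth * total_len / (2 * read_len)))
    weights = np.array([e - s + 1 for _, _, s, e in segments], float)
    weights /= weights.sum()
    seg_idx = rng.choice(len(segments), size=n_pairs, p=weights)
    frag_lens = np.clip(np.rint(rng.normal(insert_mean, insert_sd, n_pairs)),
                        min_insert, None).astype(int)
    offsets = rng.random(n_pairs)
    for i in range(n_pairs):
        rname, seq, s, e = segments[seg_idx[i]]
        fl = min(int(frag_lens[i]), e - s + 1)
        start = s + int(offsets[i] * (e - s + 1 - fl + 1))
        emit_pair(rname, seq, start, fl)

    # junction-bridging mate pairs for carried novel contigs
    if bridge_depth is None:
        bridge_depth = depth
    span = insert_mean - 2 * read_len
    for cid, carrier in truth.contig_line.items():
        if carrier != line_id:
            continue
        chrom, ins = truth.novel_contigs[cid]
        cseq = truth.reference[cid]
        chseq = truth.reference[chrom]
        clen = len(cseq)
        for end in ("left", "right"):
            n_bridge = int(rng.poisson(
                bridge_depth * max(span, 1) / (2 * read_len)))
            for _ in range(n_bridge):
                fl = int(np.clip(round(rng.normal(insert_mean, insert_sd)),
                                 min_insert, None))
                x = int(rng.integers(read_len, max(fl - read_len, read_len) + 1))
                serial += 1
                qname = f"{line_id}:b{serial:08d}"
                if end == "left":
                    # forward mate on chromosome just before the insertion,
                    # reverse mate in the contig's first bases
                    ch_pos = ins - x
                    if ch_pos < 1:
                        continue
                    c_pos = max(1, fl - x - read_len + 1)
                    reads.append(SamRead(qname, 97, chrom, ch_pos, 60,
                                         f"{read_len}M", cid, c_pos, 0,
                                         chseq[ch_pos - 1:ch_pos - 1 + read_len]))
                    reads.append(SamRead(qname, 145, cid, c_pos, 60,
                                         f"{read_len}M", chrom, ch_pos, 0,
                                         cseq[c_pos - 1:c_pos - 1 + read_len]))
                else:
                    # forward mate in the contig's last bases, reverse mate
                    # on the chromosome just after the insertion
                    c_pos = clen - x + 1
                    if c_pos < 1:
                        continue
                    ch_pos = ins + (fl - x) - read_len
                    if ch_pos < ins or ch_pos + read_len - 1 > len(chseq):
                        continue
                    reads.append(SamRead(qname, 97, cid, c_pos, 60,
                                         f"{read_len}M", chrom, ch_pos, 0,
                                         cseq[c_pos - 1:c_pos - 1 + read_len]))
                    reads.append(SamRead(qname, 145, chrom, ch_pos, 60,
                                         f"{read_len}M", cid, c_pos, 0,
                                         chseq[ch_pos - 1:ch_pos - 1 + read_len]))

    if error_rate > 0:
        for r in reads:
            n_err = rng.binomial(len(r.seq), error_rate)
            if n_err:
                buf = bytearray(r.seq, "ascii")
                for p in rng.integers(0, len(buf), n_err):
                    buf[p] = ord("ACGT"[int(rng.integers(4))])
                r.seq = buf.decode()
    return reads


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_sam(reads: Sequence[SamRead], truth: SyntheticTruth,
              path: str) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in truth.reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in reads:
            fh.write(r.to_sam_line() + "\n")


def write_fastq(reads: Sequence[SamRead], path_r1: str, path_r2: str) -> None:
    """Export simulated pairs as FASTQ (reverse mates re-complemented)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        by_name: dict[str, dict[int, SamRead]] = {}
        for r in reads:
            by_name.setdefault(r.qname, {})[1 if r.flag & 0x40 else 2] = r
        for qname, pair in by_name.items():
            if len(pair) != 2:
                continue
            for mate, fh in ((1, f1), (2, f2)):
                r = pair[mate]
                seq = r.seq
                if r.flag & 0x10:
                    seq = seq.translate(_COMPLEMENT)[::-1]
                fh.write(f"@{qname}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write the generated pangenome to standard files; returns the paths."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "reference.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "pav": os.path.join(outdir, "truth_pav.tsv"),
        "te": os.path.join(outdir, "te.bed"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "vcf": os.path.join(outdir, "truth_snps.vcf"),
        "contigs": os.path.join(outdir, "novel_contigs.tsv"),
    }
    write_fasta(truth.reference, paths["fasta"])
    write_gene_models(truth.gene_models, paths["gff3"])
    write_pav_matrix(truth.truth_pav, paths["pav"])
    write_te_intervals(truth.te_intervals, paths["te"])
    write_tree(truth.tree, paths["tree"])
    write_snps(truth.truth_snps, truth.line_ids, paths["vcf"],
               contigs={c: len(s) for c, s in truth.reference.items()})
    with open(paths["contigs"], "w") as fh:
        fh.write("contig_id\tchrom\tinsertion_pos\tline\n")
        for cid, (chrom, ins) in truth.novel_contigs.items():
            fh.write(f"{cid}\t{chrom}\t{ins}\t{truth.contig_line[cid]}\n")
    return paths
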