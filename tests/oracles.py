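"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(per-base walks, exhaustive enumeration, transcript rebuilds) and stays
independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
import re


def cigar_walk_intervals(pos: int, cigar: str) -> list[tuple[int, int]]:
    """Per-base CIGAR walker: reference positions covered by M/=/X ops."""
    covered = []
    ref = pos
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=X":
            covered.extend(range(ref, ref + n))
            ref += n
        elif op in "DN":
            ref += n
    # collapse to intervals
    out: list[tuple[int, int]] = []
    for p in covered:
        if out and p == out[-1][1] + 1:
            out[-1] = (out[-1][0], p)
        else:
            out.append((p, p))
    return out


def bitmap_coverage(read_intervals, exons) -> tuple[int, int]:
    """Per-base bitmap: (covered exon bases, total exon bases)."""
    exon_bases = set()
    for s, e in exons:
        exon_bases.update(range(s, e + 1))
    read_bases = set()
    for s, e in read_intervals:
        read_bases.update(range(s, e + 1))
    return len(exon_bases & read_bases), len(exon_bases)


_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
               "VVVVAAAADDEEGGGG")
        for (b1, b2, b3), aa in zip(itertools.product(bases, bases, bases),
                                    aas):
            _CODON_TABLE[b1 + b2 + b3] = aa
    return _CODON_TABLE


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def rebuild_translate_effect(exons, strand: str, reference: str,
                             pos: int, alt: str) -> tuple[str, str]:
    """Rebuild both transcripts, translate, and diff the proteins.

    Returns (context, effect) exactly as the classifier should:
    non_coding/none when the position is outside exons, else coding with
    synonymous / nonsense / nonsynonymous from a full protein comparison.
    """
    if not any(s <= pos <= e for s, e in exons):
        return "non_coding", "none"
    mutated = reference[:pos - 1] + alt + reference[pos:]
    table = _codon_table()

    def protein(genome: str) -> str:
        cds = "".join(genome[s - 1:e] for s, e in exons)
        if strand == "-":
            cds = _revcomp(cds)
        return "".join(table[cds[i:i + 3]]
                       for i in range(0, len(cds) - len(cds) % 3, 3))

    p_ref, p_alt = protein(reference), protein(mutated)
    if p_ref == p_alt:
        return "coding", "synonymous"
    diffs = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
    if any(b == "*" and a != "*" for a, b in diffs):
        return "coding", "nonsense"
    return "coding", "nonsynonymous"


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney by exhaustive relabelling (n <= 8).

    U statistic for sample ``a``; p = probability under the permutation
    null of a U at least as extreme (two-tailed by min-tail doubling,
    capped at 1).
    """
    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return u

    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = set(idx)
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = u_stat(x, y)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def hypergeom_fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by hypergeometric tail summation."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


def brute_force_rgene_clusters(order, rgene_ids, max_sep: int = 9):
    """All-pairs linking + union-find over ordinal positions."""
    rset = set(rgene_ids)
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    positions = []
    for seq_genes in order.values():
        pos = [(i, g) for i, g in enumerate(seq_genes) if g in rset]
        positions.append(pos)
        for _, g in pos:
            parent[g] = g
        for (i1, g1), (i2, g2) in itertools.combinations(pos, 2):
            if abs(i1 - i2) <= max_sep:
                union(g1, g2)
    comps: dict[str, set[str]] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    clusters = [c for c in comps.values() if len(c) >= 2]
    n_clustered = sum(len(c) for c in clusters)
    frac = n_clustered / len(rset) if rset else 0.0
    return clusters, frac


def subset_pan_core(matrix, line_cols) -> tuple[int, int]:
    """Set-union / intersection pan & core counts for a subset of columns."""
    present_sets = []
    for col in line_cols:
        present_sets.append({i for i, v in enumerate(matrix[:, col]) if v})
    union = set().union(*present_sets)
    inter = set.intersection(*present_sets)
    return len(union), len(inter)


def monophyletic_sets(tree) -> set[frozenset]:
    """Leaf sets of all non-root nodes of a dendropy tree, via MRCA checks."""
    tree.is_rooted = True
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    out = set()
    for r in range(1, len(taxa)):
        for combo in itertools.combinations(taxa, r):
            mrca = tree.mrca(taxon_labels=list(combo))
            below = {lf.taxon.label for lf in mrca.leaf_iter()}
            if below == set(combo):
                out.add(frozenset(combo))
    return out
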