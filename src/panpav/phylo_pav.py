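"""Placing gene presence/absence patterns on the line phylogeny.

A branch leading to a node is labelled with the genes uniquely present in
exactly the lines below that node (present in all of them, absent from all
others) and those uniquely absent there.  A variable gene whose presence or
absence set equals some node's leaf set is clade-consistent.  Terminal
branches count as clades (single-line unique genes sit on leaf branches);
the root is excluded, since a pattern spanning all lines is core.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .io_formats import PavMatrix

__all__ = ["BranchLabel", "unique_pav_for_subset", "label_tree",
           "clade_consistency_fraction"]


@dataclass
class BranchLabel:
    node_id: str
    leaf_set: frozenset[str]
    uniquely_present: list[str]
    uniquely_absent: list[str]


def unique_pav_for_subset(pav: PavMatrix, subset: frozenset[str] | set[str]
                          ) -> tuple[list[str], list[str]]:
    """Genes whose presence set (resp. absence set) is exactly ``subset``."""
    subset = frozenset(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    all_lines = frozenset(pav.line_ids)
    unknown = subset - all_lines
    if unknown:
        raise ValueError(f"unknown lines: {sorted(unknown)}")
    present, absent = [], []
    for gene in pav.gene_ids:
        pset = pav.presence_set(gene)
        if pset == subset:
            present.append(gene)
        if all_lines - pset == subset:
            absent.append(gene)
    return present, absent


def _node_leafsets(tree: dendropy.Tree) -> list[tuple[str, frozenset[str]]]:
    out = []
    i = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        node_id = node.taxon.label if node.is_leaf() else f"node{i}"
        i += 1
        out.append((node_id, leaves))
    return out


def _check_leaves(pav: PavMatrix, tree: dendropy.Tree) -> None:
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_leaves != set(pav.line_ids):
        raise ValueError(
            f"tree leaves {sorted(tree_leaves)} != PAV lines "
            f"{sorted(pav.line_ids)}")


def label_tree(pav: PavMatrix, tree: dendropy.Tree) -> list[BranchLabel]:
    """One BranchLabel per non-root node (internal and leaf)."""
    _check_leaves(pav, tree)
    all_lines = frozenset(pav.line_ids)
    # index patterns once: presence-set -> genes, absence-set -> genes
    by_presence: dict[frozenset[str], list[str]] = {}
    for gene in pav.gene_ids:
        by_presence.setdefault(pav.presence_set(gene), []).append(gene)
    labels = []
    for node_id, leaves in _node_leafsets(tree):
        present = by_presence.get(leaves, [])
        absent = by_presence.get(all_lines - leaves, [])
        labels.append(BranchLabel(node_id, leaves, list(present),
                                  list(absent)))
    return labels


def clade_consistency_fraction(pav: PavMatrix, tree: dendropy.Tree
                               ) -> dict[str, float | int]:
    """Fraction of variable genes whose PAV pattern matches a tree clade.

    A gene counts when its presence set or its absence set equals the leaf
    set of some non-root node; it is counted once even if both match
    (complementary clades of a rooted tree).  Presence-only and
    absence-only tallies are also reported.
    """
    _check_leaves(pav, tree)
    all_lines = frozenset(pav.line_ids)
    n_lines = len(all_lines)
    clades = {leaves for _, leaves in _node_leafsets(tree)}
    n_variable = 0
    n_consistent = 0
    n_present_match = 0
    n_absent_match = 0
    for gene in pav.gene_ids:
        pset = pav.presence_set(gene)
        if len(pset) == n_lines:
            continue  # core
        n_variable += 1
        pm = pset in clades
        am = (all_lines - pset) in clades
        n_present_match += pm
        n_absent_match += am
        n_consistent += pm or am
    if n_variable == 0:
        raise ValueError("no variable genes")
    return {"n_variable": n_variable, "n_consistent": n_consistent,
            "fraction": n_consistent / n_variable,
            "n_presence_match": n_present_match,
            "n_absence_match": n_absent_match}
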