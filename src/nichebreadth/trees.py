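"""Tree preparation for host and parasite phylogenies.

Trees are :class:`dendropy.Tree` objects throughout.  This module adds the
operations a host-specificity analysis needs before any diversity statistic
can be computed: Newick I/O with unit default branch lengths, ultrametric
checks and node ages, force-ultrametrization by terminal-branch extension,
seeded polytomy resolution, majority-rule consensus with mean edge lengths,
conversion of a Linnaean rank table into a quasi-phylogenetic tree, and a
root-retaining prune that preserves tip depths relative to the full tree.
"""

from __future__ import annotations

import random
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "NewickError",
    "DuplicateTipError",
    "NotUltrametricError",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "tip_labels",
    "tree_height",
    "node_depths",
    "node_ages",
    "is_ultrametric",
    "force_ultrametric_extend",
    "resolve_polytomies",
    "consensus_with_edges",
    "taxonomy_to_tree",
    "prune",
    "cophenetic_matrix",
]

ULTRAMETRIC_RTOL = 1e-9


class NewickError(ValueError):
    """Malformed Newick input."""


class DuplicateTipError(NewickError):
    """Two tips share the same label."""


class NotUltrametricError(ValueError):
    """Operation requires an ultrametric tree."""


# ---------------------------------------------------------------------------
# I/O


def read_newick(text: str, default_branch_length: float = 1.0) -> dendropy.Tree:
    """Parse a single Newick string into a rooted tree.

    Branch lengths absent from the input default to ``default_branch_length``
    (1.0, the convention used when only a topology is known).  Tip labels
    must be unique and non-empty.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise DuplicateTipError(str(e)) from e
    except Exception as e:  # dendropy raises several reader error classes
        raise NewickError(f"could not parse Newick input: {e}") from e
    tree.is_rooted = True
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise NewickError("every tip must carry a non-empty label")
    if len(set(labels)) != len(labels):
        raise DuplicateTipError(f"duplicate tip labels in tree: {sorted(labels)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = default_branch_length
        if node.parent_node is not None and node.edge.length < 0:
            raise NewickError(f"negative branch length {node.edge.length}")
    tree.seed_node.edge.length = None
    return tree


def read_newick_list(text: str) -> list[dendropy.Tree]:
    """Parse one tree per non-empty line (a tree sample)."""
    return [read_newick(line) for line in text.splitlines() if line.strip()]


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip() + ("\n" if not s.strip().endswith("\n") else "")


# ---------------------------------------------------------------------------
# Basic queries


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path lengths (the root itself has depth 0)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    top = max(tip_depths)
    if top == 0:
        return True
    return (top - min(tip_depths)) <= rtol * top


def node_ages(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> dict:
    """Map every node to its age (time before present).

    Requires an ultrametric tree: tips sit at age 0 and the root at the tree
    height T.  Ages satisfy age(parent) = age(child) + branch length(child)
    up to the ultrametricity tolerance.
    """
    if not is_ultrametric(tree, rtol=rtol):
        raise NotUltrametricError(
            "node ages are only defined for ultrametric trees; "
            "apply force_ultrametric_extend first"
        )
    depths = node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    ages = {}
    for node, d in depths.items():
        ages[node] = 0.0 if node.is_leaf() else height - d
    return ages


# ---------------------------------------------------------------------------
# Preparation algorithms


def force_ultrametric_extend(tree: dendropy.Tree) -> dendropy.Tree:
    """Make a tree ultrametric by extending terminal branches.

    Every terminal branch is lengthened by (T - depth of its tip), T being
    the maximal root-to-tip depth; internal branches are untouched.  The
    operation is idempotent.
    """
    out = tree.clone(depth=1)
    depths = node_depths(out)
    height = max(depths[leaf] for leaf in out.leaf_node_iter())
    for leaf in out.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + (height - depths[leaf])
    return out


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Resolve multifurcations into a seeded random sequence of binary splits.

    New internal branches get length 0, so all pairwise tip path lengths are
    preserved exactly and ultrametricity is maintained.  A binary tree is
    returned unchanged (as a copy).
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return out


def _clades_with_lengths(tree: dendropy.Tree) -> dict:
    """Map each clade (frozenset of tip labels, root excluded) to its edge length."""
    out = {}
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = frozenset([node.taxon.label])
        else:
            tips_below[node] = frozenset().union(*(tips_below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            out[tips_below[node]] = node.edge.length or 0.0
    return out


def consensus_with_edges(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule (>50%) consensus with per-clade mean edge lengths.

    All input trees must share one tip set.  A clade is retained when it
    appears in more than half of the trees; its edge length is the mean of
    that clade's edge lengths over the trees containing it.  This is an
    edge-length-aware consensus in the spirit of consensus methods that
    average branch lengths over a tree sample.
    """
    if not trees:
        raise ValueError("need at least one tree")
    tipsets = [frozenset(tip_labels(t)) for t in trees]
    full = tipsets[0]
    if any(ts != full for ts in tipsets):
        raise ValueError("all trees must share an identical tip set")

    n = len(trees)
    counts: dict = {}
    length_sums: dict = {}
    for t in trees:
        for clade, length in _clades_with_lengths(t).items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length
    kept = [c for c, k in counts.items() if k * 2 > n]
    mean_len = {c: length_sums[c] / counts[c] for c in kept}

    # Majority clades are pairwise compatible: build by nesting, largest first.
    kept.sort(key=len, reverse=True)
    taxa = dendropy.TaxonNamespace()
    out = dendropy.Tree(taxon_namespace=taxa)
    out.is_rooted = True
    node_for: dict = {full: out.seed_node}
    for clade in kept:
        parent_clade = min(
            (c for c in node_for if clade < c), key=len, default=full
        )
        node = dendropy.Node()
        node.edge.length = mean_len[clade]
        if len(clade) == 1:
            node.taxon = taxa.new_taxon(label=next(iter(clade)))
        node_for[parent_clade].add_child(node)
        node_for[clade] = node
    return out


def taxonomy_to_tree(table: pd.DataFrame) -> dendropy.Tree:
    """Convert a Linnaean rank table into a quasi-phylogenetic tree.

    ``table`` must have columns species, genus, subfamily, family.  The tree
    has four levels below the root, every edge of length 1, so congeners sit
    at cophenetic distance 2, confamilials sharing only the subfamily 4,
    sharing only the family 6, and members of different families 8.  The
    result is ultrametric of height 4 by construction.
    """
    required = ["species", "genus", "subfamily", "family"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"taxonomy table lacks columns: {missing}")
    tt = table[required].astype(str)
    if tt.isin(["", "nan", "None"]).any().any() or table[required].isna().any().any():
        raise ValueError("every species needs genus, subfamily, and family assigned")
    if tt["species"].duplicated().any():
        dups = sorted(tt.loc[tt["species"].duplicated(), "species"])
        raise ValueError(f"duplicate species in taxonomy table: {dups}")
    for child, parent in [("genus", "subfamily"), ("subfamily", "family")]:
        counts = tt.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValueError(
                f"inconsistent nesting: {child} {sorted(bad.index)} assigned "
                f"to multiple {parent} values"
            )

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    fam_nodes: dict = {}
    sub_nodes: dict = {}
    gen_nodes: dict = {}

    def _child(parent_node, key, store):
        if key not in store:
            node = dendropy.Node()
            node.edge.length = 1.0
            parent_node.add_child(node)
            store[key] = node
        return store[key]

    for row in tt.itertuples(index=False):
        fam = _child(tree.seed_node, row.family, fam_nodes)
        sub = _child(fam, (row.family, row.subfamily), sub_nodes)
        gen = _child(sub, (row.family, row.subfamily, row.genus), gen_nodes)
        leaf = dendropy.Node()
        leaf.edge.length = 1.0
        leaf.taxon = taxa.new_taxon(label=row.species)
        gen.add_child(leaf)
    return tree


def prune(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``tips``, keeping the original root as root.

    Unbranched internal paths are collapsed with lengths summed, but the tree
    is *not* re-rooted at the MRCA of the retained tips: root-to-tip depths
    are preserved, so evolutionary periods computed downstream retain the
    full tree's depth context.  (Two congeneric hosts must score a low
    phylogenetic breadth, which requires knowing how deep the full tree is.)
    """
    keep = set(tips)
    if not keep:
        raise ValueError("need at least one tip to retain")
    have = set(tip_labels(tree))
    unknown = keep - have
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")

    out = tree.clone(depth=1)
    # drop unwanted leaves, then any internal node left childless
    changed = True
    while changed:
        changed = False
        for node in list(out.leaf_node_iter()):
            if node.parent_node is None:
                continue
            if node.taxon is None or node.taxon.label not in keep:
                node.parent_node.remove_child(node)
                changed = True
    # collapse unary non-root internal nodes; the root stays in place (possibly
    # unary) so root-to-tip depths and all pairwise distances are preserved
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder_node_iter()):
            kids = node.child_nodes()
            if node.parent_node is not None and len(kids) == 1:
                child = kids[0]
                child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
                parent = node.parent_node
                node.remove_child(child)
                parent.remove_child(node)
                parent.add_child(child)
                changed = True
    out.taxon_namespace = dendropy.TaxonNamespace(
        [leaf.taxon for leaf in out.leaf_node_iter()]
    )
    return out


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs tip path-length (patristic distance) matrix."""
    import numpy as np

    depths = node_depths(tree)
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    tip_depth = {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}
    n = len(labels)
    dm = np.zeros((n, n))
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [node.taxon.label]
        else:
            kids = node.child_nodes()
            tips_below[node] = [lab for k in kids for lab in tips_below[k]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for la in tips_below[kids[a]]:
                        for lb in tips_below[kids[b]]:
                            i, j = idx[la], idx[lb]
                            d = tip_depth[la] + tip_depth[lb] - 2 * depths[node]
                            dm[i, j] = dm[j, i] = d
    return pd.DataFrame(dm, index=labels, columns=labels)
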