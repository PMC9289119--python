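"""Phylogenies: Newick I/O, majority-rule consensus, Brownian covariance.

The Brownian variance-covariance matrix V over a set of tip species has
V[i, j] equal to the branch-length distance from the root to the most
recent common ancestor of tips i and j (shared evolutionary time), and
V[i, i] equal to the root-to-tip distance.  Under Brownian trait
evolution, trait values at the tips are jointly normal with covariance
sigma^2 * V; V is passed unscaled to the regressions, which profile the
scale out.

The consensus of a tree sample is the 50% majority rule: a clade is
retained if it occurs in more than ``threshold`` of the trees, its branch
length is the mean over the trees containing it, and unresolved regions
become polytomies.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import dendropy
import numpy as np
import pandas as pd


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def read_trees(path) -> list[dendropy.Tree]:
    """Read a file of one Newick tree per line into dendropy trees.

    All trees must share the same tip label set; labels must be unique
    within each tree.  Malformed lines raise a parse error naming the line.
    """
    trees: list[dendropy.Tree] = []
    namespace = dendropy.TaxonNamespace()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line, schema="newick", taxon_namespace=namespace,
                    preserve_underscores=True,
                )
            except Exception as exc:  # dendropy raises several error types
                raise ValueError(f"malformed Newick on line {lineno}: {exc}") from exc
            trees.append(tree)
    if not trees:
        raise ValueError(f"no trees found in {path}")
    check_shared_tips(trees)
    return trees


def check_shared_tips(trees: list[dendropy.Tree]) -> set[str]:
    """Verify all trees share one tip set with unique labels; return it."""
    ref = tip_labels(trees[0])
    ref_set = set(ref)
    if len(ref_set) != len(ref):
        raise ValueError("duplicate tip labels in tree 1")
    for i, tree in enumerate(trees[1:], start=2):
        labels = tip_labels(tree)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate tip labels in tree {i}")
        if set(labels) != ref_set:
            extra = sorted(set(labels) - ref_set)
            missing = sorted(ref_set - set(labels))
            raise ValueError(
                f"tree {i} tip set differs from tree 1: "
                f"extra={extra}, missing={missing}"
            )
    return ref_set


def _clades_and_lengths(tree: dendropy.Tree):
    """Yield (clade, edge length) per node: clades are frozensets of labels."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade = frozenset([node.taxon.label])
        else:
            clade = frozenset().union(*(out[c][0] for c in node.child_nodes()))
        out[node] = (clade, node.edge.length)
    return list(out.values())


def _compatible(clade: frozenset, accepted: list[frozenset]) -> bool:
    return all(
        clade.isdisjoint(other) or clade <= other or other <= clade
        for other in accepted
    )


def consensus_tree(
    trees: list[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus with mean branch lengths.

    A (rooted) clade is retained when it occurs in strictly more than
    ``threshold`` of the trees; for thresholds below 0.5 retained clades
    are added greedily by frequency, skipping incompatible ones.  The
    branch length of a retained clade is the mean of its subtending edge
    lengths over the trees that contain it; tip branch lengths are means
    over all trees.
    """
    if not trees:
        raise ValueError("empty tree list")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    all_tips = frozenset(check_shared_tips(trees))
    n = len(trees)

    counts: Counter = Counter()
    lengths: defaultdict = defaultdict(list)
    for tree in trees:
        for clade, length in _clades_and_lengths(tree):
            counts[clade] += 1
            lengths[clade].append(length if length is not None else 0.0)

    def mean_len(clade):
        # fsum: exact accumulation, so the mean is input-order invariant
        vals = lengths[clade]
        return math.fsum(vals) / len(vals)

    internal = [
        c for c in counts
        if 1 < len(c) < len(all_tips) and counts[c] / n > threshold
    ]
    # larger clades first, then more frequent: greedy compatibility filter
    internal.sort(key=lambda c: (-len(c), -counts[c], sorted(c)))
    accepted: list[frozenset] = []
    for clade in internal:
        if _compatible(clade, accepted):
            accepted.append(clade)

    children: defaultdict = defaultdict(list)
    nodes = [all_tips] + accepted + [frozenset([t]) for t in sorted(all_tips)]
    for node in nodes[1:]:
        parent = min(
            (p for p in nodes if node < p), key=len
        )
        children[parent].append(node)

    def to_newick(clade) -> str:
        if len(clade) == 1:
            (label,) = clade
            quoted = label.replace(" ", "_")
            return f"{quoted}:{mean_len(clade)!r}"
        parts = ",".join(to_newick(c) for c in sorted(children[clade], key=sorted))
        if clade == all_tips:
            return f"({parts})"
        return f"({parts}):{mean_len(clade)!r}"

    newick = to_newick(all_tips) + ";"
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def brownian_vcv(tree: dendropy.Tree, species_order: list[str]) -> pd.DataFrame:
    """Brownian variance-covariance matrix over ``species_order``.

    V[i, j] is the root-to-MRCA(i, j) path length, V[i, i] the root-to-tip
    distance.  Restricting to a subset of tips here is identical to
    pruning the tree (keeping its root) first and then computing V.
    """
    if len(set(species_order)) != len(species_order):
        raise ValueError("species_order contains duplicates")
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species_order if s not in present]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    idx = {s: i for i, s in enumerate(species_order)}
    n = len(species_order)
    V = np.zeros((n, n))

    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            depth[node] = depth[node.parent_node] + bl

    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in idx:
                below[node] = [idx[label]]
                V[idx[label], idx[label]] = depth[node]
            else:
                below[node] = []
        else:
            groups = [below[c] for c in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            V[i, j] = V[j, i] = depth[node]
            below[node] = [i for g in groups for i in g]

    return pd.DataFrame(V, index=species_order, columns=species_order)


def write_trees(trees: list[dendropy.Tree], path) -> None:
    """Write trees one Newick per line (branch lengths kept)."""
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick", suppress_rooting=True
                ).strip()
                + "\n"
            )
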