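"""Phylogenetic tree plumbing: newick I/O, validation, neighbor-joining.

Trees are held as rooted :class:`dendropy.Tree` objects with tip labels
equal to specimen IDs and branch lengths in expected substitutions/site.
The neighbor-joining builder is deliberately plain plumbing — it gives the
tree-based delimiter a substrate when no externally inferred (e.g. maximum
likelihood) tree is supplied; any rooted newick tree can be used instead.
"""

from __future__ import annotations

import io
import os

import dendropy
import numpy as np
import skbio

from .distances import DistanceMatrix

__all__ = ["read_tree", "write_tree", "validate_tree", "nj_tree", "tree_from_newick"]


class TreeError(ValueError):
    pass


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tip labelling and branch-length invariants; return the tree."""
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree has an unlabelled tip")
        labels.append(leaf.taxon.label)
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
    )
    return validate_tree(tree)


def read_tree(newick_path: str | os.PathLike) -> dendropy.Tree:
    with open(newick_path) as fh:
        return tree_from_newick(fh.read())


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
        )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix, midpoint-rooted.

    Negative branch-length estimates (a well-known NJ artefact) are clamped
    to zero. Masked (undefined) entries are refused: impute or prune those
    specimens first.
    """
    off_diag = dm.mask & ~np.eye(len(dm), dtype=bool)
    if off_diag.any():
        i, j = np.argwhere(off_diag)[0]
        raise TreeError(
            f"distance matrix has undefined entries (e.g. {dm.ids[i]} vs {dm.ids[j]}); "
            "impute the distances or prune the affected specimens before NJ"
        )
    if len(dm) < 3:
        raise TreeError("neighbor joining requires at least 3 specimens")
    sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.ids))
    tree = skbio.tree.nj(sk_dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree = tree.root_at_midpoint()
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return tree_from_newick(buf.getvalue())
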