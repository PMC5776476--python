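"""Rooted phylogenetic trees (newick I/O and branch bookkeeping).

Trees are held as :class:`dendropy.Tree` objects; this module adds the thin
conventions the diversity metrics rely on: rooted, unique leaf labels,
non-negative branch lengths (``None`` treated as 0, root edge allowed 0).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "read_tree",
    "tree_from_string",
    "write_tree",
    "leaf_names",
    "total_branch_length",
    "validate_tree",
    "edge_table",
]


class TreeError(ValueError):
    """Raised for malformed trees or label mismatches."""


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    validate_tree(tree)
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    return tree_from_string(Path(path).read_text())


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    )


def validate_tree(tree: dendropy.Tree) -> None:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree contains an unlabeled leaf")
        if leaf.taxon.label in seen:
            raise TreeError(f"duplicate leaf label {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length} in tree")


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all non-root branch lengths."""
    return float(
        sum((n.edge.length or 0.0) for n in tree.preorder_node_iter() if n.parent_node is not None)
    )


def edge_table(tree: dendropy.Tree) -> tuple[np.ndarray, list[list[int]], list[str]]:
    """Postorder edge decomposition used by PD and UniFrac.

    Returns ``(lengths, leaf_sets, leaves)`` where ``lengths[e]`` is the
    branch length of the e-th non-root edge in postorder, ``leaf_sets[e]``
    the indices (into ``leaves``) of the leaves descending through that
    edge, and ``leaves`` the leaf labels in postorder.
    """
    leaves: list[str] = []
    lengths: list[float] = []
    leaf_sets: list[list[int]] = []
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = len(leaves)
            leaves.append(node.taxon.label)
            mine = [idx]
        else:
            mine = []
            for child in node.child_nodes():
                mine.extend(below.pop(id(child)))
        below[id(node)] = mine
        if node.parent_node is not None:
            lengths.append(node.edge.length or 0.0)
            leaf_sets.append(mine)
    return np.asarray(lengths, dtype=float), leaf_sets, leaves
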