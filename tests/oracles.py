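"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with grainscape: trees are handled as
scikit-bio TreeNode objects and every quantity is computed by direct
enumeration (leaf sets per edge, root paths, O(n^2) distance scans).
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode


def bf_chao1(counts) -> float:
    counts = [c for c in counts if c > 0]
    s = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return s + f1 * (f1 - 1) / (2 * (f2 + 1))


def bf_inverse_simpson(counts) -> float:
    total = sum(counts)
    return 1.0 / sum((c / total) ** 2 for c in counts if c > 0)


def skbio_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def _edges_with_leafsets(tree: TreeNode):
    """(length, descendant leaf-name set) for every non-root edge."""
    edges = []
    for node in tree.postorder(include_self=False):
        leaves = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        edges.append((node.length or 0.0, leaves))
    return edges


def bf_faith_pd(otus: set[str], tree: TreeNode) -> float:
    """Sum of edges whose descendant leaves intersect the presence set."""
    return sum(l for l, leaves in _edges_with_leafsets(tree) if leaves & set(otus))


def bf_unweighted_unifrac(set_a: set[str], set_b: set[str], tree: TreeNode) -> float:
    unique = shared = 0.0
    for l, leaves in _edges_with_leafsets(tree):
        in_a, in_b = bool(leaves & set_a), bool(leaves & set_b)
        if in_a and in_b:
            shared += l
        elif in_a or in_b:
            unique += l
    return unique / (unique + shared)


def bf_weighted_unifrac(counts_a: dict, counts_b: dict, tree: TreeNode,
                        normalized: bool = True) -> float:
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for l, leaves in _edges_with_leafsets(tree):
        pa = sum(counts_a.get(o, 0) for o in leaves) / ta
        pb = sum(counts_b.get(o, 0) for o in leaves) / tb
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    return num / den if normalized else num


def bf_nearest_neighbor(coords: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-neighbor distances."""
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        out[i] = d.min()
    return out


def bf_coverage(grain_otu_sets: list[set[str]], bulk_otus: set[str]) -> list[float]:
    """Deterministic pooling coverage: fraction of bulk OTUs in each prefix pool."""
    covs, pool = [], set()
    for s in grain_otu_sets:
        pool |= s
        covs.append(len(pool & bulk_otus) / len(bulk_otus))
    return covs
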