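"""Pairwise community comparison: UniFrac distances and presence/absence overlap.

Both UniFrac variants are computed from a single postorder traversal that
accumulates, for every branch, the read mass descending through it for each
sample:

* unweighted UniFrac — (branch length observed under exactly one sample) /
  (branch length observed under at least one sample);
* weighted UniFrac — ``sum_b L_b |p_A(b) - p_B(b)|`` with ``p_X(b)`` the
  fraction of sample X's reads below branch b, normalized by
  ``sum_b L_b (p_A(b) + p_B(b))`` by default (the GUniFrac alpha=1 form).

Similarities quoted alongside distances are ``1 - d``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .otu import OtuTable
from .trees import TreeError

__all__ = [
    "branch_masses",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "shared_otu_fraction",
    "jaccard_index",
]


def branch_masses(tree: dendropy.Tree, table: OtuTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant read mass for every sample.

    Returns ``(lengths, masses)`` with ``lengths`` of shape (n_edges,) and
    ``masses`` of shape (n_edges, n_samples): ``masses[e, s]`` is the summed
    count of sample ``s`` over the leaves below edge ``e``. Every OTU in the
    table must be a leaf of the tree (extra leaves carry zero mass).
    """
    col = {otu: j for j, otu in enumerate(table.otu_ids)}
    counts = table.counts.T  # otus x samples
    n_samples = table.n_samples
    seen: set[str] = set()
    lengths: list[float] = []
    mass_rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            seen.add(label)
            j = col.get(label)
            m = counts[j].astype(float) if j is not None else np.zeros(n_samples)
        else:
            m = np.zeros(n_samples)
            for child in node.child_nodes():
                m += below.pop(id(child))
        below[id(node)] = m
        if node.parent_node is not None:
            lengths.append(node.edge.length or 0.0)
            mass_rows.append(m)
    missing = set(col) - seen
    if missing:
        raise TreeError(f"OTUs not found in tree: {sorted(missing)[:10]}")
    return np.asarray(lengths), np.vstack(mass_rows) if mass_rows else np.zeros((0, n_samples))


def _pair_masses(sample_a: pd.Series, sample_b: pd.Series, tree: dendropy.Tree):
    otus = sorted(set(sample_a.index) | set(sample_b.index))
    data = pd.DataFrame(
        [sample_a.reindex(otus, fill_value=0), sample_b.reindex(otus, fill_value=0)],
        index=["A", "B"],
    )
    return branch_masses(tree, OtuTable(data, validate=False))


def _unweighted_from_masses(lengths: np.ndarray, ma: np.ndarray, mb: np.ndarray) -> float:
    in_a, in_b = ma > 0, mb > 0
    either = float(lengths[in_a | in_b].sum())
    if either == 0:
        raise ValueError("both communities are empty on the tree")
    unique = float(lengths[in_a ^ in_b].sum())
    return unique / either


def unweighted_unifrac(
    sample_a: pd.Series, sample_b: pd.Series, tree: dendropy.Tree
) -> float:
    """Unweighted UniFrac distance between two count vectors (presence only)."""
    lengths, masses = _pair_masses(sample_a, sample_b, tree)
    return _unweighted_from_masses(lengths, masses[:, 0], masses[:, 1])


def weighted_unifrac(
    sample_a: pd.Series,
    sample_b: pd.Series,
    tree: dendropy.Tree,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two count vectors.

    Normalized (default) gives the GUniFrac alpha=1 form in [0, 1]; the raw
    variant returns the numerator ``sum_b L_b |p_A(b) - p_B(b)|`` alone.
    """
    depth_a, depth_b = float(sample_a.sum()), float(sample_b.sum())
    if depth_a == 0 or depth_b == 0:
        raise ValueError("weighted UniFrac requires positive read totals")
    lengths, masses = _pair_masses(sample_a, sample_b, tree)
    pa, pb = masses[:, 0] / depth_a, masses[:, 1] / depth_b
    num = float(np.sum(lengths * np.abs(pa - pb)))
    if not normalized:
        return num
    den = float(np.sum(lengths * (pa + pb)))
    if den == 0:
        raise ValueError("tree carries no branch length below the compared samples")
    return num / den


def unifrac_matrix(
    table: OtuTable,
    tree: dendropy.Tree,
    metric: str = "unweighted",
    normalized: bool = True,
) -> pd.DataFrame:
    """Symmetric sample x sample UniFrac distance matrix.

    Branch masses are accumulated once for the whole table (one postorder
    pass), then pairs are combined vectorially.
    """
    if metric not in ("unweighted", "weighted"):
        raise ValueError(f"unknown metric {metric!r}")
    lengths, masses = branch_masses(tree, table)
    ids = table.sample_ids
    depths = table.depths().to_numpy().astype(float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "unweighted":
                d = _unweighted_from_masses(lengths, masses[:, i], masses[:, j])
            else:
                if depths[i] == 0 or depths[j] == 0:
                    raise ValueError("weighted UniFrac requires positive read totals")
                pa, pb = masses[:, i] / depths[i], masses[:, j] / depths[j]
                num = float(np.sum(lengths * np.abs(pa - pb)))
                if normalized:
                    den = float(np.sum(lengths * (pa + pb)))
                    d = num / den if den else 0.0
                else:
                    d = num
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def shared_otu_fraction(reference: set[str], query: set[str]) -> float:
    """Fraction of the reference OTU set also present in the query.

    Asymmetric by design: with the bulk-sediment OTU set as reference, this
    is the share of bulk richness a grain (or grain pool) harbors.
    """
    reference, query = set(reference), set(query)
    if not reference:
        raise ValueError("reference OTU set must be nonempty")
    return len(reference & query) / len(reference)


def jaccard_index(set_a: set[str], set_b: set[str]) -> float:
    """Symmetric Jaccard similarity |A n B| / |A u B|."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        raise ValueError("both sets are empty")
    return len(set_a & set_b) / len(union)
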