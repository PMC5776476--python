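"""Grain-pooling coverage curves: how many grains recover bulk-sediment richness.

Procedure: rarefy every grain to a common depth ``n`` once; order grains by
their (rarefied) observed richness, decreasing or increasing; for each pool
size ``k`` pool the first ``k`` grains (exactly ``k*n`` reads), rarefy the
pooled bulk reference to the same ``k*n`` reads, and report the fraction of
the bulk subsample's OTU richness present in the grain pool. The bulk
subsample is replicated to tame subsampling noise; grain subsamples stay
fixed across ``k``, so pool composition is strictly nested in ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = ["CoverageCurve", "coverage_curve", "grains_to_reach", "NOT_REACHED"]

#: Sentinel returned by :func:`grains_to_reach` when the target is never met.
NOT_REACHED = -1


@dataclass
class CoverageCurve:
    order: str
    grain_order: list[str]
    points: pd.DataFrame  # columns: k, coverage, sd, depth_compared, truncated
    grain_depth: int
    n_replicates: int
    seed: int | None = None

    def coverage_at(self, k: int) -> float:
        row = self.points.loc[self.points["k"] == k]
        if row.empty:
            raise KeyError(f"no pool of size {k} in curve")
        return float(row["coverage"].iloc[0])


def _order_grains(sub: OtuTable, order: str, custom: list[str] | None) -> list[str]:
    if order == "custom":
        if not custom:
            raise ValueError("order='custom' requires an explicit grain order")
        return list(custom)
    if order not in ("decreasing", "increasing"):
        raise ValueError(f"unknown order {order!r}")
    richness = (sub.data > 0).sum(axis=1)
    # ties broken by sample id for determinism
    ranked = sorted(sub.sample_ids, key=lambda s: (-richness[s], s))
    return ranked if order == "decreasing" else ranked[::-1]


def coverage_curve(
    table: OtuTable,
    grain_ids: list[str],
    bulk_ids: list[str],
    order: str = "decreasing",
    n_replicates: int = 10,
    seed: int | None = None,
    grain_depth: int | None = None,
    custom_order: list[str] | None = None,
    single_bulk: str | None = None,
) -> CoverageCurve:
    """Fraction of pooled-bulk OTU richness shared by pools of 1..K grains.

    ``grain_depth`` defaults to the lowest grain depth. The bulk reference is
    the concatenation of ``bulk_ids`` counts (``single_bulk`` restricts it to
    one bulk sample). When ``k * grain_depth`` exceeds the bulk reference's
    total depth the comparison is truncated to the bulk depth, with a
    warning; the depth actually compared is recorded per point.
    """
    if set(grain_ids) & set(bulk_ids):
        raise ValueError("grain and bulk sample sets must be disjoint")
    if not grain_ids or not bulk_ids:
        raise ValueError("need at least one grain and one bulk sample")
    rng = np.random.default_rng(seed)
    grains = table.select_samples(grain_ids)
    if grain_depth is None:
        grain_depth = int(grains.depths().min())
    from .otu import subsample  # local import to avoid cycle at module load

    grains_sub = subsample(grains, grain_depth, seed=rng, keep_zeros=True)
    ranked = _order_grains(grains_sub, order, custom_order)

    bulk_source = [single_bulk] if single_bulk else bulk_ids
    bulk_pooled = table.select_samples(bulk_source).data.sum(axis=0)
    bulk_total = int(bulk_pooled.sum())
    bulk_counts = bulk_pooled.to_numpy()
    bulk_otus = bulk_pooled.index.to_numpy()

    rows = []
    pool = np.zeros(grains_sub.n_otus, dtype=np.int64)
    for k, gid in enumerate(ranked, start=1):
        pool = pool + grains_sub.sample(gid).to_numpy()
        pool_otus = set(np.asarray(grains_sub.otu_ids)[pool > 0])
        target = k * grain_depth
        truncated = target > bulk_total
        if truncated:
            warnings.warn(
                f"pool depth {target} exceeds bulk_pooled depth {bulk_total}; "
                f"comparing at {bulk_total}",
                stacklevel=2,
            )
            target = bulk_total
        covs = []
        for _ in range(n_replicates):
            if target == bulk_total:
                draw = bulk_counts
            else:
                draw = rng.multivariate_hypergeometric(bulk_counts, target, method="count")
            bulk_set = set(bulk_otus[draw > 0])
            covs.append(len(bulk_set & pool_otus) / len(bulk_set))
        covs = np.asarray(covs)
        rows.append(
            {
                "k": k,
                "coverage": float(covs.mean()),
                "sd": float(covs.std(ddof=1)) if len(covs) > 1 else 0.0,
                "depth_compared": int(target),
                "truncated": truncated,
            }
        )
    return CoverageCurve(
        order=order,
        grain_order=ranked,
        points=pd.DataFrame(rows),
        grain_depth=grain_depth,
        n_replicates=n_replicates,
        seed=seed,
    )


def grains_to_reach(curve: CoverageCurve, target: float) -> int:
    """Smallest pool size whose mean coverage reaches ``target``.

    Returns :data:`NOT_REACHED` (= -1) if no pool size does. ``target`` must
    lie in [0, 1]; a target of 0 is trivially met at k=1 (coverage >= 0).
    """
    if not 0 <= target <= 1:
        raise ValueError(f"target must be in [0, 1], got {target}")
    pts = curve.points.sort_values("k")
    hit = pts.loc[pts["coverage"] >= target, "k"]
    return int(hit.iloc[0]) if len(hit) else NOT_REACHED
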