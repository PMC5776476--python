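"""Core community: OTUs present on every grain, and their read-share accounting.

The core community of a set of grain samples is the set of OTUs detected
(count >= a presence threshold, default 1) in at least ``min_prevalence`` of
the samples — all of them by default. The report quantifies how small that
set is relative to total observed richness and how large its share of each
sample's reads is, and a family-level breakdown apportions each sample's
reads among core families, a pooled "other core community" bucket for
families of small mean share, and the non-core remainder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable, TaxonomyMap

__all__ = ["CoreReport", "find_core", "core_family_breakdown"]

OTHER_CORE_LABEL = "other core community"
NON_CORE_LABEL = "non-core community"


@dataclass
class CoreReport:
    core_otu_ids: list[str]
    core_otu_count: int
    total_otu_count: int
    core_fraction_of_otus: float
    per_sample_core_read_share: pd.Series
    sample_ids: list[str] = field(default_factory=list)
    min_prevalence: float = 1.0
    presence_min: int = 1

    @property
    def mean_core_read_share(self) -> float:
        return float(self.per_sample_core_read_share.mean())


def find_core(
    table: OtuTable,
    sample_subset: list[str] | None = None,
    min_prevalence: float = 1.0,
    presence_min: int = 1,
    warn_unequal_depth: bool = True,
) -> CoreReport:
    """Identify the core OTU set over ``sample_subset`` (default: all samples).

    An OTU is core when its count is >= ``presence_min`` in at least
    ``ceil(min_prevalence * n_samples)`` of the subset's samples. Shares are
    meaningful across samples only at equal depth, so unequal depths trigger
    a warning (subsample first).
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    if presence_min < 1:
        raise ValueError(f"presence_min must be >= 1, got {presence_min}")
    subset = table.sample_ids if sample_subset is None else list(sample_subset)
    if not subset:
        raise ValueError("sample subset must be nonempty")
    sub = table.select_samples(subset)
    depths = sub.depths()
    if warn_unequal_depth and depths.nunique() > 1:
        warnings.warn(
            "samples have unequal depth; core read shares are depth-biased "
            "(subsample to equal depth first)",
            stacklevel=2,
        )
    observed = sub.data.loc[:, sub.data.sum(axis=0) > 0]
    prevalence = (observed >= presence_min).sum(axis=0)
    needed = math.ceil(min_prevalence * len(subset))
    core_mask = prevalence >= needed
    core_ids = list(observed.columns[core_mask])
    share = observed.loc[:, core_mask].sum(axis=1) / depths
    return CoreReport(
        core_otu_ids=core_ids,
        core_otu_count=len(core_ids),
        total_otu_count=observed.shape[1],
        core_fraction_of_otus=len(core_ids) / observed.shape[1] if observed.shape[1] else 0.0,
        per_sample_core_read_share=share,
        sample_ids=subset,
        min_prevalence=min_prevalence,
        presence_min=presence_min,
    )


def core_family_breakdown(
    report: CoreReport,
    table: OtuTable,
    tax: TaxonomyMap,
    rank: str = "family",
    min_mean_share: float = 0.005,
) -> pd.DataFrame:
    """Per-sample read share of each core family, of total sample reads.

    Core families whose mean share across samples falls below
    ``min_mean_share`` are pooled into ``"other core community"``; the
    non-core remainder completes each row, so rows sum to 1.
    """
    sub = table.select_samples(report.sample_ids)
    depths = sub.depths().astype(float)
    core = set(report.core_otu_ids)
    core_cols = [o for o in sub.otu_ids if o in core]
    labels = pd.Index([tax.at_rank(o, rank) for o in core_cols], name=rank)
    fam_counts = sub.data[core_cols].T.groupby(labels, sort=True).sum().T
    shares = fam_counts.div(depths, axis=0)
    mean_share = shares.mean(axis=0)
    keep = mean_share >= min_mean_share
    out = shares.loc[:, keep].copy()
    out[OTHER_CORE_LABEL] = shares.loc[:, ~keep].sum(axis=1)
    out[NON_CORE_LABEL] = 1.0 - shares.sum(axis=1)
    return out
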