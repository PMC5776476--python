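"""Synthetic sand-grain communities and colonization point patterns.

The generator reproduces the statistical structure the downstream analyses
assume, so the whole pipeline is testable without sequence or image data:

* a planted **core community** present on every grain and carrying a
  configurable share of each grain's reads (defaults: 394 core OTUs at 60%
  of reads, the middle of "one-half to two-thirds");
* thousands of **rare OTUs**, each included on a grain with a fixed
  occupancy probability, producing long-tailed rank-abundance curves and
  grain-to-grain presence differences;
* **bulk samples** drawn from the pooled grain mixture plus bulk-only rare
  OTUs, so grains recover only part of bulk richness;
* a random rooted bifurcating tree over all OTUs with exponential branch
  lengths, and a family-level taxonomy;
* **point patterns** with dense protected patches and sparse exposed areas,
  optionally Thomas-clustered, with touching-pair flags.

All draws come from one ``numpy`` Generator per call: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .otu import OtuTable, TaxonomyMap
from .spatial import PointPattern, flag_touching
from .trees import tree_from_string

__all__ = [
    "CommunityModel",
    "SpatialModel",
    "SyntheticDataset",
    "generate_otu_tables",
    "generate_point_pattern",
    "random_tree_newick",
]


@dataclass
class CommunityModel:
    """Parameters of the synthetic grain/bulk community.

    Defaults mirror the study conditions: 17 grains + 3 bulk replicates,
    394 core OTUs at 60% of each grain's reads, 4000 rare OTUs at 15%
    per-grain occupancy, grain depths 44901-58769 and bulk depths
    75134-137585 reads.
    """

    n_grains: int = 17
    n_bulk: int = 3
    n_core_otus: int = 394
    n_rare_otus: int = 4000
    core_read_fraction: float = 0.6
    rare_occupancy: float = 0.15
    abundance_shape: float = 1.5  # lognormal sigma of OTU base abundances
    depth_range: tuple[int, int] = (44901, 58769)
    bulk_depth_range: tuple[int, int] = (75134, 137585)
    n_bulk_only_otus: int = 800
    bulk_only_read_fraction: float = 0.05
    grain_noise_sigma: float = 0.5  # per-grain lognormal jitter of OTU weights
    n_families: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.n_core_otus < 1:
            raise ValueError("n_core_otus must be >= 1")
        if self.n_rare_otus < 0:
            raise ValueError("n_rare_otus must be >= 0")
        if self.n_core_otus + self.n_rare_otus == 0:
            raise ValueError("community must contain at least one OTU")
        if not 0 <= self.core_read_fraction <= 1:
            raise ValueError("core_read_fraction must be in [0, 1]")
        if not 0 < self.rare_occupancy <= 1:
            raise ValueError("rare_occupancy must be in (0, 1]")
        for rng_name in ("depth_range", "bulk_depth_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 1:
                raise ValueError(f"{rng_name} minimum must be >= 1")
            if lo > hi:
                raise ValueError(f"{rng_name} must satisfy min <= max")
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")


@dataclass
class SpatialModel:
    """Parameters of the synthetic colonization pattern.

    Default intensities put protected patches ~80x denser than exposed
    areas (1.0 vs 0.012 cells/um^2), reproducing the order-of-magnitude
    nearest-neighbor contrast between the two patch classes; with an 8%
    protected patch fraction the window-wide density is ~0.09 cells/um^2.
    """

    window: tuple[float, float] = (200.0, 200.0)
    exposed_intensity: float = 0.012
    protected_intensity: float = 1.0
    protected_patch_fraction: float = 0.08
    cluster_scale: float = 0.0  # um; 0 = homogeneous Poisson within patches
    points_per_cluster: float = 5.0
    touching_radius_um: float = 1.0
    n_grid: int = 16
    seed: int = 0

    def __post_init__(self):
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window must have positive area")
        if self.exposed_intensity < 0 or self.protected_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if not 0 <= self.protected_patch_fraction <= 1:
            raise ValueError("protected_patch_fraction must be in [0, 1]")
        if self.cluster_scale < 0:
            raise ValueError("cluster_scale must be non-negative")


@dataclass
class SyntheticDataset:
    table: OtuTable
    tree: object | None
    taxonomy: TaxonomyMap
    grain_ids: list[str]
    bulk_ids: list[str]
    core_otu_ids: list[str]
    model: CommunityModel

    def params_json(self) -> dict:
        return asdict(self.model)


def random_tree_newick(labels: Sequence[str], rng: np.random.Generator,
                       branch_scale: float = 0.1) -> str:
    """Random rooted bifurcating topology by iterative random joins.

    Branch lengths are exponential with mean ``branch_scale``; every leaf
    label appears exactly once.
    """
    if not labels:
        raise ValueError("need at least one leaf")
    nodes = [f"{lab}:{rng.exponential(branch_scale):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b}):0.0")
        else:
            nodes.append(f"({a},{b}):{rng.exponential(branch_scale):.6f}")
    return nodes[0] + ";"


def _lineage(family_idx: int) -> tuple[str, ...]:
    return (
        "Bacteria",
        f"Phylum_{family_idx // 12:02d}",
        f"Class_{family_idx // 6:02d}",
        f"Order_{family_idx // 3:03d}",
        f"Family_{family_idx:03d}",
    )


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_otu_tables(model: CommunityModel, build_tree: bool = True) -> SyntheticDataset:
    """Generate a grain + bulk OTU table with planted core structure.

    Each grain's read mass is split ``core_read_fraction`` : remainder
    between the core OTUs and that grain's included rare OTUs (rare OTUs are
    included independently with probability ``rare_occupancy``); counts are
    multinomial at a uniform random depth in ``depth_range``. Every core OTU
    is guaranteed a count >= 1 on every grain (zero draws are floored to 1,
    compensated within the grain's largest core count so depth is exact).
    Bulk samples are multinomial draws from the pooled grain mixture blended
    with bulk-only OTU mass.
    """
    rng = np.random.default_rng(model.seed)
    n_core, n_rare, n_bonly = model.n_core_otus, model.n_rare_otus, model.n_bulk_only_otus

    core_ids = [f"OTU_core_{i:05d}" for i in range(n_core)]
    rare_ids = [f"OTU_rare_{i:05d}" for i in range(n_rare)]
    bonly_ids = [f"OTU_bulk_{i:05d}" for i in range(n_bonly)]
    otu_ids = core_ids + rare_ids + bonly_ids
    n_otus = len(otu_ids)

    base_core = rng.lognormal(0.0, model.abundance_shape, n_core)
    base_rare = rng.lognormal(0.0, model.abundance_shape, n_rare) if n_rare else np.empty(0)
    base_bonly = rng.lognormal(0.0, model.abundance_shape, n_bonly) if n_bonly else np.empty(0)

    grain_ids = [f"grain_{i + 1:02d}" for i in range(model.n_grains)]
    bulk_ids = [f"bulk_{i + 1}" for i in range(model.n_bulk)]
    counts = np.zeros((model.n_grains + model.n_bulk, n_otus), dtype=np.int64)
    grain_probs = np.zeros((model.n_grains, n_core + n_rare))

    for g in range(model.n_grains):
        w_core = base_core * rng.lognormal(0.0, model.grain_noise_sigma, n_core)
        if n_rare:
            included = rng.random(n_rare) < model.rare_occupancy
            w_rare = np.where(included, base_rare * rng.lognormal(0.0, model.grain_noise_sigma, n_rare), 0.0)
        else:
            w_rare = np.empty(0)
        p = np.zeros(n_core + n_rare)
        rare_mass = 1.0 - model.core_read_fraction if (n_rare and w_rare.sum() > 0) else 0.0
        core_mass = 1.0 - rare_mass
        p[:n_core] = core_mass * w_core / w_core.sum()
        if rare_mass:
            p[n_core:] = rare_mass * w_rare / w_rare.sum()
        grain_probs[g] = p
        depth = int(rng.integers(model.depth_range[0], model.depth_range[1] + 1))
        row = rng.multinomial(depth, p)
        # floor core counts at 1, compensating within the largest core counts
        zero_core = np.flatnonzero(row[:n_core] == 0)
        if len(zero_core):
            row[zero_core] = 1
            deficit = len(zero_core)
            order = np.argsort(row[:n_core])[::-1]
            for idx in order:
                take = min(deficit, row[idx] - 1)
                row[idx] -= take
                deficit -= take
                if deficit == 0:
                    break
            if deficit:
                raise RuntimeError("depth too shallow to guarantee core presence")
        counts[g, : n_core + n_rare] = row

    bulk_mix = grain_probs.mean(axis=0)
    p_bulk = np.zeros(n_otus)
    bonly_mass = model.bulk_only_read_fraction if n_bonly else 0.0
    p_bulk[: n_core + n_rare] = (1.0 - bonly_mass) * bulk_mix
    if bonly_mass:
        p_bulk[n_core + n_rare:] = bonly_mass * base_bonly / base_bonly.sum()
    for b in range(model.n_bulk):
        depth = int(rng.integers(model.bulk_depth_range[0], model.bulk_depth_range[1] + 1))
        counts[model.n_grains + b] = rng.multinomial(depth, p_bulk)

    table = OtuTable(pd.DataFrame(counts, index=grain_ids + bulk_ids, columns=otu_ids))

    fam_weights = _zipf_weights(model.n_families)
    fam_idx = rng.choice(model.n_families, size=n_core + n_rare, p=fam_weights)
    # bulk-only OTUs drawn from a shifted family pool so bulk adds new clades
    bonly_fam = model.n_families + rng.choice(max(model.n_families // 2, 1), size=n_bonly)
    lineages = {otu: _lineage(int(f)) for otu, f in zip(otu_ids[: n_core + n_rare], fam_idx)}
    lineages.update({otu: _lineage(int(f)) for otu, f in zip(bonly_ids, bonly_fam)})
    taxonomy = TaxonomyMap(lineages)

    tree = tree_from_string(random_tree_newick(otu_ids, rng)) if build_tree else None
    return SyntheticDataset(
        table=table,
        tree=tree,
        taxonomy=taxonomy,
        grain_ids=grain_ids,
        bulk_ids=bulk_ids,
        core_otu_ids=core_ids,
        model=model,
    )


def generate_point_pattern(model: SpatialModel, grain_id: str | None = None) -> PointPattern:
    """Simulate a labelled colonization point pattern in a rectangular window.

    The window is tiled into ``n_grid x n_grid`` cells; a random subset
    (matching ``protected_patch_fraction``) forms the protected region. Each
    class is populated at its own intensity: homogeneous Poisson within the
    class region when ``cluster_scale`` is 0, otherwise a Thomas process
    (Poisson parents, Gaussian daughters with scale ``cluster_scale``,
    daughters falling outside the parent's class region are thinned).
    Touching flags mark points with a neighbor closer than
    ``touching_radius_um``.
    """
    rng = np.random.default_rng(model.seed)
    w, h = model.window
    n_grid = model.n_grid
    cw, ch = w / n_grid, h / n_grid
    n_cells = n_grid * n_grid
    n_protected = int(round(model.protected_patch_fraction * n_cells))
    protected_cells = rng.choice(n_cells, size=n_protected, replace=False)
    is_protected = np.zeros(n_cells, dtype=bool)
    is_protected[protected_cells] = True

    def cell_of(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx = np.minimum((x / cw).astype(int), n_grid - 1)
        cy = np.minimum((y / ch).astype(int), n_grid - 1)
        return cy * n_grid + cx

    def uniform_in_cells(cells: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        pick = rng.choice(cells, size=n)
        x = (pick % n_grid + rng.random(n)) * cw
        y = (pick // n_grid + rng.random(n)) * ch
        return x, y

    frames = []
    for cls, intensity, mask in (
        ("exposed", model.exposed_intensity, ~is_protected),
        ("protected", model.protected_intensity, is_protected),
    ):
        cells = np.flatnonzero(mask)
        area = len(cells) * cw * ch
        if area == 0 or intensity == 0:
            continue
        if model.cluster_scale == 0:
            n = rng.poisson(intensity * area)
            x, y = uniform_in_cells(cells, n)
        else:
            mu = model.points_per_cluster
            n_parents = rng.poisson(intensity * area / mu)
            px, py = uniform_in_cells(cells, n_parents)
            n_daughters = rng.poisson(mu, n_parents)
            x = np.repeat(px, n_daughters) + rng.normal(0, model.cluster_scale, n_daughters.sum())
            y = np.repeat(py, n_daughters) + rng.normal(0, model.cluster_scale, n_daughters.sum())
            inside = (x >= 0) & (x < w) & (y >= 0) & (y < h)
            x, y = x[inside], y[inside]
            same_class = mask[cell_of(x, y)]
            x, y = x[same_class], y[same_class]
        frames.append(pd.DataFrame({"x_um": x, "y_um": y, "patch": cls}))

    if frames:
        points = pd.concat(frames, ignore_index=True)
    else:
        points = pd.DataFrame(columns=["x_um", "y_um", "patch"])
    if grain_id is not None:
        points["grain_id"] = grain_id
    pattern = PointPattern(points, model.window, touching_radius_um=model.touching_radius_um)
    pattern.points["touching"] = flag_touching(pattern, model.touching_radius_um).to_numpy()
    return pattern
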