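"""End-to-end pipeline: simulate -> filter -> subsample -> diversity -> core ->
pooling -> geometry -> spatial, driven by a single YAML/JSON config.

Every stochastic stage takes an explicit seed derived deterministically from
the run seed, so re-running a config reproduces byte-identical outputs; the
run manifest records inputs, seeds, package version and a SHA-256 checksum
of every file written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .alpha import alpha_table
from .beta import unifrac_matrix
from .core import core_family_breakdown, find_core
from .geometry import GeometryParams, geometry_report
from .otu import (OtuTable, read_otu_table, read_taxonomy, remove_rare_otus,
                  subsample, write_otu_table, write_taxonomy)
from .pooling import coverage_curve, grains_to_reach
from .spatial import nn_distances, read_point_pattern, write_point_pattern
from .synthetic import CommunityModel, SpatialModel, generate_otu_tables, generate_point_pattern
from .trees import read_tree, write_tree

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "filter", "subsample", "alpha", "beta", "core",
              "pooling", "geometry", "spatial")


class ConfigError(ValueError):
    """Raised when a run configuration cannot be validated."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    community: dict | None = None        # CommunityModel kwargs (simulate)
    spatial_model: dict | None = None    # SpatialModel kwargs (simulate)
    otu_table: Path | None = None        # pre-existing inputs, if not simulating
    tree: Path | None = None
    taxonomy: Path | None = None
    points: Path | None = None
    points_window: tuple[float, float] | None = None
    grain_prefix: str = "grain"
    bulk_prefix: str = "bulk"
    min_total: int = 3
    abundance_permille: float | None = None
    core_prevalence: float = 1.0
    pooling_order: tuple[str, ...] = ("decreasing", "increasing")
    pooling_replicates: int = 10
    pooling_target: float = 0.5
    geometry: dict | None = None         # GeometryParams kwargs
    exclude_touching: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config requires 'outdir'")
        cfg = cls(**{**raw, "outdir": Path(raw["outdir"])})
        cfg.stages = tuple(cfg.stages)
        for p in ("otu_table", "tree", "taxonomy", "points"):
            v = getattr(cfg, p)
            if v is not None:
                setattr(cfg, p, Path(v))
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        simulating = "simulate" in self.stages
        needs_table = {"filter", "subsample", "alpha", "beta", "core", "pooling"} & set(self.stages)
        if needs_table and not simulating and self.otu_table is None:
            raise ConfigError("table-based stages requested but no otu_table input and no simulate stage")
        if "beta" in self.stages and not simulating and self.tree is None:
            raise ConfigError("beta stage requires a tree (input or simulated)")
        if "core" in self.stages and not simulating and self.taxonomy is None:
            raise ConfigError("core stage requires a taxonomy (input or simulated)")
        if "spatial" in self.stages and not simulating:
            if self.points is None:
                raise ConfigError("spatial stage requires a point pattern (input or simulated)")
            if self.points_window is None:
                raise ConfigError("spatial stage on an input CSV requires points_window")


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_samples(table: OtuTable, cfg: RunConfig) -> tuple[list[str], list[str]]:
    grains = [s for s in table.sample_ids if s.startswith(cfg.grain_prefix)]
    bulks = [s for s in table.sample_ids if s.startswith(cfg.bulk_prefix)]
    return grains, bulks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: int(np.random.SeedSequence(config.seed).spawn(len(ALL_STAGES))[i]
                        .generate_state(1)[0] % (2**31))
             for i, stage in enumerate(ALL_STAGES)}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(config.stages),
        "outputs": {},
    }
    written: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        written[name] = path

    table = tree = taxonomy = None
    pattern = None
    dataset = None

    if "simulate" in config.stages:
        model = CommunityModel(**{**(config.community or {}), "seed": seeds["simulate"]})
        dataset = generate_otu_tables(model)
        table, tree, taxonomy = dataset.table, dataset.tree, dataset.taxonomy
        write_otu_table(table, out / "otu_table.tsv")
        emit("otu_table", out / "otu_table.tsv")
        write_tree(tree, out / "tree.nwk")
        emit("tree", out / "tree.nwk")
        write_taxonomy(taxonomy, out / "taxonomy.tsv")
        emit("taxonomy", out / "taxonomy.tsv")
        smodel = SpatialModel(**{**(config.spatial_model or {}), "seed": seeds["simulate"]})
        pattern = generate_point_pattern(smodel)
        write_point_pattern(pattern, out / "points.csv")
        emit("points", out / "points.csv")
        (out / "generator_params.json").write_text(
            json.dumps({"community": dataset.params_json(),
                        "spatial": vars(smodel) | {"window": list(smodel.window)}},
                       indent=2, default=str)
        )
        emit("generator_params", out / "generator_params.json")
    else:
        if config.otu_table is not None:
            table = read_otu_table(config.otu_table)
        if config.tree is not None:
            tree = read_tree(config.tree)
        if config.taxonomy is not None:
            taxonomy = read_taxonomy(config.taxonomy)
        if config.points is not None:
            pattern = read_point_pattern(config.points, config.points_window)

    if "filter" in config.stages:
        table = remove_rare_otus(table, min_total=config.min_total)
        write_otu_table(table, out / "filtered.tsv")
        emit("filtered", out / "filtered.tsv")

    if "subsample" in config.stages:
        table = subsample(table, seed=seeds["subsample"])
        if config.abundance_permille is not None:
            from .otu import abundance_threshold
            table = abundance_threshold(table, config.abundance_permille)
        write_otu_table(table, out / "subsampled.tsv")
        emit("subsampled", out / "subsampled.tsv")

    if "alpha" in config.stages:
        alpha = alpha_table(table, tree=tree)
        alpha.to_csv(out / "alpha.tsv", sep="\t")
        emit("alpha", out / "alpha.tsv")

    if "beta" in config.stages:
        for metric in ("unweighted", "weighted"):
            mat = unifrac_matrix(table, tree, metric=metric)
            mat.to_csv(out / f"beta_{metric}_unifrac.tsv", sep="\t")
            emit(f"beta_{metric}", out / f"beta_{metric}_unifrac.tsv")

    core_report = None
    if "core" in config.stages:
        grains, _ = _split_samples(table, config)
        if not grains:
            raise ConfigError(f"no samples match grain prefix {config.grain_prefix!r}")
        core_report = find_core(table, grains, min_prevalence=config.core_prevalence,
                                warn_unequal_depth=False)
        (out / "core_report.json").write_text(json.dumps({
            "core_otu_count": core_report.core_otu_count,
            "total_otu_count": core_report.total_otu_count,
            "core_fraction_of_otus": core_report.core_fraction_of_otus,
            "mean_core_read_share": core_report.mean_core_read_share,
            "per_sample_core_read_share": core_report.per_sample_core_read_share.round(6).to_dict(),
            "core_otu_ids": core_report.core_otu_ids,
        }, indent=2))
        emit("core_report", out / "core_report.json")
        if taxonomy is not None:
            fam = core_family_breakdown(core_report, table, taxonomy)
            fam.to_csv(out / "core_families.tsv", sep="\t")
            emit("core_families", out / "core_families.tsv")

    if "pooling" in config.stages:
        grains, bulks = _split_samples(table, config)
        if not grains or not bulks:
            raise ConfigError("pooling stage needs both grain and bulk samples")
        summary = {}
        for order in config.pooling_order:
            curve = coverage_curve(table, grains, bulks, order=order,
                                   n_replicates=config.pooling_replicates,
                                   seed=seeds["pooling"])
            curve.points.to_csv(out / f"pooling_{order}.tsv", sep="\t", index=False)
            emit(f"pooling_{order}", out / f"pooling_{order}.tsv")
            summary[order] = grains_to_reach(curve, config.pooling_target)
        (out / "pooling_summary.json").write_text(json.dumps(
            {"target": config.pooling_target, "grains_to_reach": summary}, indent=2))
        emit("pooling_summary", out / "pooling_summary.json")

    if "geometry" in config.stages:
        report = geometry_report(GeometryParams(**(config.geometry or {})))
        (out / "geometry.json").write_text(json.dumps(
            {"raw": report.raw, "printed": report.printed}, indent=2))
        emit("geometry", out / "geometry.json")

    if "spatial" in config.stages:
        summaries = nn_distances(pattern, exclude_touching=config.exclude_touching)
        summaries.to_csv(out / "spatial_nn.tsv", sep="\t")
        emit("spatial", out / "spatial_nn.tsv")

    manifest["outputs"] = {name: {"path": str(p), "sha256": _sha256(p)}
                           for name, p in sorted(written.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
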