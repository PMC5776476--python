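"""Nearest-neighbor cell spacing statistics on 2-D point patterns.

Cell coordinates come from maximum-intensity projections of grain-surface
micrographs, each point labelled by surface patch class (``exposed`` —
convex, abrasion-prone areas — versus ``protected`` depressions). Cells the
detector could not separate ("touching", pair distance below a touching
radius) are excluded by default, which biases distances upward exactly as
the original measurement did. Distances are plain 2-D Euclidean with no
edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PATCH_CLASSES",
    "PointPattern",
    "read_point_pattern",
    "write_point_pattern",
    "flag_touching",
    "nn_distances",
    "theoretical_vs_observed",
]

PATCH_CLASSES = ("exposed", "protected")


@dataclass
class PointPattern:
    """Cell coordinates (um) with patch class and optional touching flags.

    ``points`` columns: ``x_um``, ``y_um``, ``patch`` and optionally
    ``touching`` (bool) and ``grain_id``. ``window`` is (width, height) in um
    with origin at (0, 0).
    """

    points: pd.DataFrame
    window: tuple[float, float]
    touching_radius_um: float | None = None

    def __post_init__(self):
        required = {"x_um", "y_um", "patch"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"point table missing columns: {sorted(missing)}")
        bad = set(self.points["patch"]) - set(PATCH_CLASSES)
        if bad:
            raise ValueError(f"unknown patch classes: {sorted(bad)}")
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window must have positive area")
        x, y = self.points["x_um"], self.points["y_um"]
        if len(x) and ((x < 0).any() or (x > w).any() or (y < 0).any() or (y > h).any()):
            raise ValueError("points fall outside the window")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return self.points[["x_um", "y_um"]].to_numpy(dtype=float)


def read_point_pattern(
    path: str | Path, window: tuple[float, float], touching_radius_um: float | None = None
) -> PointPattern:
    """Read a CSV of ``x_um,y_um,patch[,touching][,grain_id]``."""
    df = pd.read_csv(path)
    if "touching" in df.columns:
        df["touching"] = df["touching"].astype(bool)
    return PointPattern(df, window, touching_radius_um)


def write_point_pattern(pattern: PointPattern, path: str | Path) -> None:
    pattern.points.to_csv(path, index=False)


def flag_touching(pattern: PointPattern, radius_um: float | None = None) -> pd.Series:
    """Boolean flag per point: has a neighbor strictly closer than the radius.

    Uses explicit ``touching`` flags when present and no radius is forced.
    """
    if radius_um is None and "touching" in pattern.points.columns:
        return pattern.points["touching"].astype(bool)
    radius = radius_um if radius_um is not None else (pattern.touching_radius_um or 1.0)
    flags = np.zeros(pattern.n_points, dtype=bool)
    if pattern.n_points >= 2:
        coords = pattern.coords()
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(radius):
            if np.linalg.norm(coords[i] - coords[j]) < radius:  # strict
                flags[i] = flags[j] = True
    return pd.Series(flags, index=pattern.points.index, name="touching")


def nn_distances(
    pattern: PointPattern,
    exclude_touching: bool = True,
    touching_radius_um: float | None = None,
    within_class: bool = True,
) -> pd.DataFrame:
    """Per-class nearest-neighbor distance summaries.

    For every retained point, the distance to its nearest retained neighbor
    in the same patch class (``within_class=False`` pools classes for the
    neighbor search while still summarizing per class). Classes with fewer
    than two retained points get null statistics but a reported ``n_cells``.
    """
    touching = (
        flag_touching(pattern, touching_radius_um)
        if exclude_touching
        else pd.Series(False, index=pattern.points.index)
    )
    retained = pattern.points.loc[~touching]
    rows = []
    all_coords = retained[["x_um", "y_um"]].to_numpy(dtype=float)
    pooled_tree = cKDTree(all_coords) if len(all_coords) >= 2 else None
    for cls in PATCH_CLASSES:
        sub = retained.loc[retained["patch"] == cls]
        n = len(sub)
        row = {"patch_class": cls, "n_cells": n, "mean_nn_um": np.nan,
               "sd_nn_um": np.nan, "min_um": np.nan, "max_um": np.nan}
        coords = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if within_class:
            if n >= 2:
                tree = cKDTree(coords)
                dist, _ = tree.query(coords, k=2)
                nn = dist[:, 1]
            else:
                nn = None
        else:
            nn = pooled_tree.query(coords, k=2)[0][:, 1] if (pooled_tree is not None and n) else None
        if nn is not None and len(nn):
            row.update(
                mean_nn_um=float(nn.mean()),
                sd_nn_um=float(nn.std(ddof=1)) if len(nn) > 1 else 0.0,
                min_um=float(nn.min()),
                max_um=float(nn.max()),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patch_class")


def theoretical_vs_observed(density_cells_per_um2: float, summaries: pd.DataFrame) -> dict:
    """Observed class NN means next to the two theoretical spacings.

    The square-lattice spacing ``sqrt(1/rho)`` (the geometric convention used
    for the bulk density estimate) and the homogeneous-Poisson nearest-
    neighbor expectation ``1/(2 sqrt(rho))``.
    """
    if density_cells_per_um2 <= 0:
        raise ValueError("density must be positive")
    rho = density_cells_per_um2
    return {
        "density_cells_per_um2": rho,
        "lattice_spacing_um": float(np.sqrt(1.0 / rho)),
        "poisson_mean_nn_um": float(1.0 / (2.0 * np.sqrt(rho))),
        "observed_mean_nn_um": {
            cls: (float(summaries.loc[cls, "mean_nn_um"]) if cls in summaries.index else None)
            for cls in PATCH_CLASSES
        },
    }
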