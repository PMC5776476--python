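"""Grain colonization geometry: cell density, spacing, colonized fraction, cells per grain.

The model links three bulk measurements — total cell count per cm^3 of
sediment, grain surface area per cm^3 (from micro-CT), and the footprint of
an average cell — into a surface colonization picture:

* colonization density  rho = cells_per_cm3 / surface_area_um2_per_cm3  (cells/um^2)
* area per cell         a   = 1 / rho                                   (um^2)
* lattice spacing       s   = sqrt(a)                                   (um)
* colonized fraction    f   = footprint * rho
* cells per grain, surface route:  pi * d^2 * rho    (sphere of diameter d)
* cells per grain, packing route:  cells_per_cm3 / grains_per_cm3, with
  grains_per_cm3 = (1 - porosity) / (pi d^3 / 6), d in cm.

Raw values are kept at full precision; the printed-style rounding (density to
two decimals, area/spacing to one decimal, whole-percent colonized fraction,
two significant figures for cells per grain) is applied only in the reporting
view, where the derived chain (area, spacing, fraction) is recomputed from
the two-decimal density, matching how such numbers are conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GeometryParams",
    "GeometryReport",
    "round_sig",
    "colonization_density",
    "spacing_and_fraction",
    "cells_per_grain_eq1",
    "grains_per_cm3",
    "cells_per_grain_eq23",
    "geometry_report",
]


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + digits - 1)


@dataclass
class GeometryParams:
    """Inputs of the colonization model, defaulting to the North Sea study site.

    ``porosity`` feeds only the grain-packing route; it is a fitted default
    (back-solved so that route reproduces the study's quoted range), not a
    measured value.
    """

    cells_per_cm3: float = 1.1e9
    surface_area_um2_per_cm3: float = 1.2e10
    cell_footprint_um2: float = 0.43
    grain_diameters_um: tuple[float, ...] = (202.0, 635.0)
    porosity: float = 0.423

    def __post_init__(self):
        for name in ("cells_per_cm3", "surface_area_um2_per_cm3", "cell_footprint_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(d <= 0 for d in self.grain_diameters_um):
            raise ValueError("grain diameters must be positive")
        if not 0 < self.porosity < 1:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")


def colonization_density(params: GeometryParams) -> float:
    """Cells per um^2 of grain surface (raw, unrounded)."""
    if params.surface_area_um2_per_cm3 <= 0:
        raise ValueError("surface area must be positive")
    return params.cells_per_cm3 / params.surface_area_um2_per_cm3


def spacing_and_fraction(density: float, footprint_um2: float) -> tuple[float, float, float]:
    """(area per cell, lattice spacing, colonized fraction) at a given density.

    Spacing follows the square-lattice convention sqrt(1/rho): the distance
    between neighbors if each cell sat in the middle of its own equal square.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    area = 1.0 / density
    return area, math.sqrt(area), footprint_um2 * density


def cells_per_grain_eq1(diameter_um: float, density: float) -> float:
    """Cells on one grain via the sphere-surface route: pi d^2 rho."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter_um**2 * density


def grains_per_cm3(diameter_um: float, porosity: float) -> float:
    """Number of grains in 1 cm^3 of sediment: (1 - porosity) / sphere volume."""
    if not 0 < porosity < 1:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    d_cm = diameter_um * 1e-4
    volume = math.pi * d_cm**3 / 6.0
    return (1.0 - porosity) / volume


def cells_per_grain_eq23(params: GeometryParams, diameter_um: float) -> float:
    """Cells per grain via the packing route: cells per cm^3 / grains per cm^3."""
    return params.cells_per_cm3 / grains_per_cm3(diameter_um, params.porosity)


@dataclass
class GeometryReport:
    raw: dict
    printed: dict
    params: GeometryParams = field(repr=False, default_factory=GeometryParams)


def geometry_report(params: GeometryParams | None = None) -> GeometryReport:
    """Full colonization report with raw and printed-precision views."""
    params = params or GeometryParams()
    rho_raw = colonization_density(params)
    area_raw, spacing_raw, frac_raw = spacing_and_fraction(rho_raw, params.cell_footprint_um2)
    raw = {
        "density_cells_per_um2": rho_raw,
        "area_per_cell_um2": area_raw,
        "theoretical_spacing_um": spacing_raw,
        "colonized_fraction": frac_raw,
        "cells_per_grain_surface_route": {
            d: cells_per_grain_eq1(d, rho_raw) for d in params.grain_diameters_um
        },
        "grains_per_cm3": {
            d: grains_per_cm3(d, params.porosity) for d in params.grain_diameters_um
        },
        "cells_per_grain_count_route": {
            d: cells_per_grain_eq23(params, d) for d in params.grain_diameters_um
        },
    }
    # printed chain: derived quantities recomputed from the two-decimal density
    rho_p = round(rho_raw, 2)
    area_p, spacing_p, frac_p = spacing_and_fraction(rho_p, params.cell_footprint_um2)
    printed = {
        "density_cells_per_um2": rho_p,
        "area_per_cell_um2": round(area_p, 1),
        "theoretical_spacing_um": round(spacing_p, 1),
        "colonized_surface_percent": round(frac_p * 100.0),
        "cells_per_grain_surface_route": {
            d: round_sig(cells_per_grain_eq1(d, rho_p), 2) for d in params.grain_diameters_um
        },
        "cells_per_grain_count_route": {
            d: round_sig(cells_per_grain_eq23(params, d), 2) for d in params.grain_diameters_um
        },
    }
    return GeometryReport(raw=raw, printed=printed, params=params)
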