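"""Grain-size statistics, surface-to-volume ratio, cell-density conversions and
convex-hull surface roughness.

The sediment surface-to-volume ratio for a grain-size distribution ``p(d_g)``
with porosity ``theta`` is

    S_VT = 6 (1 - theta) * Integral p(d_g) / d_g  d d_g

which for a measured sample of diameters reduces to ``6 (1 - theta) * mean(1/d_g)``
(the unbiased sample estimator; no density fit is needed for n in the hundreds).
Areal cell densities (cells cm^-2) multiplied by S_VT (cm^2 cm^-3) give
volumetric densities (cells cm^-3), from which cell-specific respiration rates
and colony-scale volumetric rates follow by unit bookkeeping.

Surface roughness of a grain outline is the radial difference between the
outline and its convex hull, measured from the outline's area centroid — a 2D
proxy for the surface irregularity that thickens the diffusive boundary layer.

Unit conventions: lengths are micrometres except inside the surface-to-volume
integral, where diameters are converted to centimetres so S_VT comes out in
cm^2 cm^-3. Rates are micromoles per litre per hour at the bulk scale,
femtomoles per cell per hour at the cell scale and millimoles per litre per
hour at the colony scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from shapely.geometry import Polygon

__all__ = [
    "GrainSizeDistribution",
    "GrainSample",
    "RoughnessProfile",
    "surface_to_volume",
    "porosity_from_drying",
    "cells_per_volume",
    "cell_specific_rate",
    "colony_volumetric_rate",
    "roughness",
]

UM_PER_CM = 1.0e4


class InvalidMeasurementError(ValueError):
    """Raised when a physical measurement yields an out-of-range quantity."""


@dataclass
class GrainSizeDistribution:
    """Sample of grain diameters in micrometres, optionally with a fitted density.

    Parameters
    ----------
    diameters_um:
        Measured grain diameters (µm). All must be positive.
    density:
        Optional probability density p(d_g) in µm^-1 over ``support_um``.
        When given, integral evaluations use it instead of the sample.
    support_um:
        (d_min, d_max) integration support for ``density``.
    """

    diameters_um: np.ndarray
    density: Callable[[np.ndarray], np.ndarray] | None = None
    support_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.diameters_um.size == 0:
            raise ValueError("grain-size distribution needs at least one diameter")
        if np.any(self.diameters_um <= 0) or not np.all(np.isfinite(self.diameters_um)):
            raise ValueError("grain diameters must be positive and finite")
        if self.density is not None:
            if self.support_um is None:
                raise ValueError("a fitted density requires an integration support")
            norm, _ = quad(self.density, *self.support_um, limit=200)
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"fitted density integrates to {norm!r}, not 1")

    @property
    def median_diameter_um(self) -> float:
        return float(np.median(self.diameters_um))


@dataclass
class GrainSample:
    """A sediment sample: size distribution, porosity and cell densities."""

    distribution: GrainSizeDistribution
    porosity: float
    areal_cell_density_per_cm2: float | None = None
    surface_to_volume_cm2_per_cm3: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")
        if self.surface_to_volume_cm2_per_cm3 is None:
            self.surface_to_volume_cm2_per_cm3 = surface_to_volume(
                self.distribution, self.porosity
            )

    @property
    def volumetric_cell_density_per_cm3(self) -> float | None:
        if self.areal_cell_density_per_cm2 is None:
            return None
        return cells_per_volume(
            self.areal_cell_density_per_cm2, self.surface_to_volume_cm2_per_cm3
        )


@dataclass
class RoughnessProfile:
    """Per-vertex radial deviation (µm, magnitudes) of an outline from its hull."""

    deviations_um: np.ndarray
    angles_rad: np.ndarray

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.deviations_um))

    @property
    def max_um(self) -> float:
        return float(np.max(self.deviations_um))


def surface_to_volume(
    distribution: GrainSizeDistribution, porosity: float
) -> float:
    """Sediment surface-to-volume ratio S_VT in cm^2 cm^-3.

    Evaluates 6 (1 - theta) <1/d_g>, with the expectation taken over the
    measured sample by default, or over the fitted density when one is present
    (numerical quadrature, relative tolerance 1e-6).
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError("porosity must lie in (0, 1)")
    if distribution.density is not None:
        integral, _ = quad(
            lambda d: distribution.density(d) / d,
            *distribution.support_um,
            epsrel=1e-6,
            limit=200,
        )
        mean_inv_um = integral
    else:
        mean_inv_um = float(np.mean(1.0 / distribution.diameters_um))
    # <1/d> in um^-1 -> cm^-1
    return 6.0 * (1.0 - porosity) * mean_inv_um * UM_PER_CM


def porosity_from_drying(
    total_volume_ml: float,
    wet_mass_g: float,
    dry_mass_g: float,
    water_density_g_per_ml: float = 1.0,
) -> float:
    """Porosity from the wet/dry mass difference of a known sediment volume."""
    if total_volume_ml <= 0:
        raise ValueError("total volume must be positive")
    if wet_mass_g < dry_mass_g:
        raise ValueError("wet mass cannot be below dry mass")
    theta = ((wet_mass_g - dry_mass_g) / water_density_g_per_ml) / total_volume_ml
    if not 0.0 < theta < 1.0:
        raise InvalidMeasurementError(
            f"porosity {theta:.3f} outside (0, 1); check the measurement"
        )
    return theta


def cells_per_volume(
    areal_cell_density_per_cm2: float, surface_to_volume_cm2_per_cm3: float
) -> float:
    """Cells per cm^3 of sediment from areal density x surface-to-volume ratio."""
    if areal_cell_density_per_cm2 < 0 or surface_to_volume_cm2_per_cm3 < 0:
        raise ValueError("densities and ratios must be non-negative")
    return areal_cell_density_per_cm2 * surface_to_volume_cm2_per_cm3


def cell_specific_rate(
    bulk_rate_umol_per_L_h: float, volumetric_cell_density_per_cm3: float
) -> float:
    """Cell-specific O2 rate (fmol O2 cell^-1 h^-1) from a bulk volumetric rate.

    1 µmol L^-1 = 1e-9 mol cm^-3; dividing by cells cm^-3 gives mol cell^-1 h^-1,
    reported in fmol (1e-15 mol). The sign of the bulk rate is preserved
    (negative = consumption).
    """
    if volumetric_cell_density_per_cm3 <= 0:
        raise ValueError("volumetric cell density must be positive")
    mol_per_cm3_h = bulk_rate_umol_per_L_h * 1.0e-9
    return mol_per_cm3_h / volumetric_cell_density_per_cm3 * 1.0e15


def colony_volumetric_rate(
    cell_specific_rate_fmol_per_h: float, biovolume_um3: float
) -> float:
    """Colony-scale volumetric rate (mmol L^-1 h^-1) from a cell-specific rate.

    Divides the per-cell rate by the characteristic cell biovolume, i.e. the
    rate per litre of cell biovolume: 1 fmol / 1 µm^3 = 1 mol L^-1.
    """
    if biovolume_um3 <= 0:
        raise ValueError("biovolume must be positive")
    mol_per_L_h = cell_specific_rate_fmol_per_h / biovolume_um3
    return mol_per_L_h * 1.0e3


def _polygon(outline_xy_um: Sequence[Sequence[float]]) -> Polygon:
    pts = np.asarray(outline_xy_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("outline must be an (n >= 3, 2) array of vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("outline polygon is self-intersecting or degenerate")
    return poly


def roughness(outline_xy_um: Sequence[Sequence[float]]) -> RoughnessProfile:
    """Convex-hull surface roughness of a closed grain outline.

    For each outline vertex the radial distance from the outline's area
    centroid is compared with the convex hull's radius at the same polar angle
    (hull radius linearly interpolated in angle between hull vertices). The
    deviation magnitudes are zero for convex outlines and measure indentation
    depth for rough grains.
    """
    poly = _polygon(outline_xy_um)
    cx, cy = poly.centroid.x, poly.centroid.y

    pts = np.asarray(outline_xy_um, dtype=float)
    ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
    rad = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)

    hull = np.asarray(poly.convex_hull.exterior.coords[:-1], dtype=float)
    hang = np.arctan2(hull[:, 1] - cy, hull[:, 0] - cx)
    hrad = np.hypot(hull[:, 0] - cx, hull[:, 1] - cy)
    order = np.argsort(hang)
    hang, hrad = hang[order], hrad[order]
    # periodic extension for interpolation across the -pi/pi seam
    hang_ext = np.concatenate([hang - 2 * np.pi, hang, hang + 2 * np.pi])
    hrad_ext = np.tile(hrad, 3)
    hull_at = np.interp(ang, hang_ext, hrad_ext)

    dev = np.maximum(hull_at - rad, 0.0)
    return RoughnessProfile(deviations_um=dev, angles_rad=ang)
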