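"""Environmental predictors per study site.

Three covariates drive the inference stage: mean flowering
nectar-plant coverage along the activity transect (resource proxy),
mean percent sealed surface within 500/1000/2000 m of the site centre
(urbanization proxy), and the habitat patch area in hectares. The
sealing raster rarely covers the whole domain, so unobserved cells are
imputed with the mean sealing of their biotope class before zonal
statistics are taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon, shape

from .raster import Raster
from .trajectory import TransectRecord

DEFAULT_RADII_M = (500.0, 1000.0, 2000.0)


@dataclass
class LandscapeInputs:
    """Sealing raster (percent, with nodata), co-registered biotope
    class grid, site centre points and habitat polygons."""

    sealing: Raster
    biotopes: Raster
    site_centers: dict[str, tuple[float, float]] = field(default_factory=dict)
    habitat_polygons: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sealing.same_grid(self.biotopes):
            raise ValueError("sealing and biotope grids are not co-registered")
        present = self.sealing.data[self.sealing.mask]
        if present.size and (present.min() < 0 or present.max() > 100):
            raise ValueError("sealing percentages must lie in [0, 100]")


@dataclass(frozen=True)
class SiteCovariates:
    site_id: str
    np_cov: float
    urbanization: dict[float, float]
    habitat_area: float  # ha

    def __post_init__(self):
        if not 0.0 <= self.np_cov <= 100.0:
            raise ValueError("np_cov outside [0, 100]")
        for r, u in self.urbanization.items():
            if not 0.0 <= u <= 100.0:
                raise ValueError(f"urbanization({r} m) outside [0, 100]")
        if self.habitat_area <= 0:
            raise ValueError("habitat area must be positive")


def np_coverage(transect: list[TransectRecord]) -> float:
    """Mean nectar-plant cover over the transect's 1-m segments,
    percent: NPcov = (Σ NPx_i) / NTS."""
    if not transect:
        raise ValueError("empty transect")
    return float(np.mean([r.np_cover for r in transect]))


def class_sealing_means(sealing: Raster, biotopes: Raster) -> dict[int, float]:
    """Mean observed sealing per biotope class.

    Classes without any observed sealing cell map to NaN (flagged with
    a warning); they cannot support imputation.
    """
    if not sealing.same_grid(biotopes):
        raise ValueError("sealing and biotope grids are not co-registered")
    covered = sealing.mask & biotopes.mask
    if not covered.any():
        raise ValueError("sealing and biotope coverage do not overlap")
    out: dict[int, float] = {}
    classes = np.unique(biotopes.data[biotopes.mask]).astype(int)
    for cls in classes:
        sel = covered & (biotopes.data == cls)
        if sel.any():
            out[int(cls)] = float(sealing.data[sel].mean())
        else:
            warnings.warn(f"biotope class {cls} has no observed sealing cells", stacklevel=2)
            out[int(cls)] = float("nan")
    return out


def impute_sealing(
    sealing: Raster, biotopes: Raster, class_means: dict[int, float] | None = None
) -> Raster:
    """Fill unobserved sealing cells with their biotope class mean.

    Identity on fully covered rasters, hence idempotent. Raises if an
    unobserved cell's class has no usable mean.
    """
    if not sealing.same_grid(biotopes):
        raise ValueError("sealing and biotope grids are not co-registered")
    if class_means is None:
        class_means = class_sealing_means(sealing, biotopes)
    out = sealing.copy()
    holes = ~sealing.mask
    if not holes.any():
        return out
    hole_classes = np.unique(biotopes.data[holes & biotopes.mask]).astype(int)
    missing = [int(c) for c in hole_classes
               if c not in class_means or not np.isfinite(class_means[int(c)])]
    if missing or (holes & ~biotopes.mask).any():
        raise ValueError(
            f"cannot impute: classes without a sealing mean {missing}"
            + ("; some uncovered cells have no biotope class" if (holes & ~biotopes.mask).any() else "")
        )
    for cls in hole_classes:
        sel = holes & (biotopes.data == cls)
        out.data[sel] = class_means[int(cls)]
    return out


def zonal_urbanization(raster: Raster, center: tuple[float, float], radius: float) -> float:
    """Mean raster value over cells whose centres fall within
    ``radius`` metres of ``center``.

    Cell membership is by centre point; at 2-m cells against >=500-m
    radii the discretization error is negligible (<0.1%).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    X, Y = raster.cell_centers()
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
    sel = inside & raster.mask
    if not sel.any():
        raise ValueError("buffer does not intersect any observed raster cell")
    if (inside & ~raster.mask).any():
        warnings.warn("buffer contains nodata cells; mean taken over observed cells",
                      stacklevel=2)
    return float(raster.data[sel].mean())


def habitat_area(polygon: Polygon | dict) -> float:
    """Planar polygon area in hectares, holes subtracted."""
    poly = shape(polygon) if isinstance(polygon, dict) else polygon
    if not poly.is_valid:
        raise ValueError("invalid (e.g. self-intersecting) habitat polygon")
    if poly.is_empty or poly.area <= 0:
        raise ValueError("habitat polygon has no area")
    return float(poly.area) / 1e4


def site_covariates(
    site_id: str,
    transect: list[TransectRecord],
    landscape: LandscapeInputs,
    radii: tuple[float, ...] = DEFAULT_RADII_M,
) -> SiteCovariates:
    """Assemble all predictors for one site (imputing sealing first)."""
    full = impute_sealing(landscape.sealing, landscape.biotopes)
    center = landscape.site_centers[site_id]
    urb = {float(r): zonal_urbanization(full, center, float(r)) for r in radii}
    return SiteCovariates(
        site_id=site_id,
        np_cov=np_coverage(transect),
        urbanization=urb,
        habitat_area=habitat_area(landscape.habitat_polygons[site_id]),
    )


# ---------------------------------------------------------------------------
# GeoJSON helpers for points and polygons
# ---------------------------------------------------------------------------

def read_site_centers(path: str | Path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, Point):
            raise ValueError("site centers must be Point features")
        out[str(feat["properties"]["site_id"])] = (geom.x, geom.y)
    return out


def read_habitat_polygons(path: str | Path) -> dict[str, Polygon]:
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        out[str(feat["properties"]["site_id"])] = geom
    return out
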