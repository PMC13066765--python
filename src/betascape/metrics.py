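"""Per-landscape habitat amount, fragmentation, distance, and climate metrics.

Patch delineation follows the FRAGSTATS conventions: connected components of
habitat cells (8-neighbourhood by default), clipped to the landscape polygon
by the cell-center-in-polygon rule before labelling.  ENN is measured between
border-cell centers.  Landscapes with no habitat have undefined mean patch
size; landscapes with fewer than two patches have undefined ENN — both are
reported as NaN, never as exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, DesignError, MetricError
from .rasters import Raster

EARTH_RADIUS_KM = 6371.0

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def _clip_mask(raster: Raster, polygon) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the polygon (all if None)."""
    if polygon is None:
        return np.ones(raster.shape, dtype=bool)
    gx, gy = raster.cell_centers()
    return shapely.contains_xy(polygon, gx, gy)


def habitat_cover(raster: Raster, polygon=None) -> float:
    """Percentage of valid (non-nodata) in-polygon cells that are habitat."""
    sel = _clip_mask(raster, polygon) & raster.valid_mask
    n_valid = int(sel.sum())
    if n_valid == 0:
        raise MetricError("no valid cells with center inside the polygon")
    n_habitat = int((raster.grid[sel] == 1).sum())
    return 100.0 * n_habitat / n_valid


def patches(
    raster: Raster, polygon=None, connectivity: int = 8
) -> tuple[int, float, np.ndarray]:
    """Return (n_patches, mean_patch_size in ha, label grid).

    Mean patch size is NaN when there is no habitat.  Labels are 1..n inside
    patches, 0 elsewhere (same shape as the raster grid).
    """
    if connectivity not in _STRUCTURES:
        raise ConfigurationError("connectivity must be 4 or 8")
    habitat = (raster.grid == 1) & _clip_mask(raster, polygon) & raster.valid_mask
    labels, n = ndimage.label(habitat, structure=_STRUCTURES[connectivity])
    if n == 0:
        return 0, float("nan"), labels
    total_ha = habitat.sum() * raster.cell_size**2 / 10_000.0
    return int(n), float(total_ha / n), labels


def enn_mn(labels: np.ndarray, cell_size: float) -> float:
    """Mean over patches of the nearest-neighbour distance (m) between
    border-cell centers; NaN when fewer than two patches exist."""
    n = int(labels.max())
    if n < 2:
        return float("nan")
    inside = labels > 0
    # border cell: habitat cell with a 4-neighbour outside its own patch
    border = np.zeros_like(inside)
    padded = np.pad(labels, 1, constant_values=0)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        border |= inside & (neigh != labels)
    rows, cols = np.nonzero(border)
    pts = np.column_stack([cols, rows]).astype(float) * cell_size
    labs = labels[rows, cols]
    dists = []
    for patch in range(1, n + 1):
        own = labs == patch
        tree = cKDTree(pts[~own])
        d, _ = tree.query(pts[own], k=1)
        dists.append(float(np.min(d)))
    return float(np.mean(dists))


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def mean_spatial_distance(coords: np.ndarray, mode: str = "planar") -> float:
    """Mean pairwise distance in km among inventory coordinates.

    ``mode='planar'`` treats coords as km; ``mode='lonlat'`` as (lon, lat)
    degrees and uses the haversine formula.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise DesignError("mean_spatial_distance needs at least 2 points")
    if mode == "planar":
        return float(pdist(coords).mean())
    if mode == "lonlat":
        n = coords.shape[0]
        acc = [
            haversine_km(*coords[i], *coords[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return float(np.mean(acc))
    raise ConfigurationError(f"unknown distance mode {mode!r}")


def zonal_mean(raster: Raster, polygon=None) -> float:
    """Mean raster value over valid cells with center in the polygon."""
    sel = _clip_mask(raster, polygon) & raster.valid_mask
    if not sel.any():
        raise MetricError("no valid cells with center inside the polygon")
    return float(np.asarray(raster.grid, dtype=float)[sel].mean())


def zonal_climate(climate_rasters: dict[str, Raster], polygon=None) -> dict[str, float]:
    """Per-variable zonal mean over the polygon."""
    return {name: zonal_mean(r, polygon) for name, r in climate_rasters.items()}


def reference_raster(rasters: list[Raster], reference_year: int) -> Raster:
    """Pick the raster matching the reference year; else the nearest year at or
    before it; else the earliest available."""
    if not rasters:
        raise ConfigurationError("empty raster set")
    dated = [r for r in rasters if r.year is not None]
    if not dated:
        return rasters[0]
    exact = [r for r in dated if r.year == reference_year]
    if exact:
        return exact[0]
    before = [r for r in dated if r.year <= reference_year]
    if before:
        return max(before, key=lambda r: r.year)
    return min(dated, key=lambda r: r.year)


@dataclass
class LandscapeMetrics:
    landscape_id: str
    habitat_cover: float
    n_patches: int
    mean_patch_size: float
    enn_mn: float
    mean_spatial_distance: float


def landscape_metrics(
    landscape_id: str,
    raster: Raster,
    polygon,
    coords: np.ndarray,
    connectivity: int = 8,
    distance_mode: str = "planar",
) -> LandscapeMetrics:
    n, mps, labels = patches(raster, polygon, connectivity)
    return LandscapeMetrics(
        landscape_id=landscape_id,
        habitat_cover=habitat_cover(raster, polygon),
        n_patches=n,
        mean_patch_size=mps,
        enn_mn=enn_mn(labels, raster.cell_size),
        mean_spatial_distance=mean_spatial_distance(coords, distance_mode),
    )


def metrics_table(records: list[LandscapeMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in records])
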