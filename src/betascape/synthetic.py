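"""Synthetic landscapes, habitat rasters, species pools, and communities.

The generator produces a complete study dataset with the statistical
structure the downstream analysis assumes:

* habitat rasters from a seeded-growth cluster process, with exact cover
  control and patch count increasing with the number of growth nuclei;
* communities whose pairwise dissimilarity grows with inter-site distance
  (a spatially correlated log-normal suitability field), shrinks with the
  number of nuclei (generalist dominance) and with habitat cover, and whose
  endemic relative abundance rises with cover.

Landscape centers sit on a pointy-top hexagon lattice anchored at (0, 0) so
that the study-design stage reconstructs the true landscape memberships.
Per-landscape RNG substreams are derived by stable hashing of the landscape
id: adding landscapes never perturbs existing ones.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from .design import HexGrid
from .endemism import CATEGORIES, CATEGORY_SCORES, SpeciesRecord
from .errors import ConfigurationError, DesignError, DomainError
from .rasters import Raster, write_ascii_grid

SQRT3_HALF = math.sqrt(3.0) / 2.0

CLIMATE_VARIABLES = (
    "temperature",
    "temperature_seasonality",
    "precipitation",
    "precipitation_seasonality",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study generator."""

    n_landscapes: int = 95
    landscape_area: float = 100.0  # km^2
    cell_size: float = 30.0  # m
    habitat_amount_range: tuple[float, float] = (0.0, 1.0)
    fragmentation_nuclei_range: tuple[int, int] = (1, 25)
    inventories_per_landscape_range: tuple[int, int] = (2, 12)
    pool_size: int = 200
    endemism_mix: tuple[float, ...] = (0.05, 0.25, 0.30, 0.25, 0.15)
    distance_decay_rate: float = 0.5  # per km
    homogenization_strength: float = 0.0
    endemism_cover_coupling: float = 0.0
    cover_homogenization: float = 0.0  # links habitat cover to site-noise shrinkage
    site_noise_sd: float = 1.0
    alpha_mean: float = 60.0
    individuals_per_inventory: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("habitat_amount_range", "fragmentation_nuclei_range",
                     "inventories_per_landscape_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        lo, hi = self.habitat_amount_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("habitat_amount_range must lie in [0, 1]")
        if self.inventories_per_landscape_range[0] < 2:
            raise ConfigurationError("at least 2 inventories per landscape are required")
        mix = np.asarray(self.endemism_mix, dtype=float)
        if mix.size != len(CATEGORIES) or np.any(mix < 0) or np.any(mix > 1):
            raise ConfigurationError("endemism_mix needs 5 probabilities in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("endemism_mix must sum to 1")
        if self.pool_size < 5:
            raise ConfigurationError("pool_size must be >= 5")
        if self.n_landscapes < 1:
            raise ConfigurationError("n_landscapes must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for name in ("habitat_amount_range", "fragmentation_nuclei_range",
                     "inventories_per_landscape_range", "endemism_mix"):
            if name in d and isinstance(d[name], (list, tuple)):
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class LandscapeTruth:
    """Generating parameters of one landscape, for parameter-recovery tests."""

    landscape_id: str
    center: tuple[float, float]
    polygon: Polygon
    target_cover: float
    n_nuclei: int
    n_inventories: int
    #: placement region for inventory sites; defaults to the landscape polygon.
    #: The study generator uses a disc of landscape-specific radius so that
    #: mean inter-site distance varies between landscapes.
    site_polygon: Polygon | None = None
    site_radius: float = float("nan")


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset emulating the inventory-database workflow."""

    config: SimulationConfig
    inventories: pd.DataFrame  # inventory_id, landscape_id, x, y, year, effort_ha, dbh_cutoff_cm
    abundances: pd.DataFrame  # wide: index inventory_id, columns species ids
    species: pd.DataFrame  # species_id, category, score
    rasters: dict[str, Raster]
    climate: pd.DataFrame  # landscape_id + the four climate variables
    truth: pd.DataFrame  # landscape_id, cx, cy, target_cover, n_nuclei, n_inventories


def _landscape_rng(seed: int, landscape_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(landscape_id.encode())])
    )


def generate_habitat_raster(
    extent: float,
    cell_size: float,
    target_cover: float,
    n_nuclei: int,
    seed: int | np.random.Generator,
    origin: tuple[float, float] = (0.0, 0.0),
    year: int | None = None,
) -> Raster:
    """Seeded-growth binary habitat raster over a square of ``extent`` km^2.

    Places ``n_nuclei`` random habitat nuclei and iteratively converts random
    habitat-adjacent cells until exactly floor(target_cover * n_cells) habitat
    cells exist.  Deterministic given the seed.
    """
    if not 0.0 <= target_cover <= 1.0:
        raise DomainError("target_cover must lie in [0, 1]")
    if n_nuclei < 1:
        raise DomainError("n_nuclei must be >= 1")
    side = math.sqrt(extent * 1e6) / cell_size
    n = int(round(side))
    if n < 10:
        raise ConfigurationError("extent/cell_size yields a grid smaller than 10x10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ncells = n * n
    target = int(math.floor(target_cover * ncells))
    grid = np.zeros((n, n), dtype=np.int64)
    if target > 0:
        k = min(n_nuclei, target)
        nuclei = rng.choice(ncells, size=k, replace=False)
        frontier: list[int] = []
        placed = 0

        def _push_neighbors(cell: int) -> None:
            r, c = divmod(cell, n)
            if r > 0 and not grid[r - 1, c]:
                frontier.append(cell - n)
            if r < n - 1 and not grid[r + 1, c]:
                frontier.append(cell + n)
            if c > 0 and not grid[r, c - 1]:
                frontier.append(cell - 1)
            if c < n - 1 and not grid[r, c + 1]:
                frontier.append(cell + 1)

        for cell in nuclei:
            grid[divmod(cell, n)] = 1
            placed += 1
        for cell in nuclei:
            _push_neighbors(int(cell))
        while placed < target:
            i = int(rng.integers(len(frontier)))
            cand = frontier[i]
            frontier[i] = frontier[-1]
            frontier.pop()
            r, c = divmod(cand, n)
            if grid[r, c]:
                continue
            grid[r, c] = 1
            placed += 1
            _push_neighbors(cand)
    return Raster(grid=grid, cell_size=cell_size, origin=origin, year=year)


def generate_species_pool(
    pool_size: int,
    endemism_mix,
    seed: int | np.random.Generator,
) -> list[SpeciesRecord]:
    """Assign each of ``pool_size`` species an endemism category by the mix."""
    if pool_size < 5:
        raise ConfigurationError("pool_size must be >= 5")
    mix = np.asarray(endemism_mix, dtype=float)
    if mix.size != len(CATEGORIES) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise DomainError("endemism_mix must be 5 non-negative probabilities summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(CATEGORIES), size=pool_size, p=mix)
    return [
        SpeciesRecord(
            species_id=f"sp{i:04d}",
            category=CATEGORIES[c],
            score=CATEGORY_SCORES[CATEGORIES[c]],
        )
        for i, c in enumerate(idx)
    ]


def species_table(pool: list[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species_id, s.category, s.score) for s in pool],
        columns=["species_id", "category", "score"],
    )


def _geometric_ratio(pool_size: int, n_individuals: int, alpha_mean: float) -> float:
    """Geometric-series decay ratio giving an expected multinomial richness of
    about ``alpha_mean`` species per inventory (bisection on the closed form)."""
    alpha_mean = min(alpha_mean, pool_size * 0.98)

    def expected_richness(ratio: float) -> float:
        p = ratio ** np.arange(pool_size)
        p /= p.sum()
        return float(np.sum(1.0 - (1.0 - p) ** n_individuals))

    lo, hi = 0.01, 0.999999
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_richness(mid) < alpha_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _uniform_points_in_polygon(
    polygon: Polygon, k: int, rng: np.random.Generator
) -> np.ndarray:
    import shapely

    xmin, ymin, xmax, ymax = polygon.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < k:
        xs = rng.uniform(xmin, xmax, size=4 * k)
        ys = rng.uniform(ymin, ymax, size=4 * k)
        inside = shapely.contains_xy(polygon, xs, ys)
        pts.extend(zip(xs[inside], ys[inside]))
    return np.array(pts[:k])


def generate_communities(
    truth: LandscapeTruth,
    pool: list[SpeciesRecord],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Site coordinates and abundance rows for one landscape.

    Species weights start from a geometric rank profile, get (a) a per-site
    log-normal perturbation whose between-site correlation decays with
    distance at ``distance_decay_rate``, (b) a generalist-dominance boost
    growing with the landscape's nuclei count (scaled by
    ``homogenization_strength``) that also damps generalist site noise, and
    (c) an endemic multiplier (1 + endemism_cover_coupling * cover).  Counts
    are multinomial draws of ``individuals_per_inventory``.
    """
    k = truth.n_inventories
    if k < 2:
        raise DesignError("a landscape needs at least 2 inventory sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region = truth.site_polygon if truth.site_polygon is not None else truth.polygon
    sites = _uniform_points_in_polygon(region, k, rng)
    S = len(pool)
    scores = np.array([s.score for s in pool])

    ratio = _geometric_ratio(S, config.individuals_per_inventory, config.alpha_mean)
    base = ratio ** np.arange(S)

    weights = base.copy()
    endemic = scores >= 2
    weights[endemic] *= 1.0 + config.endemism_cover_coupling * truth.target_cover

    lo_n, hi_n = config.fragmentation_nuclei_range
    nuclei_scaled = (truth.n_nuclei - lo_n) / max(hi_n - lo_n, 1)
    generalist = np.arange(S) < max(int(0.15 * S), 3)  # commonest ranks
    g_boost = 1.0 + config.homogenization_strength * nuclei_scaled
    weights[generalist] *= g_boost

    # spatially correlated site noise: corr(site j, site k) = exp(-rate * d_jk)
    d = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=-1)
    corr = np.exp(-config.distance_decay_rate * d)
    L = np.linalg.cholesky(corr + 1e-9 * np.eye(k))
    z = rng.standard_normal((S, k))
    sigma = config.site_noise_sd * math.exp(
        -config.cover_homogenization * truth.target_cover
    )
    sigma_vec = np.full(S, sigma)
    sigma_vec[generalist] = sigma / g_boost
    log_noise = (z @ L.T) * sigma_vec[:, None]

    site_weights = weights[:, None] * np.exp(log_noise)
    probs = site_weights / site_weights.sum(axis=0, keepdims=True)
    counts = np.empty((k, S), dtype=np.int64)
    for j in range(k):
        counts[j] = rng.multinomial(config.individuals_per_inventory, probs[:, j])
    return sites, counts


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study; reproducible under config.seed."""
    rng = np.random.default_rng(config.seed)
    grid = HexGrid(cell_area=config.landscape_area, origin=(0.0, 0.0))
    a = grid.edge
    pool = generate_species_pool(config.pool_size, config.endemism_mix, rng)
    sp_table = species_table(pool)
    sp_ids = list(sp_table["species_id"])

    ncols = int(math.ceil(math.sqrt(config.n_landscapes)))
    cells = []
    i = 0
    while len(cells) < config.n_landscapes:
        q, r = i % ncols, i // ncols
        cells.append((q - r // 2, r))  # de-skew axial q so the block stays compact
        i += 1

    inv_rows = []
    ab_rows = []
    ab_index = []
    rasters: dict[str, Raster] = {}
    climate_rows = []
    truth_rows = []
    lo_c, hi_c = config.habitat_amount_range
    lo_n, hi_n = config.fragmentation_nuclei_range
    lo_k, hi_k = config.inventories_per_landscape_range
    raster_extent = (2.0 * a) ** 2  # square covering the hexagon bbox

    for idx, (q, r) in enumerate(cells):
        lid = f"L{idx + 1:03d}"
        lrng = _landscape_rng(config.seed, lid)
        cx, cy = grid.center(q, r)
        polygon = grid.polygon(q, r)
        cover = float(lrng.uniform(lo_c, hi_c))
        n_nuclei = int(lrng.integers(lo_n, hi_n + 1))
        k = int(lrng.integers(lo_k, hi_k + 1))
        years = lrng.integers(1995, 2019, size=k)
        # site-placement disc: keeps sites inside the hexagon (inradius
        # ~0.866 a) while varying mean inter-site distance across landscapes
        max_radius = 0.92 * (SQRT3_HALF * a)
        site_radius = float(lrng.uniform(0.15 * max_radius, max_radius))
        from shapely.geometry import Point

        truth = LandscapeTruth(
            landscape_id=lid,
            center=(cx, cy),
            polygon=polygon,
            target_cover=cover,
            n_nuclei=n_nuclei,
            n_inventories=k,
            site_polygon=Point(cx, cy).buffer(site_radius, quad_segs=32),
            site_radius=site_radius,
        )
        side = 2.0 * a
        rasters[lid] = generate_habitat_raster(
            raster_extent,
            config.cell_size,
            cover,
            n_nuclei,
            lrng,
            origin=(cx - side / 2.0, cy - side / 2.0),
            year=int(years.min()),
        )
        sites, counts = generate_communities(truth, pool, config, lrng)
        for j in range(k):
            inv_rows.append(
                {
                    "inventory_id": f"{lid}-I{j + 1:02d}",
                    "landscape_id": lid,
                    "x": sites[j, 0],
                    "y": sites[j, 1],
                    "year": int(years[j]),
                    "effort_ha": round(float(lrng.uniform(0.10, 1.0)), 3),
                    "dbh_cutoff_cm": 5.0,
                }
            )
            ab_rows.append(counts[j])
            ab_index.append(f"{lid}-I{j + 1:02d}")
        # smooth climate surfaces over the study block plus small local noise
        climate_rows.append(
            {
                "landscape_id": lid,
                "temperature": 22.0 - 0.05 * cy + 0.02 * cx + float(lrng.normal(0, 0.4)),
                "temperature_seasonality": 2.0 + 0.015 * cy + float(lrng.normal(0, 0.15)),
                "precipitation": 1500.0 + 4.0 * cx - 2.0 * cy + float(lrng.normal(0, 60.0)),
                "precipitation_seasonality": 35.0 + 0.08 * cx + float(lrng.normal(0, 2.0)),
            }
        )
        truth_rows.append(
            {
                "landscape_id": lid,
                "center_x": cx,
                "center_y": cy,
                "target_cover": cover,
                "n_nuclei": n_nuclei,
                "n_inventories": k,
                "site_radius": site_radius,
            }
        )

    inventories = pd.DataFrame(inv_rows)
    abundances = pd.DataFrame(np.vstack(ab_rows), index=ab_index, columns=sp_ids)
    abundances.index.name = "inventory_id"
    return SyntheticStudy(
        config=config,
        inventories=inventories,
        abundances=abundances,
        species=sp_table,
        rasters=rasters,
        climate=pd.DataFrame(climate_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write the study as delimited text tables plus one ASCII-grid raster per
    landscape under ``outdir`` (rasters in ``outdir``/rasters)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.inventories.to_csv(outdir / "inventories.csv", index=False)
    study.abundances.to_csv(outdir / "abundances.csv")
    study.species.to_csv(outdir / "species.csv", index=False)
    study.climate.to_csv(outdir / "climate.csv", index=False)
    study.truth.to_csv(outdir / "truth.csv", index=False)
    rdir = outdir / "rasters"
    rdir.mkdir(exist_ok=True)
    for lid, raster in study.rasters.items():
        write_ascii_grid(raster, rdir / f"{lid}.asc")
    return outdir
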