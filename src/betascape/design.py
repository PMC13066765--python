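"""Study design: inventory filtering, hexagon tessellation, landscape assignment.

Coordinates are planar km unless stated otherwise.  The hexagon lattice is
pointy-top, anchored at a fixed origin (default (0, 0)) so that independently
constructed grids over different extents are mutually consistent.  Point
assignment uses exact axial (cube-rounding) arithmetic, which makes the
tessellation a true partition: every point belongs to exactly one cell, with
edge ties resolved deterministically by the rounding rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigurationError, DataError, DesignError

SQRT3 = math.sqrt(3.0)

#: machine-readable drop reasons, in first-failure order
REASON_EFFORT = "effort"
REASON_DBH = "dbh"
REASON_COMPLETENESS = "completeness"

#: metadata columns an inventory row must provide
INVENTORY_COLUMNS = ("inventory_id", "x", "y", "year", "effort_ha", "dbh_cutoff_cm")


def hexagon_edge(cell_area: float) -> float:
    """Edge length of a regular hexagon of the given area (A = 3*sqrt(3)/2 * a^2)."""
    if cell_area <= 0:
        raise ConfigurationError("cell_area must be positive")
    return math.sqrt(2.0 * cell_area / (3.0 * SQRT3))


def _axial_round(qf: float, rf: float) -> tuple[int, int]:
    # cube rounding: round each cube coordinate, fix the one with largest error
    sf = -qf - rf
    q, r, s = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(s - sf)
    if dq > dr and dq > ds:
        q = -r - s
    elif dr > ds:
        r = -q - s
    return int(q), int(r)


@dataclass(frozen=True)
class HexGrid:
    """Pointy-top hexagon lattice in planar km, anchored at ``origin``."""

    cell_area: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def edge(self) -> float:
        return hexagon_edge(self.cell_area)

    def center(self, q: int, r: int) -> tuple[float, float]:
        a = self.edge
        return (
            self.origin[0] + a * (SQRT3 * q + SQRT3 / 2.0 * r),
            self.origin[1] + a * 1.5 * r,
        )

    def assign(self, x: float, y: float) -> tuple[int, int]:
        """Axial coordinates of the hexagon containing a point (exact partition)."""
        a = self.edge
        px = x - self.origin[0]
        py = y - self.origin[1]
        qf = (SQRT3 / 3.0 * px - py / 3.0) / a
        rf = (2.0 / 3.0 * py) / a
        return _axial_round(qf, rf)

    def polygon(self, q: int, r: int) -> Polygon:
        cx, cy = self.center(q, r)
        a = self.edge
        angles = np.deg2rad(np.arange(30, 390, 60))  # pointy-top: vertex at 90 deg
        return Polygon(
            [(cx + a * math.cos(t), cy + a * math.sin(t)) for t in angles]
        )

    def cells_covering(self, bounds: tuple[float, float, float, float]) -> list[tuple[int, int]]:
        """Axial indices of all cells intersecting the (xmin, ymin, xmax, ymax) bbox."""
        xmin, ymin, xmax, ymax = bounds
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError("extent is degenerate")
        a = self.edge
        r_lo = math.floor((ymin - self.origin[1]) / (1.5 * a)) - 1
        r_hi = math.ceil((ymax - self.origin[1]) / (1.5 * a)) + 1
        cells = []
        for r in range(r_lo, r_hi + 1):
            q_lo = math.floor((xmin - self.origin[0]) / (SQRT3 * a) - r / 2.0) - 1
            q_hi = math.ceil((xmax - self.origin[0]) / (SQRT3 * a) - r / 2.0) + 1
            cells.extend((q, r) for q in range(q_lo, q_hi + 1))
        return cells


def hexagon_grid(
    bounds: tuple[float, float, float, float],
    cell_area: float = 100.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> list[Polygon]:
    """Regular pointy-top hexagons tiling (covering) the given bbox, no gaps/overlaps."""
    grid = HexGrid(cell_area=cell_area, origin=origin)
    return [grid.polygon(q, r) for q, r in grid.cells_covering(bounds)]


@dataclass
class LandscapeUnit:
    """One retained hexagon cell with its member inventories."""

    id: str
    hexagon: Polygon
    inventory_ids: list[str]
    reference_year: int
    axial: tuple[int, int] = field(default=(0, 0))


def read_inventories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(INVENTORY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"inventory table missing columns: {sorted(missing)}")
    return df


def read_abundances(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "inventory_id"
    return df


def filter_inventories(
    inventories: pd.DataFrame,
    abundances: pd.DataFrame | None = None,
    min_effort: float = 0.10,
    min_dbh: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three survey filters; return (kept, dropped-with-reasons).

    Rules, in first-failure order: sampling effort >= ``min_effort`` ha, DBH
    inclusion cutoff >= ``min_dbh`` cm, and complete metadata/abundance data.
    ``dropped`` has columns inventory_id and reason.
    """
    missing_cols = set(INVENTORY_COLUMNS) - set(inventories.columns)
    if missing_cols:
        raise DataError(f"inventory table missing columns: {sorted(missing_cols)}")
    reasons: list[tuple[str, str]] = []
    keep_mask = []
    for _, row in inventories.iterrows():
        inv_id = row["inventory_id"]
        reason = None
        if pd.isna(row["effort_ha"]) or float(row["effort_ha"]) < min_effort:
            reason = REASON_EFFORT
        elif pd.isna(row["dbh_cutoff_cm"]) or float(row["dbh_cutoff_cm"]) < min_dbh:
            reason = REASON_DBH
        elif row[list(INVENTORY_COLUMNS)].isna().any():
            reason = REASON_COMPLETENESS
        elif abundances is not None:
            if inv_id not in abundances.index:
                reason = REASON_COMPLETENESS
            elif abundances.loc[inv_id].isna().any():
                reason = REASON_COMPLETENESS
        if reason is None:
            keep_mask.append(True)
        else:
            keep_mask.append(False)
            reasons.append((inv_id, reason))
    kept = inventories.loc[np.asarray(keep_mask, dtype=bool)].reset_index(drop=True)
    dropped = pd.DataFrame(reasons, columns=["inventory_id", "reason"])
    return kept, dropped


def assign_landscapes(
    inventories: pd.DataFrame,
    grid: HexGrid | None = None,
    min_inventories: int = 2,
    cell_area: float = 100.0,
) -> list[LandscapeUnit]:
    """Assign each inventory to the hexagon containing it; keep cells with
    at least ``min_inventories`` members; reference year = min member year."""
    if grid is None:
        grid = HexGrid(cell_area=cell_area)
    if min_inventories < 1:
        raise ConfigurationError("min_inventories must be >= 1")
    buckets: dict[tuple[int, int], list[int]] = {}
    for i, row in inventories.iterrows():
        if pd.isna(row["x"]) or pd.isna(row["y"]):
            raise DesignError(f"inventory {row['inventory_id']!r} has no coordinates")
        qr = grid.assign(float(row["x"]), float(row["y"]))
        buckets.setdefault(qr, []).append(i)
    units = []
    for (q, r), idx in sorted(buckets.items()):
        if len(idx) < min_inventories:
            continue
        members = inventories.loc[idx]
        units.append(
            LandscapeUnit(
                id=f"H{q}_{r}",
                hexagon=grid.polygon(q, r),
                inventory_ids=list(members["inventory_id"]),
                reference_year=int(members["year"].min()),
                axial=(q, r),
            )
        )
    return units


def membership_table(units: list[LandscapeUnit]) -> pd.DataFrame:
    """Long-format landscape membership: landscape_id, inventory_id, reference_year."""
    rows = [
        {"landscape_id": u.id, "inventory_id": inv, "reference_year": u.reference_year}
        for u in units
        for inv in u.inventory_ids
    ]
    return pd.DataFrame(rows, columns=["landscape_id", "inventory_id", "reference_year"])
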