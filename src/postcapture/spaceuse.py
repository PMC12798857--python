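"""Daily kernel home ranges on a fixed 100-m grid and their overlap.

Each day's fixes get a bivariate isotropic Gaussian kernel density estimate
with the classical ad hoc reference bandwidth, evaluated at the centers of
a 100-m grid snapped to multiples of the cell size. The 99% isopleth is the
smallest set of highest-density cells holding 99% of the grid mass; its
area is the cell count (one 100-m cell = exactly 1 ha). Overlap between
consecutive daily ranges defaults to the Jaccard index on cell sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .telemetry import Deployment, MOVEMENT_DAYS


def href_bandwidth(points: np.ndarray, exponent: float = -1.0 / 6.0,
                   floor_m: float = 25.0) -> float:
    """Ad hoc bivariate reference bandwidth h = 0.5 (sd_x + sd_y) n^(-1/6).

    Sample SDs use the n-1 denominator. Degenerate inputs (n < 2 or zero
    variance) fall back to ``floor_m``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        return floor_m
    sd = pts.std(axis=0, ddof=1)
    h = 0.5 * (sd[0] + sd[1]) * n ** exponent
    if not np.isfinite(h) or h <= 0:
        return floor_m
    return float(max(h, 1e-12))


@dataclass
class GridDensity:
    """KDE mass on a cell grid. ``mass[i, j]`` is cell (ix0+i, iy0+j)."""

    mass: np.ndarray
    ix0: int
    iy0: int
    cell_m: float


@dataclass
class DailyRange:
    """Cells of one day's isopleth; 100-m cells make area_ha = cell count."""

    deployment_id: str
    day: int
    bandwidth_m: float
    cells: frozenset[tuple[int, int]]
    cell_m: float = 100.0

    @property
    def area_ha(self) -> float:
        return len(self.cells) * (self.cell_m / 100.0) ** 2

    def polygon(self):
        """Union of member cells as a shapely polygon (planar meters)."""
        from shapely.geometry import box
        from shapely.ops import unary_union
        c = self.cell_m
        return unary_union([box(ix * c, iy * c, (ix + 1) * c, (iy + 1) * c)
                            for ix, iy in self.cells])


def kde_on_grid(points: np.ndarray, h: float, cell_m: float = 100.0,
                pad_factor: float = 3.0) -> GridDensity:
    """Isotropic Gaussian KDE evaluated at cell centers, normalized to 1.

    The grid snaps to multiples of ``cell_m`` and extends ``pad_factor * h``
    beyond the fix bounding box, so essentially all kernel mass lies inside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("kde_on_grid: empty point set")
    pad = pad_factor * h + cell_m
    ix0 = int(np.floor((pts[:, 0].min() - pad) / cell_m))
    ix1 = int(np.ceil((pts[:, 0].max() + pad) / cell_m))
    iy0 = int(np.floor((pts[:, 1].min() - pad) / cell_m))
    iy1 = int(np.ceil((pts[:, 1].max() + pad) / cell_m))
    cx = (np.arange(ix0, ix1) + 0.5) * cell_m
    cy = (np.arange(iy0, iy1) + 0.5) * cell_m
    # separable kernel: sum_k exp(-(dx^2+dy^2)/2h^2) via outer products
    gx = np.exp(-0.5 * ((cx[None, :] - pts[:, 0][:, None]) / h) ** 2)
    gy = np.exp(-0.5 * ((cy[None, :] - pts[:, 1][:, None]) / h) ** 2)
    mass = gx.T @ gy  # (nx, ny)
    total = mass.sum()
    if total <= 0:
        raise ValueError("kde_on_grid: degenerate density")
    return GridDensity(mass=mass / total, ix0=ix0, iy0=iy0, cell_m=cell_m)


def isopleth(grid: GridDensity, level: float = 0.99,
             deployment_id: str = "", day: int = 0,
             bandwidth_m: float = float("nan")) -> DailyRange:
    """Smallest highest-density cell set holding ``level`` of the mass.

    Cells are ranked by density descending; the shortest prefix whose
    cumulative mass reaches the level is kept, with density ties at the cut
    included together.
    """
    if not (0 < level <= 1):
        raise ValueError("isopleth level must lie in (0, 1]")
    flat = grid.mass.ravel()
    pos = np.nonzero(flat > 0)[0]
    ny = grid.mass.shape[1]
    if level >= 1.0:  # every positive-mass cell belongs to the 100% range
        cells = frozenset((grid.ix0 + i // ny, grid.iy0 + i % ny) for i in pos)
        return DailyRange(deployment_id=deployment_id, day=day,
                          bandwidth_m=bandwidth_m, cells=cells,
                          cell_m=grid.cell_m)
    order = pos[np.argsort(flat[pos])[::-1]]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level * flat.sum() - 1e-12)) + 1
    k = min(k, len(order))
    cut = flat[order[k - 1]]
    in_set = order[:k].tolist()
    # include density ties at the cut
    ties = pos[np.isclose(flat[pos], cut, rtol=1e-12, atol=0.0)]
    chosen = set(in_set) | set(ties.tolist())
    ny = grid.mass.shape[1]
    cells = frozenset((grid.ix0 + i // ny, grid.iy0 + i % ny) for i in chosen)
    return DailyRange(deployment_id=deployment_id, day=day,
                      bandwidth_m=bandwidth_m, cells=cells,
                      cell_m=grid.cell_m)


def range_overlap(a: DailyRange, b: DailyRange,
                  mode: str = "jaccard") -> float:
    """Overlap between two daily ranges on their shared absolute grid.

    ``jaccard`` (default) is area(A&B)/area(A|B); ``directional`` is
    area(A&B)/area(A). Both grids snap to multiples of the cell size, so
    cell indices align by construction.
    """
    if not a.cells or not b.cells:
        raise ValueError("range_overlap: empty range")
    if a.cell_m != b.cell_m:
        raise ValueError("range_overlap: mismatched cell sizes")
    inter = len(a.cells & b.cells)
    if mode == "jaccard":
        return inter / len(a.cells | b.cells)
    if mode == "directional":
        return inter / len(a.cells)
    raise ValueError(f"unknown overlap mode {mode!r}")


def daily_range(dep: Deployment, day: int, level: float = 0.99,
                cell_m: float = 100.0) -> DailyRange | None:
    """99% kernel range for one day of a deployment (None if no fixes)."""
    tcol = ("timestamp_local" if "timestamp_local" in dep.fixes.columns
            else "timestamp_utc")
    days = (dep.fixes[tcol].dt.normalize() - dep.capture_day).dt.days
    pts = dep.fixes.loc[days == day, ["x_m", "y_m"]].to_numpy(dtype=float)
    if len(pts) == 0:
        return None
    h = href_bandwidth(pts)
    grid = kde_on_grid(pts, h, cell_m=cell_m)
    return isopleth(grid, level=level, deployment_id=dep.deployment_id,
                    day=day, bandwidth_m=h)


def space_use_series(dep: Deployment, level: float = 0.99,
                     cell_m: float = 100.0,
                     overlap_mode: str = "jaccard"
                     ) -> tuple[dict[int, float], dict[int, float]]:
    """Daily range sizes (ha, days 1-30) and consecutive overlaps (days 1-29).

    The overlap for day d pairs the ranges of days d and d+1, so 30
    consecutive daily ranges yield exactly 29 overlap values.
    """
    ranges = {day: daily_range(dep, day, level=level, cell_m=cell_m)
              for day in MOVEMENT_DAYS}
    sizes = {day: (r.area_ha if r is not None else float("nan"))
             for day, r in ranges.items()}
    overlaps = {}
    for day in range(1, 30):
        a, b = ranges.get(day), ranges.get(day + 1)
        overlaps[day] = (range_overlap(a, b, mode=overlap_mode)
                         if a is not None and b is not None else float("nan"))
    return sizes, overlaps


def export_geojson(ranges: list[DailyRange], path, crs: str = "EPSG:32614") -> None:
    """Write daily-range polygons as a GeoJSON feature collection."""
    import json
    from shapely.geometry import mapping
    features = [{
        "type": "Feature",
        "properties": {"deployment_id": r.deployment_id, "day": r.day,
                       "area_ha": r.area_ha, "bandwidth_m": r.bandwidth_m,
                       "crs": crs},
        "geometry": mapping(r.polygon()),
    } for r in ranges]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
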