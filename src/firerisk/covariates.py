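"""Construction of the model covariates from primitive inputs.

The eight covariates of the fire-risk model are built here from monthly
climate series, road and settlement geometry, binary change maps and
categorical land-cover maps:

* annual MCWD (maximum climatological water deficit) and its anomaly,
* annual-mean temperature anomaly,
* weighted Euclidean distance to roads,
* population-weighted kernel density of settlements,
* land-cover class fractions and deforestation fractions aggregated from a
  finer binary/categorical map.

MCWD follows the standard accumulation rule: the monthly water deficit is
``WD_n = min(0, WD_{n-1} + P_n - threshold)`` with the evapotranspiration
proxy ``threshold`` defaulting to 100 mm/month, reset to zero at the start
of the hydrological year; MCWD is the most negative deficit reached over
the 12-month window (<= 0, in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Grid, GridMismatchError, Layer, aggregate_fraction

__all__ = [
    "MonthlyClimateSeries",
    "AnomalyLayer",
    "RoadSet",
    "SettlementSet",
    "compute_mcwd",
    "annual_mean_temperature",
    "compute_anomaly",
    "distance_to_roads",
    "settlement_density",
    "landcover_fraction",
]

MCWD_THRESHOLD_MM = 100.0  # evapotranspiration proxy, mm per month
LST_SCALE_FACTOR = 0.02  # MOD11C3-style integer LST -> kelvin

DEFAULT_ROAD_WEIGHTS = {"paved": 1.0, "unpaved": 0.5}


@dataclass
class MonthlyClimateSeries:
    """Monthly precipitation (mm) and temperature (K) cubes on one grid.

    Arrays are indexed ``[year_index, month_index, row, col]`` with
    month_index 0 = January; ``years`` is the inclusive year range.
    """

    grid: Grid
    years: tuple[int, int]
    precipitation: np.ndarray
    temperature: np.ndarray

    def __post_init__(self):
        n_years = self.years[1] - self.years[0] + 1
        expected = (n_years, 12) + self.grid.shape
        for nm, arr in (("precipitation", self.precipitation),
                        ("temperature", self.temperature)):
            if arr.shape != expected:
                raise ValueError(f"{nm} shape {arr.shape} != {expected}")
        valid = ~self.grid.mask
        if np.any(self.precipitation[..., valid] < 0):
            raise ValueError("negative precipitation")
        t = self.temperature[..., valid]
        if np.any((t <= 150) | (t >= 350)):
            raise ValueError("temperature outside plausible (150, 350) K range")

    def year_index(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[1]):
            raise ValueError(f"year {year} outside coverage {self.years}")
        return year - self.years[0]

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class AnomalyLayer(Layer):
    """Continuous layer of departures of one year from a multi-year baseline.

    Sign convention: negative MCWD anomaly = drier than baseline; positive
    temperature anomaly = warmer than baseline.
    """

    target_year: int = 0
    baseline_years: tuple[int, ...] = ()


@dataclass
class RoadSet:
    """Polyline road network with per-class distance weights.

    Coordinates are in the grid's world units (km).  A smaller weight makes
    that class dominate the combined weighted distance.
    """

    polylines: list[tuple[str, np.ndarray]]  # (class, vertices (n, 2))
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROAD_WEIGHTS))

    def __post_init__(self):
        for cls, verts in self.polylines:
            if cls not in self.weights:
                raise ValueError(f"road class {cls!r} has no weight")
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
                raise ValueError("each polyline needs >= 2 (x, y) vertices")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("road weights must be > 0")

    @classmethod
    def from_csv(cls, path: str, weights: dict[str, float] | None = None) -> "RoadSet":
        """Load from CSV with columns road_id, class, x, y (vertex order by row)."""
        df = pd.read_csv(path)
        polylines = []
        for (_, c), grp in df.groupby(["road_id", "class"], sort=True):
            polylines.append((str(c), grp[["x", "y"]].to_numpy(float)))
        return cls(polylines, weights or dict(DEFAULT_ROAD_WEIGHTS))

    def to_csv(self, path: str) -> None:
        rows = []
        for i, (c, verts) in enumerate(self.polylines):
            for x, y in verts:
                rows.append({"road_id": i, "class": c, "x": x, "y": y})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class SettlementSet:
    """Point settlements with population weights (persons)."""

    points: np.ndarray  # (n, 2) x, y in km
    population: np.ndarray  # (n,) persons

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.population = np.asarray(self.population, dtype=float).reshape(-1)
        if self.points.shape[0] != self.population.shape[0]:
            raise ValueError("points and population lengths differ")
        if np.any(self.population <= 0):
            raise ValueError("population weights must be > 0")

    @classmethod
    def from_csv(cls, path: str) -> "SettlementSet":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(float), df["population"].to_numpy(float))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "population": self.population}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Climate covariates


def compute_mcwd(series: MonthlyClimateSeries, year: int,
                 threshold: float = MCWD_THRESHOLD_MM,
                 reset_month: int = 1) -> Layer:
    """Maximum climatological water deficit for one hydrological year.

    The deficit accumulates over the 12 months starting at ``reset_month``
    (1 = January) of ``year``; months spilling past December come from the
    following calendar year.  Returns the most negative deficit per cell
    (<= 0, mm).
    """
    if not 1 <= reset_month <= 12:
        raise ValueError("reset_month must be in 1..12")
    months = []  # (year, month) pairs of the window
    y, m = year, reset_month
    for _ in range(12):
        months.append((y, m))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    for yy, _ in months:
        if not (series.years[0] <= yy <= series.years[1]):
            raise ValueError(
                f"MCWD window for {year} (reset month {reset_month}) needs year {yy}, "
                f"outside coverage {series.years}"
            )
    wd = np.zeros(series.grid.shape)
    mcwd = np.zeros(series.grid.shape)
    for yy, mm in months:
        p = series.precipitation[series.year_index(yy), mm - 1]
        wd = np.minimum(0.0, wd + p - threshold)
        mcwd = np.minimum(mcwd, wd)
    mcwd[series.grid.mask] = 0.0
    return Layer(grid=series.grid, name=f"mcwd_{year}", values=mcwd, units="mm")


def annual_mean_temperature(series: MonthlyClimateSeries, year: int) -> Layer:
    """Mean of the 12 monthly temperatures of a calendar year (K)."""
    t = series.temperature[series.year_index(year)].mean(axis=0)
    t = t.copy()
    t[series.grid.mask] = 0.0
    return Layer(grid=series.grid, name=f"tmean_{year}", values=t, units="K")


def compute_anomaly(per_year: dict[int, Layer], target_year: int,
                    name: str | None = None) -> AnomalyLayer:
    """Departure of one year from the mean over all supplied baseline years.

    The baseline is every layer in ``per_year`` (it includes the target year,
    as in a 2000-2010 baseline containing 2010).  The mean anomaly over the
    baseline years is zero per cell by construction.
    """
    if len(per_year) < 2:
        raise ValueError("anomaly needs >= 2 baseline years")
    if target_year not in per_year:
        raise ValueError(f"target year {target_year} not among baseline layers")
    grid = per_year[target_year].grid
    for y, layer in per_year.items():
        if not layer.grid.compatible(grid):
            raise GridMismatchError(f"baseline year {y} on a mismatched grid")
    baseline = np.mean([l.values for l in per_year.values()], axis=0)
    anom = per_year[target_year].values - baseline
    anom[grid.mask] = 0.0
    return AnomalyLayer(
        grid=grid,
        name=name or f"anomaly_{target_year}",
        values=anom,
        units=per_year[target_year].units,
        target_year=target_year,
        baseline_years=tuple(sorted(per_year)),
    )


# ---------------------------------------------------------------------------
# Access / settlement covariates


def rasterize_roads(roads: RoadSet, grid: Grid) -> dict[str, np.ndarray]:
    """Boolean road mask per class: every cell a polyline touches.

    Segments are sampled at an eighth of a cell so no crossed cell is missed.
    """
    masks: dict[str, np.ndarray] = {}
    step = grid.cell_size / 8.0
    ox, oy = grid.origin
    for cls, verts in roads.polylines:
        mask = masks.setdefault(cls, np.zeros(grid.shape, dtype=bool))
        for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
            seg_len = float(np.hypot(x1 - x0, y1 - y0))
            n = max(2, int(np.ceil(seg_len / step)) + 1)
            xs = np.linspace(x0, x1, n)
            ys = np.linspace(y0, y1, n)
            cols = np.floor((xs - ox) / grid.cell_size).astype(int)
            rows = np.floor((oy - ys) / grid.cell_size).astype(int)
            ok = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
            mask[rows[ok], cols[ok]] = True
    return masks


def distance_to_roads(roads: RoadSet, grid: Grid) -> Layer:
    """Weighted Euclidean distance to the nearest road, in metres.

    Per cell: ``min over classes of (distance to nearest cell of that class
    x class weight)``.  Road cells score 0.  Each class's unweighted distance
    field is 1-Lipschitz on the grid.
    """
    if not roads.polylines:
        raise ValueError("empty road set")
    masks = rasterize_roads(roads, grid)
    if not any(m.any() for m in masks.values()):
        raise ValueError("no road intersects the grid")
    combined = np.full(grid.shape, np.inf)
    for cls, mask in masks.items():
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(~mask) * grid.cell_size * 1000.0
        combined = np.minimum(combined, dist * roads.weights[cls])
    combined[grid.mask] = 0.0
    return Layer(grid=grid, name="roads", values=combined, units="m")


def settlement_density(settlements: SettlementSet, grid: Grid,
                       bandwidth: float = 10.0) -> Layer:
    """Population-weighted 2-D quartic (biweight) kernel density, persons/km^2.

    ``K(u) = (3 / (pi h^2)) (1 - u^2)^2`` for ``u = d/h <= 1``; the density
    integrates to the total population for settlements at least one bandwidth
    from the boundary, up to discretization error.  Density is additive in
    settlements.  An empty set yields a zero layer.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    dens = np.zeros(grid.shape)
    if settlements.points.shape[0] == 0:
        return Layer(grid=grid, name="settlements", values=dens, units="persons/km^2")
    cx, cy = grid.cell_centers()
    norm = 3.0 / (np.pi * bandwidth**2)
    h_cells = int(np.ceil(bandwidth / grid.cell_size)) + 1
    ox, oy = grid.origin
    for (x, y), pop in zip(settlements.points, settlements.population):
        # restrict to the kernel's support window for speed
        col = int((x - ox) / grid.cell_size)
        row = int((oy - y) / grid.cell_size)
        r0, r1 = max(0, row - h_cells), min(grid.n_rows, row + h_cells + 1)
        c0, c1 = max(0, col - h_cells), min(grid.n_cols, col + h_cells + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        d2 = (cx[r0:r1, c0:c1] - x) ** 2 + (cy[r0:r1, c0:c1] - y) ** 2
        u2 = d2 / bandwidth**2
        inside = u2 <= 1.0
        dens[r0:r1, c0:c1] += np.where(inside, pop * norm * (1.0 - u2) ** 2, 0.0)
    dens[grid.mask] = 0.0
    return Layer(grid=grid, name="settlements", values=dens, units="persons/km^2")


def landcover_fraction(landcover: Layer, code: int, factor: int,
                       name: str | None = None) -> Layer:
    """Fraction of fine cells equal to ``code`` per coarse cell."""
    if landcover.kind != "categorical":
        raise ValueError("landcover_fraction expects a categorical layer")
    if landcover.codes is not None and code not in landcover.codes:
        raise ValueError(f"code {code} not among declared codes {landcover.codes}")
    binary = Layer(grid=landcover.grid, name=landcover.name,
                   values=(landcover.values == code).astype(np.float64))
    out = aggregate_fraction(binary, factor)
    out.name = name or f"{landcover.name}_frac{code}"
    return out
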