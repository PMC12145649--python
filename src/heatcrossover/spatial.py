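"""Zonal aggregation of gridded daily weather to region-level series.

Regions (forward-sortation-area analogues) are polygons intersected with an
inhabited-land ("ecumene") mask before aggregation, so that uninhabited heat
sinks such as lakes and forest do not dilute the exposure signal.  Each grid
cell contributes to a region's daily mean in proportion to the exact fraction
of the masked polygon's area that falls inside the cell ("pixel fraction"
weighting).  Relative humidity is derived from water vapour pressure and
daily mean temperature via Bolton's saturation vapour pressure approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "EmptyEcumeneError",
    "RegionWeights",
    "mask_to_ecumene",
    "compute_weights",
    "aggregate_daily",
    "saturation_vapour_pressure",
    "relative_humidity",
    "build_region_series",
]

# Bolton (1980) saturation vapour pressure constants:
# e_s(T) = 6.112 hPa * exp(17.67 T / (T + 243.5)), T in deg C.
_BOLTON_ES0_KPA = 0.6112
_BOLTON_A = 17.67
_BOLTON_B = 243.5


class EmptyEcumeneError(ValueError):
    """A region polygon has no intersection with the ecumene mask."""

    def __init__(self, region_id: str):
        self.region_id = region_id
        super().__init__(f"region {region_id!r}: ecumene intersection is empty")


@dataclass(frozen=True)
class RegionWeights:
    """Normalised pixel-fraction weights of one region over grid cells.

    ``cell_weights`` maps (row, col) cell indices to weights in [0, 1] that
    sum to one; cells with zero overlap are absent rather than zero-filled.
    """

    region_id: str
    cell_weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.cell_weights.values())
        if self.cell_weights and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"region {self.region_id!r}: weights sum to {total}, not 1"
            )
        if any(w < 0 for w in self.cell_weights.values()):
            raise ValueError(f"region {self.region_id!r}: negative weight")


def _as_valid(geom: BaseGeometry, region_id: str) -> BaseGeometry:
    if geom.is_valid:
        return geom
    repaired = make_valid(geom)
    if repaired.is_valid and not repaired.is_empty:
        return repaired
    raise ValueError(f"region {region_id!r}: geometry invalid and unrepairable")


def mask_to_ecumene(
    region: BaseGeometry, ecumene: BaseGeometry, region_id: str = "?"
) -> BaseGeometry:
    """Intersect a region polygon with its inhabited-land mask.

    Raises :class:`EmptyEcumeneError` when the intersection is empty, rather
    than silently returning an empty polygon, so that uninhabited regions are
    dropped explicitly upstream.
    """
    region = _as_valid(region, region_id)
    ecumene = _as_valid(ecumene, region_id)
    masked = region.intersection(ecumene)
    if masked.is_empty or masked.area == 0.0:
        raise EmptyEcumeneError(region_id)
    return masked


def compute_weights(
    masked: BaseGeometry, geotransform: "GridGeometry", region_id: str = "?"
) -> RegionWeights:
    """Exact area-fraction weights of a masked polygon over grid cells.

    weight(cell) = area(cell ∩ polygon) / Σ area(cell ∩ polygon).  Only cells
    whose rectangle intersects the polygon's bounding box are visited.
    """
    minx, miny, maxx, maxy = masked.bounds
    c0, r0 = geotransform.cell_index(minx, miny, clip=True)
    c1, r1 = geotransform.cell_index(maxx, maxy, clip=True)
    raw: dict[tuple[int, int], float] = {}
    for r in range(min(r0, r1), max(r0, r1) + 1):
        for c in range(min(c0, c1), max(c0, c1) + 1):
            a = geotransform.cell_box(r, c).intersection(masked).area
            if a > 0.0:
                raw[(r, c)] = a
    total = sum(raw.values())
    if total <= 0.0:
        raise ValueError(f"region {region_id!r}: zero overlap with the grid")
    weights = {rc: a / total for rc, a in raw.items()}
    # renormalise away float round-off so the sum-to-one invariant holds
    s = sum(weights.values())
    weights = {rc: w / s for rc, w in weights.items()}
    return RegionWeights(region_id=region_id, cell_weights=weights)


@dataclass(frozen=True)
class GridGeometry:
    """Affine geometry of a regular grid (planar CRS, km units).

    Cell (row, col) spans [x0 + col*dx, x0 + (col+1)*dx] ×
    [y0 + row*dy, y0 + (row+1)*dy].
    """

    x0: float
    y0: float
    dx: float
    dy: float
    nrows: int
    ncols: int

    def cell_box(self, row: int, col: int):
        return box(
            self.x0 + col * self.dx,
            self.y0 + row * self.dy,
            self.x0 + (col + 1) * self.dx,
            self.y0 + (row + 1) * self.dy,
        )

    def cell_index(self, x: float, y: float, clip: bool = False) -> tuple[int, int]:
        col = int(np.floor((x - self.x0) / self.dx))
        row = int(np.floor((y - self.y0) / self.dy))
        if clip:
            col = min(max(col, 0), self.ncols - 1)
            row = min(max(row, 0), self.nrows - 1)
        return col, row

    @property
    def extent(self):
        return box(
            self.x0, self.y0, self.x0 + self.ncols * self.dx, self.y0 + self.nrows * self.dy
        )


def aggregate_daily(grid, weights: RegionWeights) -> pd.DataFrame:
    """Weighted mean of each grid variable over one region, per day.

    ``grid`` is a WeatherGrid (xarray Dataset with dims date/row/col and
    variables tmax, tmean, vp).  Returns a DataFrame indexed by date with
    columns tmax_c, tmean_c, vp_kpa.  Missing (NaN) cell values on any date
    are a contract violation and raise with the offending date and cell.
    """
    cells = sorted(weights.cell_weights)
    w = np.array([weights.cell_weights[rc] for rc in cells])
    rows = np.array([rc[0] for rc in cells])
    cols = np.array([rc[1] for rc in cells])
    out = {}
    for var, col_name in (("tmax", "tmax_c"), ("tmean", "tmean_c"), ("vp", "vp_kpa")):
        vals = grid[var].values[:, rows, cols]  # (n_dates, n_cells)
        if not np.isfinite(vals).all():
            d_idx, c_idx = np.argwhere(~np.isfinite(vals))[0]
            date = pd.Timestamp(grid["date"].values[d_idx]).date()
            raise ValueError(
                f"missing {var} value on {date} at cell {tuple(int(v) for v in (rows[c_idx], cols[c_idx]))}"
            )
        out[col_name] = vals @ w
    return pd.DataFrame(out, index=pd.DatetimeIndex(grid["date"].values, name="date"))


def saturation_vapour_pressure(temperature_c):
    """Bolton's approximation to saturation vapour pressure, in kPa."""
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t <= -_BOLTON_B):
        raise ValueError(f"temperature must exceed {-_BOLTON_B} degC")
    return _BOLTON_ES0_KPA * np.exp(_BOLTON_A * t / (t + _BOLTON_B))


def relative_humidity(vapour_pressure_kpa, temperature_c):
    """Relative humidity in percent: 100 * e / e_s(T).

    Values above 100 (supersaturation artefacts of independent rounding of e
    and T) are retained, not clipped: they are informative for QC.
    """
    e = np.asarray(vapour_pressure_kpa, dtype=float)
    if np.any(e < 0):
        raise ValueError("vapour pressure must be non-negative")
    return 100.0 * e / saturation_vapour_pressure(temperature_c)


def build_region_series(grid, regions: dict[str, dict], geotransform: GridGeometry) -> pd.DataFrame:
    """Full aggregation: mask → weights → per-day weighted means → RH.

    ``regions`` maps region_id to {"polygon": geom, "ecumene": geom}.  Weights
    are computed once per region and reused across dates.  RH is computed from
    the daily mean temperature (vapour pressure is a daily average, so the
    daily mean is the matching temperature scale).
    """
    frames = []
    for region_id, geoms in regions.items():
        masked = mask_to_ecumene(geoms["polygon"], geoms["ecumene"], region_id)
        weights = compute_weights(masked, geotransform, region_id)
        df = aggregate_daily(grid, weights).reset_index()
        df.insert(0, "region_id", region_id)
        frames.append(df)
    series = pd.concat(frames, ignore_index=True)
    series["rh_pct"] = relative_humidity(series["vp_kpa"], series["tmean_c"])
    return series
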