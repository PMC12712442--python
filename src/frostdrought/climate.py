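"""Species climate-range summaries from occurrences and gridded layers.

Occurrence thinning (max records / minimum great-circle spacing), nearest-
cell raster extraction, range percentiles (5th percentile of the Aridity
Index and of daily minimum temperature describe the dry and cold edges of a
species' climatic envelope), and the order-statistic estimate of maximum
plant height.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClimateGrid", "read_grid", "haversine_km",
    "thin_occurrences", "extract_at_points", "range_percentile",
    "max_height_estimate", "summarize_species_climate", "species_max_heights",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClimateGrid:
    """Regular lon/lat grid, row 0 = northernmost row (ESRI-ASCII layout).

    ``x0``/``y0`` are the lower-left corner of the grid, ``cellsize`` in
    degrees; ``nodata`` cells read as missing.
    """

    x0: float
    y0: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x0 + (col + 0.5) * self.cellsize
        lat = self.y0 + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def to_text(self) -> str:
        head = (f"ncols {self.ncols}\nnrows {self.nrows}\n"
                f"xllcorner {self.x0}\nyllcorner {self.y0}\n"
                f"cellsize {self.cellsize}\nnodata_value {self.nodata}\n")
        body = "\n".join(" ".join(f"{v:.6g}" for v in row)
                         for row in np.where(np.isnan(self.values),
                                             self.nodata, self.values))
        return head + body + "\n"


def read_grid(source: str) -> ClimateGrid:
    """Read a plain-text grid: 6 header lines (ncols, nrows, xllcorner,
    yllcorner, cellsize, nodata_value) followed by the matrix rows."""
    if "\n" in source:
        lines = source.strip().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().strip().splitlines()
    header = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    values = np.loadtxt(io.StringIO("\n".join(lines[6:])))
    values = np.atleast_2d(values)
    grid = ClimateGrid(header["xllcorner"], header["yllcorner"],
                       header["cellsize"], values,
                       header.get("nodata_value", -9999.0))
    grid.values = np.where(grid.values == grid.nodata, np.nan, grid.values)
    if grid.values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    return grid


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(points: np.ndarray, max_n: int = 15_000,
                     min_dist_km: float = 10.0, seed: int = 0) -> np.ndarray:
    """Spatially thin occurrence points.

    A greedy pass over the seed-shuffled points keeps a point iff it lies at
    least ``min_dist_km`` (great circle) from every already-kept point; the
    kept set is then randomly subsampled to ``max_n`` if needed.
    Deterministic given ``seed``; returns the kept points (n, 2) as
    (lon, lat) rows.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if np.any(np.abs(points[:, 0]) > 180) or np.any(np.abs(points[:, 1]) > 90):
        raise ValueError("coordinates out of bounds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(points))
    kept: list[int] = []
    klon = np.empty(len(points))
    klat = np.empty(len(points))
    for i in order:
        lon, lat = points[i]
        if kept:
            d = haversine_km(lon, lat, klon[: len(kept)], klat[: len(kept)])
            if np.min(d) < min_dist_km:
                continue
        klon[len(kept)] = lon
        klat[len(kept)] = lat
        kept.append(i)
    kept_arr = np.array(kept, dtype=int)
    if len(kept_arr) > max_n:
        kept_arr = rng.choice(kept_arr, size=max_n, replace=False)
    return points[np.sort(kept_arr)]


def extract_at_points(grid: ClimateGrid, points: np.ndarray) -> np.ndarray:
    """Nearest-cell lookup; out-of-grid and nodata yield NaN."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    col = np.floor((points[:, 0] - grid.x0) / grid.cellsize).astype(int)
    row_from_bottom = np.floor((points[:, 1] - grid.y0) / grid.cellsize).astype(int)
    row = grid.nrows - 1 - row_from_bottom
    out = np.full(len(points), np.nan)
    ok = (col >= 0) & (col < grid.ncols) & (row >= 0) & (row < grid.nrows)
    out[ok] = grid.values[row[ok], col[ok]]
    return out


def range_percentile(values, q: float = 0.05) -> float:
    """Linear-interpolation percentile over non-missing values."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no non-missing values to summarize")
    return float(np.percentile(values, 100.0 * q, method="linear"))


def max_height_estimate(
    heights, outlier_flags=None, model_hmax: float | None = None,
    min_records: int = 100, rank: int = 10,
) -> tuple[float | None, str]:
    """Maximum-height estimate for one species.

    A model-based asymptotic height, when available, wins outright; otherwise
    outlier-flagged field records are dropped and, with at least
    ``min_records`` remaining, the ``rank``-th tallest record is returned.
    Species failing the record threshold are excluded (None, reason).
    """
    if model_hmax is not None and np.isfinite(model_hmax):
        return float(model_hmax), "model"
    heights = np.asarray(heights, dtype=float)
    if outlier_flags is not None:
        heights = heights[~np.asarray(outlier_flags, dtype=bool)]
    heights = heights[np.isfinite(heights)]
    if np.any(heights <= 0):
        raise ValueError("heights must be positive")
    if len(heights) < min_records:
        return None, f"fewer than {min_records} records ({len(heights)})"
    return float(np.sort(heights)[-rank]), "order_statistic"


def species_max_heights(records: pd.DataFrame,
                        model_table: pd.DataFrame | None = None,
                        min_records: int = 100, rank: int = 10) -> pd.DataFrame:
    """Apply :func:`max_height_estimate` per species.

    ``records`` needs columns species, height_m and optionally outlier_flag;
    ``model_table`` species, hmax_model_m.  Returns species, max_height,
    height_source (excluded species keep the exclusion reason, NaN height).
    """
    model = {}
    if model_table is not None:
        model = dict(zip(model_table["species"], model_table["hmax_model_m"]))
    rows = []
    for sp, grp in records.groupby("species", sort=True):
        flags = grp["outlier_flag"] if "outlier_flag" in grp else None
        h, source = max_height_estimate(
            grp["height_m"], flags, model.get(sp), min_records, rank)
        rows.append({"species": sp, "max_height": h, "height_source": source})
    for sp, hm in model.items():
        if sp not in set(records["species"]):
            rows.append({"species": sp, "max_height": float(hm),
                         "height_source": "model"})
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


def summarize_species_climate(
    occurrences: pd.DataFrame,
    grids: dict[str, ClimateGrid],
    max_n: int = 15_000,
    min_dist_km: float = 10.0,
    percentile: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species climate summary over thinned occurrences.

    ``grids`` may hold layers named map, mat, ai, tmin; means are reported
    for map/mat and the lower ``percentile`` for ai/tmin (the dry and cold
    range edges).  Nodata extractions are excluded with a count.
    """
    rows = []
    for k, (sp, grp) in enumerate(occurrences.groupby("species", sort=True)):
        pts = thin_occurrences(grp[["lon", "lat"]].to_numpy(),
                               max_n, min_dist_km, seed=seed + k)
        row: dict = {"species": sp, "n_points_used": int(len(pts))}
        for name, grid in grids.items():
            vals = extract_at_points(grid, pts)
            finite = vals[np.isfinite(vals)]
            row[f"n_missing_{name}"] = int(len(vals) - len(finite))
            if name in ("ai", "tmin"):
                row[f"{name}_p05"] = (range_percentile(finite, percentile)
                                      if len(finite) else np.nan)
            else:
                row[f"{name}_mean"] = (float(np.mean(finite))
                                       if len(finite) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
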