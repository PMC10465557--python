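"""Equal-area gridding of georeferenced records.

Records are binned on a Behrmann cylindrical equal-area projection
(standard parallel 30 deg N) so that every grid cell covers the same area
regardless of latitude.  The supported cell sizes — 96.5, 193 and
385.9 km — correspond to 1, 2 and 4 degrees of longitude at 30 N.  Cells
are half-open intervals [x0, x0 + w) x [y0, y0 + w) in projected meters,
anchored so cell boundaries pass through the equator and the prime
meridian; a point exactly on a shared edge belongs to the cell on the
+x/+y side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: authalic Earth radius in meters (sphere with the ellipsoid's surface area)
EARTH_RADIUS = 6_371_007.181

#: supported cell sizes in meters (1, 2 and 4 degrees longitude at 30 N)
RESOLUTIONS = (96_500.0, 193_000.0, 385_900.0)


@dataclass(frozen=True)
class GridSpec:
    """Equal-area grid definition.

    ``cell_size`` is the cell edge length in projected meters;
    ``standard_parallel`` the latitude of true scale (30 for Behrmann);
    ``origin`` the projected coordinate of cell (0, 0)'s lower-left corner.
    """

    cell_size: float = 193_000.0
    standard_parallel: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def _cos_sp(self) -> float:
        return float(np.cos(np.deg2rad(self.standard_parallel)))


def project(lat, lon, spec: GridSpec | None = None):
    """Forward Behrmann projection, degrees WGS84 -> projected meters.

    x = R * lambda * cos(phi1),  y = R * sin(phi) / cos(phi1).
    Accepts scalars or arrays; raises for |lat| > 90.
    """
    spec = spec or GridSpec()
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    c = spec._cos_sp
    x = EARTH_RADIUS * np.deg2rad(lon) * c
    y = EARTH_RADIUS * np.sin(np.deg2rad(lat)) / c
    return x, y


def unproject(x, y, spec: GridSpec | None = None):
    """Inverse Behrmann projection, meters -> (lat, lon) degrees."""
    spec = spec or GridSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = spec._cos_sp
    s = y * c / EARTH_RADIUS
    if np.any(np.abs(s) > 1 + 1e-12):
        raise ValueError("y outside the projected range of the sphere")
    lat = np.rad2deg(np.arcsin(np.clip(s, -1.0, 1.0)))
    lon = np.rad2deg(x / (EARTH_RADIUS * c))
    return lat, lon


def assign_cell(lat: float, lon: float, spec: GridSpec) -> tuple[int, int]:
    """Cell id (row, col) of a single georeferenced point."""
    if lat is None or lon is None or not np.isfinite(lat) or not np.isfinite(lon):
        raise ValueError("record has missing coordinates; filter upstream")
    x, y = project(lat, lon, spec)
    w = spec.cell_size
    col = int(np.floor((x - spec.origin[0]) / w))
    row = int(np.floor((y - spec.origin[1]) / w))
    return row, col


def cell_label(row: int, col: int) -> str:
    return f"r{row}c{col}"


def parse_cell_label(label: str) -> tuple[int, int]:
    r, c = label[1:].split("c")
    return int(r), int(c)


def cell_bounds(row: int, col: int, spec: GridSpec) -> tuple[float, float, float, float]:
    """Projected bounding box (x0, y0, x1, y1) of a cell."""
    w = spec.cell_size
    x0 = spec.origin[0] + col * w
    y0 = spec.origin[1] + row * w
    return x0, y0, x0 + w, y0 + w


def cell_centroid(row: int, col: int, spec: GridSpec) -> tuple[float, float]:
    """(lat, lon) of the cell's projected center."""
    x0, y0, x1, y1 = cell_bounds(row, col, spec)
    lat, lon = unproject((x0 + x1) / 2.0, (y0 + y1) / 2.0, spec)
    return float(lat), float(lon)


def assign_cells(records: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Vectorized cell assignment for a record table with lat/lon columns.

    Returns a copy with ``cell_row``, ``cell_col`` and ``cell`` columns.
    Raises if any record lacks coordinates (records must be pre-filtered).
    """
    lat = records["lat"].to_numpy(dtype=float)
    lon = records["lon"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("records with missing coordinates; apply filters first")
    x, y = project(lat, lon, spec)
    w = spec.cell_size
    col = np.floor((x - spec.origin[0]) / w).astype(int)
    row = np.floor((y - spec.origin[1]) / w).astype(int)
    out = records.copy()
    out["cell_row"] = row
    out["cell_col"] = col
    out["cell"] = [cell_label(r, c) for r, c in zip(row, col)]
    return out


def cell_table(records: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Per-cell centroid table: cell, row, col, centroid lat/lon, area (m^2),
    and the majority continent of the cell's records (used for stratified
    train/test splitting)."""
    rows = []
    for cell, grp in records.groupby("cell", sort=True):
        r, c = parse_cell_label(cell)
        lat, lon = cell_centroid(r, c, spec)
        continent = grp["continent"].mode().iloc[0] if "continent" in grp else ""
        rows.append(
            {
                "cell": cell,
                "cell_row": r,
                "cell_col": c,
                "centroid_lat": lat,
                "centroid_lon": lon,
                "area_m2": spec.cell_size**2,
                "continent": continent,
                "n_records": len(grp),
            }
        )
    return pd.DataFrame(rows)


def cell_coords(cells: list[str] | pd.Series, spec: GridSpec) -> np.ndarray:
    """(n, 2) array of projected centroid coordinates for cell labels."""
    out = np.empty((len(cells), 2))
    for i, label in enumerate(cells):
        r, c = parse_cell_label(label)
        x0, y0, x1, y1 = cell_bounds(r, c, spec)
        out[i] = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
    return out
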