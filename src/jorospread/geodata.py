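"""Occurrence and raster I/O, spatial thinning, background sampling, extraction.

Coordinates are WGS84 lon/lat degrees throughout. Rasters are regular
lon/lat grids stored row 0 = northernmost row, read and written as ESRI
ASCII grids (a plain-text format every GIS reads). Point-in-cell lookups
use the half-open convention [min, max) on both axes so a point on a
shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mean Earth radius, km (IUGG)
EARTH_RADIUS_KM = 6371.0088
#: km per degree of latitude (2*pi*R/360)
KM_PER_DEG = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0


@dataclass(frozen=True)
class Occurrence:
    """One georeferenced, dated record of a species."""

    record_id: str
    lon: float
    lat: float
    date: _date
    species: str = "Trichonephila clavata"
    source: str = "synthetic"  # inat | gbif | synthetic

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class Extent:
    """Rectangular lon/lat window; membership is half-open [min, max)."""

    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float

    def __post_init__(self) -> None:
        if not (self.min_lon < self.max_lon and self.min_lat < self.max_lat):
            raise ValueError("extent must satisfy min < max on both axes")

    def contains(self, lon: float, lat: float) -> bool:
        return (self.min_lon <= lon < self.max_lon) and (
            self.min_lat <= lat < self.max_lat
        )


# Study windows used throughout: the native (Asian) and introduced (North
# American) ranges at which predictor rasters are trimmed.
ASIA_EXTENT = Extent(52.083, -7.042, 146.833, 52.375)
NORTH_AMERICA_EXTENT = Extent(-125.042, 23.833, -64.417, 61.792)


@dataclass
class RasterLayer:
    """A gridded predictor on a regular lon/lat grid.

    ``values[0, 0]`` is the north-west cell. ``x_min``/``y_min`` are the
    outer corner of the south-west cell, ``cell`` the square cell size in
    degrees. Nodata is carried as NaN in memory and as ``nodata`` on disk.
    """

    name: str
    x_min: float
    y_min: float
    cell: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> Extent:
        return Extent(
            self.x_min,
            self.y_min,
            self.x_min + self.n_cols * self.cell,
            self.y_min + self.n_rows * self.cell,
        )

    def same_grid(self, other: "RasterLayer") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_min, other.x_min)
            and np.isclose(self.y_min, other.y_min)
            and np.isclose(self.cell, other.cell)
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if off-grid."""
        col = int(np.floor((lon - self.x_min) / self.cell))
        row_s = int(np.floor((lat - self.y_min) / self.cell))  # from south
        if 0 <= col < self.n_cols and 0 <= row_s < self.n_rows:
            return self.n_rows - 1 - row_s, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_min + (col + 0.5) * self.cell
        lat = self.y_min + (self.n_rows - row - 0.5) * self.cell
        return lon, lat

    def value_at(self, lon: float, lat: float) -> float:
        """Nearest-cell (containing-cell) value; NaN if off-grid or nodata."""
        idx = self.cell_index(lon, lat)
        if idx is None:
            return float("nan")
        return float(self.values[idx])


@dataclass
class PointSample:
    lon: float
    lat: float
    label: str  # presence | background
    predictor_values: dict[str, float] = field(default_factory=dict)


def read_ascii_grid(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid {path}: missing {key}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid body shape {values.shape} does not match header")
    values[values == nodata] = np.nan
    return RasterLayer(
        name=name or path.stem,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell=header["cellsize"],
        values=values,
        nodata=nodata,
    )


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    path = Path(path)
    vals = np.where(np.isnan(layer.values), layer.nodata, layer.values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {layer.n_cols}\nnrows {layer.n_rows}\n"
            f"xllcorner {layer.x_min!r}\nyllcorner {layer.y_min!r}\n"
            f"cellsize {layer.cell!r}\nNODATA_value {layer.nodata!r}\n"
        )
        np.savetxt(fh, vals, fmt="%.10g")


# Column maps for the export styles we ingest. Values are (lon, lat, date,
# species) column names; species may be None (single-species export).
_COLUMN_MAPS = {
    "inat": ("longitude", "latitude", "observed_on", "scientific_name"),
    "gbif": ("decimalLongitude", "decimalLatitude", "eventDate", "species"),
    "synthetic": ("lon", "lat", "date", "species"),
}


def read_occurrences(
    path: str | Path,
    source: str = "synthetic",
    column_map: tuple[str, str, str, str | None] | None = None,
) -> list[Occurrence]:
    """Read a research-grade-style occurrence CSV.

    Rows whose coordinates or dates do not parse (or fall outside valid
    lon/lat bounds) are dropped and counted in the log. A missing required
    column is fatal.
    """
    cols = column_map or _COLUMN_MAPS[source]
    lon_c, lat_c, date_c, sp_c = cols
    df = pd.read_csv(path)
    for c in (lon_c, lat_c, date_c):
        if c not in df.columns:
            raise ValueError(f"occurrence file {path} is missing column '{c}'")
    id_col = next((c for c in ("record_id", "id") if c in df.columns), None)
    lons = pd.to_numeric(df[lon_c], errors="coerce")
    lats = pd.to_numeric(df[lat_c], errors="coerce")
    dates = pd.to_datetime(df[date_c], errors="coerce")
    ok = (
        lons.notna() & lats.notna() & dates.notna()
        & lons.between(-180, 180) & lats.between(-90, 90)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_occurrences: dropped %d unparseable rows from %s",
                    n_dropped, path)
    occs = []
    for i in df.index[ok]:
        occs.append(
            Occurrence(
                record_id=str(df.at[i, id_col]) if id_col else str(i),
                lon=float(lons[i]),
                lat=float(lats[i]),
                date=dates[i].date(),
                species=str(df.at[i, sp_c]) if sp_c and sp_c in df.columns
                else "Trichonephila clavata",
                source=source,
            )
        )
    return occs


def write_occurrences(occs: list[Occurrence], path: str | Path) -> None:
    pd.DataFrame(
        {
            "record_id": [o.record_id for o in occs],
            "lon": [o.lon for o in occs],
            "lat": [o.lat for o in occs],
            "date": [o.date.isoformat() for o in occs],
            "species": [o.species for o in occs],
            "source": [o.source for o in occs],
        }
    ).to_csv(path, index=False)


def clip_to_extent(occs: list[Occurrence], extent: Extent) -> list[Occurrence]:
    """Keep records inside the half-open window [min, max)."""
    return [o for o in occs if extent.contains(o.lon, o.lat)]


def dedupe_occurrences(occs: list[Occurrence]) -> list[Occurrence]:
    """Drop exact duplicates on (lon, lat, date, species), keeping the first."""
    seen: set[tuple] = set()
    out = []
    for o in occs:
        key = (o.lon, o.lat, o.date, o.species)
        if key not in seen:
            seen.add(key)
            out.append(o)
    return out


def thin_occurrences(
    occs: list[Occurrence], grid: RasterLayer, seed: int
) -> list[Occurrence]:
    """Spatially thin to at most one record per grid cell.

    Community-science records cluster where observers live; thinning to one
    record per ~4 km predictor cell removes that density signal. The record
    kept within a cell is chosen uniformly at random under ``seed``; output
    order is deterministic (sorted by cell row, col).
    """
    rng = np.random.default_rng(seed)
    by_cell: dict[tuple[int, int], list[Occurrence]] = {}
    n_off = 0
    for o in occs:
        idx = grid.cell_index(o.lon, o.lat)
        if idx is None:
            n_off += 1
            continue
        by_cell.setdefault(idx, []).append(o)
    if n_off:
        logger.warning("thin_occurrences: %d records fall off the grid", n_off)
    return [
        cell_occs[rng.integers(len(cell_occs))]
        for _, cell_occs in sorted(by_cell.items())
    ]


def sample_background(
    template: RasterLayer, n: int, extent: Extent | None = None, seed: int = 0
) -> list[PointSample]:
    """Sample ``n`` background cells uniformly without replacement.

    Presence-background SDMs contrast presences against a random sample of
    the landscape; the study default is 50,000 points per region. Points are
    returned at cell centers of non-nodata cells whose centers fall in
    ``extent``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = np.nonzero(~np.isnan(template.values))
    if extent is not None:
        keep = []
        for i, (r, c) in enumerate(zip(rows, cols)):
            lon, lat = template.cell_center(r, c)
            if extent.contains(lon, lat):
                keep.append(i)
        rows, cols = rows[keep], cols[keep]
    if len(rows) < n:
        raise ValueError(
            f"only {len(rows)} valid cells available for {n} background points"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    out = []
    for i in pick:
        lon, lat = template.cell_center(int(rows[i]), int(cols[i]))
        out.append(PointSample(lon=lon, lat=lat, label="background"))
    return out


def extract_values(
    points: list[tuple[float, float]],
    layers: list[RasterLayer],
    label: str = "presence",
) -> list[PointSample]:
    """Attach the containing-cell value of every layer to each point.

    Points hitting nodata (or falling off-grid) in any layer are dropped and
    counted in the log; layers must share one grid geometry.
    """
    for lay in layers[1:]:
        if not lay.same_grid(layers[0]):
            raise ValueError(
                f"layer '{lay.name}' geometry does not match '{layers[0].name}'"
            )
    out = []
    n_dropped = 0
    for lon, lat in points:
        vals = {lay.name: lay.value_at(lon, lat) for lay in layers}
        if any(np.isnan(v) for v in vals.values()):
            n_dropped += 1
            continue
        out.append(PointSample(lon=lon, lat=lat, label=label, predictor_values=vals))
    if n_dropped:
        logger.info("extract_values: dropped %d points hitting nodata", n_dropped)
    return out


def samples_to_frame(samples: list[PointSample]) -> pd.DataFrame:
    """Tabulate PointSamples: lon, lat, label, one column per predictor."""
    rows = [
        {"lon": s.lon, "lat": s.lat, "label": s.label, **s.predictor_values}
        for s in samples
    ]
    return pd.DataFrame(rows)
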