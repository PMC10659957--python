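"""Directional range-expansion estimation from an invasion centroid.

Two complementary measures of spread, both anchored at the centroid of the
earliest documented introduction records:

* **Leading edge (distance method)** — classify every dated occurrence into
  the NE/SE/NW/SW quadrant around the centroid and, per year and quadrant,
  average the great-circle distances of the three farthest records.
* **Occupied area (KDE method)** — per year, fit an isotropic bivariate
  Gaussian KDE at the reference bandwidth h = 0.5*(sd_lon + sd_lat)*n^(-1/6)
  to the (spatially thinned) occurrences, take the highest-density region
  holding 99% of the probability mass (the 0.99 isopleth), and report its
  area in km^2 split by quadrant.

The KDE is evaluated in degree space because the reference-bandwidth
formula is stated in degrees; areas are converted to km^2 cell-by-cell with
a cos(latitude) equal-area correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodata import KM_PER_DEG, EARTH_RADIUS_KM, Occurrence

QUADRANTS = ("NE", "SE", "NW", "SW")


@dataclass(frozen=True)
class InvasionCentroid:
    lon: float
    lat: float


@dataclass(frozen=True)
class LeadingEdgeEstimate:
    year: int
    direction: str
    distance_km: float
    n_used: int


@dataclass
class KDEResult:
    grid_lon: np.ndarray  # (n_grid,) cell-center lons
    grid_lat: np.ndarray  # (n_grid,) cell-center lats
    density: np.ndarray   # (n_lat, n_lon), integrates to ~1 over the grid
    bandwidth: float      # degrees
    level: float
    threshold: float      # density cut defining the isopleth
    total_area_km2: float
    quadrant_areas_km2: dict[str, float] = field(default_factory=dict)

    def isopleth_mask(self) -> np.ndarray:
        return self.density >= self.threshold

    def isopleth_polygons(self):
        """Isopleth boundary as shapely polygons (lon/lat degrees)."""
        from shapely.geometry import Polygon
        from skimage import measure

        mask = self.isopleth_mask().astype(float)
        dlon = self.grid_lon[1] - self.grid_lon[0]
        dlat = self.grid_lat[1] - self.grid_lat[0]
        polys = []
        for contour in measure.find_contours(mask, 0.5):
            lons = self.grid_lon[0] + contour[:, 1] * dlon
            lats = self.grid_lat[0] + contour[:, 0] * dlat
            if len(lons) >= 4:
                poly = Polygon(np.column_stack([lons, lats]))
                if poly.is_valid and poly.area > 0:
                    polys.append(poly)
        return polys

    def to_geojson(self) -> dict:
        """Isopleth boundary as a GeoJSON FeatureCollection (lon/lat)."""
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": poly.__geo_interface__,
                    "properties": {"level": self.level,
                                   "bandwidth_deg": self.bandwidth},
                }
                for poly in self.isopleth_polygons()
            ],
        }


def compute_centroid(points: list[tuple[float, float]]) -> InvasionCentroid:
    """Arithmetic mean of the founding (lon, lat) coordinates."""
    lons = [p[0] for p in points]
    lats = [p[1] for p in points]
    return InvasionCentroid(lon=float(np.mean(lons)), lat=float(np.mean(lats)))


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points."""
    lon1, lat1 = np.radians(a)
    lon2, lat2 = np.radians(b)
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s)))


def classify_quadrant(lon: float, lat: float, c: InvasionCentroid) -> str:
    """N iff lat >= centroid lat, E iff lon >= centroid lon (ties go NE)."""
    ns = "N" if lat >= c.lat else "S"
    ew = "E" if lon >= c.lon else "W"
    return ns + ew


def leading_edge(
    occs: list[Occurrence],
    c: InvasionCentroid,
    year: int,
    direction: str,
    n_farthest: int = 3,
) -> LeadingEdgeEstimate | None:
    """Mean distance of the up-to-``n_farthest`` farthest records.

    Only records dated in ``year`` and lying in ``direction`` are used.
    Returns None (a missing value, not zero) when no record qualifies —
    e.g. a single qualifying record yields that record's distance with
    n_used = 1.
    """
    dists = sorted(
        (
            haversine_km((o.lon, o.lat), (c.lon, c.lat))
            for o in occs
            if o.date.year == year and classify_quadrant(o.lon, o.lat, c) == direction
        ),
        reverse=True,
    )
    if not dists:
        return None
    top = dists[:n_farthest]
    return LeadingEdgeEstimate(
        year=year, direction=direction,
        distance_km=float(np.mean(top)), n_used=len(top),
    )


def leading_edge_series(
    occs: list[Occurrence],
    c: InvasionCentroid,
    years: range | list[int],
    n_farthest: int = 3,
) -> list[LeadingEdgeEstimate]:
    out = []
    for year in years:
        for d in QUADRANTS:
            est = leading_edge(occs, c, year, d, n_farthest)
            if est is not None:
                out.append(est)
    return out


def expansion_rates(series: list[LeadingEdgeEstimate]) -> dict[str, float]:
    """Per-quadrant km/yr rate: OLS slope of edge distance on year."""
    rates = {}
    for d in QUADRANTS:
        pts = [(e.year, e.distance_km) for e in series if e.direction == d]
        if len(pts) >= 2:
            yrs, dist = zip(*pts)
            rates[d] = float(np.polyfit(yrs, dist, 1)[0])
    return rates


def reference_bandwidth(lons: np.ndarray, lats: np.ndarray) -> float:
    """Plug-in bandwidth h = 0.5*(sd_lon + sd_lat)*n^(-1/6), sample sd (n-1)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    if n < 2:
        raise ValueError("need at least 2 points for the reference bandwidth")
    return float(0.5 * (lons.std(ddof=1) + lats.std(ddof=1)) * n ** (-1.0 / 6.0))


def kde_quadrant_areas(
    lons: np.ndarray,
    lats: np.ndarray,
    c: InvasionCentroid,
    level: float = 0.99,
    bandwidth: float | None = None,
    grid_n: int = 512,
    pad_bandwidths: float = 4.0,
) -> KDEResult:
    """Area of the KDE isopleth at ``level``, split by quadrant.

    The isopleth is the grid-based highest-density region: cell densities
    are sorted descending and the threshold is the density at which the
    accumulated mass first reaches ``level``. Areas are km^2 on a
    cos(latitude) equal-area approximation; the four quadrant areas
    partition the total exactly (each grid cell belongs to one quadrant by
    its center).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if not 0.0 < level < 1.0:
        raise ValueError("isopleth level must lie in (0, 1)")
    if lons.size < 5:
        raise ValueError("need at least 5 points for a yearly KDE")
    h = reference_bandwidth(lons, lats) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth is 0 (degenerate point set)")
    pad = pad_bandwidths * h
    gx = np.linspace(lons.min() - pad, lons.max() + pad, grid_n)
    gy = np.linspace(lats.min() - pad, lats.max() + pad, grid_n)
    dlon = gx[1] - gx[0]
    dlat = gy[1] - gy[0]
    # isotropic Gaussian KDE evaluated on the grid; separable kernel
    kx = np.exp(-0.5 * ((gx[None, :] - lons[:, None]) / h) ** 2)  # (n_pts, n_x)
    ky = np.exp(-0.5 * ((gy[None, :] - lats[:, None]) / h) ** 2)  # (n_pts, n_y)
    density = (ky.T @ kx) / (lons.size * 2 * np.pi * h**2)  # (n_y, n_x)
    mass = density * dlon * dlat
    total_mass = mass.sum()
    # highest-density region: threshold at the `level` mass quantile
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(np.sort(mass.ravel())[::-1])
    idx = int(np.searchsorted(cum, level * total_mass))
    threshold = float(flat[min(idx, flat.size - 1)])
    inside = density >= threshold
    # per-cell km^2 with cos(lat) shrinking of the lon dimension
    cell_km2 = (dlat * KM_PER_DEG) * (dlon * KM_PER_DEG * np.cos(np.radians(gy)))
    cell_km2 = np.broadcast_to(cell_km2[:, None], density.shape)
    east = gx[None, :] >= c.lon
    north = gy[:, None] >= c.lat
    quads = {
        "NE": north & east, "SE": ~north & east,
        "NW": north & ~east, "SW": ~north & ~east,
    }
    areas = {
        q: float(cell_km2[inside & m].sum()) for q, m in quads.items()
    }
    return KDEResult(
        grid_lon=gx, grid_lat=gy, density=density,
        bandwidth=h, level=level, threshold=threshold,
        total_area_km2=float(cell_km2[inside].sum()),
        quadrant_areas_km2=areas,
    )
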