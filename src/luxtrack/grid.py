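"""Spherical grids and great-circle geometry.

The state space is a quasi-regular set of nodes ~50 km apart built from
equal-area latitude bands: bands are spaced ``spacing`` km apart and within
each band nodes are spaced ``spacing / cos(lat)`` degrees of longitude, so
nearest-neighbour distances stay close to the nominal spacing everywhere off
the poles.  Two boolean masks ride along with the nodes: ``mask_any`` (node
usable at all -- a hard spatial mask) and ``mask_stationary`` (the sedentary
behavioural state is allowed there; migrants may still overfly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .solar import GeoPosition, wrap_lon

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "SpatialGrid",
    "make_grid",
    "make_grid_bbox",
    "gc_distance",
    "bearing",
    "destination",
    "apply_stationary_mask",
    "mask_from_raster",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # 111.195 km per degree of arc


def _split(p):
    if isinstance(p, GeoPosition):
        return np.asarray(p.lon, float), np.asarray(p.lat, float)
    lon, lat = p
    return np.asarray(lon, dtype=float), np.asarray(lat, dtype=float)


def gc_distance(a, b):
    """Great-circle distance in km (haversine on a 6371-km sphere)."""
    lon1, lat1 = _split(a)
    lon2, lat2 = _split(b)
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    out = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    return float(out) if np.ndim(out) == 0 else out


def bearing(a, b):
    """Initial great-circle bearing from a to b, degrees clockwise from north."""
    lon1, lat1 = _split(a)
    lon2, lat2 = _split(b)
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    out = np.degrees(np.arctan2(y, x)) % 360.0
    return float(out) if np.ndim(out) == 0 else out


def destination(lon, lat, bearing_deg, dist_km):
    """Point reached from (lon, lat) moving ``dist_km`` on bearing ``bearing_deg``."""
    lon1 = np.radians(np.asarray(lon, dtype=float))
    lat1 = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    return wrap_lon(np.degrees(lon2)), np.degrees(lat2)


def _unit_xyz(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack(
        (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
    )


@dataclass
class SpatialGrid:
    """Node set with spacing and masks; nearest-node queries via a KD-tree."""

    lon: np.ndarray
    lat: np.ndarray
    spacing_km: float
    mask_any: np.ndarray
    mask_stationary: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _tree_any: cKDTree | None = field(default=None, repr=False, compare=False)
    _any_index: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.lon = wrap_lon(np.asarray(self.lon, dtype=float))
        self.lat = np.asarray(self.lat, dtype=float)
        self.mask_any = np.asarray(self.mask_any, dtype=bool)
        self.mask_stationary = np.asarray(self.mask_stationary, dtype=bool) & self.mask_any

    @property
    def n_nodes(self):
        return self.lon.size

    def nearest_node(self, lon, lat):
        """Index of the nearest node (any node, masked or not)."""
        if self._tree is None:
            self._tree = cKDTree(_unit_xyz(self.lon, self.lat))
        _, idx = self._tree.query(_unit_xyz(lon, lat))
        return idx if np.ndim(lon) else int(idx[0])

    def nearest_usable(self, lon, lat):
        """Index of the nearest node with ``mask_any`` true."""
        if self._tree_any is None:
            self._any_index = np.flatnonzero(self.mask_any)
            self._tree_any = cKDTree(
                _unit_xyz(self.lon[self._any_index], self.lat[self._any_index])
            )
        _, idx = self._tree_any.query(_unit_xyz(lon, lat))
        out = self._any_index[idx]
        return out if np.ndim(lon) else int(out[0])

    def position(self, idx):
        return GeoPosition(float(self.lon[idx]), float(self.lat[idx]))


def _band_nodes(center_lon, center_lat, lat_lo, lat_hi, spacing_km):
    dlat = spacing_km / KM_PER_DEG
    n_south = int(np.floor((center_lat - lat_lo) / dlat))
    n_north = int(np.floor((lat_hi - center_lat) / dlat))
    lats = center_lat + dlat * np.arange(-n_south, n_north + 1)
    lons_all, lats_all = [], []
    for la in lats:
        dlon = spacing_km / (KM_PER_DEG * np.cos(np.radians(la)))
        n_half = int(np.floor(180.0 / dlon))
        lo = center_lon + dlon * np.arange(-n_half, n_half + 1)
        lons_all.append(lo)
        lats_all.append(np.full(lo.size, la))
    return np.concatenate(lons_all), np.concatenate(lats_all)


def _check_spacing(spacing_km):
    if not 10.0 <= spacing_km <= 500.0:
        raise ValueError(f"spacing {spacing_km} km outside supported range [10, 500]")


def make_grid(center, radius_km, spacing_km=50.0):
    """Quasi-regular grid of nodes within ``radius_km`` of ``center``.

    All masks start true.  Regions reaching a pole are unsupported.
    """
    _check_spacing(spacing_km)
    lon0, lat0 = _split(center)
    reach = radius_km / KM_PER_DEG
    if abs(lat0) + reach > 89.0:
        raise ValueError("grid region touches a pole; unsupported")
    lons, lats = _band_nodes(
        float(lon0), float(lat0), lat0 - reach, lat0 + reach, spacing_km
    )
    d = gc_distance((lons, lats), (float(lon0), float(lat0)))
    keep = d <= radius_km
    if not np.any(keep):
        keep = d <= d.min() + 1e-9  # degenerate tiny radius: keep nearest node
    lons, lats = lons[keep], lats[keep]
    ones = np.ones(lons.size, dtype=bool)
    return SpatialGrid(lons, lats, spacing_km, ones, ones.copy())


def make_grid_bbox(lon_min, lon_max, lat_min, lat_max, spacing_km=50.0):
    """Grid covering a lon/lat bounding box (lon_min may exceed lon_max to
    wrap the antimeridian is *not* supported; supply lon_min < lon_max)."""
    _check_spacing(spacing_km)
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError("bounding box must have lon_min < lon_max, lat_min < lat_max")
    if max(abs(lat_min), abs(lat_max)) > 89.0:
        raise ValueError("grid region touches a pole; unsupported")
    c_lon, c_lat = 0.5 * (lon_min + lon_max), 0.5 * (lat_min + lat_max)
    lons, lats = _band_nodes(c_lon, c_lat, lat_min, lat_max, spacing_km)
    keep = (lons >= lon_min) & (lons <= lon_max)
    lons, lats = lons[keep], lats[keep]
    ones = np.ones(lons.size, dtype=bool)
    return SpatialGrid(lons, lats, spacing_km, ones, ones.copy())


def apply_stationary_mask(grid, predicate):
    """Restrict the sedentary state to nodes where ``predicate`` holds.

    ``predicate`` maps a :class:`GeoPosition` to bool (applied per node).
    ``mask_any`` is unchanged: masked habitat may be overflown, not settled.
    """
    ok = np.fromiter(
        (bool(predicate(GeoPosition(lo, la))) for lo, la in zip(grid.lon, grid.lat)),
        dtype=bool,
        count=grid.n_nodes,
    )
    new_stat = ok & grid.mask_any
    if not np.any(new_stat):
        raise ValueError("stationary mask leaves no valid settling node")
    return SpatialGrid(
        grid.lon.copy(), grid.lat.copy(), grid.spacing_km, grid.mask_any.copy(), new_stat
    )


def mask_from_raster(path):
    """Load a lon/lat boolean raster as a predicate for the stationary mask.

    Accepts ESRI ASCII grid (``ncols``/``nrows``/``xllcorner``/``yllcorner``/
    ``cellsize``/``nodata_value`` header) with nonzero cells meaning
    "settling allowed"; cells outside the raster are allowed.
    """
    with open(path) as fh:
        header = {}
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValueError("raster body does not match ncols/nrows header")
    x0, y0, cell = header["xllcorner"], header["yllcorner"], header["cellsize"]
    nodata = header.get("nodata_value")

    def predicate(pos):
        col = int(np.floor((pos.lon - x0) / cell))
        row = int(np.floor((pos.lat - y0) / cell))
        if not (0 <= col < ncols and 0 <= row < nrows):
            return True
        v = data[nrows - 1 - row, col]  # ESRI rows run north to south
        if nodata is not None and v == nodata:
            return True
        return bool(v)

    return predicate
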