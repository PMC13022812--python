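"""Background (pseudo-absence) sampling in a buffered convex hull.

Background points characterize the environments available to the species; they
are drawn uniformly inside the convex hull of the presences dilated by a buffer
(default 100 km).  Geometry uses a local equirectangular approximation: 1 deg
latitude = 111.32 km and 1 deg longitude = 111.32 * cos(latitude at the hull
centroid) km, adequate (error at the percent level) at study latitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import transform as shp_transform

KM_PER_DEG_LAT = 111.32


class GeometryError(ValueError):
    pass


@dataclass
class BackgroundSet:
    points: np.ndarray  # (n, 2) columns lat, lon
    region: Polygon     # buffered hull, in (lon, lat) degree coordinates
    n: int
    seed: int


def km_projection(lat0: float):
    """Forward/inverse maps between (lon, lat) degrees and a km plane.

    Local equirectangular approximation anchored at latitude ``lat0``:
    1 deg latitude = 111.32 km, 1 deg longitude = 111.32 * cos(lat0) km.
    Error grows with the latitudinal extent of the geometry (a few percent
    over tens of degrees); adequate for buffer construction at study scales.
    """
    fx = KM_PER_DEG_LAT * float(np.cos(np.deg2rad(lat0)))
    fy = KM_PER_DEG_LAT

    def fwd(lon, lat):
        return np.asarray(lon, float) * fx, np.asarray(lat, float) * fy

    def inv(x, y):
        return np.asarray(x, float) / fx, np.asarray(y, float) / fy

    return fwd, inv


def presence_hull_buffer(presence_points: np.ndarray, buffer_km: float = 100.0) -> Polygon:
    """Convex hull of presence (lat, lon) points dilated by ``buffer_km``.

    The hull is buffered in the km plane of :func:`km_projection` anchored at
    the hull centroid and mapped back to degrees, so the buffer width is
    metric on both axes.
    """
    pts = np.asarray(presence_points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need at least 3 presence points for a convex hull")
    hull = MultiPoint([(lon, lat) for lat, lon in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise GeometryError("presence points are collinear; convex hull is degenerate")
    fwd, inv = km_projection(hull.centroid.y)
    hull_km = shp_transform(fwd, hull)
    buffered_km = hull_km.buffer(buffer_km, quad_segs=32)
    return shp_transform(inv, buffered_km)


def sample_background(
    region: Polygon,
    n: int = 10_000,
    seed: int = 0,
    valid_fn=None,
    max_proposals: int = 10_000_000,
) -> BackgroundSet:
    """Draw ``n`` points uniformly inside ``region`` by rejection sampling.

    Proposals come from the region's bounding box; points outside the polygon
    (or rejected by ``valid_fn``, e.g. falling on masked climate cells) are
    resampled until exactly ``n`` valid points exist.  Deterministic per seed.
    """
    if region.is_empty or region.area <= 0:
        raise GeometryError("region has no area")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    accepted_lat: list[np.ndarray] = []
    accepted_lon: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    while n_acc < n:
        batch = max(4 * (n - n_acc), 1024)
        if n_prop + batch > max_proposals:
            batch = max_proposals - n_prop
            if batch <= 0:
                raise GeometryError(
                    f"acceptance rate too low after {n_prop} proposals; degenerate region"
                )
        lon = rng.uniform(minx, maxx, batch)
        lat = rng.uniform(miny, maxy, batch)
        n_prop += batch
        keep = shapely.contains_xy(region, lon, lat)
        if valid_fn is not None and keep.any():
            keep[keep] &= np.asarray(valid_fn(lat[keep], lon[keep]), dtype=bool)
        accepted_lat.append(lat[keep])
        accepted_lon.append(lon[keep])
        n_acc += int(keep.sum())
        if n_prop >= 1e7 and n_acc < max(1, n_prop * 1e-4):
            raise GeometryError("acceptance rate < 1e-4; degenerate region")
    lat = np.concatenate(accepted_lat)[:n]
    lon = np.concatenate(accepted_lon)[:n]
    return BackgroundSet(points=np.column_stack([lat, lon]), region=region, n=n, seed=seed)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(a))
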