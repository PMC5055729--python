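"""Geographic cluster areas from tweet coordinates.

Dense population centres are found with DBSCAN over great-circle distances,
each cluster is wrapped in a convex hull, and later tweets are assigned to
the hull containing them (or to a reserved noise cluster).  The hull model
is what makes assignment cheap for the full stream: clustering runs once on
a sample, containment tests run per tweet.

The DBSCAN here is deliberately scan-order deterministic: points are
processed in input order and a border point joins the first core cluster
that reaches it.  Border assignment in DBSCAN is inherently order dependent,
so the order is pinned to make runs reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
NOISE = -1


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (array-friendly)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def dbscan(
    points: Sequence[tuple[float, float]], eps_km: float, min_points: int
) -> np.ndarray:
    """Density-based clustering over (lat, lon) points; returns per-point labels.

    Core points have at least ``min_points`` neighbours (themselves included)
    within ``eps_km`` great-circle distance; clusters are maximal
    density-connected sets; unreachable points get the ``NOISE`` label (-1).
    """
    if eps_km <= 0:
        raise ValueError("eps_km must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)

    from sklearn.neighbors import BallTree

    tree = BallTree(np.radians(pts), metric="haversine")
    neighbourhoods = tree.query_radius(np.radians(pts), r=eps_km / EARTH_RADIUS_KM)
    is_core = np.array([len(nb) >= min_points for nb in neighbourhoods])

    UNVISITED = -2
    labels = np.full(n, UNVISITED, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != UNVISITED:
            continue
        if not is_core[i]:
            labels[i] = NOISE
            continue
        labels[i] = cluster
        queue = [int(j) for j in neighbourhoods[i] if j != i]
        head = 0
        while head < len(queue):
            j = queue[head]
            head += 1
            if labels[j] == NOISE:
                labels[j] = cluster  # border point adopted by first reaching cluster
            if labels[j] != UNVISITED:
                continue
            labels[j] = cluster
            if is_core[j]:
                queue.extend(int(k) for k in neighbourhoods[j] if labels[k] == UNVISITED or labels[k] == NOISE)
        cluster += 1
    return labels


@dataclass(frozen=True)
class ClusterArea:
    cluster_id: int
    label: str
    hull: tuple[tuple[float, float], ...]  # (lat, lon) vertices, counter-clockwise
    area_km2: float

    def polygon(self) -> Polygon:
        return Polygon([(lon, lat) for lat, lon in self.hull])


@dataclass
class ClusterModel:
    """Convex-hull polygons for each cluster plus a reserved noise sink."""

    clusters: list[ClusterArea] = field(default_factory=list)
    noise_id: int = NOISE

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("cluster ids must be unique")
        self._polygons = [c.polygon() for c in self.clusters]
        # smallest-area hull wins when hulls overlap
        self._order = sorted(
            range(len(self.clusters)), key=lambda i: self.clusters[i].area_km2
        )

    def label_of(self, cluster_id: int) -> str:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c.label
        return "noise"

    def assign(self, lat: float, lon: float) -> int:
        p = Point(lon, lat)
        for i in self._order:
            if self._polygons[i].covers(p):  # boundary counts as inside
                return self.clusters[i].cluster_id
        return self.noise_id

    def assign_many(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        pts = shapely.points(np.asarray(lons, dtype=float), np.asarray(lats, dtype=float))
        out = np.full(len(pts), self.noise_id, dtype=int)
        undecided = np.ones(len(pts), dtype=bool)
        for i in self._order:
            if not undecided.any():
                break
            inside = shapely.covers(self._polygons[i], pts) & undecided
            out[inside] = self.clusters[i].cluster_id
            undecided &= ~inside
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "noise_id": self.noise_id,
                    "clusters": [
                        {
                            "cluster_id": c.cluster_id,
                            "label": c.label,
                            "hull": [list(v) for v in c.hull],
                            "area_km2": c.area_km2,
                        }
                        for c in self.clusters
                    ],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            clusters=[
                ClusterArea(
                    cluster_id=c["cluster_id"],
                    label=c["label"],
                    hull=tuple((float(a), float(b)) for a, b in c["hull"]),
                    area_km2=float(c["area_km2"]),
                )
                for c in obj["clusters"]
            ],
            noise_id=obj.get("noise_id", NOISE),
        )


def _polygon_area_km2(poly: Polygon) -> float:
    """Planar area in a local equirectangular km projection about the centroid."""
    lon0, lat0 = poly.centroid.x, poly.centroid.y
    coslat = np.cos(np.radians(lat0))
    xs, ys = zip(*poly.exterior.coords)
    x = (np.asarray(xs) - lon0) * np.pi / 180 * EARTH_RADIUS_KM * coslat
    y = (np.asarray(ys) - lat0) * np.pi / 180 * EARTH_RADIUS_KM
    return float(Polygon(zip(x, y)).area)


def build_cluster_model(
    points: Sequence[tuple[float, float]],
    labels: Sequence[int],
    names: dict[int, str] | None = None,
) -> ClusterModel:
    """Convex hull per non-noise cluster; degenerate clusters are dropped.

    A cluster whose points are fewer than 3 distinct locations, or all
    collinear, cannot form a polygon and is dropped with a warning.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    names = names or {}
    areas: list[ClusterArea] = []
    for cid in sorted(set(labels[labels != NOISE])):
        cluster_pts = pts[labels == cid]
        hull = MultiPoint([(lon, lat) for lat, lon in cluster_pts]).convex_hull
        if not isinstance(hull, Polygon):
            logger.warning(
                "cluster %d dropped: %d points form no polygon", cid, len(cluster_pts)
            )
            continue
        hull = orient(hull, sign=1.0)  # counter-clockwise exterior
        vertices = tuple(
            (lat, lon) for lon, lat in list(hull.exterior.coords)[:-1]
        )
        areas.append(
            ClusterArea(
                cluster_id=int(cid),
                label=names.get(int(cid), f"area-{cid}"),
                hull=vertices,
                area_km2=_polygon_area_km2(hull),
            )
        )
    return ClusterModel(clusters=areas)


def assign_cluster(
    point: tuple[float, float], model: ClusterModel
) -> int:
    """Id of the (smallest-area) hull containing the point, else the noise id."""
    return model.assign(point[0], point[1])
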