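"""Hexagonal tessellation, geodetic distance, and detection aggregation.

The analysis unit is a 1-km² flat-top hexagon. The lattice is laid out in a
local Lambert azimuthal equal-area (LAEA) projection centred on the study
bounding box, so every cell has the configured area on the (spherical) globe;
centroids and polygons are re-expressed in WGS84 longitude/latitude for
storage and for geodetic distance computations.

Point detections (lon, lat, year, detected) are aggregated to a binary
hexagon-year response: presence = 1 if any record in that hexagon-year is a
detection, 0 if the hexagon-year was surveyed without detections; never-
surveyed hexagon-years carry no row at all.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres (IUGG mean radius R1).
EARTH_RADIUS_M = 6_371_008.8

#: Landcover classes coded 1; everything else in the vocabulary codes 0.
LANDCOVER_POSITIVE_CLASSES = frozenset(
    {
        "Urban and built-up",
        "mixed needle-leaved cold deciduous forest, medium density",
    }
)

#: Default landcover vocabulary (positive classes plus common other classes).
DEFAULT_LANDCOVER_VOCABULARY = LANDCOVER_POSITIVE_CLASSES | {
    "Water",
    "Cropland",
    "Grassland",
    "Wetland",
    "Barren",
    "Broad-leaved deciduous forest",
    "Needle-leaved evergreen forest",
    "Mixed forest",
    "Shrubland",
}


class UnsupportedRegionError(ValueError):
    """Raised for bounding boxes this grid builder cannot handle."""


class OutOfNeighborhoodError(ValueError):
    """Raised when a distance beyond the configured cutoff is standardized."""


def geodetic_distance(p, q):
    """Great-circle distance in metres between WGS84 points.

    Parameters are ``(lon, lat)`` pairs in decimal degrees; either argument
    may hold arrays for vectorised use.  Uses the haversine formula on a
    sphere of radius :data:`EARTH_RADIUS_M`; the central angle is clamped
    into [0, pi] to absorb floating-point overshoot.
    """
    lon1, lat1 = np.radians(np.asarray(p[0], dtype=float)), np.radians(
        np.asarray(p[1], dtype=float)
    )
    lon2, lat2 = np.radians(np.asarray(q[0], dtype=float)), np.radians(
        np.asarray(q[1], dtype=float)
    )
    sin_dlat = np.sin((lat2 - lat1) / 2.0)
    sin_dlon = np.sin((lon2 - lon1) / 2.0)
    h = sin_dlat**2 + np.cos(lat1) * np.cos(lat2) * sin_dlon**2
    h = np.clip(h, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(h))


class LocalEqualArea:
    """Spherical Lambert azimuthal equal-area projection about a centre point.

    Areas are preserved exactly on the sphere, which is the property the
    1-km² tessellation relies on; shape distortion is negligible at the
    study-area scales used here.
    """

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_M):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius = float(radius)

    def forward(self, lon, lat):
        """(lon, lat) degrees -> planar (x, y) metres."""
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) metres -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_phi = np.cos(c) * np.sin(phi0) + np.where(
                rho > 0, y * np.sin(c) * np.cos(phi0) / np.where(rho > 0, rho, 1.0), 0.0
            )
            lam = np.arctan2(
                x * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            )
        lat = np.degrees(np.arcsin(np.clip(sin_phi, -1.0, 1.0)))
        lon = self.lon0 + np.degrees(np.where(rho > 0, lam, 0.0))
        lat = np.where(rho > 0, lat, self.lat0)
        return lon, lat


@dataclass
class HexGrid:
    """A flat-top hexagon lattice clipped to a study bounding box.

    ``hex_id`` is a dense 0..n-1 integer assigned row-major over the kept
    lattice cells.  Projected centroid coordinates (metres, equal-area plane)
    are kept alongside the WGS84 centroids because point-to-hexagon
    assignment and neighbour queries run in the plane.
    """

    hex_id: np.ndarray
    centroid_lon: np.ndarray
    centroid_lat: np.ndarray
    cell_area_km2: float
    circumradius_m: float
    proj: LocalEqualArea
    row: np.ndarray
    col: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bbox: tuple[float, float, float, float]
    _cell_index: dict = field(default_factory=dict, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(set(self.hex_id.tolist())) != len(self.hex_id):
            raise ValueError("hex_ids must be unique")
        self._cell_index = {
            (int(r), int(c)): int(h)
            for r, c, h in zip(self.row, self.col, self.hex_id)
        }

    def __len__(self) -> int:
        return len(self.hex_id)

    # -- geometry -----------------------------------------------------------

    @property
    def spacing(self) -> tuple[float, float]:
        """(dx, dy) lattice spacing in metres: column pitch and row pitch."""
        r = self.circumradius_m
        return 1.5 * r, np.sqrt(3.0) * r

    def polygon_xy(self, idx: int) -> Polygon:
        """Hexagon polygon in projected metres for positional index ``idx``."""
        r = self.circumradius_m
        ang = np.arange(6) * np.pi / 3.0
        vx = self.x[idx] + r * np.cos(ang)
        vy = self.y[idx] + r * np.sin(ang)
        return Polygon(zip(vx, vy))

    def polygons_xy(self) -> np.ndarray:
        """All hexagon polygons (projected plane) as a shapely array."""
        r = self.circumradius_m
        ang = np.arange(6) * np.pi / 3.0
        vx = self.x[:, None] + r * np.cos(ang)[None, :]
        vy = self.y[:, None] + r * np.sin(ang)[None, :]
        return shapely.polygons(np.stack([vx, vy], axis=-1))

    def polygons_lonlat(self) -> np.ndarray:
        """All hexagon polygons re-expressed in WGS84 lon/lat."""
        r = self.circumradius_m
        ang = np.arange(6) * np.pi / 3.0
        vx = self.x[:, None] + r * np.cos(ang)[None, :]
        vy = self.y[:, None] + r * np.sin(ang)[None, :]
        lon, lat = self.proj.inverse(vx, vy)
        return shapely.polygons(np.stack([lon, lat], axis=-1))

    def areas_km2(self) -> np.ndarray:
        return shapely.area(self.polygons_xy()) / 1e6

    def neighbor_pairs(self) -> np.ndarray:
        """(m, 2) array of positional index pairs sharing an edge."""
        if self._tree is None:
            self._tree = cKDTree(np.column_stack([self.x, self.y]))
        _, dy = self.spacing
        pairs = self._tree.query_pairs(dy * 1.001, output_type="ndarray")
        return pairs

    def neighbors(self) -> dict[int, list[int]]:
        """hex_id -> sorted list of adjacent hex_ids."""
        out: dict[int, list[int]] = {int(h): [] for h in self.hex_id}
        for i, j in self.neighbor_pairs():
            out[int(self.hex_id[i])].append(int(self.hex_id[j]))
            out[int(self.hex_id[j])].append(int(self.hex_id[i]))
        return {h: sorted(v) for h, v in out.items()}

    # -- point assignment ---------------------------------------------------

    def assign_points(self, lon, lat) -> np.ndarray:
        """Map WGS84 points to hex_ids; -1 for points outside the grid.

        Assignment is by nearest lattice centroid in the equal-area plane
        (the hexagons are the Voronoi cells of their centroids, so this is
        exact point-in-polygon). Ties at shared edges resolve to the lowest
        hex_id. A point whose nearest *lattice* cell was clipped away is
        outside the grid.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        px, py = self.proj.forward(lon, lat)
        dx, dy = self.spacing
        col0 = np.rint(px / dx).astype(int)
        n = len(px)
        best_d = np.full(n, np.inf)
        cand_d = np.empty((n, 9))
        cand_rc = np.empty((n, 9, 2), dtype=int)
        k = 0
        for dc in (-1, 0, 1):
            cols = col0 + dc
            shift = (np.mod(cols, 2)) * dy / 2.0
            row0 = np.rint((py - shift) / dy).astype(int)
            for dr in (-1, 0, 1):
                rows = row0 + dr
                cx = cols * dx
                cy = rows * dy + shift
                cand_d[:, k] = np.hypot(px - cx, py - cy)
                cand_rc[:, k, 0] = rows
                cand_rc[:, k, 1] = cols
                k += 1
        best_d = cand_d.min(axis=1)
        eps = self.circumradius_m * 1e-9
        out = np.full(n, -1, dtype=int)
        for i in range(n):
            tied = np.nonzero(cand_d[i] <= best_d[i] + eps)[0]
            ids = [
                self._cell_index.get((int(cand_rc[i, t, 0]), int(cand_rc[i, t, 1])))
                for t in tied
            ]
            ids = [h for h in ids if h is not None]
            if ids:
                out[i] = min(ids)
        return out

    # -- serialisation ------------------------------------------------------

    def to_geojson(self, path) -> None:
        """Write the grid as a GeoJSON FeatureCollection (WGS84 polygons).

        Lattice metadata (projection centre, cell area, row/col) is stored as
        foreign members / feature properties so the grid round-trips.
        """
        polys = self.polygons_lonlat()
        feats = []
        for i in range(len(self)):
            coords = shapely.get_coordinates(polys[i]).tolist()
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "hex_id": int(self.hex_id[i]),
                        "row": int(self.row[i]),
                        "col": int(self.col[i]),
                        "centroid_lon": float(self.centroid_lon[i]),
                        "centroid_lat": float(self.centroid_lat[i]),
                    },
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                }
            )
        doc = {
            "type": "FeatureCollection",
            "grid": {
                "cell_area_km2": self.cell_area_km2,
                "circumradius_m": self.circumradius_m,
                "proj_lon0": self.proj.lon0,
                "proj_lat0": self.proj.lat0,
                "bbox": list(self.bbox),
            },
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path) -> "HexGrid":
        with open(path) as fh:
            doc = json.load(fh)
        meta = doc["grid"]
        proj = LocalEqualArea(meta["proj_lon0"], meta["proj_lat0"])
        props = [f["properties"] for f in doc["features"]]
        hex_id = np.array([p["hex_id"] for p in props], dtype=int)
        row = np.array([p["row"] for p in props], dtype=int)
        col = np.array([p["col"] for p in props], dtype=int)
        lon = np.array([p["centroid_lon"] for p in props], dtype=float)
        lat = np.array([p["centroid_lat"] for p in props], dtype=float)
        r = meta["circumradius_m"]
        dx, dy = 1.5 * r, np.sqrt(3.0) * r
        x = col * dx
        y = row * dy + (np.mod(col, 2)) * dy / 2.0
        return cls(
            hex_id=hex_id,
            centroid_lon=lon,
            centroid_lat=lat,
            cell_area_km2=meta["cell_area_km2"],
            circumradius_m=r,
            proj=proj,
            row=row,
            col=col,
            x=x,
            y=y,
            bbox=tuple(meta["bbox"]),
        )


def build_hex_grid(
    bbox: tuple[float, float, float, float], cell_area_km2: float = 1.0
) -> HexGrid:
    """Tessellate a lon/lat bounding box with flat-top hexagons.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max) in decimal degrees.
    Every point of the bbox is covered by exactly one hexagon (ties on shared
    edges break to the lower hex_id); hexagons are kept whenever their
    polygon intersects the projected bbox region, so coverage extends
    slightly beyond the box edges.
    """
    lon_min, lat_min, lon_max, lat_max = map(float, bbox)
    if lon_min > lon_max:
        raise UnsupportedRegionError(
            "bbox crosses the antimeridian (lon_min > lon_max); split the region first"
        )
    if lon_min == lon_max or lat_min >= lat_max:
        raise ValueError("bbox must be non-degenerate (lon_min < lon_max, lat_min < lat_max)")
    if lon_min < -180 or lon_max > 180 or lat_min < -90 or lat_max > 90:
        raise UnsupportedRegionError("bbox leaves valid WGS84 bounds")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")

    proj = LocalEqualArea((lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0)

    # densely sampled bbox boundary -> projected study region polygon
    t = np.linspace(0.0, 1.0, 64)
    blon = np.concatenate(
        [
            lon_min + t * (lon_max - lon_min),
            np.full_like(t, lon_max),
            lon_max - t * (lon_max - lon_min),
            np.full_like(t, lon_min),
        ]
    )
    blat = np.concatenate(
        [
            np.full_like(t, lat_min),
            lat_min + t * (lat_max - lat_min),
            np.full_like(t, lat_max),
            lat_max - t * (lat_max - lat_min),
        ]
    )
    bx, by = proj.forward(blon, blat)
    region = Polygon(zip(bx, by)).buffer(0)

    area_m2 = cell_area_km2 * 1e6
    r = np.sqrt(2.0 * area_m2 / (3.0 * np.sqrt(3.0)))  # circumradius
    dx, dy = 1.5 * r, np.sqrt(3.0) * r

    xmin, ymin, xmax, ymax = region.bounds
    c_lo = int(np.floor((xmin - r) / dx)) - 1
    c_hi = int(np.ceil((xmax + r) / dx)) + 1
    r_lo = int(np.floor((ymin - dy) / dy)) - 1
    r_hi = int(np.ceil((ymax + dy) / dy)) + 1
    cols, rows = np.meshgrid(np.arange(c_lo, c_hi + 1), np.arange(r_lo, r_hi + 1))
    cols = cols.ravel()
    rows = rows.ravel()
    cx = cols * dx
    cy = rows * dy + (np.mod(cols, 2)) * dy / 2.0

    ang = np.arange(6) * np.pi / 3.0
    vx = cx[:, None] + r * np.cos(ang)[None, :]
    vy = cy[:, None] + r * np.sin(ang)[None, :]
    polys = shapely.polygons(np.stack([vx, vy], axis=-1))
    keep = shapely.intersects(polys, region)

    rows, cols, cx, cy = rows[keep], cols[keep], cx[keep], cy[keep]
    order = np.lexsort((cols, rows))  # row-major id assignment
    rows, cols, cx, cy = rows[order], cols[order], cx[order], cy[order]
    lon, lat = proj.inverse(cx, cy)
    return HexGrid(
        hex_id=np.arange(len(rows)),
        centroid_lon=np.asarray(lon),
        centroid_lat=np.asarray(lat),
        cell_area_km2=cell_area_km2,
        circumradius_m=r,
        proj=proj,
        row=rows,
        col=cols,
        x=cx,
        y=cy,
        bbox=(lon_min, lat_min, lon_max, lat_max),
    )


def aggregate_detections(
    points: pd.DataFrame,
    grid: HexGrid,
    year_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Collapse point detection records to the binary hexagon-year response.

    ``points`` needs columns lon, lat, year, detected (0/1). presence = 1 if
    any record in a hexagon-year is a detection, 0 if all its records are
    non-detections; hexagon-years with no records get no row. Points falling
    outside the grid are dropped with a logged count.
    """
    required = {"lon", "lat", "year", "detected"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    if len(points) == 0:
        return pd.DataFrame(columns=["hex_id", "year", "presence"]).astype(
            {"hex_id": int, "year": int, "presence": int}
        )
    det = points["detected"].to_numpy()
    if not np.isin(det, (0, 1)).all():
        raise ValueError("detected flags must be 0 or 1")
    years = points["year"].to_numpy().astype(int)
    if year_window is not None:
        lo, hi = year_window
        if ((years < lo) | (years > hi)).any():
            raise ValueError(f"detection years outside study window [{lo}, {hi}]")
    hx = grid.assign_points(points["lon"].to_numpy(), points["lat"].to_numpy())
    outside = hx < 0
    if outside.any():
        logger.warning("rejected %d detection points outside the grid", int(outside.sum()))
    tab = (
        pd.DataFrame({"hex_id": hx[~outside], "year": years[~outside], "presence": det[~outside]})
        .groupby(["hex_id", "year"], as_index=False)["presence"]
        .max()
    )
    return tab.astype({"hex_id": int, "year": int, "presence": int})


def encode_landcover(majority_class: str, vocabulary=None) -> int:
    """Dichotomise a majority landcover class label.

    1 for urban/built-up and medium-density mixed needle-leaved cold
    deciduous forest; 0 for any other class in the vocabulary. Labels outside
    the vocabulary raise.
    """
    vocab = DEFAULT_LANDCOVER_VOCABULARY if vocabulary is None else set(vocabulary)
    if majority_class not in vocab:
        raise ValueError(f"unknown landcover class label: {majority_class!r}")
    return 1 if majority_class in LANDCOVER_POSITIVE_CLASSES else 0


def read_detections_csv(path) -> pd.DataFrame:
    """Read lon,lat,year,detected[,source] CSV of point detection records."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def write_occurrence_csv(occ: pd.DataFrame, path) -> None:
    occ[["hex_id", "year", "presence"]].to_csv(path, index=False)


def read_occurrence_csv(path) -> pd.DataFrame:
    return pd.read_csv(path).astype({"hex_id": int, "year": int, "presence": int})
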