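"""The 24-metric slice classification schema.

One row per slice: position (raw and survey-flattened coordinates), shape of
the 0.8 m prism (vertices, triangles, height, surface area and the derived
Base = surface area / height), object-aligned bounding-box lengths and their
ratio, mass- vs geometric-centre depths and their ratio, backscatter
statistics (linear-domain sample mean reported in dB, and the max−mean
"Sv_UNCAL diff"), per-object vertical velocity ("Relative depth in time",
positive = rising), beam-intersection diagnostics, and a 4-group k-means
cluster code built from Vertices and the mass-centre coordinates.

Column names follow the documented schema verbatim (see ``TABLE2_COLUMNS``).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .extract import EXTRUSION_THICKNESS, MultiPingObject, SliceRegion, extrude_slice

__all__ = [
    "TABLE2_COLUMNS",
    "COORDINATE_COLUMNS",
    "METRIC_UNITS",
    "geometric_center",
    "mass_center",
    "shape_metrics",
    "depth_ratio",
    "sv_metrics",
    "relative_depth_in_time",
    "beam_metrics",
    "flatten_coords",
    "unflatten_coords",
    "cluster_feature",
    "build_feature_table",
]

#: metres per degree of great-circle arc (WGS84 equatorial circumference/360)
METERS_PER_DEGREE = 111319.4907932736

TABLE2_COLUMNS = [
    "x",
    "y",
    "Geometric center latitude",
    "Geometric center longitude",
    "Mass center latitude",
    "Mass center longitude",
    "Geometric center depth",
    "Mass center depth",
    "Depth ratio",
    "Vertices",
    "Triangles",
    "Height",
    "Surface area",
    "Base",
    "Cluster",
    "Length 1",
    "Length 2",
    "Length ratio",
    "Relative depth in time",
    "Sv_UNCAL diff",
    "Sample mean",
    "Beams",
    "Intersection area first beam",
    "Intersection area last beam",
]

#: the six raw-location columns exempt from normalization and dropped
#: before ensemble training
COORDINATE_COLUMNS = TABLE2_COLUMNS[:6]

METRIC_UNITS = {
    "x": "n.a.",
    "y": "n.a.",
    "Geometric center latitude": "decimal degrees",
    "Geometric center longitude": "decimal degrees",
    "Mass center latitude": "decimal degrees",
    "Mass center longitude": "decimal degrees",
    "Geometric center depth": "m",
    "Mass center depth": "m",
    "Depth ratio": "n.a.",
    "Vertices": "n.a.",
    "Triangles": "n.a.",
    "Height": "m",
    "Surface area": "sqm",
    "Base": "m",
    "Cluster": "n.a.",
    "Length 1": "m",
    "Length 2": "m",
    "Length ratio": "n.a.",
    "Relative depth in time": "m/s",
    "Sv_UNCAL diff": "dB",
    "Sample mean": "dB",
    "Beams": "n.a.",
    "Intersection area first beam": "sqm",
    "Intersection area last beam": "sqm",
}

ID_COLUMNS = ["slice_id", "ping_id", "object_id", "label"]


def _world_to_latlon(x: float, y: float, origin: tuple[float, float]):
    lat0, lon0 = origin
    lat = lat0 + y / METERS_PER_DEGREE
    lon = lon0 + x / (METERS_PER_DEGREE * math.cos(math.radians(lat0)))
    return lat, lon


def _slice_world_xy(s: SliceRegion, across: float) -> tuple[float, float]:
    h = math.radians(s.nav[2])
    ax, ay = math.cos(h), -math.sin(h)
    return s.nav[0] + ax * across, s.nav[1] + ay * across


def geometric_center(
    s: SliceRegion, origin: tuple[float, float]
) -> tuple[float, float, float]:
    """Unweighted (lat, lon, depth) centroid of the extruded prism.

    The prism is symmetric along-track about the ping plane, so its volume
    centroid is the area centroid of the cross-section polygon.
    """
    c = s.polygon.centroid
    x, y = _slice_world_xy(s, c.x)
    lat, lon = _world_to_latlon(x, y, origin)
    return lat, lon, float(c.y)


def mass_center(
    s: SliceRegion, origin: tuple[float, float]
) -> tuple[float, float, float]:
    """Backscatter-weighted (lat, lon, depth) centroid of the member samples.

    Weights are linear power ``10^(Sv/10)``.
    """
    w = 10.0 ** (np.asarray(s.sv, dtype=float) / 10.0)
    w = w / w.sum()
    across = float(np.sum(w * s.across))
    depth = float(np.sum(w * s.depth))
    x, y = _slice_world_xy(s, across)
    lat, lon = _world_to_latlon(x, y, origin)
    return lat, lon, depth


def shape_metrics(s: SliceRegion) -> dict:
    """Prism shape: height, surface area, counts, Base, bounding-box lengths.

    Height is the vertical extent of the cross-section; surface area is the
    total triangle area of the extruded polyhedron; Base = surface area /
    height.  The object-aligned bounding box has dimensions (across-track
    extent, vertical extent, 0.8 m along-track); the two longest, sorted
    descending, are Length 1 and Length 2.
    """
    poly = extrude_slice(s)
    ys, ds = np.asarray(s.polygon.exterior.coords).T
    height = float(ds.max() - ds.min())
    width = float(ys.max() - ys.min())
    surface_area = poly.surface_area
    dims = sorted([width, height, poly.thickness], reverse=True)
    length1, length2 = dims[0], dims[1]
    return {
        "Vertices": poly.n_vertices,
        "Triangles": poly.n_faces,
        "Height": height,
        "Surface area": surface_area,
        "Base": surface_area / height if height > 0 else np.nan,
        "Length 1": length1,
        "Length 2": length2,
        "Length ratio": length2 / length1 if length1 > 0 else np.nan,
    }


def depth_ratio(geo_depth: float, mass_depth: float) -> float:
    """Geometric-centre depth over mass-centre depth.

    Below 1 when the mass centre sits deeper than the geometric centre, as
    for platform legs whose backscatter grows with range.
    """
    if geo_depth <= 0 or mass_depth <= 0:
        raise ValueError("depths must be positive")
    return geo_depth / mass_depth


def sv_metrics(s: SliceRegion) -> tuple[float, float]:
    """(sample mean dB, Sv diff dB) over the member samples.

    The mean is taken in the linear power domain and reported in dB;
    Sv diff = max(dB) − mean(dB) ≥ 0.
    """
    sv = np.asarray(s.sv, dtype=float)
    mean_db = 10.0 * math.log10(np.mean(10.0 ** (sv / 10.0)))
    return mean_db, float(sv.max() - mean_db)


def relative_depth_in_time(
    obj: MultiPingObject, slices_by_id: dict[int, SliceRegion]
) -> dict[int, float]:
    """Per-slice vertical velocity within a multi-ping object, m/s.

    For consecutive slices i, i+1: (depth_i − depth_{i+1}) / Δt, so a rising
    target (depth decreasing in time) is positive.  The last slice inherits
    the previous value; singleton objects get 0.
    """
    sl = [slices_by_id[i] for i in obj.slice_ids]
    if len(sl) < 2:
        return {obj.slice_ids[0]: 0.0} if sl else {}
    out: dict[int, float] = {}
    for a, b in zip(sl[:-1], sl[1:]):
        dt = b.time - a.time
        da = a.polygon.centroid.y
        db = b.polygon.centroid.y
        out[a.slice_id] = (da - db) / dt if dt > 0 else 0.0
    out[sl[-1].slice_id] = out[sl[-2].slice_id]
    return out


def beam_metrics(s: SliceRegion) -> tuple[int, float, float]:
    """(beam count, intersection area with first beam, with last beam).

    Beam count is the number of distinct beams holding member samples.  The
    first/last-beam areas are the polygon∩beam-sector areas for the two
    outermost beams of the combined swath — non-zero only when the slice is
    clipped at the swath edge (partial insonification).
    """
    beams = int(np.unique(s.beam_idx).size)
    geom = s.geometry
    angles = np.sort(geom.beam_angles.ravel())
    spacing = geom.beam_angles[0, 1] - geom.beam_angles[0, 0]
    rmax = float(geom.ranges[-1]) + geom.range_bin
    areas = []
    for theta in (angles[0], angles[-1]):
        lo, hi = math.radians(theta - spacing / 2), math.radians(theta + spacing / 2)
        sector = Polygon(
            [
                (0.0, 0.0),
                (rmax * math.sin(lo), rmax * math.cos(lo)),
                (rmax * math.sin(hi), rmax * math.cos(hi)),
            ]
        )
        areas.append(float(sector.intersection(s.polygon).area))
    return beams, areas[0], areas[1]


def flatten_coords(
    lats: np.ndarray, lons: np.ndarray, centroid: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection about the survey centroid, metres.

    The centroid maps to (0, 0); 1° of longitude at the equator maps to
    ~111,320 m east.
    """
    lat0, lon0 = centroid
    x = (np.asarray(lons) - lon0) * METERS_PER_DEGREE * math.cos(math.radians(lat0))
    y = (np.asarray(lats) - lat0) * METERS_PER_DEGREE
    return x, y


def unflatten_coords(
    x: np.ndarray, y: np.ndarray, centroid: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`flatten_coords`."""
    lat0, lon0 = centroid
    lat = lat0 + np.asarray(y) / METERS_PER_DEGREE
    lon = lon0 + np.asarray(x) / (METERS_PER_DEGREE * math.cos(math.radians(lat0)))
    return lat, lon


def cluster_feature(
    table: pd.DataFrame, k: int = 4, seed: int = 0
) -> np.ndarray:
    """k-means cluster codes from Vertices and the mass-centre coordinates.

    The three inputs are standardized to zero mean / unit variance before
    clustering; codes are stable under refit with the same seed.
    """
    X = table[["Vertices", "Mass center latitude", "Mass center longitude"]].to_numpy(
        dtype=float
    )
    X = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=min(k, len(table)), n_init=10, random_state=seed)
    return km.fit_predict(X)


def build_feature_table(
    slices: Sequence[SliceRegion],
    objects: Iterable[MultiPingObject],
    origin: tuple[float, float],
    seed: int = 0,
    labels: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    """Assemble the full 24-column feature table, one row per slice.

    ``origin`` is the (lat, lon) mapped to world (0, 0).  ``labels`` maps
    slice_id to an operator class label; unlabelled slices get "".
    """
    slices_by_id = {s.slice_id: s for s in slices}
    rdt: dict[int, float] = {}
    for obj in objects:
        rdt.update(relative_depth_in_time(obj, slices_by_id))

    rows = []
    for s in slices:
        glat, glon, gdep = geometric_center(s, origin)
        mlat, mlon, mdep = mass_center(s, origin)
        shape = shape_metrics(s)
        mean_db, diff_db = sv_metrics(s)
        beams, a_first, a_last = beam_metrics(s)
        row = {
            "slice_id": s.slice_id,
            "ping_id": s.ping_id,
            "object_id": s.object_id if s.object_id is not None else -1,
            "label": (labels or {}).get(s.slice_id, ""),
            "Geometric center latitude": glat,
            "Geometric center longitude": glon,
            "Mass center latitude": mlat,
            "Mass center longitude": mlon,
            "Geometric center depth": gdep,
            "Mass center depth": mdep,
            "Depth ratio": depth_ratio(gdep, mdep),
            "Relative depth in time": rdt.get(s.slice_id, 0.0),
            "Sample mean": mean_db,
            "Sv_UNCAL diff": diff_db,
            "Beams": beams,
            "Intersection area first beam": a_first,
            "Intersection area last beam": a_last,
        }
        row.update(shape)
        rows.append(row)
    df = pd.DataFrame(rows)

    centroid = (
        float(df["Geometric center latitude"].mean()),
        float(df["Geometric center longitude"].mean()),
    )
    x, y = flatten_coords(
        df["Geometric center latitude"].to_numpy(),
        df["Geometric center longitude"].to_numpy(),
        centroid,
    )
    df["x"], df["y"] = x, y
    df["Cluster"] = cluster_feature(df, k=4, seed=seed)
    return df[ID_COLUMNS + TABLE2_COLUMNS]
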