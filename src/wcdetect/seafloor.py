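"""Per-beam bottom detection and the resampled seafloor TIN.

The seabed is picked independently in every beam of every ping (strongest
return below the near field), the soundings are Delaunay-triangulated into a
TIN, and the TIN is resampled onto a 2 m × 2 m grid with a maximum
triangulation distance of 20 m — grid nodes farther than that from any
sounding are undefined.  The resampled grid is what the water-column masking
stage queries (bilinear lookup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import Delaunay, cKDTree

from .simulate import PingFan

__all__ = [
    "SeafloorTIN",
    "detect_bottom_per_beam",
    "build_and_resample_tin",
    "tin_depth_at",
]


@dataclass
class SeafloorTIN:
    """Delaunay TIN over the soundings plus its resampled depth raster."""

    soundings: np.ndarray  # (n, 3): x, y, depth
    triangles: np.ndarray  # (m, 3) vertex indices
    grid_x: np.ndarray  # (nx,) node eastings
    grid_y: np.ndarray  # (ny,) node northings
    grid_depth: np.ndarray  # (ny, nx), NaN where undefined
    resolution: float = 2.0
    max_triangulation_distance: float = 20.0

    def depth_at(self, x, y):
        """Bilinear depth lookup on the resampled grid (NaN if undefined)."""
        interp = RegularGridInterpolator(
            (self.grid_y, self.grid_x),
            self.grid_depth,
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )
        pts = np.column_stack([np.atleast_1d(y), np.atleast_1d(x)])
        out = interp(pts)
        return out if np.ndim(x) else float(out[0])

    def to_ascii_grid(self, path) -> None:
        """Write the resampled raster as an ESRI ASCII grid."""
        nodata = -9999.0
        vals = np.where(np.isnan(self.grid_depth), nodata, self.grid_depth)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.grid_x.size}\n")
            fh.write(f"nrows {self.grid_y.size}\n")
            fh.write(f"xllcorner {self.grid_x[0] - self.resolution / 2}\n")
            fh.write(f"yllcorner {self.grid_y[0] - self.resolution / 2}\n")
            fh.write(f"cellsize {self.resolution}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in vals[::-1]:  # ESRI grids run north to south
                fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")


def detect_bottom_per_beam(
    fan: PingFan, min_sv: float = -55.0, near_field: float = 4.0
) -> np.ndarray:
    """Soundings (x, y, depth) from the strongest return in each beam.

    Per beam the maximum-Sv sample beyond the near field is taken as the
    seabed; beams with no return above ``min_sv`` yield no sounding.  The
    slant range and beam angle give depth = r·cosθ and the across-track
    offset r·sinθ, rotated into world coordinates by the ping heading.
    """
    geom = fan.geometry
    searchable = geom.ranges >= near_field
    vals = np.where(np.isnan(fan.sv), -np.inf, fan.sv)
    vals = np.where(searchable[None, None, :], vals, -np.inf)
    idx = np.argmax(vals, axis=2)  # (2, n_beams)
    ti, bi = np.meshgrid(
        np.arange(vals.shape[0]), np.arange(vals.shape[1]), indexing="ij"
    )
    peak = vals[ti, bi, idx]
    ok = peak >= min_sv
    r = geom.ranges[idx[ok]]
    theta = np.radians(fan.geometry.beam_angles[ok])
    depth = r * np.cos(theta)
    across = r * np.sin(theta)
    ax, ay = fan.across_unit
    x = fan.nav[0] + ax * across
    y = fan.nav[1] + ay * across
    return np.column_stack([x, y, depth])


def build_and_resample_tin(
    soundings: np.ndarray,
    resolution: float = 2.0,
    max_triangulation_distance: float = 20.0,
) -> SeafloorTIN:
    """Delaunay-triangulate the soundings and resample onto a regular grid.

    Grid depth is the planar interpolation on the containing triangle;
    nodes outside the hull or farther than ``max_triangulation_distance``
    from any sounding stay NaN.
    """
    soundings = np.asarray(soundings, dtype=float)
    if soundings.shape[0] < 3:
        raise ValueError("need at least 3 soundings")
    try:
        tri = Delaunay(soundings[:, :2])
    except Exception as exc:  # qhull raises on collinear input
        raise ValueError("soundings are collinear or degenerate") from exc
    if tri.simplices.size == 0:
        raise ValueError("soundings are collinear or degenerate")

    pad = resolution
    x0, x1 = soundings[:, 0].min() - pad, soundings[:, 0].max() + pad
    y0, y1 = soundings[:, 1].min() - pad, soundings[:, 1].max() + pad
    gx = np.arange(math.floor(x0), math.ceil(x1) + resolution, resolution)
    gy = np.arange(math.floor(y0), math.ceil(y1) + resolution, resolution)
    XX, YY = np.meshgrid(gx, gy)
    interp = LinearNDInterpolator(tri, soundings[:, 2])
    depth = interp(XX, YY)

    tree = cKDTree(soundings[:, :2])
    dist, _ = tree.query(np.column_stack([XX.ravel(), YY.ravel()]))
    depth.ravel()[dist > max_triangulation_distance] = np.nan

    return SeafloorTIN(
        soundings=soundings,
        triangles=tri.simplices.copy(),
        grid_x=gx,
        grid_y=gy,
        grid_depth=depth,
        resolution=resolution,
        max_triangulation_distance=max_triangulation_distance,
    )


def tin_depth_at(tin: SeafloorTIN, x, y):
    """Convenience wrapper for :meth:`SeafloorTIN.depth_at`."""
    return tin.depth_at(x, y)


def soundings_from_survey(
    fans: Sequence[PingFan], min_sv: float = -55.0, stride: int = 1
) -> np.ndarray:
    """Stack per-beam soundings from every ``stride``-th ping."""
    parts = [detect_bottom_per_beam(f, min_sv=min_sv) for f in fans[::stride]]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty((0, 3))
    return np.vstack(parts)
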