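"""Geometry of LD-LD interfaces from traced monolayer coordinates.

Interfaces between lipid droplets are imaged in electron cryo-tomograms as
two closely apposed phospholipid monolayers (~10 nm apart). Their geometry
is quantified from manually traced control points:

* each monolayer trace (ordered points per tomographic z slice) is
  interpolated onto a regular 2-nm grid (:func:`interpolate_surface`);
* inter-monolayer distances are nearest-neighbour Euclidean distances
  between the two gridded surfaces (:func:`compute_distance_map`), with
  min/max/mean/median/SD summaries — the median is the per-interface
  statistic of choice because the distance distributions are not Gaussian;
* droplet radii are recovered from the circle radii of two parallel
  tomographic cross-sections via
  ``r = sqrt(a² + ((a² - b² - z²) / (2z))²)`` (:func:`radius_from_sections`),
  exact for a sphere; an equatorial section gives the radius directly;
* interface asymmetry is summarized by the large-to-small diameter ratio.

All lengths are in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "MonolayerTrace",
    "InterpolatedSurface",
    "DistanceMap",
    "interpolate_surface",
    "compute_distance_map",
    "heatmap",
    "radius_from_sections",
    "diameter_ratio",
    "fit_circle",
]

TRACE_COLUMNS = ["surface_id", "x_nm", "y_nm", "z_nm", "point_index"]


@dataclass
class MonolayerTrace:
    """Ordered control points of one monolayer, grouped by z slice."""

    surface_id: str
    points: pd.DataFrame  # columns x_nm, y_nm, z_nm, point_index

    def __post_init__(self) -> None:
        pts = self.points
        missing = {"x_nm", "y_nm", "z_nm"} - set(pts.columns)
        if missing:
            raise ValueError(f"trace missing columns {sorted(missing)}")
        if "point_index" not in pts.columns:
            pts = pts.assign(point_index=pts.groupby("z_nm").cumcount())
        self.points = pts.sort_values(["z_nm", "point_index"]).reset_index(drop=True)
        zs = self.slice_z
        if len(zs) < 2:
            raise ValueError("a surface needs control points on at least 2 z slices")
        if np.any(np.diff(zs) <= 0):
            raise ValueError("slice z values must be strictly increasing")
        counts = self.points.groupby("z_nm").size()
        if (counts < 2).any():
            raise ValueError("every slice needs at least 2 control points")

    @property
    def slice_z(self) -> np.ndarray:
        return np.unique(self.points["z_nm"].to_numpy())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, surface_id: str | None = None) -> "MonolayerTrace":
        if surface_id is None:
            ids = df["surface_id"].unique() if "surface_id" in df else ["?"]
            if len(ids) != 1:
                raise ValueError("dataframe holds multiple surfaces; pass surface_id")
            surface_id = str(ids[0])
        sub = df[df["surface_id"] == surface_id] if "surface_id" in df else df
        return cls(surface_id, sub.drop(columns=["surface_id"], errors="ignore").copy())

    @classmethod
    def from_csv(cls, path: str | Path, surface_id: str | None = None) -> "MonolayerTrace":
        return cls.from_dataframe(pd.read_csv(path, comment="#"), surface_id)


def _slice_is_simple(xy: np.ndarray) -> bool:
    """True if the open polyline through the slice points does not self-intersect."""
    try:
        from shapely.geometry import LineString
    except ImportError:  # pragma: no cover
        return True
    if len(xy) < 3:
        return True
    return LineString(xy).is_simple


@dataclass
class InterpolatedSurface:
    """A monolayer sampled on a regular grid.

    ``points`` has shape ``(n_z, n_s, 3)``: rows are z levels spaced by
    ``grid_spacing``, columns run along the traced curve with ~2-nm arc
    steps. ``control_residual`` is the largest distance between a control
    point and the interpolant at its own parameter (should be ~machine
    epsilon: the per-slice splines interpolate, not smooth).
    """

    points: np.ndarray
    grid_spacing: float
    provenance: dict = field(default_factory=dict)
    control_residual: float = 0.0

    @property
    def flat(self) -> np.ndarray:
        return self.points.reshape(-1, 3)


def interpolate_surface(
    trace: MonolayerTrace, grid_spacing: float = 2.0
) -> InterpolatedSurface:
    """Interpolate a traced monolayer onto a regular grid (default 2 nm).

    Each slice's control points are joined by an arc-length parameterized
    cubic spline (exact at the points); slices are then blended linearly
    along z onto z levels every ``grid_spacing`` nm, sampling each curve at
    matching normalized arc positions so the grid is regular in both
    directions.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    zs = trace.slice_z
    splines = []
    lengths = []
    max_resid = 0.0
    for z in zs:
        sl = trace.points[trace.points["z_nm"] == z]
        xy = sl[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if not _slice_is_simple(xy):
            raise ValueError(f"slice z={z} polyline self-intersects")
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
        if chord[-1] == 0:
            raise ValueError(f"slice z={z} has zero length")
        bc = "natural" if len(xy) > 2 else None
        if len(xy) > 2:
            spl = CubicSpline(chord, xy, axis=0, bc_type=bc)
        else:
            spl = CubicSpline(chord, xy, axis=0, bc_type=((1, (xy[1] - xy[0]) / chord[-1]),) * 2)
        resid = np.max(np.linalg.norm(spl(chord) - xy, axis=1))
        max_resid = max(max_resid, float(resid))
        splines.append((spl, chord[-1]))
        lengths.append(chord[-1])

    n_s = max(int(np.ceil(max(lengths) / grid_spacing)) + 1, 2)
    u = np.linspace(0.0, 1.0, n_s)
    slice_samples = np.stack(
        [np.asarray(spl(u * length)) for spl, length in splines]
    )  # (n_slices, n_s, 2)

    z_grid = np.arange(zs[0], zs[-1] + 1e-9, grid_spacing)
    # linear blend between neighbouring traced slices at each target z
    xy_grid = np.empty((len(z_grid), n_s, 2))
    for k, zg in enumerate(z_grid):
        i = int(np.clip(np.searchsorted(zs, zg, side="right") - 1, 0, len(zs) - 2))
        w = (zg - zs[i]) / (zs[i + 1] - zs[i])
        xy_grid[k] = (1 - w) * slice_samples[i] + w * slice_samples[i + 1]
    pts = np.concatenate(
        [xy_grid, np.broadcast_to(z_grid[:, None, None], (len(z_grid), n_s, 1))], axis=2
    )
    return InterpolatedSurface(
        points=pts,
        grid_spacing=grid_spacing,
        provenance={"surface_id": trace.surface_id, "scheme": "slice-spline+linear-z"},
        control_residual=max_resid,
    )


@dataclass
class DistanceMap:
    """Gridded inter-monolayer distances for one interface.

    ``distances`` is NaN outside the interface region (grid points of A
    whose nearest B point is farther than the region cutoff). Summary
    statistics are computed over the region only; the per-interface
    summary statistic is the median.
    """

    distances: np.ndarray  # (n_z, n_s), NaN outside region
    interface_id: str = ""
    grid_spacing: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.distances).any():
            raise ValueError("empty interface region: no grid point within cutoff")

    @property
    def values(self) -> np.ndarray:
        d = self.distances[np.isfinite(self.distances)]
        return d

    @property
    def stats(self) -> dict:
        v = self.values
        return {
            "interface_id": self.interface_id,
            "min_nm": float(v.min()),
            "max_nm": float(v.max()),
            "mean_nm": float(v.mean()),
            "median_nm": float(np.median(v)),
            "sd_nm": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n_points": int(v.size),
        }

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def compute_distance_map(
    surface_a: InterpolatedSurface,
    surface_b: InterpolatedSurface,
    *,
    max_distance: float = 50.0,
    interface_id: str = "",
) -> DistanceMap:
    """Nearest-neighbour distances from every grid point of A to B's grid.

    Points of A farther than ``max_distance`` (nm) from B are outside the
    apposed interface region and excluded from the statistics. Raises if
    the region is empty.
    """
    tree = cKDTree(surface_b.flat)
    d, _ = tree.query(surface_a.flat)
    d = d.reshape(surface_a.points.shape[:2]).astype(float)
    d[d > max_distance] = np.nan
    return DistanceMap(
        distances=d,
        interface_id=interface_id or surface_a.provenance.get("surface_id", ""),
        grid_spacing=surface_a.grid_spacing,
    )


def heatmap(
    distance_map: DistanceMap, path: str | Path | None = None, cmap: str = "viridis"
):
    """2D distance image over the interface grid; optionally render to file.

    Returns the (n_z, n_s) array (NaN outside the region). Rendering is
    cosmetic and needs matplotlib only when a path is given.
    """
    img = distance_map.distances
    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(img, origin="lower", cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="distance (nm)")
        ax.set_xlabel("arc position (grid index)")
        ax.set_ylabel("z (grid index)")
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return img


def radius_from_sections(a: float, b: float, z: float) -> float:
    """Sphere radius from two parallel cross-section radii spaced z apart.

    For circles of radii ``a`` and ``b`` cut at heights ``h`` and ``h + z``
    of a sphere, ``(a² - b² - z²) / (2z)`` recovers ``h`` and hence
    ``r = sqrt(a² + h²)`` the sphere radius — exactly, for a true sphere.
    If an equatorial section is available, its radius is the sphere radius
    and no second section is needed.
    """
    if a <= 0 or b <= 0:
        raise ValueError("section radii must be positive")
    if z <= 0:
        raise ValueError("slice spacing z must be positive")
    h = (a**2 - b**2 - z**2) / (2.0 * z)
    return math.sqrt(a**2 + h**2)


def diameter_ratio(diameter_1: float, diameter_2: float) -> float:
    """Large-to-small diameter ratio of an LD pair (>= 1, auto-ordered)."""
    if diameter_1 <= 0 or diameter_2 <= 0:
        raise ValueError("diameters must be positive")
    large, small = max(diameter_1, diameter_2), min(diameter_1, diameter_2)
    return large / small


def fit_circle(points_xy: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Kåsa) to points in a slice.

    Stand-in for curvature readouts on traced monolayer arcs: returns
    ``(cx, cy, r)``. Exact for points lying on a circle.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    bvec = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(c + cx**2 + cy**2)
    return float(cx), float(cy), float(r)
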