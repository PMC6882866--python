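"""Interpolated cortical maps of per-electrode observables.

Scattered per-electrode values are interpolated onto a regular mesh grid
over the array footprint (50 x 90 steps by default, i.e. a grid step of
one tenth of the 0.550 mm array step), masked outside the convex hull of
the retained electrodes.  The default interpolator is piecewise-linear
over a Delaunay triangulation: it is exact at the electrode positions and
cannot overshoot the input range, which keeps contour maps honest; a
smoother radial-basis option is available.  Electrode markers for the
inter-session maps are sized inversely to the across-subject standard
deviation at the electrode (big marker = consistent value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RBFInterpolator
from scipy.spatial import Delaunay, QhullError

from .io import ArrayGeometry


@dataclass
class MeshGrid:
    """Regular grid over the electrode bounding box (nx x ny steps)."""

    x: np.ndarray          # nx + 1 grid-line coordinates, mm
    y: np.ndarray          # ny + 1
    step_x: float
    step_y: float
    origin: tuple[float, float]

    @property
    def nx(self) -> int:
        return len(self.x) - 1

    @property
    def ny(self) -> int:
        return len(self.y) - 1

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="xy")


@dataclass
class InterpolatedMap:
    grid: MeshGrid
    values: np.ndarray             # (ny+1, nx+1), NaN outside the mask
    mask: np.ndarray               # True where defined (inside hull)
    markers: pd.DataFrame          # electrode, x, y, value[, sd, size]
    excluded: list[str]


def build_grid(geometry: ArrayGeometry, nx: int = 50, ny: int = 90) -> MeshGrid:
    """Mesh grid spanning the electrode bounding box with nx x ny steps."""
    coords = geometry.coords()
    if coords.shape[0] < 3 or np.linalg.matrix_rank(coords - coords.mean(axis=0)) < 2:
        raise ValueError("need >= 3 non-collinear electrodes to define a map plane")
    (x0, y0), (x1, y1) = coords.min(axis=0), coords.max(axis=0)
    return MeshGrid(
        x=np.linspace(x0, x1, nx + 1),
        y=np.linspace(y0, y1, ny + 1),
        step_x=(x1 - x0) / nx,
        step_y=(y1 - y0) / ny,
        origin=(float(x0), float(y0)),
    )


def interpolate_map(
    values: dict[str, float],
    geometry: ArrayGeometry,
    grid: MeshGrid | None = None,
    method: str = "linear",
    marker_sd: dict[str, float] | None = None,
    size_bounds: tuple[float, float] = (20.0, 200.0),
) -> InterpolatedMap:
    """Interpolate per-electrode values onto the mesh grid.

    Electrodes absent from ``values`` are treated as excluded: they take no
    part in the interpolation and are listed for open-marker rendering.
    Cells outside the convex hull of the retained electrodes are masked.
    """
    retained = [e for e in geometry.electrodes if e in values]
    if len(retained) < 3:
        raise ValueError("need >= 3 retained electrodes with values")
    pts = geometry.coords(retained)
    vals = np.array([values[e] for e in retained], dtype=float)
    grid = grid or build_grid(geometry)
    gx, gy = grid.points()
    flat = np.column_stack([gx.ravel(), gy.ravel()])

    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError("retained electrodes are collinear") from e
    inside = tri.find_simplex(flat) >= 0
    if method == "linear":
        interp = LinearNDInterpolator(tri, vals)
        z = interp(flat)
    elif method == "rbf":
        rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline")
        z = rbf(flat)
        z[~inside] = np.nan
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    z = np.where(inside, z, np.nan).reshape(gx.shape)

    markers = pd.DataFrame(
        {"electrode": retained, "x_mm": pts[:, 0], "y_mm": pts[:, 1], "value": vals}
    )
    if marker_sd is not None:
        sds = np.array([marker_sd.get(e, np.nan) for e in retained], dtype=float)
        markers["sd"] = sds
        markers["size"] = marker_sizes(sds, size_bounds)
    return InterpolatedMap(
        grid=grid,
        values=z,
        mask=inside.reshape(gx.shape),
        markers=markers,
        excluded=[e for e in geometry.electrodes if e not in values],
    )


def marker_sizes(
    sds: np.ndarray,
    bounds: tuple[float, float] = (20.0, 200.0),
    eps: float = 1e-12,
) -> np.ndarray:
    """Marker sizes inversely proportional to the across-subject SD.

    Raw sizes 1/(sd + eps) are affinely mapped into ``bounds``; sd = 0
    maps to the maximal size, and the size ordering is exactly the
    reversed SD ordering.  (A large marker therefore means low variability
    across subjects at that electrode.)
    """
    sds = np.asarray(sds, dtype=float)
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    lo, hi = bounds
    raw = 1.0 / (sds + eps)
    finite = np.isfinite(raw)
    if not finite.any():
        return np.full_like(sds, np.nan)
    rmin, rmax = raw[finite].min(), raw[finite].max()
    if rmax == rmin:
        return np.where(finite, hi, np.nan)
    out = lo + (raw - rmin) / (rmax - rmin) * (hi - lo)
    return np.where(finite, out, np.nan)


def map_to_frame(m: InterpolatedMap) -> pd.DataFrame:
    """Gridded map as a tidy (x, y, value, inside) table for export."""
    gx, gy = m.grid.points()
    return pd.DataFrame(
        {
            "x_mm": gx.ravel(),
            "y_mm": gy.ravel(),
            "value": m.values.ravel(),
            "inside": m.mask.ravel(),
        }
    )
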