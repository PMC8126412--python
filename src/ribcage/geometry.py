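"""Per-embryo reference frame and point geometry.

All metrics in this package are expressed relative to a single per-embryo
frame: an axis-aligned bounding cuboid of the organ (y = anterior→posterior,
x = lateral, z = depth, µm) and a midline running parallel to the AP axis
through the point where the left and right visceral-muscle sheets merge at
the last analyzed timepoint (T4).  The same midline and cuboid are applied
retrospectively to every earlier timepoint of that embryo, so the
normalization denominator (maximal organ width) is constant within an
embryo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError

log = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"
TIE = "tie"


@dataclass(frozen=True)
class BoundingCuboid:
    """Axis-aligned minimal cuboid of the organ, in µm.

    The x-extent is the maximal organ width — the denominator used to
    normalize distance metrics to percentages.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min):
            raise GeometryError("degenerate cuboid: zero width (x_max <= x_min)")
        if not (self.y_max >= self.y_min and self.z_max >= self.z_min):
            raise GeometryError("degenerate cuboid: inverted y or z extent")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def center(self) -> tuple[float, float, float]:
        return (
            (self.x_min + self.x_max) / 2.0,
            (self.y_min + self.y_max) / 2.0,
            (self.z_min + self.z_max) / 2.0,
        )


@dataclass(frozen=True)
class Midline:
    """AP-parallel line through the T4 merge point.

    The direction is fixed to +y, so the perpendicular distance from a point
    (x, y, z) is sqrt((x - x0)^2 + (z - z0)^2), independent of y.
    """

    x: float
    y: float
    z: float

    @property
    def point(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class RegionWindow:
    """Half-open AP analysis window measured from the anterior tip.

    Defaults select nuclei 40–80 µm posterior of the tip; the half-open
    convention [near, far) avoids double-counting a nucleus sitting exactly
    on the 40 µm boundary between the anterior and posterior regions.
    """

    near_um: float = 40.0
    far_um: float = 80.0
    anterior_tip_y: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.near_um < self.far_um):
            raise GeometryError("region window requires 0 <= near_um < far_um")


def _as_points(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        arr = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) point array, got shape {arr.shape}")
    return arr


def fit_bounding_cuboid(points_or_mesh) -> BoundingCuboid:
    """Axis-aligned min/max box of a point set (nuclei or mesh vertices).

    Input coordinates must already be AP-aligned (y = AP axis).  When both a
    mesh and nuclei are available the caller passes the mesh vertices: the
    organ surface, not the nuclei, defines the maximal organ width.
    """
    arr = _as_points(points_or_mesh)
    if arr.shape[0] < 2:
        raise GeometryError("cuboid fit needs at least 2 points")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    if hi[0] <= lo[0]:
        raise GeometryError("degenerate cuboid: zero width (all x equal)")
    return BoundingCuboid(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def define_midline(merge_point) -> Midline:
    """Midline through the point where left/right muscle sheets merge at T4.

    One midline is defined per embryo and reused for all of its timepoints.
    """
    x, y, z = (float(v) for v in merge_point)
    if not all(np.isfinite([x, y, z])):
        raise GeometryError("merge point coordinates must be finite")
    return Midline(x, y, z)


def estimate_merge_point(left_leading_points, right_leading_points) -> tuple[float, float, float]:
    """Default merge point when none was placed manually.

    Takes the medial-most point of each side — the point closest to the
    other side in x — and returns their midpoint in x and z at their mean y.
    Works for either left/right x-orientation: the lower-x set contributes
    its max-x point, the higher-x set its min-x point.
    """
    a = _as_points(left_leading_points)
    b = _as_points(right_leading_points)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise GeometryError("merge-point estimate needs nonempty point sets on both sides")
    if a[:, 0].mean() > b[:, 0].mean():
        a, b = b, a
    p_lo = a[np.argmax(a[:, 0])]  # medial-most of the lower-x side
    p_hi = b[np.argmin(b[:, 0])]  # medial-most of the higher-x side
    return (
        (p_lo[0] + p_hi[0]) / 2.0,
        (p_lo[1] + p_hi[1]) / 2.0,
        (p_lo[2] + p_hi[2]) / 2.0,
    )


def distance_to_midline(point, midline: Midline) -> np.ndarray | float:
    """Perpendicular 3D distance (µm) from point(s) to the midline.

    For the +y midline this is the in-plane distance sqrt(dx^2 + dz^2).
    Accepts a single (x, y, z) or an (n, 3) array / nucleus table.
    """
    arr = _as_points(point)
    d = np.hypot(arr[:, 0] - midline.x, arr[:, 2] - midline.z)
    single = not isinstance(point, pd.DataFrame) and np.asarray(point, dtype=float).ndim == 1
    return float(d[0]) if single else d


def assign_side(points, midline: Midline, flip: bool = False) -> np.ndarray:
    """Label each point left/right by the sign of (x - midline.x).

    Default convention (ventral view): x < midline.x → right, x > midline.x
    → left; ``flip`` swaps the labels for the opposite viewing orientation.
    Points exactly on the midline are labelled "tie" and are excluded from
    per-side statistics by the callers (with a logged warning).
    """
    arr = _as_points(points)
    dx = arr[:, 0] - midline.x
    neg, pos = (RIGHT, LEFT) if not flip else (LEFT, RIGHT)
    labels = np.where(dx < 0, neg, np.where(dx > 0, pos, TIE))
    n_tie = int((labels == TIE).sum())
    if n_tie:
        log.warning("%d nucleus/nuclei exactly on the midline: tie-flagged, excluded from per-side statistics", n_tie)
    return labels


def region_mask(y, window: RegionWindow) -> np.ndarray:
    """Boolean mask for the half-open AP window [near, far) from the tip."""
    rel = np.asarray(y, dtype=float) - window.anterior_tip_y
    return (rel >= window.near_um) & (rel < window.far_um)


def filter_region(points, window: RegionWindow):
    """Keep points with near_um <= (y - anterior_tip_y) < far_um.

    Returns the same container type as the input (DataFrame or array).
    An empty result is returned as-is with a warning, not an error.
    """
    if isinstance(points, pd.DataFrame):
        mask = region_mask(points["y_um"].to_numpy(dtype=float), window)
        out = points.loc[mask]
    else:
        arr = _as_points(points)
        mask = region_mask(arr[:, 1], window)
        out = arr[mask]
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("region filter [%g, %g) µm from tip: excluded %d of %d nuclei",
                 window.near_um, window.far_um, n_dropped, mask.size)
    if len(out) == 0:
        log.warning("region filter left no nuclei in the analysis window")
    return out
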