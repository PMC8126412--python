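"""The three per-embryo measurements: midline distance, collectivity, path length.

All three are computed per side (left/right of the midline) on nuclei in the
posterior analysis window, and normalized where noted by the maximal organ
width (the x-extent of the bounding cuboid):

normalized midline distance (%)
    mean over nuclei of the perpendicular 3D distance to the midline, as a
    percentage of the maximal width.  Lower values mean nuclei sit closer
    to the midline.

collectivity index (%)
    each nucleus is linked to its nearest strictly-more-posterior same-side
    neighbor (3D Euclidean distance); each unordered pair is counted once;
    the mean link length is reported as a percentage of the maximal width.
    Higher values mean a more dispersed (less collective) arrangement.

migration path length (µm)
    sum of segment lengths of a nucleus's fine-sampled track over the
    tracking window, by default on the xy projection (paths are traced on
    maximum-intensity projections of the movies); 'xyz' is available.

Empty sides and single-nucleus sides yield missing values (NaN), never
zeros, so cohort averages are not biased toward zero.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import GeometryError
from .geometry import (
    LEFT,
    RIGHT,
    TIE,
    BoundingCuboid,
    Midline,
    RegionWindow,
    assign_side,
    define_midline,
    distance_to_midline,
    estimate_merge_point,
    filter_region,
    fit_bounding_cuboid,
)
from .synthetic import TIMEPOINT_LABELS, EmbryoSeries

log = logging.getLogger(__name__)

METRICS_COLUMNS = ["embryo_id", "side", "timepoint", "metric", "value", "n_nuclei"]

MIDLINE_DISTANCE_PCT = "midline_distance_pct"
COLLECTIVITY_PCT = "collectivity_pct"
PATH_LENGTH_UM = "path_length_um"


def normalized_midline_distance(nuclei_one_side, midline: Midline, cuboid: BoundingCuboid) -> float:
    """Per-embryo mean of 100 × distance-to-midline / maximal width.

    Returns NaN for an empty side (missing value, not zero).
    """
    pts = nuclei_one_side[["x_um", "y_um", "z_um"]].to_numpy(dtype=float) \
        if isinstance(nuclei_one_side, pd.DataFrame) else np.asarray(nuclei_one_side, dtype=float)
    if pts.size == 0:
        return math.nan
    if cuboid.width <= 0:
        raise GeometryError("cuboid width must be positive")
    d = distance_to_midline(pts.reshape(-1, 3), midline)
    return float(np.mean(100.0 * d / cuboid.width))


def nearest_posterior_pairs(points, ids=None) -> list[tuple]:
    """Unordered links (id_i, id_j, distance) to nearest posterior neighbors.

    For each nucleus i with at least one same-side nucleus strictly
    posterior (greater y), the 3D-nearest such j is linked; identical
    unordered pairs are deduplicated.  Distance ties break to the smallest
    nucleus id for determinism; candidates at identical y are excluded
    ("most posterior" is strict).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if ids is None:
        ids = list(range(n))
    ids = list(ids)
    order = sorted(range(n), key=lambda k: str(ids[k]))  # deterministic tie-break order
    links: dict[frozenset, float] = {}
    for i in range(n):
        best_j, best_d = None, np.inf
        for j in order:  # id-sorted, so ties at equal distance keep the smallest id
            if pts[j, 1] <= pts[i, 1]:
                continue
            d = float(np.linalg.norm(pts[j] - pts[i]))
            if d < best_d:
                best_j, best_d = j, d
        if best_j is not None:
            links.setdefault(frozenset((ids[i], ids[best_j])), best_d)
    return [(*sorted(pair, key=str), d) for pair, d in links.items()]


def collectivity_index(nuclei_one_side, cuboid: BoundingCuboid, ids=None) -> float:
    """Mean nearest-posterior-neighbor link length as % of maximal width.

    Requires ≥2 nuclei and at least one strictly-posterior relation;
    otherwise returns NaN (with a warning when all nuclei share one y).
    """
    if isinstance(nuclei_one_side, pd.DataFrame):
        pts = nuclei_one_side[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if ids is None and "nucleus_id" in nuclei_one_side.columns:
            ids = nuclei_one_side["nucleus_id"].tolist()
    else:
        pts = np.asarray(nuclei_one_side, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 2:
        return math.nan
    pairs = nearest_posterior_pairs(pts, ids=ids)
    if not pairs:
        log.warning("collectivity undefined: no strictly-posterior relations (all nuclei at one y)")
        return math.nan
    mean_d = float(np.mean([d for _, _, d in pairs]))
    return 100.0 * mean_d / cuboid.width


def migration_path_length(track: pd.DataFrame, projection: str = "xy") -> float:
    """Traced path length (µm) of one nucleus over its sampled positions.

    ``projection='xy'`` (default) measures on the 2D projection; ``'xyz'``
    in full 3D.  Returns NaN for tracks with fewer than 2 points.
    """
    if projection not in ("xy", "xyz"):
        raise ValueError(f"projection must be 'xy' or 'xyz', got {projection!r}")
    t = track["t_minutes"].to_numpy(dtype=float)
    if len(t) < 2:
        return math.nan
    if (np.diff(t) <= 0).any():
        raise ValueError("track t_minutes must be strictly increasing")
    cols = ["x_um", "y_um"] if projection == "xy" else ["x_um", "y_um", "z_um"]
    pos = track[cols].to_numpy(dtype=float)
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def _resolve_frame(series: EmbryoSeries, config: AnalysisConfig):
    """Cuboid, anterior tip, and midline for one embryo (from its T4 state)."""
    t4 = series.nuclei[series.nuclei["timepoint"] == "T4"]
    if series.mesh_vertices is not None and len(series.mesh_vertices) >= 2:
        organ_pts = np.asarray(series.mesh_vertices, dtype=float)
    else:
        organ_pts = t4[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    cuboid = fit_bounding_cuboid(organ_pts)
    tip = config.anterior_tip_y if config.anterior_tip_y is not None else float(organ_pts[:, 1].min())

    if config.merge_point is not None:
        merge = config.merge_point
    elif series.merge_point is not None:
        merge = series.merge_point
    else:
        # No configured merge point: split the T4 nuclei at the cuboid
        # x-center and take the midpoint of the medial-most points.
        pts = t4[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        cx = cuboid.center[0]
        lo, hi = pts[pts[:, 0] < cx], pts[pts[:, 0] >= cx]
        merge = estimate_merge_point(lo, hi)
        log.info("%s: merge point estimated from T4 nuclei at x=%.2f", series.embryo_id, merge[0])
    return cuboid, tip, define_midline(merge)


def compute_metrics(series: EmbryoSeries, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Run the full per-embryo pipeline: region filter → sides → 3 metrics.

    Produces one row per (side, timepoint) for the distance and
    collectivity metrics at T1–T4, and one row per side for the migration
    path length over the configured tracking window (labelled with the
    window-start timepoint).  Missing values are omitted, with the reason
    logged.
    """
    cuboid, tip, midline = _resolve_frame(series, config)
    window = RegionWindow(config.region_near_um, config.region_far_um, anterior_tip_y=tip)
    rows: list[tuple] = []

    for label in TIMEPOINT_LABELS:
        frame = series.nuclei[series.nuclei["timepoint"] == label]
        if len(frame) == 0:
            continue
        selected = filter_region(frame, window)
        if len(selected) == 0:
            log.warning("%s %s: no nuclei in analysis window", series.embryo_id, label)
            continue
        sides = assign_side(selected, midline, flip=config.flip_sides)
        n_tie = int((sides == TIE).sum())
        if n_tie:
            log.warning("%s %s: excluded %d midline-tie nuclei", series.embryo_id, label, n_tie)
        for side in (LEFT, RIGHT):
            sub = selected.loc[sides == side]
            n = len(sub)
            if n == 0:
                log.warning("%s %s: empty %s side, missing value", series.embryo_id, label, side)
                continue
            dist = normalized_midline_distance(sub, midline, cuboid)
            rows.append((series.embryo_id, side, label, MIDLINE_DISTANCE_PCT, dist, n))
            coll = collectivity_index(sub, cuboid)
            if not math.isnan(coll):
                rows.append((series.embryo_id, side, label, COLLECTIVITY_PCT, coll, n))
            else:
                log.warning("%s %s %s: collectivity missing (<2 nuclei or no posterior relations)",
                            series.embryo_id, label, side)

    rows.extend(_path_rows(series, config, cuboid, midline, window))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def _path_rows(series, config, cuboid, midline, window):
    """Per-side mean migration path length over the tracking window."""
    tracks = series.tracks
    if tracks is None or len(tracks) == 0:
        return []
    t0 = config.path_start_minutes
    t1 = t0 + config.path_window_minutes
    win = tracks[(tracks["t_minutes"] >= t0 - 1e-9) & (tracks["t_minutes"] <= t1 + 1e-9)]
    lengths: dict[str, list[float]] = {LEFT: [], RIGHT: []}
    n_short = 0
    for nid, grp in win.groupby("nucleus_id", sort=True):
        grp = grp.sort_values("t_minutes")
        if len(grp) < 2:
            n_short += 1
            continue
        start = grp.iloc[0]
        # Inclusion and side are judged at the window start position.
        if not (window.near_um <= start["y_um"] - window.anterior_tip_y < window.far_um):
            continue
        side = assign_side(
            np.array([[start["x_um"], start["y_um"], start["z_um"]]]), midline,
            flip=config.flip_sides,
        )[0]
        if side == TIE:
            continue
        lengths[side].append(migration_path_length(grp, projection=config.projection))
    if n_short:
        log.warning("%s: skipped %d track(s) with <2 points in window", series.embryo_id, n_short)
    label = f"T{int(t0 // 10) + 1}" if t0 in (0.0, 10.0, 20.0, 30.0) else f"{t0:g}min"
    rows = []
    for side, vals in lengths.items():
        if vals:
            rows.append((series.embryo_id, side, label, PATH_LENGTH_UM, float(np.mean(vals)), len(vals)))
    return rows


def measure_cohort(cohort: list[EmbryoSeries], config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Concatenated metrics table for a list of embryos."""
    tables = [compute_metrics(s, config) for s in cohort]
    if not tables:
        return pd.DataFrame(columns=METRICS_COLUMNS)
    return pd.concat(tables, ignore_index=True)
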