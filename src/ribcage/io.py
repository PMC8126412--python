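"""Interchange formats: nucleus/track CSV, OBJ/PLY vertex clouds, JSON stats.

Tables are RFC 4180 CSV, UTF-8, "." decimal, with fixed header strings:

``nucleus table``   embryo_id,nucleus_id,timepoint,x_um,y_um,z_um
``track table``     embryo_id,nucleus_id,t_minutes,x_um,y_um,z_um
``metrics table``   embryo_id,side,timepoint,metric,value,n_nuclei

Lines starting with ``#`` are metadata comments (seed, config hash) and are
skipped by all readers.  Unknown extra columns are preserved.  The
``timepoint`` column accepts the labels T1–T4 or minutes; labels map to
minutes with T4 as the reference: Tk = T4_minutes − (4 − k) × 10.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, IntegrityError

NUCLEUS_COLUMNS = ["embryo_id", "nucleus_id", "timepoint", "x_um", "y_um", "z_um"]
TRACK_COLUMNS = ["embryo_id", "nucleus_id", "t_minutes", "x_um", "y_um", "z_um"]
METRICS_COLUMNS = ["embryo_id", "side", "timepoint", "metric", "value", "n_nuclei"]

#: Expected fine-track sampling (warn, don't fail, on other spacings).
EXPECTED_TRACK_INTERVAL_MIN = 5.0
EXPECTED_TRACK_SPAN_MIN = 30.0


@dataclass(frozen=True)
class MeshVertices:
    """A surface model reduced to its vertex cloud."""

    vertices: np.ndarray  # (n, 3) µm
    source_format: str  # "OBJ" | "PLY"


def timepoint_to_minutes(label, t4_minutes: float = 30.0) -> float:
    """Map a T1–T4 label (or a numeric string / number) to minutes."""
    s = str(label).strip()
    if s.upper() in {"T1", "T2", "T3", "T4"}:
        k = int(s[1])
        return t4_minutes - (4 - k) * 10.0
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"unrecognized timepoint label {label!r}") from None


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", dtype={"embryo_id": str, "nucleus_id": str, "timepoint": str}
    )


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column '{col}' at data row {row + 1}"
            )
        if not np.isfinite(converted.to_numpy(dtype=float)).all():
            row = int(np.flatnonzero(~np.isfinite(converted.to_numpy(dtype=float)))[0])
            raise FormatError(f"{path}: non-finite coordinate in column '{col}' at data row {row + 1}")
        df[col] = converted.astype(float)
    return df


def read_nucleus_table(path) -> pd.DataFrame:
    """Read and validate a nucleus-position table.

    Raises :class:`FormatError` for missing columns or non-numeric
    coordinates (with the row number) and :class:`IntegrityError` for
    duplicate (embryo_id, nucleus_id, timepoint) keys.
    """
    df = _read_csv(path)
    _check_columns(df, NUCLEUS_COLUMNS, path)
    df = _check_numeric(df, ["x_um", "y_um", "z_um"], path)
    key = ["embryo_id", "nucleus_id", "timepoint"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(f"{path}: duplicate nucleus key {tuple(first)}")
    return df


def read_track_table(path) -> pd.DataFrame:
    """Read and validate a fine-grained track table.

    Enforces strictly increasing t per (embryo_id, nucleus_id); warns (does
    not fail) when the sampling deviates from 5-min steps over 30 min.
    """
    df = _read_csv(path)
    _check_columns(df, TRACK_COLUMNS, path)
    df = _check_numeric(df, ["t_minutes", "x_um", "y_um", "z_um"], path)
    irregular = False
    for (eid, nid), grp in df.groupby(["embryo_id", "nucleus_id"], sort=False):
        t = grp["t_minutes"].to_numpy()
        if (np.diff(t) <= 0).any():
            raise IntegrityError(
                f"{path}: t_minutes not strictly increasing for nucleus ({eid}, {nid})"
            )
        steps = np.diff(t)
        if len(steps) and (
            not np.allclose(steps, EXPECTED_TRACK_INTERVAL_MIN)
            or not np.isclose(t[-1] - t[0], EXPECTED_TRACK_SPAN_MIN)
        ):
            irregular = True
    if irregular:
        warnings.warn(
            f"{path}: track sampling deviates from the expected "
            f"{EXPECTED_TRACK_INTERVAL_MIN:g}-min steps over {EXPECTED_TRACK_SPAN_MIN:g} min",
            stacklevel=2,
        )
    return df


def read_mesh_vertices(path) -> MeshVertices:
    """Read an OBJ or ASCII PLY surface model as a vertex cloud.

    Faces are ignored; vertices are returned in file order.
    """
    p = Path(path)
    ext = p.suffix.lower().lstrip(".")
    if ext not in {"obj", "ply"}:
        raise FormatError(f"{path}: unsupported mesh format '.{ext}' (expected .obj or .ply)")
    loaded = trimesh.load(str(p), file_type=ext, process=False)
    if not hasattr(loaded, "vertices"):  # trimesh yields an empty Scene for vertex-less files
        raise FormatError(f"{path}: mesh contains no vertices")
    vertices = np.asarray(loaded.vertices, dtype=float)
    if vertices.size == 0:
        raise FormatError(f"{path}: mesh contains no vertices")
    return MeshVertices(vertices=vertices, source_format=ext.upper())


def _meta_comment(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={meta[k]}" for k in sorted(meta))
    return f"# {parts}\n"


def _write_table(df: pd.DataFrame, columns: list[str], path, meta: dict | None) -> None:
    extra = [c for c in df.columns if c not in columns]
    out = df[columns + extra] if len(df) else pd.DataFrame(columns=columns + extra)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_comment(meta))
        out.to_csv(fh, index=False)


def write_nucleus_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(df, NUCLEUS_COLUMNS, path, meta)


def write_track_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(df, TRACK_COLUMNS, path, meta)


def write_metrics(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a metrics table (CSV, full precision; header always present)."""
    _write_table(table, METRICS_COLUMNS, path, meta)


def read_metrics(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_columns(df, METRICS_COLUMNS, path)
    return _check_numeric(df, ["value", "n_nuclei"], path)


def write_mesh_obj(vertices: np.ndarray, path) -> None:
    """Write a vertex cloud as a minimal OBJ ('v x y z' lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in np.asarray(vertices, dtype=float):
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")


def write_stats(results: dict, path, meta: dict | None = None) -> None:
    """Write statistical results as deterministic (sorted-key) JSON."""
    payload = dict(results)
    if meta:
        payload["_meta"] = meta
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_stats(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
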