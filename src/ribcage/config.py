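"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for the measurement pipeline.

    merge_point
        (x, y, z) µm anchor of the midline; when None it is taken from the
        embryo metadata (simulated data) or estimated from the T4 nuclei.
    flip_sides
        swap the left/right labels (image vs anatomical orientation).
    region_near_um / region_far_um
        half-open AP analysis window measured from the anterior tip.
    anterior_tip_y
        override for the anterior tip; default is the minimum y of the
        organ representation (mesh if present, else nuclei at T4).
    projection
        'xy' (paths traced on maximum-intensity projections) or 'xyz'.
    path_start_minutes / path_window_minutes
        migration-path tracking window, default the 30 min from T1.
    """

    merge_point: tuple[float, float, float] | None = None
    flip_sides: bool = False
    region_near_um: float = 40.0
    region_far_um: float = 80.0
    anterior_tip_y: float | None = None
    projection: str = "xy"
    path_start_minutes: float = 0.0
    path_window_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.projection not in ("xy", "xyz"):
            raise ValidationError(f"projection must be 'xy' or 'xyz', got {self.projection!r}")
        if not (0.0 <= self.region_near_um < self.region_far_um):
            raise ValidationError("region window requires 0 <= near < far")
        if self.path_window_minutes <= 0:
            raise ValidationError("path_window_minutes must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["merge_point"] is not None:
            d["merge_point"] = list(d["merge_point"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("merge_point") is not None:
            d["merge_point"] = tuple(float(v) for v in d["merge_point"])
        return cls(**d)


def config_hash(obj) -> str:
    """Short stable hash of a config-like object, for output provenance."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
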