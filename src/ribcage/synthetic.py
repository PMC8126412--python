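"""Synthetic embryo cohorts with controlled nuclear-positioning structure.

The generator emulates the nuclear arrangements seen in the embryonic
*Drosophila* anterior midgut (AMG) visceral muscle between stages 13 and 14:
two AP-parallel files of nuclei ("rib-cage" arrangement), one per lateral
side, each nucleus holding a characteristic fractional distance from the
midline and spaced along the AP axis, with small random nuclear movements
sampled at fixed intervals.  Three genotype presets encode the phenotype
contrasts the analysis is designed to detect:

``wildtype``
    bilaterally symmetric fractions, dense AP spacing, slow migration.
``dlp_like``
    (glypican / Wnt4-signaling loss) both fractions reduced — nuclei closer
    to the midline on both sides — with inflated AP spacing (dispersal) and
    faster migration.
``linc_like``
    (LINC complex / myosin II loss) the right-side fraction alone reduced —
    a right-side-only shift toward the midline.

Coordinates: x lateral, y anterior→posterior (tip at y = 0), z depth, µm.
Frames are emitted at T1–T4 (10-min spacing, T1 = 0 min); fine-grained
tracks at ``fine_interval`` minutes over ``fine_duration`` minutes from T1.
The 8 corner vertices of the organ cuboid are emitted as a stand-in surface
model so that downstream cuboid fitting recovers the true organ width.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TIMEPOINT_LABELS = ("T1", "T2", "T3", "T4")
TIMEPOINT_MINUTES = {"T1": 0.0, "T2": 10.0, "T3": 20.0, "T4": 30.0}

#: Minimum nuclei per side after the rounded-Normal count draw.
MIN_NUCLEI_PER_SIDE = 3

NUCLEUS_COLUMNS = ["embryo_id", "nucleus_id", "timepoint", "x_um", "y_um", "z_um"]
TRACK_COLUMNS = ["embryo_id", "nucleus_id", "t_minutes", "x_um", "y_um", "z_um"]


@dataclass(frozen=True)
class GenotypePreset:
    """Generator parameters for one genotype.

    midline_distance_fraction_* are fractions of the maximal organ width
    (0–0.5); spacing/jitter/step parameters are µm.  migration_step_sd is
    the per-axis SD of the isotropic Gaussian displacement per 5-min step.
    nuclei_count_mean/sd parameterize the rounded-Normal per-embryo total
    nucleus count (split evenly between sides, truncated at ≥3 per side).
    """

    name: str
    midline_distance_fraction_left: float
    midline_distance_fraction_right: float
    ap_spacing_mean: float
    ap_spacing_sd: float
    lateral_jitter_sd: float
    migration_step_sd: float
    nuclei_count_mean: float
    nuclei_count_sd: float

    def validate(self) -> None:
        for side in ("left", "right"):
            f = getattr(self, f"midline_distance_fraction_{side}")
            if not (0.0 < f < 0.5):
                raise ValidationError(
                    f"midline_distance_fraction_{side}={f} violates 0 < fraction < 0.5"
                )
        for name in ("ap_spacing_sd", "lateral_jitter_sd", "migration_step_sd", "nuclei_count_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.ap_spacing_mean <= 0:
            raise ValidationError("ap_spacing_mean must be > 0")
        if self.nuclei_count_mean <= 0:
            raise ValidationError("nuclei_count_mean must be > 0")


#: Wild-type defaults.  The count mean/SD (20.1 ± 4.8 nuclei per embryo)
#: matches the reported per-embryo average; the fractional midline distance
#: (0.30 of width per side) and the organ dimensions are free parameters
#: chosen so that the 40–80 µm window holds roughly half the nuclei.
WILDTYPE = GenotypePreset(
    name="wildtype",
    midline_distance_fraction_left=0.30,
    midline_distance_fraction_right=0.30,
    ap_spacing_mean=10.0,
    ap_spacing_sd=2.0,
    lateral_jitter_sd=2.0,
    migration_step_sd=0.5,
    nuclei_count_mean=20.1,
    nuclei_count_sd=4.8,
)

#: Glypican-loss-like: both sides 0.10 of width closer to the midline,
#: AP spacing inflated 1.5x (dispersal), migration twice as fast.
DLP_LIKE = dataclasses.replace(
    WILDTYPE,
    name="dlp_like",
    midline_distance_fraction_left=0.20,
    midline_distance_fraction_right=0.20,
    ap_spacing_mean=15.0,
    ap_spacing_sd=3.0,
    migration_step_sd=1.0,
)

#: LINC-complex-loss-like: right side alone shifted toward the midline.
LINC_LIKE = dataclasses.replace(
    WILDTYPE,
    name="linc_like",
    midline_distance_fraction_right=0.20,
)

PRESETS = {p.name: p for p in (WILDTYPE, DLP_LIKE, LINC_LIKE)}


@dataclass(frozen=True)
class EmbryoSpec:
    """Full recipe for one synthetic embryo.

    T1–T4 frame times are fixed at 0/10/20/30 min (10-min acquisition
    spacing); fine tracks run at ``fine_interval`` min over
    ``fine_duration`` min starting at T1.
    """

    preset: GenotypePreset = WILDTYPE
    organ_length: float = 100.0
    organ_max_width: float = 50.0
    organ_depth: float = 30.0
    fine_interval: float = 5.0
    fine_duration: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        self.preset.validate()
        if self.organ_length < 80.0:
            raise ValidationError(
                f"organ_length={self.organ_length} violates organ_length >= 80 µm "
                "(the 40–80 µm analysis window must exist)"
            )
        if self.organ_max_width <= 0 or self.organ_depth <= 0:
            raise ValidationError("organ_max_width and organ_depth must be > 0")
        if self.fine_interval <= 0:
            raise ValidationError("fine_interval must be > 0 minutes")
        if self.fine_duration < TIMEPOINT_MINUTES["T4"]:
            raise ValidationError("fine_duration must cover T1–T4 (>= 30 minutes)")


@dataclass
class EmbryoSeries:
    """One embryo: T1–T4 nucleus frames, fine tracks, organ box, midline.

    ``nuclei`` and ``tracks`` are tables in the interchange schema
    (see :mod:`ribcage.io`); ``mesh_vertices`` is the organ surface as a
    vertex cloud; ``merge_point`` is where the left/right sheets merge at
    T4 — the anchor of the midline.
    """

    embryo_id: str
    nuclei: pd.DataFrame
    tracks: pd.DataFrame
    mesh_vertices: np.ndarray | None = None
    merge_point: tuple[float, float, float] | None = None
    spec: EmbryoSpec | None = None
    extras: dict = field(default_factory=dict)


def _organ_corners(spec: EmbryoSpec) -> np.ndarray:
    w, l, d = spec.organ_max_width, spec.organ_length, spec.organ_depth
    return np.array(
        [[x, y, z] for x in (0.0, w) for y in (0.0, l) for z in (0.0, d)]
    )


def generate_embryo(spec: EmbryoSpec, embryo_id: str = "embryo") -> EmbryoSeries:
    """Generate one embryo from a spec; deterministic for a fixed seed.

    Nuclei are placed on two AP-parallel arcs at signed lateral offsets
    ±(fraction × width) around the organ x-center (plus lateral jitter), AP
    positions cumulatively spaced by Normal(ap_spacing_mean, ap_spacing_sd)
    draws starting at the anterior tip (y = 0).  Each nucleus performs an
    isotropic Gaussian random walk sampled at ``fine_interval`` steps; all
    positions are clipped into the organ cuboid.  The side convention
    matches the analysis default (ventral view): left arcs sit at
    x > midline, right arcs at x < midline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    preset = spec.preset
    mid_x = spec.organ_max_width / 2.0
    mid_z = spec.organ_depth / 2.0

    # Per-5-min-step SD rescaled to the actual sampling interval so the
    # walk's diffusivity is interval-independent.
    step_sd = preset.migration_step_sd * np.sqrt(spec.fine_interval / 5.0)
    t_fine = np.arange(0.0, spec.fine_duration + 1e-9, spec.fine_interval)

    frames = []
    tracks = []
    for side, sign, frac in (
        ("L", +1.0, preset.midline_distance_fraction_left),
        ("R", -1.0, preset.midline_distance_fraction_right),
    ):
        half_mean = preset.nuclei_count_mean / 2.0
        half_sd = preset.nuclei_count_sd / np.sqrt(2.0)
        n = max(MIN_NUCLEI_PER_SIDE, int(round(rng.normal(half_mean, half_sd))))
        spacing = rng.normal(preset.ap_spacing_mean, preset.ap_spacing_sd, size=n)
        y0 = np.cumsum(spacing)
        x0 = mid_x + sign * frac * spec.organ_max_width + rng.normal(
            0.0, preset.lateral_jitter_sd, size=n
        )
        z0 = np.full(n, mid_z)
        start = np.column_stack([x0, y0, z0])

        steps = rng.normal(0.0, step_sd, size=(n, len(t_fine) - 1, 3)) if step_sd > 0 else \
            np.zeros((n, len(t_fine) - 1, 3))
        walk = np.concatenate(
            [np.zeros((n, 1, 3)), np.cumsum(steps, axis=1)], axis=1
        )
        pos = start[:, None, :] + walk  # (n, t, 3)
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([spec.organ_max_width, spec.organ_length, spec.organ_depth])
        pos = np.clip(pos, lo, hi)

        ids = [f"{embryo_id}_{side}{i + 1:02d}" for i in range(n)]
        for i, nid in enumerate(ids):
            for k, t in enumerate(t_fine):
                tracks.append((embryo_id, nid, float(t), *pos[i, k]))
            for label in TIMEPOINT_LABELS:
                tmin = TIMEPOINT_MINUTES[label]
                xyz = [np.interp(tmin, t_fine, pos[i, :, ax]) for ax in range(3)]
                frames.append((embryo_id, nid, label, *xyz))

    nuclei = pd.DataFrame(frames, columns=NUCLEUS_COLUMNS)
    track_df = pd.DataFrame(tracks, columns=TRACK_COLUMNS)
    return EmbryoSeries(
        embryo_id=embryo_id,
        nuclei=nuclei,
        tracks=track_df,
        mesh_vertices=_organ_corners(spec),
        merge_point=(mid_x, spec.organ_length / 2.0, mid_z),
        spec=spec,
    )


def generate_cohort(spec: EmbryoSpec, n_embryos: int, seed: int | None = None) -> list[EmbryoSeries]:
    """Generate independent embryos with derived per-embryo seeds.

    ``seed`` defaults to ``spec.seed``; each embryo's own seed is spawned
    from it with :class:`numpy.random.SeedSequence`, so cohorts are
    reproducible and embryos mutually independent.
    """
    if n_embryos < 1:
        raise ValidationError(f"n_embryos={n_embryos} violates n_embryos >= 1")
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = root.spawn(n_embryos)
    cohort = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        espec = dataclasses.replace(spec, seed=child_seed)
        cohort.append(generate_embryo(espec, embryo_id=f"{spec.preset.name}_e{i + 1:02d}"))
    return cohort


def generate_laterality_sample(
    p_normal: float,
    p_inverse: float,
    p_none: float,
    n: int,
    seed: int,
    overlap_halfwidth_um: float = 2.0,
    max_offset_um: float = 15.0,
) -> list[tuple[float, str]]:
    """Draw (joint_x offset µm, true category) pairs for laterality scoring.

    The scored quantity is the lateral offset of the proventriculus–AMG
    joint from the midline: negative (left of midline) for the normal
    situs, positive for inverse, and within ±overlap_halfwidth_um for
    no-laterality embryos whose joint overlaps the midline.
    """
    probs = np.array([p_normal, p_inverse, p_none], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"category probabilities {probs.tolist()} must be >= 0 and sum to 1"
        )
    if n < 0:
        raise ValidationError("n must be >= 0")
    if overlap_halfwidth_um < 0:
        raise ValidationError("overlap_halfwidth_um must be >= 0")
    rng = np.random.default_rng(seed)
    cats = rng.choice(["normal", "inverse", "no_laterality"], size=n, p=probs)
    out: list[tuple[float, str]] = []
    for cat in cats:
        if cat == "no_laterality":
            off = rng.uniform(-overlap_halfwidth_um, overlap_halfwidth_um)
        else:
            mag = rng.uniform(overlap_halfwidth_um + 0.5, overlap_halfwidth_um + max_offset_um)
            off = -mag if cat == "normal" else mag
        out.append((float(off), str(cat)))
    return out
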