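# Methods

## Coordinate frame and reference geometry

All coordinates are in µm with y the anterior→posterior (AP) axis
(posterior increasing), x lateral, z depth; acquisition is assumed to have
aligned the embryo's AP axis to y, and no rotational fitting is performed.
The per-embryo reference frame has two elements:

- **Bounding cuboid.** The axis-aligned min/max box of the organ
  representation.  When a surface model is available its vertex cloud
  defines the box; otherwise the T4 nuclei do.  The x-extent is the
  *maximal organ width* `W`, the denominator of all percentage metrics.
  The cuboid is computed once from the T4 state and reused for T1–T3, so
  the normalization denominator is constant within an embryo (the midline
  is defined retrospectively from T4; we apply the same retrospective rule
  to the cuboid for consistency).
- **Midline.** An AP-parallel line (direction exactly +y) through the
  *merge point* — the point where the left and right visceral-muscle
  sheets meet at T4.  The perpendicular distance of a nucleus at
  (x, y, z) is therefore `hypot(x − mx, z − mz)`, independent of y.  One
  midline per embryo, used for all timepoints.

The merge point is taken from, in order of precedence: the analysis
config, the embryo's own metadata (the generator records its true organ
center), or an estimate from the T4 nuclei — the midpoint, in x and z, of
the two medial-most points after a provisional split at the cuboid
x-center.  The estimate is a fallback only: when the two sides sit at
*different* fractional distances (LINC-like embryos) a nuclei-derived
midline is biased toward the shifted side and would smear a one-sided
effect onto both sides, so configured/recorded merge points always win.

Side assignment uses the sign of x − mx; the default convention (ventral
view) labels x < mx as *right* and x > mx as *left*, with a `flip_sides`
flag for mirrored orientations.  Nuclei exactly on the midline are
tie-flagged, excluded from per-side statistics, and counted in the log.

The analysis region is the half-open window [40, 80) µm posterior of the
anterior tip (minimum y of the organ representation, overridable).
Half-openness is a deliberate tie-break so a nucleus exactly at 40 µm
belongs to exactly one of the anterior/posterior regions.

## Metrics

**Normalized midline distance** is the per-side mean of
`100·d_i/W`.  **Collectivity** links each nucleus to its 3D-nearest
*strictly* more-posterior same-side neighbor; equal-y candidates are
excluded (ties in distance break to the smallest nucleus id, a
determinism device only — exact float ties essentially never occur in
data); unordered pairs are deduplicated so each measured link counts
once; the mean link length is reported as `100·mean/W`.  Both metrics are
invariant to y-translation and uniform scaling and equivariant under
reflection about the midline (left/right values swap exactly); these are
tested properties, and the collectivity implementation is checked for
exact pair-set agreement against an independent O(n²) brute force.

**Migration path length** sums segment lengths of the fine-sampled track
over a window (default: 30 min from T1 at 5-min sampling).  The default
projection is xy because nuclear paths are traced on maximum-intensity
projections of the movies; full-3D (`xyz`) is an option and is never
shorter than xy.  The window length is configurable
(`path_window_minutes`) rather than fixed, because reported tracking
windows vary between 10 and 30 min; results are labelled with the
window-start timepoint, one value per side per embryo.  Sides and region
membership for tracks are judged at the window-start position.

Empty sides, single-nucleus sides, and all-equal-y configurations yield
*missing* values (omitted rows), never zeros — a zero would bias cohort
averages downward.  Every exclusion (region filter, midline ties, short
tracks, empty sides) is logged with counts.

## Statistics

Cohort cells (side × timepoint × metric) aggregate per-embryo means —
never pooled nuclei — as mean ± SD with divisor n (population SD,
matching the spreadsheet convention the workflow replaces; divisor n−1 is
an option).  Two cohorts are compared per cell with a two-sided F-test of
variance equality; if its p ≥ `alpha_variance` (default 0.05) the
equal-variance two-sample t-test is used, otherwise Welch's.  The variant
actually used is recorded in each result.  The tests are two-sample, not
paired: the compared units are different embryos of different genotypes,
so no pairing exists.  No multiple-testing correction is applied by
default (a Bonferroni option exists).  Degenerate zero-variance cells are
handled explicitly: identical constant groups give t = 0, p = 1; constant
groups with different means give p = 0.

Laterality is scored from the lateral offset of the proventriculus–AMG
joint: offset < −h → normal (joint left of the midline), > +h → inverse,
|offset| ≤ h → no laterality, with overlap half-width h (default 2 µm).
Phenotype frequencies are compared with a Pearson χ² against expected
counts derived from control proportions rescaled to the test group's
total, df = categories − 1; a category with zero expected count is merged
into its neighbor with a warning.

The Monte-Carlo type-I error of the full F-gated t-test under a Normal
null (n = 10 per group) is computed by the acceptance script and sits at
the nominal 5% within sampling error.

## Synthetic embryos

The generator emulates the statistical structure the analysis assumes,
not images: each side is a file of nuclei at lateral offset
±(fraction × W) from the organ center with Gaussian lateral jitter, AP
positions cumulatively spaced by Normal(spacing_mean, spacing_sd) draws
from the anterior tip, z at the organ mid-depth, and per-nucleus isotropic
Gaussian random walks (per-axis SD `migration_step_sd` per 5-min step,
rescaled by √(Δt/5) for other sampling intervals).  All positions are
clipped to the organ cuboid.  Frames at T1–T4 (0/10/20/30 min) are the
walk's states at those times; the organ surface is stood in by the
cuboid's 8 corner vertices (synthetic; the pipeline consumes surfaces
only as vertex clouds), so cuboid fitting recovers the true width and
zero-noise parameter recovery is exact.

Preset parameters:

| parameter | wildtype | dlp_like | linc_like | basis |
|---|---|---|---|---|
| fraction left / right (of W) | 0.30 / 0.30 | 0.20 / 0.20 | 0.30 / 0.20 | free; mutants shift ≥0.08·W toward the midline, LINC-like on the right only |
| AP spacing mean ± sd (µm) | 10 ± 2 | 15 ± 3 | 10 ± 2 | dispersal ×1.5 in dlp-like |
| lateral jitter sd (µm) | 2 | 2 | 2 | free |
| migration step sd (µm / 5 min) | 0.5 | 1.0 | 0.5 | augmented migration in dlp-like |
| nuclei per embryo | 20.1 ± 4.8 | same | same | reported per-embryo average |

Counts are drawn per side as round(Normal(mean/2, sd/√2)) truncated at
≥3.  Organ defaults (length 100 µm, width 50 µm, depth 30 µm) are free
parameters chosen so the 40–80 µm window holds roughly half the nuclei
(~4 per side); no absolute organ dimensions are reported for real
embryos.  Cohorts derive per-embryo seeds from a root `SeedSequence`, so
everything is reproducible and byte-identical across reruns.

What the generator does **not** emulate: curved organ surfaces (the
midline of a real AMG is anchored to anatomy, not a box center), nuclear
volume exclusion and cohesion mechanics, z-structure of the muscle sheet,
tracking noise and missed detections, and inter-embryo size variation
beyond the count draw.  Passing tests therefore demonstrate that the
*measurement and inference machinery* is correct and well-powered for
effects of the stated sizes — not that real cohorts will show those
effect sizes.

## Numerical and design choices

- Percent metrics are exact ratios of float64 quantities; no rounding is
  applied before output, and tables are written at full repr precision so
  write→read round trips are lossless.
- The collectivity search is an O(n²) scan (n ≤ a few dozen per side);
  no spatial index is warranted at this scale.
- The distance oracle in tests uses dense line sampling; agreement is
  required to 1e-6 µm, far below any biological scale.
- Determinism: all randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; outputs embed the seed and
  a sha256-derived config hash; JSON is written with sorted keys.
- Validation errors name the violated invariant; file-format errors name
  the missing column or the offending row.

## Study sizes used in validation

Replicate-study validation uses 10 embryos per cohort (the conventional
cohort size for this assay) with 100 replicate studies for contrast
detection rates, 10,000 Monte-Carlo draws for type-I error, 500 random
configurations for the collectivity oracle, and 1,000 cases for the
distance oracle.

## Known limitations

- The merge-point estimator assumes roughly symmetric medial extremes; on
  strongly one-sided data supply the merge point explicitly.
- `estimate_merge_point` and the region filter operate on the supplied
  frame only; no temporal smoothing or track-based imputation is done.
- The χ² test uses the asymptotic distribution; very small cohorts (n of
  a few) should be interpreted with care, as in any frequency test.
- The pipeline assumes AP alignment upstream; gross misalignment inflates
  the apparent width and deflates percentage metrics.
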