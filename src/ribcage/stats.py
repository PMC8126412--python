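"""Cohort aggregation, F-gated two-sample t-tests, χ² and laterality calls.

Statistics follow the spreadsheet workflow used to analyze the original
embryo cohorts: per-embryo means are first averaged within a genotype
(mean ± population SD, divisor n), then genotypes are compared with a
two-sided F-test of variance equality that gates the choice between the
equal-variance and Welch two-sample t-tests.  Laterality phenotypes
(normal / inverse / no laterality, from the lateral offset of the
proventriculus–AMG joint) are compared against control frequencies with a
Pearson χ² test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

LATERALITY_CATEGORIES = ("normal", "no_laterality", "inverse")


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test."""

    test: str  # "f_test" | "t_test" | "chi_square"
    statistic: float
    df: tuple
    p: float
    variant: str = "n/a"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "variant": self.variant,
        }


def summarize_cohort(
    metrics: pd.DataFrame | list[pd.DataFrame],
    genotype: str,
    sd_convention: str = "population",
) -> pd.DataFrame:
    """Mean ± SD of per-embryo values per (side, timepoint, metric).

    The averaged unit is the embryo (its per-embryo mean), never pooled
    nuclei.  SD uses divisor n ("population") by default; "sample"
    (divisor n−1) is available.  Missing per-embryo values were never
    emitted as rows, so n_embryos reflects embryos contributing a value.
    """
    if isinstance(metrics, list):
        metrics = pd.concat(metrics, ignore_index=True) if metrics else pd.DataFrame(
            columns=["embryo_id", "side", "timepoint", "metric", "value", "n_nuclei"]
        )
    if sd_convention not in ("population", "sample"):
        raise ValidationError(f"sd_convention must be 'population' or 'sample', got {sd_convention!r}")
    ddof = 0 if sd_convention == "population" else 1
    rows = []
    for (side, tp, metric), grp in metrics.groupby(["side", "timepoint", "metric"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
        rows.append((genotype, side, tp, metric, float(np.mean(vals)), sd, int(vals.size)))
    return pd.DataFrame(
        rows, columns=["genotype", "side", "timepoint", "metric", "mean", "sd", "n_embryos"]
    )


def f_test_two_sided(a, b) -> StatResult:
    """Two-sided F-test of variance equality (spreadsheet F.TEST convention)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("F-test requires at least 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    if va == 0.0 and vb == 0.0:
        return StatResult("f_test", 1.0, (dfa, dfb), 1.0)
    if vb == 0.0 or va == 0.0:
        return StatResult("f_test", float("inf") if vb == 0 else 0.0, (dfa, dfb), 0.0)
    f = va / vb
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return StatResult("f_test", float(f), (dfa, dfb), float(min(p, 1.0)))


def compare_cohorts(a, b, alpha_variance: float = 0.05) -> tuple[StatResult, StatResult]:
    """F-test, then the F-gated two-sided two-sample t-test.

    The equal-variance t-test is used when the F-test does not reject
    variance equality at ``alpha_variance`` (default 0.05); otherwise the
    unequal-variance (Welch) variant.  Returns (f_result, t_result).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    fres = f_test_two_sided(a, b)
    equal_var = fres.p >= alpha_variance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance degenerate groups
        t = sps.ttest_ind(a, b, equal_var=equal_var)
    stat, p, df = float(t.statistic), float(t.pvalue), float(t.df)
    if np.isnan(stat):  # both groups constant and equal
        stat, p = 0.0, 1.0
    variant = "equal-variance" if equal_var else "unequal-variance"
    return fres, StatResult("t_test", stat, (df,), p, variant)


def chi_square_frequencies(observed, expected_from) -> StatResult:
    """Pearson χ² of observed category counts against control proportions.

    ``expected_from`` are the control genotype's counts; they are rescaled
    to the observed total.  df = categories − 1.  A category with zero
    expected count is merged into its neighbor (with a warning) so the
    statistic stays defined.
    """
    obs = np.asarray(observed, dtype=float)
    ctl = np.asarray(expected_from, dtype=float)
    if obs.shape != ctl.shape or obs.ndim != 1:
        raise ValidationError("observed and control counts must be 1-D and the same length")
    if obs.sum() <= 0 or ctl.sum() <= 0:
        raise ValidationError("zero total count")
    if (obs < 0).any() or (ctl < 0).any():
        raise ValidationError("counts must be non-negative")
    expected = ctl / ctl.sum() * obs.sum()
    while (expected == 0).any() and expected.size > 1:
        k = int(np.flatnonzero(expected == 0)[0])
        j = k - 1 if k > 0 else k + 1
        warnings.warn(
            f"merging category {k} (expected count 0) into category {j}", stacklevel=2
        )
        keep = np.ones(expected.size, dtype=bool)
        keep[k] = False
        expected[j] += expected[k]
        obs[j] += obs[k]
        expected, obs = expected[keep], obs[keep]
    res = sps.chisquare(obs, expected)
    df = obs.size - 1
    return StatResult("chi_square", float(res.statistic), (df,), float(res.pvalue))


def classify_laterality(joint_x_offset_um: float, overlap_halfwidth_um: float = 2.0) -> str:
    """Score a laterality phenotype from the joint's lateral offset.

    Joint left of the midline (offset < −halfwidth) → normal; right
    (offset > +halfwidth) → inverse; overlapping the midline → no
    laterality.  The sign convention follows the geometry module's default
    side convention (flip upstream if the view is mirrored).
    """
    if overlap_halfwidth_um < 0:
        raise ValidationError("overlap_halfwidth_um must be >= 0")
    off = float(joint_x_offset_um)
    if abs(off) <= overlap_halfwidth_um:
        return "no_laterality"
    return "normal" if off < 0 else "inverse"


@dataclass
class ComparisonReport:
    """All F/t results of one cohort-vs-cohort comparison."""

    genotype_a: str
    genotype_b: str
    alpha_variance: float
    cells: dict = field(default_factory=dict)  # (side, timepoint, metric) -> dict

    def to_dict(self) -> dict:
        out = {
            "genotype_a": self.genotype_a,
            "genotype_b": self.genotype_b,
            "alpha_variance": self.alpha_variance,
            "comparisons": {},
        }
        for key, cell in sorted(self.cells.items()):
            out["comparisons"]["/".join(map(str, key))] = cell
        return out


def compare_metric_tables(
    a: pd.DataFrame,
    b: pd.DataFrame,
    genotype_a: str = "a",
    genotype_b: str = "b",
    alpha_variance: float = 0.05,
    bonferroni: bool = False,
) -> ComparisonReport:
    """Run compare_cohorts per (side, timepoint, metric) cell present in both.

    Cells with fewer than 2 embryos on either side are skipped (logged in
    the report as "skipped").  With ``bonferroni`` the t-test p-values gain
    an adjusted value multiplied by the number of compared cells (off by
    default — the original workflow applies no correction).
    """
    report = ComparisonReport(genotype_a, genotype_b, alpha_variance)
    key_cols = ["side", "timepoint", "metric"]
    keys = sorted(
        set(map(tuple, a[key_cols].drop_duplicates().to_numpy()))
        & set(map(tuple, b[key_cols].drop_duplicates().to_numpy()))
    )
    cells = {}
    for key in keys:
        side, tp, metric = key
        va = _cell_values(a, side, tp, metric)
        vb = _cell_values(b, side, tp, metric)
        if va.size < 2 or vb.size < 2:
            cells[key] = {"skipped": f"n_a={va.size}, n_b={vb.size} (need >= 2 per group)"}
            continue
        fres, tres = compare_cohorts(va, vb, alpha_variance=alpha_variance)
        cells[key] = {
            "n_a": int(va.size),
            "n_b": int(vb.size),
            "mean_a": float(np.mean(va)),
            "mean_b": float(np.mean(vb)),
            "f_test": fres.to_dict(),
            "t_test": tres.to_dict(),
        }
    if bonferroni:
        m = sum(1 for c in cells.values() if "t_test" in c)
        for c in cells.values():
            if "t_test" in c:
                c["t_test"]["p_bonferroni"] = min(1.0, c["t_test"]["p"] * m)
    report.cells = cells
    return report


def _cell_values(df: pd.DataFrame, side, tp, metric) -> np.ndarray:
    sub = df[(df["side"] == side) & (df["timepoint"] == tp) & (df["metric"] == metric)]
    vals = sub["value"].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]
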