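"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain Python loops (or dense
sampling), independent of the code paths in the package.
"""

from __future__ import annotations

import math


def brute_force_minmax_box(points):
    """Per-axis min/max by explicit iteration."""
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    zs = [p[2] for p in points]
    return (min(xs), max(xs), min(ys), max(ys), min(zs), max(zs))


def brute_force_line_distance(point, line_point, y_lo=-50.0, y_hi=200.0, step=1e-4):
    """Min distance to a +y line by dense sampling of line points."""
    px, py, pz = point
    lx, _, lz = line_point
    best = math.inf
    y = y_lo
    # restrict the scan to a band around the foot of the perpendicular
    y_lo = py - 1.0
    y_hi = py + 1.0
    n = int((y_hi - y_lo) / step) + 1
    for i in range(n):
        y = y_lo + i * step
        d = math.sqrt((px - lx) ** 2 + (py - y) ** 2 + (pz - lz) ** 2)
        if d < best:
            best = d
    return best


def brute_force_nearest_posterior_pairs(points, ids=None):
    """O(n^2) nearest strictly-posterior neighbor links, deduplicated.

    Returns a set of (id_a, id_b) pairs (sorted within the pair) and a dict
    pair -> distance.  Distance ties break to the smallest nucleus id.
    """
    n = len(points)
    if ids is None:
        ids = list(range(n))
    pairs = {}
    for i in range(n):
        candidates = []
        for j in range(n):
            if points[j][1] > points[i][1]:
                d = math.dist(points[i], points[j])
                candidates.append((d, str(ids[j]), j))
        if not candidates:
            continue
        candidates.sort()
        d, _, j = candidates[0]
        key = tuple(sorted((ids[i], ids[j]), key=str))
        pairs.setdefault(key, d)
    return pairs


def brute_force_collectivity_pct(points, width, ids=None):
    """Mean deduplicated link length as a percentage of width, or None."""
    pairs = brute_force_nearest_posterior_pairs(points, ids)
    if not pairs:
        return None
    return 100.0 * sum(pairs.values()) / len(pairs) / width


def brute_force_path_length(positions):
    """Sum of consecutive segment lengths."""
    total = 0.0
    for a, b in zip(positions, positions[1:]):
        total += math.dist(a, b)
    return total


def closed_form_pooled_t(a, b):
    """Equal-variance two-sample t statistic from the textbook formula."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def closed_form_welch_t(a, b):
    """Welch t statistic and Welch–Satterthwaite df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def t_two_sided_p_by_quadrature(t, df):
    """Two-sided Student-t p-value via numerical integration of the density."""
    from scipy.integrate import quad

    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def dens(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(dens, abs(t), math.inf, epsabs=1e-15, epsrel=1e-13)
    return 2.0 * tail


def chi2_stat_by_hand(observed, expected):
    """Pearson statistic by explicit summation."""
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))
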