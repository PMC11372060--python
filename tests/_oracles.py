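"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is written directly from first principles (enumeration,
textbook formulas, normal equations) and deliberately shares no code with
the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special as _sp


# ---------------------------------------------------------------------------
# Peak detection: exhaustive enumerator following the prominence-based
# conventions (plateau floor-midpoint, greedy-by-height distance thinning,
# full width at half prominence with linear interpolation).
# ---------------------------------------------------------------------------

def local_maxima(x):
    """Indices of strict local maxima; plateaus collapse to floor-midpoint."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def prominence_and_bases(x, p):
    """Prominence of peak p against the lower of the two flanking minima
    inside its base (window bounded by the border or a strictly higher
    sample); returns (prominence, left_base, right_base)."""
    left_base, left_min = p, x[p]
    i = p - 1
    while i >= 0 and x[i] <= x[p]:
        if x[i] < left_min:
            left_min, left_base = x[i], i
        i -= 1
    right_base, right_min = p, x[p]
    j = p + 1
    while j <= len(x) - 1 and x[j] <= x[p]:
        if x[j] < right_min:
            right_min, right_base = x[j], j
        j += 1
    return x[p] - max(left_min, right_min), left_base, right_base


def width_at_half_prominence(x, p):
    """Full width of peak p at half its prominence, interpolated."""
    prom, lb, rb = prominence_and_bases(x, p)
    h = x[p] - 0.5 * prom
    i = p
    while i > lb and x[i] > h:
        i -= 1
    left_ip = float(i)
    if x[i] < h:
        left_ip = i + (h - x[i]) / (x[i + 1] - x[i])
    j = p
    while j < rb and x[j] > h:
        j += 1
    right_ip = float(j)
    if x[j] < h:
        right_ip = j - (h - x[j]) / (x[j - 1] - x[j])
    return right_ip - left_ip


def thin_by_distance(positions, heights, min_distance):
    """Iteratively keep the highest remaining peak and drop any other peak
    closer than min_distance samples (ties: later index has priority)."""
    positions = list(positions)
    heights = list(heights)
    order = list(np.argsort(heights, kind="stable"))[::-1]
    keep = [True] * len(positions)
    for k in order:
        if not keep[k]:
            continue
        for m in range(len(positions)):
            if m != k and keep[m] and abs(positions[m] - positions[k]) < min_distance:
                keep[m] = False
    return [p for p, kp in zip(positions, keep) if kp]


def brute_find_peaks(x, min_distance=1, min_height=None, min_width=None):
    """Reference peak finder: enumerate maxima, filter by height, thin by
    distance, then filter by width at half prominence."""
    x = list(map(float, x))
    cand = local_maxima(x)
    if min_height is not None:
        cand = [p for p in cand if x[p] >= min_height]
    cand = sorted(thin_by_distance(cand, [x[p] for p in cand], min_distance))
    if min_width is not None:
        cand = [p for p in cand if width_at_half_prominence(x, p) >= min_width]
    return cand


# ---------------------------------------------------------------------------
# Exact hypergeometric right tail via integer enumeration.
# ---------------------------------------------------------------------------

def fisher_right_enum(a, b, c, d):
    """P(X >= a) for fixed margins, by exact summation of hypergeometric
    point masses computed with integer binomials."""
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n_total, col1)
    hi = min(row1, col1)
    num = sum(
        math.comb(row1, x) * math.comb(n_total - row1, col1 - x)
        for x in range(a, hi + 1)
    )
    return num / denom


def hypergeom_tail_table(n_total, row1, col1):
    """All right-tail probabilities P(X >= a) for a = a_min..a_max at fixed
    margins, as (a_values, tails)."""
    a_min = max(0, row1 + col1 - n_total)
    a_max = min(row1, col1)
    denom = math.comb(n_total, col1)
    pmf_num = [
        math.comb(row1, x) * math.comb(n_total - row1, col1 - x)
        for x in range(a_min, a_max + 1)
    ]
    tails = []
    running = 0
    for v in reversed(pmf_num):
        running += v
        tails.append(running / denom)
    tails.reverse()
    return list(range(a_min, a_max + 1)), tails


# ---------------------------------------------------------------------------
# Textbook two-sample statistics (formulas + scipy.special CDFs only).
# ---------------------------------------------------------------------------

def _f_sf(stat, d1, d2):
    # survival of F(d1, d2) via the regularized incomplete beta function
    return float(_sp.betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * stat)))


def _t_sf2(t, df):
    # two-sided tail of Student's t via scipy.special.stdtr
    return float(2.0 * (1.0 - _sp.stdtr(df, abs(t))))


def levene_oracle(a, b):
    """Classic Levene W on absolute deviations from the group mean."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    na, nb = len(a), len(b)
    n = na + nb
    zbar = (za.sum() + zb.sum()) / n
    between = na * (za.mean() - zbar) ** 2 + nb * (zb.mean() - zbar) ** 2
    within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    w = (n - 2) * between / within
    return w, _f_sf(w, 1, n - 2)


def student_oracle(a, b):
    """Pooled-variance two-sided t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, _t_sf2(t, na + nb - 2)


def welch_oracle(a, b):
    """Welch's t with Welch-Satterthwaite degrees of freedom, two-sided."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, _t_sf2(t, df)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, by hand.
# ---------------------------------------------------------------------------

def bh_oracle(pvals, q):
    """Step-up adjusted p-values and discovery flags."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj, adj <= q


# ---------------------------------------------------------------------------
# OLS polynomial fit via raw normal equations.
# ---------------------------------------------------------------------------

def polyfit_normal_equations(t, y, degree):
    """Lowest-order-first coefficients from the monomial normal equations."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    design = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef
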