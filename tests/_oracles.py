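"""Independent brute-force reference implementations used by the test suite.

Each function recomputes a quantity by direct enumeration or the naive
O(n)/O(L) algorithm, deliberately avoiding the package's vectorised code
paths, so agreement is a genuine cross-check.
"""

from itertools import combinations

import numpy as np


def occupancy_brute(row) -> int:
    """Count genomes with at least one member by explicit iteration."""
    n = 0
    for cell in row:
        if cell >= 1:
            n += 1
    return n


def circular_distance_brute(pos: int, ori: int, L: int) -> int:
    """Shortest way around the circle, by walking both directions."""
    cw = (pos - ori) % L
    ccw = (ori - pos) % L
    return min(cw, ccw)


def half_label_brute(pos: int, ori: int, L: int, ter: int | None = None) -> str:
    """O(L)-style nearest-arc half assignment for one position.

    Walk clockwise from ori to ter (antipode when ter is None) labelling the
    first half of the walk upper, then the same anticlockwise; tie indices
    (exactly at an arc midpoint) go lower.
    """
    if ter is None:
        d = circular_distance_brute(pos, ori, L)
        return "upper" if 4 * d < L else "lower"
    arc_cw = (ter - ori) % L
    arc_ccw = L - arc_cw
    step_cw = (pos - ori) % L
    if step_cw < arc_cw:  # on the clockwise replichore
        return "upper" if 2 * step_cw < arc_cw else "lower"
    step_ccw = (ori - pos) % L
    return "upper" if 2 * step_ccw < arc_ccw else "lower"


def sliding_mean_brute(values, window: int, circular: bool = True):
    """Centred moving average by explicit per-position index arithmetic."""
    x = list(map(float, values))
    n = len(x)
    left = window // 2
    out = []
    for i in range(n):
        idx = range(i - left, i - left + window)
        if circular:
            vals = [x[j % n] for j in idx]
        else:
            vals = [x[j] for j in idx if 0 <= j < n]
        out.append(sum(vals) / len(vals))
    return out


def chi2_gof_brute(upper: int, lower: int, e_up: float, e_lo: float) -> float:
    """Sum of (O-E)^2/E over the two cells."""
    return (upper - e_up) ** 2 / e_up + (lower - e_lo) ** 2 / e_lo


def ranksum_exact_p_brute(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of group labellings.

    Uses midranks so tied data are handled the same way the test statistic
    defines them; feasible for n+m up to ~12.
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    obs = sum(ranks[:n])
    mean = n * (n + m + 1) / 2
    count = 0
    total = 0
    for combo in combinations(range(n + m), n):
        s = sum(ranks[i] for i in combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def quantile_brute(values, q: float) -> float:
    """Linear interpolation between order statistics at position (n-1)*q."""
    v = sorted(values)
    pos = (len(v) - 1) * q
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
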