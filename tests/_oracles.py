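"""Independent oracles used by the test suite.

Everything here is deliberately naive and self-contained — exhaustive
dynamic programming, explicit path intersection, numerical quadrature —
so the implementations under test are checked against code that shares
nothing with them.
"""

from __future__ import annotations

import math


def gotoh_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    mode: str = "local",
) -> float:
    """Exhaustive affine-gap alignment score (Gotoh three-state DP).

    ``gap_open`` is the score of the first gap column and ``gap_extend``
    of each further column.  ``mode`` is "local" (Smith-Waterman, floor
    at zero) or "global" (Needleman-Wunsch with end gaps charged).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    local = mode == "local"
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    if local:
        for i in range(n + 1):
            M[i][0] = 0.0
        for j in range(m + 1):
            M[0][j] = 0.0
    else:
        for i in range(1, n + 1):
            X[i][0] = gap_open + gap_extend * (i - 1)
        for j in range(1, m + 1):
            Y[0][j] = gap_open + gap_extend * (j - 1)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if local:
                diag = max(diag, 0.0)
            M[i][j] = diag + s
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) + gap_open,
                X[i - 1][j] + gap_extend,
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) + gap_open,
                Y[i][j - 1] + gap_extend,
            )
            if local and M[i][j] > best:
                best = M[i][j]
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


def brute_force_lca(parent: dict[int, int], taxa: set[int]) -> int:
    """LCA by explicit root-path intersection, deepest common element."""

    def path(t: int) -> list[int]:
        out = [t]
        while parent[out[-1]] != out[-1]:
            out.append(parent[out[-1]])
        return out

    paths = [path(t) for t in taxa]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest = largest root distance
    def depth(t: int) -> int:
        d = 0
        while parent[t] != t:
            t = parent[t]
            d += 1
        return d

    return max(common, key=depth)


def chi2_sf_quadrature(x: float, tol: float = 1e-12) -> float:
    """Survival function of the chi-square df=1 density by quadrature.

    Integrates f(t) = exp(-t/2) / sqrt(2 pi t) from x to infinity,
    independently of any library chi-square routine.
    """
    from scipy.integrate import quad

    if x <= 0:
        return 1.0
    density = lambda t: math.exp(-t / 2.0) / math.sqrt(2.0 * math.pi * t)
    val, _ = quad(density, x, math.inf, epsabs=tol, epsrel=tol)
    return val
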