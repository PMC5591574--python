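"""Independent reference implementations used only by the test suite.

These evaluate the warping recurrences directly by memoized recursion over
the predecessor DAG — an exhaustive minimisation over every admissible warp
path — with none of the vectorised table-filling of the package code.
"""

from functools import lru_cache

import numpy as np


def _steps(M):
    return [(1, m) for m in range(1, M + 1)] + [(m, 1) for m in range(2, M + 1)]


def dtw_oracle(A, B, M):
    """Recursive evaluation of the time-warping dissimilarity.

    Cell cost compares fixed one-step increments; the recursion minimises
    over the step set with predecessors clamped at the first sample.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    steps = _steps(M)

    def inc(x, i, ip):
        return x[i] - x[ip]

    @lru_cache(maxsize=None)
    def tau(i, j):
        if i == 0 and j == 0:
            return 0.0
        cost = float(np.abs(inc(a, i, max(i - 1, 0))
                            - inc(b, j, max(j - 1, 0))).sum())
        omega = min(tau(max(i - ca, 0), max(j - cb, 0)) for ca, cb in steps)
        return cost + omega

    return tau(len(a) - 1, len(b) - 1)


def dpw_oracle(A, B, M):
    """Recursive evaluation of the positional-warping dissimilarity.

    Increments are taken relative to the predecessor selected by each warp
    step, and the recursion minimises increment cost plus predecessor cost
    jointly over the step set.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    steps = _steps(M)

    @lru_cache(maxsize=None)
    def tau(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = None
        for ca, cb in steps:
            ip, jp = max(i - ca, 0), max(j - cb, 0)
            cost = float(np.abs((a[i] - a[ip]) - (b[j] - b[jp])).sum())
            cand = cost + tau(ip, jp)
            if best is None or cand < best:
                best = cand
        return best

    return tau(len(a) - 1, len(b) - 1)


def haar_cwt_oracle(signal, scale):
    """Direct inner-product Haar coefficients with reflection padding."""
    s = np.asarray(signal, dtype=float)
    h = scale // 2
    padded = np.pad(s, h, mode="reflect")
    out = np.empty(len(s))
    for b in range(len(s)):
        first = sum(padded[b + k] for k in range(h))
        second = sum(padded[b + h + k] for k in range(h))
        out[b] = (second - first) / np.sqrt(scale)
    return out
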