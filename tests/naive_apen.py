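"""Naive triple-loop approximate-entropy reference.

Independent oracle for the optimised distance-matrix implementation: plain
Python loops straight from the defining formulas, with no shared code.
O(N^2 m) per call, fine at test sizes.
"""

import math


def naive_chebyshev(u, i, j, k):
    return max(abs(u[i + t] - u[j + t]) for t in range(k))


def naive_phi(u, k, r):
    n = len(u)
    n_vec = n - k + 1
    total = 0.0
    for i in range(n_vec):
        count = 0
        for j in range(n_vec):
            if naive_chebyshev(u, i, j, k) <= r:
                count += 1
        total += math.log(count / n_vec)
    return total / n_vec


def naive_apen(u, m, r):
    u = list(map(float, u))
    return naive_phi(u, m, r) - naive_phi(u, m + 1, r)


def naive_correlation_integral(u, i, k, r):
    """C_i^k(r) with 1-based i, counting the self-match."""
    u = list(map(float, u))
    n_vec = len(u) - k + 1
    count = sum(1 for j in range(n_vec) if naive_chebyshev(u, i - 1, j, k) <= r)
    return count / n_vec
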