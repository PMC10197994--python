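"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with naive algorithms, separate from
the package's implementations.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def naive_smith_waterman_affine(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Textbook three-matrix affine-gap local alignment score.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                Ix[i - 1][j - 1] + s,
                Iy[i - 1][j - 1] + s,
            )
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                Ix[i - 1][j] - gap_extend,
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Iy[i][j - 1] - gap_extend,
            )
            best = max(best, M[i][j])
    return best


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf using exact
    integer binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def reachability_closure(n_nodes: int, edges: list[tuple[int, int]]):
    """Transitive closure by Floyd-Warshall-style boolean relaxation."""
    reach = [[False] * n_nodes for _ in range(n_nodes)]
    for i, j in edges:
        reach[i][j] = True
    for k in range(n_nodes):
        for i in range(n_nodes):
            if reach[i][k]:
                for j in range(n_nodes):
                    if reach[k][j]:
                        reach[i][j] = True
    return reach
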