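"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: costs are found by
exhaustively enumerating every admissible monotone corner-to-corner path on
the (N, M) grid with steps {(1,0), (0,1), (1,1)} and symmetric weights
(1, 2, 1), accumulating |ref_i - query_j| along the way.  Feasible only for
tiny inputs (N, M <= ~7).
"""

from __future__ import annotations

import numpy as np


def enumerate_paths(n: int, m: int):
    """Yield every admissible monotone path from (0,0) to (n-1,m-1)."""

    def extend(path):
        i, j = path[-1]
        if i == n - 1 and j == m - 1:
            yield list(path)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                yield from extend(path + [(i + di, j + dj)])

    yield from extend([(0, 0)])


def path_cost(ref, query, path) -> float:
    """Symmetric (1,2,1)-weighted accumulated cost of one explicit path."""
    ref = np.asarray(ref, dtype=float)
    query = np.asarray(query, dtype=float)
    total = 2.0 * abs(ref[0] - query[0])
    for (pi, pj), (i, j) in zip(path, path[1:]):
        w = 2.0 if (i - pi, j - pj) == (1, 1) else 1.0
        total += w * abs(ref[i] - query[j])
    return total


def brute_force_dtw_cost(ref, query) -> float:
    """Minimum accumulated cost over all enumerated admissible paths."""
    return min(
        path_cost(ref, query, p) for p in enumerate_paths(len(ref), len(query))
    )
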