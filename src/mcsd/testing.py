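"""Brute-force cross-check utilities for small problem instances.

These helpers are deliberately naive and combinatorial so they share no code
path with the production solvers; they exist to validate the solvers on tiny
instances in the test suite and acceptance checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["l1_min_enumeration"]


def l1_min_enumeration(A: np.ndarray, y: np.ndarray, feastol: float = 1e-9) -> float:
    """Minimum l1 norm over solutions of ``A x = y`` by vertex enumeration.

    A minimum-l1 solution of a consistent linear system is attained at a
    basic solution whose support size does not exceed ``rank(A)``. For tiny
    systems we can therefore enumerate every column subset up to that size,
    solve the restricted least-squares problem, keep the feasible candidates
    and return the smallest l1 norm. Exponential in the number of columns —
    only use for n of order 10.
    """
    A = np.asarray(A, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    c, n = A.shape
    if np.linalg.norm(y) == 0:
        return 0.0
    r = int(np.linalg.matrix_rank(A))
    scale = max(np.linalg.norm(y), 1.0)
    best = np.inf
    for k in range(1, r + 1):
        for cols in combinations(range(n), k):
            sub = A[:, cols]
            x, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.linalg.norm(sub @ x - y) <= feastol * scale:
                best = min(best, float(np.abs(x).sum()))
    if not np.isfinite(best):
        raise ValueError("system appears inconsistent; no feasible basic solution")
    return best
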