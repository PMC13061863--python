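"""Compiled stepwise-regression inner loop.

Same algorithm as ``swlda._stepwise_python`` (reversible sweep operator on
centered cross-products with partial-F entry/removal), written as explicit
loops for numba.  Floating-point operation order matches the numpy
reference elementwise, so both engines produce identical selections; the
agreement is asserted in the test suite.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def _sweep_nb(A, k):  # pragma: no cover - exercised via stepwise_nb
    p1 = A.shape[0]
    d = A[k, k]
    row = A[k].copy()
    col = A[:, k].copy()
    for i in range(p1):
        ci = col[i]
        for j in range(p1):
            A[i, j] = A[i, j] - ci * row[j] / d
    for j in range(p1):
        A[k, j] = row[j] / d
        A[j, k] = col[j] / d
    A[k, k] = -1.0 / d


@numba.njit(cache=True)
def _unsweep_nb(A, k):  # pragma: no cover
    p1 = A.shape[0]
    d = A[k, k]
    row = A[k].copy()
    col = A[:, k].copy()
    for i in range(p1):
        ci = col[i]
        for j in range(p1):
            A[i, j] = A[i, j] - ci * row[j] / d
    for j in range(p1):
        A[k, j] = -row[j] / d
        A[j, k] = -col[j] / d
    A[k, k] = -1.0 / d


@numba.njit(cache=True)
def stepwise_nb(A, n, max_features, max_iterations, crit_enter, crit_remove):
    """Entry/removal loop; returns included column indices in entry order."""
    p = A.shape[0] - 1
    tol = 1e-10
    diag0 = np.empty(p)
    for j in range(p):
        diag0[j] = A[j, j] if A[j, j] > 1.0 else 1.0
    in_mask = np.zeros(p, dtype=np.bool_)
    cap = max_features if max_features < p else p
    order = np.empty(cap, dtype=np.int64)
    k = 0
    for _ in range(max_iterations):
        changed = False
        # entry: candidate with the largest partial F
        df2 = n - k - 2
        if k < max_features and df2 >= 1:
            sse = A[p, p]
            best_f = -1.0
            best_j = -1
            for j in range(p):
                if in_mask[j] or A[j, j] <= tol * diag0[j]:
                    continue
                ssr = A[j, p] * A[j, p] / A[j, j]
                denom = sse - ssr
                if denom < 1e-300:
                    denom = 1e-300
                f = ssr * df2 / denom
                if f > best_f:
                    best_f = f
                    best_j = j
            if best_j >= 0 and best_f > crit_enter[df2]:
                _sweep_nb(A, best_j)
                in_mask[best_j] = True
                order[k] = best_j
                k += 1
                changed = True
        # removal: drop the weakest included column while it fails p_remove
        while k > 0:
            df2 = n - k - 1
            if df2 < 1:
                break
            sse = A[p, p]
            worst_f = np.inf
            worst_i = -1
            for i in range(k):
                j = order[i]
                c = -A[j, j]
                if c < 1e-300:
                    c = 1e-300
                f = A[j, p] * A[j, p] / c / (sse / df2)
                if f < worst_f:
                    worst_f = f
                    worst_i = i
            if worst_f < crit_remove[df2]:
                j = order[worst_i]
                _unsweep_nb(A, j)
                in_mask[j] = False
                for i in range(worst_i, k - 1):
                    order[i] = order[i + 1]
                k -= 1
                changed = True
            else:
                break
        if not changed:
            break
    return order[:k].copy()
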