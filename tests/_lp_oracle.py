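"""Independent LP oracle for tiny instances: a two-phase tableau simplex.

Deliberately written from scratch (dense tableau, Bland's anti-cycling
rule) so that agreement with the package's solver is a genuine
cross-check rather than the same code called twice.  Only suitable for
the tiny instances the tests build (tens of variables).
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-9


def solve_lp(c, A, b, bounds):
    """Minimize ``c @ x`` s.t. ``A @ x <= b`` and per-variable bounds.

    ``bounds`` is a sequence of ``(lo, hi)`` with finite ``lo`` and
    ``hi`` possibly ``None`` (unbounded above).  Returns ``(x, obj)``;
    raises ``ValueError`` if infeasible, ``ArithmeticError`` if
    unbounded.
    """
    c = np.asarray(c, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(c)

    # shift lower bounds to zero: x = lo + y
    lo = np.array([bd[0] for bd in bounds], dtype=float)
    if not np.isfinite(lo).all():
        raise ValueError("oracle requires finite lower bounds")
    const = float(c @ lo)
    b_shift = b - A @ lo

    # upper bounds become extra <= rows on y
    ub_rows = []
    ub_rhs = []
    for i, bd in enumerate(bounds):
        hi = bd[1]
        if hi is not None and np.isfinite(hi):
            row = np.zeros(n)
            row[i] = 1.0
            ub_rows.append(row)
            ub_rhs.append(hi - lo[i])
    G = np.vstack([A] + ub_rows) if ub_rows else A.copy()
    h = np.concatenate([b_shift, np.asarray(ub_rhs)]) if ub_rhs else b_shift.copy()

    m = G.shape[0]
    # equality form: G y + s = h, y >= 0, s >= 0; negate rows with h < 0
    sign = np.where(h < 0, -1.0, 1.0)
    E = np.hstack([G * sign[:, None], np.diag(sign)])
    rhs = h * sign

    n_total = n + m
    # phase 1: artificial variable on every row
    T = np.hstack([E, np.eye(m)])
    basis = list(range(n_total, n_total + m))
    cost1 = np.concatenate([np.zeros(n_total), np.ones(m)])
    T, rhs, basis = _simplex(T, rhs, basis, cost1)
    if float(cost1[basis] @ rhs) > 1e-7:
        raise ValueError("infeasible")

    # drop artificial columns; pivot any artificial still in the basis out
    for r, bi in enumerate(basis):
        if bi >= n_total:
            piv = next(
                (j for j in range(n_total) if abs(T[r, j]) > _TOL), None
            )
            if piv is None:
                continue  # redundant row, harmless to keep
            _pivot(T, rhs, r, piv)
            basis[r] = piv
    keep = [r for r, bi in enumerate(basis) if bi < n_total]
    T = T[keep][:, :n_total]
    rhs = rhs[keep]
    basis = [basis[r] for r in keep]

    cost2 = np.concatenate([c, np.zeros(m)])
    T, rhs, basis = _simplex(T, rhs, basis, cost2)

    y = np.zeros(n_total)
    for r, bi in enumerate(basis):
        y[bi] = rhs[r]
    x = y[:n] + lo
    return x, float(cost2[basis] @ rhs) + const


def _pivot(T, rhs, r, j):
    piv = T[r, j]
    T[r] /= piv
    rhs[r] /= piv
    for i in range(T.shape[0]):
        if i != r and abs(T[i, j]) > 0:
            rhs[i] -= T[i, j] * rhs[r]
            T[i] -= T[i, j] * T[r]


def _simplex(T, rhs, basis, cost, max_iter=20000):
    """Primal simplex with Bland's rule on tableau ``T y = rhs``."""
    T = T.copy()
    rhs = rhs.copy()
    basis = list(basis)
    for _ in range(max_iter):
        # reduced costs
        cb = cost[basis]
        red = cost - cb @ T
        entering = next(
            (j for j in range(T.shape[1]) if red[j] < -_TOL), None
        )
        if entering is None:
            return T, rhs, basis
        # ratio test, Bland's tie-break (smallest basis index)
        best = None
        for i in range(T.shape[0]):
            if T[i, entering] > _TOL:
                ratio = rhs[i] / T[i, entering]
                if best is None or ratio < best[0] - _TOL or (
                    abs(ratio - best[0]) <= _TOL and basis[i] < basis[best[1]]
                ):
                    best = (ratio, i)
        if best is None:
            raise ArithmeticError("unbounded")
        r = best[1]
        # pivot
        piv = T[r, entering]
        T[r] /= piv
        rhs[r] /= piv
        for i in range(T.shape[0]):
            if i != r and abs(T[i, entering]) > _TOL:
                factor = T[i, entering]
                T[i] -= factor * T[r]
                rhs[i] -= factor * rhs[r]
        basis[r] = entering
    raise ArithmeticError("simplex iteration limit reached")
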