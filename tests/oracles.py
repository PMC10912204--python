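"""Independent reference implementations used to verify pipeline numerics.

Each oracle derives its answer by a different route than the package:
the QP oracle polishes an SLSQP solve through a dense KKT system; the LP
oracle enumerates basic feasible points of the flux polytope; the Shapley
oracle enumerates all 2^p feature subsets with the combinatorial weights;
the hypergeometric oracle sums binomial coefficients in exact rational
arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.optimize import minimize


def kkt_polished_qp(S, b, w, lb, ub):
    """min ||v - w||^2 s.t. S v = b, lb <= v <= ub, via SLSQP + KKT polish.

    The active bounds detected in the SLSQP solution are fixed and the
    equality-constrained optimum recomputed exactly from the dense KKT
    system, giving a machine-precision reference point.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    v = None
    res = minimize(
        lambda x: 0.5 * np.sum((x - w) ** 2),
        np.clip(w, lb, ub),
        jac=lambda x: x - w,
        method="SLSQP",
        constraints=[dict(type="eq", fun=lambda x: S @ x - b, jac=lambda x: S)],
        bounds=list(zip(lb, ub)),
        options=dict(maxiter=2000, ftol=1e-12),
    )
    if res.success and np.linalg.norm(S @ res.x - b, np.inf) < 1e-6:
        v = res.x
    else:  # fall back: only active-set detection is needed before the polish
        from scipy.optimize import Bounds, LinearConstraint

        res = minimize(
            lambda x: 0.5 * np.sum((x - w) ** 2),
            np.clip(w, lb, ub),
            jac=lambda x: x - w,
            hess=lambda x: np.eye(n),
            method="trust-constr",
            constraints=[LinearConstraint(S, b, b)],
            bounds=Bounds(lb, ub),
            options=dict(gtol=1e-10, xtol=1e-12, maxiter=3000),
        )
        assert res.constr_violation < 1e-6, f"QP oracle pre-solve failed: {res.message}"
        v = res.x
    rows, rhs = [S], [b]
    for j in range(n):
        if v[j] - lb[j] < 1e-5:
            e = np.zeros(n); e[j] = 1.0
            rows.append(e[None, :]); rhs.append([lb[j]])
        elif ub[j] - v[j] < 1e-5:
            e = np.zeros(n); e[j] = 1.0
            rows.append(e[None, :]); rhs.append([ub[j]])
    A = np.vstack(rows)
    bb = np.concatenate([np.ravel(r) for r in rhs])
    m = A.shape[0]
    kkt = np.block([[np.eye(n), A.T], [A, np.zeros((m, m))]])
    sol, *_ = np.linalg.lstsq(kkt, np.concatenate([w, bb]), rcond=None)
    return sol[:n]


def lp_max_by_vertex_enumeration(S, lb, ub, c):
    """max c.v over {S v = 0, lb <= v <= ub} by basic-feasible-point search.

    With finite bounds the polytope is bounded, so the maximum is attained at
    a point where n - rank(S) variables sit on a bound.  Enumerates all such
    candidate points.  Returns the best objective (None if infeasible).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    d = n - r
    best = None
    for fixed in combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        for pattern in range(2 ** d):
            vals = np.array(
                [lb[j] if (pattern >> i) & 1 == 0 else ub[j] for i, j in enumerate(fixed)]
            )
            rhs = -S[:, fixed] @ vals
            sol, residual, rank, _ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = vals
            v[free] = sol
            if np.linalg.norm(S @ v, np.inf) > 1e-7:
                continue
            if (v < lb - 1e-7).any() or (v > ub + 1e-7).any():
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def exact_shapley(predict, x, background, ):
    """Exact Shapley values by full subset enumeration.

    phi_j = sum_S |S|!(p-|S|-1)!/p! * (v(S u {j}) - v(S)), where v(S) is the
    mean prediction with features in S from x and the rest from each
    background row.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.shape[0]
    # cache v(S) for every subset encoded as a bitmask
    values = np.empty(2 ** p)
    for mask in range(2 ** p):
        comp = background.copy()
        for j in range(p):
            if (mask >> j) & 1:
                comp[:, j] = x[j]
        values[mask] = float(np.mean(predict(comp)))
    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for j in range(p):
        for mask in range(2 ** p):
            if (mask >> j) & 1:
                continue
            s = bin(mask).count("1")
            weight = fact[s] * fact[p - s - 1] / fact[p]
            phi[j] += weight * (values[mask | (1 << j)] - values[mask])
    return phi


def hypergeom_tails_exact(N, K, n, k):
    """(P[X >= k], P[X <= k]) for X ~ Hypergeometric(N, K, n), exact rationals."""
    denom = math.comb(N, n)
    def pmf(i):
        return Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    upper = sum((pmf(i) for i in range(max(k, lo), hi + 1)), Fraction(0))
    lower = sum((pmf(i) for i in range(lo, min(k, hi) + 1)), Fraction(0))
    return upper, lower
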