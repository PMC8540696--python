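"""Independent brute-force oracles used to verify the solvers.

These deliberately avoid the code paths they check: the constrained
least-squares oracle enumerates active sets directly (KKT: at the optimum,
each sign-constrained coefficient is either at its bound or the problem
restricted to the free columns is unconstrained-optimal), and the order
oracle enumerates every regressor subset.
"""

from itertools import combinations

import numpy as np


def constrained_lsq_oracle(phi, p, nonpos_mask):
    """Global minimum of ||phi theta - p||^2 s.t. theta[nonpos] <= 0.

    Enumerates every subset of constrained columns clamped to zero, solves
    the reduced unconstrained problem, keeps feasible candidates, and returns
    (theta, sse) of the best one.
    """
    phi = np.asarray(phi, float)
    p = np.asarray(p, float)
    constrained = [j for j, c in enumerate(nonpos_mask) if c]
    best = None
    for r in range(len(constrained) + 1):
        for clamped in combinations(constrained, r):
            free = [j for j in range(phi.shape[1]) if j not in clamped]
            theta = np.zeros(phi.shape[1])
            if free:
                sol, *_ = np.linalg.lstsq(phi[:, free], p, rcond=None)
                theta[free] = sol
            if any(theta[j] > 1e-9 for j in constrained):
                continue
            resid = p - phi @ theta
            sse = float(resid @ resid)
            if best is None or sse < best[1] - 1e-15:
                best = (theta, sse)
    assert best is not None
    return best


def exhaustive_order_oracle(problem, aic_fn, solver):
    """Minimum AIC over every regressor subset of a regression problem.

    Returns (best_aic, best_subset) with ties broken toward the smaller
    subset, then lexicographic column indices.
    """
    k = problem.n_regressors
    best = None
    for size in range(k + 1):
        for subset in combinations(range(k), size):
            fit = solver(problem.subproblem(list(subset)))
            value = aic_fn(fit.sse, fit.n, size)
            if best is None or value < best[0] - 1e-15:
                best = (value, subset)
    return best
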