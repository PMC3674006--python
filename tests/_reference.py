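"""Independent reference CP decomposition for cross-checking the ALS engine.

Minimizes the CP least-squares objective directly with scipy's L-BFGS-B
on the stacked factor vector with analytic gradients — a deliberately
different algorithmic route from the package's alternating least squares,
so agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _unpack(x, n, J, K, R):
    a = x[: n * R].reshape(n, R)
    b = x[n * R : n * R + J * R].reshape(J, R)
    c = x[n * R + J * R :].reshape(K, R)
    return a, b, c


def cp_fit_reference(tensor, rank, n_starts=3, seed=0, maxiter=5000):
    """Best-of-starts direct CP fit; returns (A, B, C, residual_ss)."""
    X = np.asarray(tensor, dtype=float)
    n, J, K = X.shape
    R = rank
    rng = np.random.default_rng(seed)

    def fun(x):
        a, b, c = _unpack(x, n, J, K, R)
        M = np.einsum("ir,jr,kr->ijk", a, b, c) - X
        f = float((M**2).sum())
        ga = 2 * np.einsum("ijk,jr,kr->ir", M, b, c)
        gb = 2 * np.einsum("ijk,ir,kr->jr", M, a, c)
        gc = 2 * np.einsum("ijk,ir,jr->kr", M, a, b)
        return f, np.concatenate([ga.ravel(), gb.ravel(), gc.ravel()])

    best = None
    for _ in range(n_starts):
        x0 = rng.standard_normal((n + J + K) * R) * 0.5
        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b, c = _unpack(best.x, n, J, K, R)
    return a, b, c, float(best.fun)
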