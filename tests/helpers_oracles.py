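"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: the natural spline
oracle is the classical truncated-power construction, the constrained fit is
a KKT solve, and the sandwich is explicit matrix arithmetic.
"""

import numpy as np


def truncated_power_ncs(x, knots):
    """Natural cubic spline columns via the truncated-power construction.

    Non-intercept columns: x and d_k(x) - d_{K-1}(x) for k = 1..K-2, where
    d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3] / (t_K - t_k).
    Together with the constant this spans the natural-spline space.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    K = len(t)

    def d(k):
        return (np.maximum(x - t[k], 0.0) ** 3 - np.maximum(x - t[K - 1], 0.0) ** 3) / (
            t[K - 1] - t[k]
        )

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def span_residual(A, B):
    """Max norm of the residual of projecting columns of A onto span(B)."""
    Q, _ = np.linalg.qr(B)
    resid = A - Q @ (Q.T @ A)
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    return float(np.max(np.linalg.norm(resid, axis=0) / scale))


def constrained_ols_kkt(X, y, constraint_row):
    """Equality-constrained least squares via the KKT system.

    Minimizes ||y - X b||^2 subject to constraint_row @ b = 0.
    """
    n, p = X.shape
    a = np.asarray(constraint_row, dtype=float)
    kkt = np.zeros((p + 1, p + 1))
    kkt[:p, :p] = 2.0 * X.T @ X
    kkt[:p, p] = a
    kkt[p, :p] = a
    rhs = np.concatenate([2.0 * X.T @ y, [0.0]])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:p]


def sandwich_hc0(X, e):
    """Explicit (X'X)^-1 X' diag(e^2) X (X'X)^-1."""
    XtXi = np.linalg.inv(X.T @ X)
    meat = X.T @ np.diag(e**2) @ X
    return XtXi @ meat @ XtXi


def central_second_derivative(f, x, h=1e-4):
    return (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2
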