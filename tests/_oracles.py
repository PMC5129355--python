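"""Independent oracles used by the test suite.

Deliberately written without touching the package internals: plain-Python
log-likelihoods, finite-difference Newton maximization, and a textbook
de Boor recursion.  These are the second route of every dual-route check.
"""

import numpy as np


# ---------------------------------------------------------------------------
# de Boor recursion (Cox - de Boor), straight from the recurrence
# ---------------------------------------------------------------------------


def deboor_basis(x, knots, degree):
    """B-spline basis by the raw recurrence; closed at the right endpoint."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    n_basis = len(t) - degree - 1
    B = np.zeros((x.size, len(t) - 1))
    for i in range(len(t) - 1):
        B[:, i] = (t[i] <= x) & (x < t[i + 1])
    # right-closure: x exactly at the last basis knot
    last = x == t[n_basis]
    if np.any(last):
        B[last, :] = 0.0
        B[last, n_basis - 1] = 1.0
    for d in range(1, degree + 1):
        Bn = np.zeros((x.size, len(t) - d - 1))
        for i in range(len(t) - d - 1):
            left = np.zeros(x.size)
            if t[i + d] > t[i]:
                left = (x - t[i]) / (t[i + d] - t[i]) * B[:, i]
            right = np.zeros(x.size)
            if t[i + d + 1] > t[i + 1]:
                right = (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * B[:, i + 1]
            Bn[:, i] = left + right
        B = Bn
    return B[:, :n_basis]


# ---------------------------------------------------------------------------
# plain negative log-likelihoods
# ---------------------------------------------------------------------------


def nll_binary(params, X, y):
    """Bernoulli-logit negative log-likelihood, P(y=1) = F(X params)."""
    total = 0.0
    for i in range(len(y)):
        eta = float(np.dot(X[i], params))
        total -= y[i] * eta - np.logaddexp(0.0, eta)
    return total


def nll_cumulative(params, X, y, K):
    """Proportional-odds nll; params = (theta_1..theta_{K-1}, beta).

    P(y <= j) = F(theta_j - x'beta).  Returns +inf for unordered thresholds
    so the optimizer stays in the valid region.
    """
    q = K - 1
    theta = np.asarray(params[:q], dtype=float)
    beta = np.asarray(params[q:], dtype=float)
    if np.any(np.diff(theta) <= 0):
        return np.inf
    total = 0.0
    for i in range(len(y)):
        w = float(np.dot(X[i], beta)) if beta.size else 0.0
        cdf = [0.0] + [1.0 / (1.0 + np.exp(-(t - w))) for t in theta] + [1.0]
        p = cdf[y[i]] - cdf[y[i] - 1]
        total -= np.log(max(p, 1e-300))
    return total


# ---------------------------------------------------------------------------
# finite-difference Newton maximizer
# ---------------------------------------------------------------------------


def _fd_grad(f, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def _fd_hess(f, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros_like(x)
        e[i] = h
        H[:, i] = (_fd_grad(f, x + e) - _fd_grad(f, x - e)) / (2.0 * h)
    return (H + H.T) / 2.0


def newton_minimize(f, x0, tol=1e-10, max_iter=200):
    """Damped Newton with purely finite-difference derivatives."""
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    for _ in range(max_iter):
        g = _fd_grad(f, x)
        H = _fd_hess(f, x)
        try:
            step = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = -g
        if np.dot(step, g) > 0:  # not a descent direction
            step = -g
        lam = 1.0
        for _ in range(60):
            xt = x + lam * step
            ft = f(xt)
            if np.isfinite(ft) and ft <= fx:
                break
            lam *= 0.5
        else:
            break
        moved = np.max(np.abs(lam * step))
        x, fx = xt, ft
        if moved < tol:
            break
    return x
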