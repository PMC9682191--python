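"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own solvers: a brute-force simplex
grid, a projected-gradient QP solver, and a standalone IRLS solver for
smoothed-l2,1 least squares.
"""

import numpy as np


def brute_force_simplex(Q, s, step=1e-3):
    """Grid search over the 3-simplex at the given resolution."""
    best, best_f = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for a in ticks:
        for b in np.arange(0.0, 1.0 - a + step / 2, step):
            c = 1.0 - a - b
            t = np.array([a, b, c])
            f = t @ Q @ t - t @ s
            if f < best_f:
                best, best_f = t, f
    return best, best_f


def projected_gradient(Q, s, iters=200000, tol=1e-14):
    """Projected gradient with Euclidean simplex projection, tight tolerance."""
    d = len(s)

    def project(v):
        u = np.sort(v)[::-1]
        css = np.cumsum(u)
        rho = np.nonzero(u * np.arange(1, d + 1) > (css - 1))[0][-1]
        tau = (css[rho] - 1) / (rho + 1.0)
        return np.maximum(v - tau, 0.0)

    L = max(np.linalg.eigvalsh(2 * Q).max(), 1e-12)
    t = np.full(d, 1.0 / d)
    fprev = np.inf
    for _ in range(iters):
        g = 2 * Q @ t - s
        t = project(t - g / L)
        f = t @ Q @ t - t @ s
        if abs(fprev - f) < tol * max(1.0, abs(f)):
            break
        fprev = f
    return t, float(t @ Q @ t - t @ s)


def smoothed_l21_least_squares(X, Y, alpha, epsilon, iters=500, tol=1e-12):
    """IRLS for min ||W'X' + b1' - Y||^2 + alpha * sum_i sqrt(|w_i|^2 + eps).

    A self-contained fixed-point loop on the stacked single-block problem,
    used as the oracle for the frozen-theta reduction of the full model.
    Returns the converged objective value.
    """
    n, d = X.shape
    k = Y.shape[0]
    W = np.zeros((d, k))
    b = np.zeros(k)
    prev = np.inf
    for _ in range(iters):
        b = (Y.sum(axis=1) - W.T @ X.sum(axis=0)) / n
        N = 1.0 / (2.0 * np.sqrt(np.sum(W * W, axis=1) + epsilon))
        A = X.T @ X + alpha * np.diag(N)
        rhs = X.T @ (Y.T - np.outer(np.ones(n), b))
        W = np.linalg.solve(A, rhs)
        obj = (
            np.sum((W.T @ X.T + np.outer(b, np.ones(n)) - Y) ** 2)
            + alpha * np.sum(np.sqrt(np.sum(W * W, axis=1) + epsilon))
        )
        if abs(prev - obj) <= tol * max(1.0, abs(obj)):
            break
        prev = obj
    return obj


def random_model_state(data, rng, scale=1.0):
    """A ModelState with random weights/bias and a random simplex theta."""
    from agmfs.optim import _init_state

    state = _init_state(data)
    state.W = [
        rng.normal(scale=scale, size=(dv, data.n_classes)) for dv in data.dims
    ]
    state.b = rng.normal(size=data.n_classes)
    theta = rng.uniform(0.1, 1.0, size=data.total_dim)
    state.theta = theta / theta.sum()
    return state
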