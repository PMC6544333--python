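"""Cyclic coordinate-descent LASSO on precomputed Gram matrices.

Solves ``min_b (1/2N)||y_c - X_c b||^2 + penalty * ||b||_1`` using only the
centered Gram matrix ``G = X_c' X_c`` and covariance vector ``c = X_c' y_c``
(the "covariance updates" formulation).  Working on the Gram scale makes the
per-sweep cost independent of the number of observations, and lets the
rolling cross-validation grow its training window by rank-one updates
instead of refitting from raw data.  Warm starts across both the window and
the penalty grid make the expanding-window forecast loop tractable.

Convergence: a sweep ends the iteration when the largest absolute
coefficient change falls below ``tol``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a soft requirement
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def cd_lasso_gram(G: np.ndarray, c: np.ndarray, n_obs: float, penalty: float,
                  b: np.ndarray, tol: float, max_iter: int) -> int:
    """In-place coordinate descent on the Gram system; returns sweep count.

    ``b`` is the warm-start coefficient vector, overwritten with the
    solution.  The soft threshold is ``n_obs * penalty`` because the
    residual term carries a ``1/N`` factor while G and c are raw sums.
    """
    p = G.shape[0]
    thresh = n_obs * penalty
    q = G @ b  # q_j = (G b)_j, maintained across updates
    for sweep in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = c[j] - q[j] + gjj * b[j]
            if rho > thresh:
                new = (rho - thresh) / gjj
            elif rho < -thresh:
                new = (rho + thresh) / gjj
            else:
                new = 0.0
            delta = new - b[j]
            if delta != 0.0:
                q += G[:, j] * delta
                b[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return sweep + 1
    return max_iter


@njit(cache=True)
def path_at_step(G: np.ndarray, c: np.ndarray, n_obs: float,
                 grid: np.ndarray, B: np.ndarray, tol: float,
                 max_iter: int) -> None:
    """Solve the whole penalty grid at one training window, warm-started.

    ``B`` (n_penalties x p) holds the previous window's solutions on entry
    and this window's on exit.
    """
    for a in range(grid.shape[0]):
        cd_lasso_gram(G, c, n_obs, grid[a], B[a], tol, max_iter)


def solve_lasso(X: np.ndarray, y: np.ndarray, penalty: float,
                b0: np.ndarray | None = None, tol: float = 1e-7,
                max_iter: int = 2000) -> tuple[np.ndarray, float]:
    """Convenience wrapper: center, build the Gram system, solve, and
    recover the unpenalized intercept."""
    n = len(y)
    mx = X.mean(axis=0)
    my = y.mean()
    Xc = X - mx
    G = Xc.T @ Xc
    c = Xc.T @ (y - my)
    b = np.zeros(X.shape[1]) if b0 is None else b0.astype(float).copy()
    cd_lasso_gram(G, c, float(n), penalty, b, tol, max_iter)
    return b, float(my - mx @ b)
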