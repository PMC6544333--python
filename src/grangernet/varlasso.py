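"""Conditional Granger causality by LASSO-penalized vector autoregression.

Each genus is modelled, one equation at a time, as a linear function of the
lagged values (lags 1..L, default L=20) of *every* genus in the community,
itself included.  Conditioning on the whole community removes the spurious
links that pairwise Granger tests produce under sequential or differentially
delayed driving, and shrinks the hypothesis count from one per ordered pair
to one model per genus.

With n genera the design has n*L columns — several times the number of
usable time points — so the fit is an L1-penalized least squares (LASSO).
The penalty is chosen by rolling-origin cross-validation: fit on the first
third of the series, score one-step-ahead forecasts while the origin rolls
through the middle third, pick the penalty minimizing the mean squared
forecast error (MSFE), then report an independent MSFE on the final third.

A nonzero coefficient B[effect][cause][lag] in the resulting tensor is read
as "cause Granger-causes effect at that lag, conditional on the rest of the
community", with magnitude in response-SD per predictor-SD on the
differenced scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import cd_lasso_gram, path_at_step, solve_lasso
from .config import RunConfig
from .tables import ProcessedSeries

CD_TOL = 1e-7        # max absolute coefficient change per sweep
CD_MAX_ITER = 10_000  # sweep cap for a standalone fit

# Rolling CV tracks solutions along an expanding window: converge hard once
# at the initial window, then spend a small sweep budget per added
# observation (warm-started solutions move very little per step).  The
# near-unpenalized end of the grid converges slowly when columns outnumber
# rows, but those penalties are overfit regimes whose forecasts lose the
# selection regardless of residual inaccuracy.
CD_CV_TOL = 1e-5
CD_CV_COLD_MAX_ITER = 2000
CD_CV_STEP_MAX_ITER = 15


@dataclass
class LaggedDesign:
    """Design matrix for one response genus.

    ``X`` has one row per usable time point (oldest first) and one column
    per (predictor taxon, lag) pair, ordered by taxon then lag ascending.
    Row ``r`` predicts the processed value at time index ``r + L``.
    """

    response_taxon: str
    y: np.ndarray
    X: np.ndarray
    column_labels: list[tuple[str, int]]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class PenaltyPath:
    """Penalty grid with rolling-CV forecast errors and the selected value."""

    grid: np.ndarray
    msfe: np.ndarray
    selected: float
    validation_msfe: float


@dataclass
class CoefficientTensor:
    """Fitted Granger coefficients, shape (n_effects, n_causes, L).

    ``B[i, j, k]`` is the effect of taxon ``j`` at lag ``k+1`` days on taxon
    ``i``; exact zero means the LASSO did not retain the term.
    """

    taxa: list[str]
    B: np.ndarray
    selected_penalty: np.ndarray
    intercepts: np.ndarray
    penalty_paths: dict[str, PenaltyPath] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def lags(self) -> int:
        return self.B.shape[2]

    def nonzero_fraction(self) -> float:
        return float(np.mean(self.B != 0))


def build_lagged_design(series: ProcessedSeries, response: str,
                        L: int) -> LaggedDesign:
    """Assemble the lagged design for one response genus.

    Column for (taxon g, lag k) holds g's processed value k steps before
    the predicted time point.
    """
    if response not in series.taxa:
        raise ValueError(f"unknown response taxon {response!r}")
    Z = series.matrix
    T = Z.shape[1]
    if L >= T:
        raise ValueError(f"lag order {L} >= series length {T}")
    n = series.n_taxa
    rows = T - L
    X = np.empty((rows, n * L))
    labels: list[tuple[str, int]] = []
    for j, taxon in enumerate(series.taxa):
        for k in range(1, L + 1):
            # value of taxon j at time (r + L - k) for row r
            X[:, j * L + (k - 1)] = Z[j, L - k:T - k]
            labels.append((taxon, k))
    y = Z[series.taxa.index(response), L:]
    return LaggedDesign(response_taxon=response, y=y, X=X,
                        column_labels=labels)


def lambda_max(design: LaggedDesign) -> float:
    """Smallest penalty at which the LASSO solution is entirely zero.

    Equals ``max_j |<x_j, y - mean(y)>| / N`` for the intercept-included
    objective ``(1/2N)||y - b0 - Xb||^2 + penalty * ||b||_1``.
    """
    yc = design.y - design.y.mean()
    return float(np.max(np.abs(design.X.T @ yc)) / design.n_obs)


def lasso_objective(design: LaggedDesign, coef: np.ndarray, intercept: float,
                    penalty: float) -> float:
    resid = design.y - design.X @ coef - intercept
    n = design.n_obs
    return float(resid @ resid / (2 * n) + penalty * np.abs(coef).sum())


def lasso_fit(design: LaggedDesign,
              penalty: float) -> tuple[np.ndarray, float]:
    """L1-penalized least squares with an unpenalized intercept.

    Minimizes ``(1/2N)·sum(residual²) + penalty·sum|coef|`` by coordinate
    descent.  ``penalty = 0`` falls back to ordinary least squares on the
    centered design.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if not (np.all(np.isfinite(design.X)) and np.all(np.isfinite(design.y))):
        raise ValueError("design contains non-finite entries")
    if penalty == 0:
        Xc = design.X - design.X.mean(axis=0)
        yc = design.y - design.y.mean()
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = design.y.mean() - design.X.mean(axis=0) @ coef
        return coef, float(intercept)
    return solve_lasso(design.X, design.y, penalty, tol=CD_TOL,
                       max_iter=CD_MAX_ITER)


def penalty_grid(lam_max: float, size: int, ratio: float) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to lambda_max/ratio."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive to build a grid")
    if size == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max / ratio, size)


def rolling_cv_select(series: ProcessedSeries, response: str,
                      config: RunConfig,
                      grid: np.ndarray | None = None) -> PenaltyPath:
    """Choose the LASSO penalty by rolling-origin one-step forecasts.

    The usable observations (design rows) are split into thirds.  For each
    grid penalty the model is refit on an expanding window that starts at
    the first third and advances one observation at a time through the
    middle third, scoring each next-step forecast; the penalty with minimal
    mean squared forecast error wins (ties -> least shrinkage).  The final
    third yields an independent validation MSFE at the selected penalty,
    with the origin still rolling but the penalty frozen.
    """
    design = build_lagged_design(series, response, config.lags)
    N = design.n_obs
    if N < 3 * 2:
        raise ValueError(f"series too short for rolling CV (N={N})")
    t1, t2 = N // 3, (2 * N) // 3
    if grid is None:
        grid = penalty_grid(lambda_max(design), config.lambda_grid_size,
                            config.lambda_ratio)
    grid = np.asarray(grid, dtype=float)
    X, y = design.X, design.y
    p = design.n_columns

    # expanding-window sums; centered Gram recovered as
    # G_c = G_u - t * outer(mean_x, mean_x), c_c = c_u - t * mean_x * mean_y
    Sx = X[:t1].sum(axis=0)
    Sy = float(y[:t1].sum())
    Gu = X[:t1].T @ X[:t1]
    cu = X[:t1].T @ y[:t1]

    def centered(t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        mx, my = Sx / t, Sy / t
        Gc = Gu - t * np.outer(mx, mx)
        cc = cu - t * mx * my
        return Gc, cc, mx, my

    def grow(t: int) -> None:
        nonlocal Sx, Sy, Gu, cu
        Sx += X[t]
        Sy += float(y[t])
        Gu += np.outer(X[t], X[t])
        cu += X[t] * y[t]

    B = np.zeros((len(grid), p))  # warm-started solutions per penalty
    sq_err = np.zeros((t2 - t1, len(grid)))
    for i, t in enumerate(range(t1, t2)):
        Gc, cc, mx, my = centered(t)
        cap = CD_CV_COLD_MAX_ITER if t == t1 else CD_CV_STEP_MAX_ITER
        path_at_step(Gc, cc, float(t), grid, B, CD_CV_TOL, cap)
        preds = my + B @ (X[t] - mx)
        sq_err[i] = (y[t] - preds) ** 2
        grow(t)
    msfe = sq_err.mean(axis=0)
    # grid is decreasing; the last index among minimizers is the smallest
    # penalty, i.e. least shrinkage
    best = int(np.flatnonzero(msfe == msfe.min())[-1])
    selected = float(grid[best])

    b = B[best].copy()
    val_err = []
    for t in range(t2, N):
        Gc, cc, mx, my = centered(t)
        cap = CD_CV_COLD_MAX_ITER if t == t2 else CD_CV_STEP_MAX_ITER
        cd_lasso_gram(Gc, cc, float(t), selected, b, CD_CV_TOL, cap)
        val_err.append((y[t] - (my + (X[t] - mx) @ b)) ** 2)
        grow(t)
    return PenaltyPath(grid=grid, msfe=msfe, selected=selected,
                       validation_msfe=float(np.mean(val_err)))


def fit_all_responses(series: ProcessedSeries,
                      config: RunConfig) -> CoefficientTensor:
    """Fit one penalized autoregression per genus and assemble the tensor."""
    n, L = series.n_taxa, config.lags
    B = np.zeros((n, n, L))
    penalties = np.zeros(n)
    intercepts = np.zeros(n)
    paths: dict[str, PenaltyPath] = {}
    for i, response in enumerate(series.taxa):
        path = rolling_cv_select(series, response, config)
        design = build_lagged_design(series, response, L)
        coef, intercept = lasso_fit(design, path.selected)
        for c, (taxon, lag) in enumerate(design.column_labels):
            if coef[c] != 0:
                B[i, series.taxa.index(taxon), lag - 1] = coef[c]
        penalties[i] = path.selected
        intercepts[i] = intercept
        paths[response] = path
    return CoefficientTensor(taxa=list(series.taxa), B=B,
                             selected_penalty=penalties,
                             intercepts=intercepts, penalty_paths=paths)


def hypothesis_budget(n_taxa: int, alpha: float,
                      mode: str) -> tuple[int, int]:
    """Hypothesis count and expected false positives at level ``alpha``.

    ``pairwise`` counts one test per unordered taxon pair (the convention
    behind the printed per-site totals); ``conditional`` counts one model
    per taxon, the reduction that motivates the multivariate analysis.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if mode == "pairwise":
        count = n_taxa * (n_taxa - 1) // 2
    elif mode == "conditional":
        count = n_taxa
    else:
        raise ValueError(f"unknown mode {mode!r}")
    expected_fp = int(np.floor(count * alpha + 0.5))
    return count, expected_fp
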