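"""Cross-validated ridge regression with GCV penalty selection.

The same engine serves the vertex-wise fMRI encoding models, the
seed-based connectivity regressions and the reading-speed model: runs are
paired into folds (odd run with its subsequent even run), the ridge
penalty is selected per fold by generalized cross-validation over a
log-spaced grid, weights are averaged over folds, and out-of-sample
accuracy is the fold-mean correlation of predicted and observed response,
Fisher z-transformed.  Scrambled-feature refits with frozen penalties
provide a null distribution that standardises the observed accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .design import DesignMatrix, ScrambleSet

logger = logging.getLogger(__name__)

__all__ = ["CVScheme", "EncodingResult", "lambda_grid", "fit_cv", "null_calibrate", "gcv_curve"]


def lambda_grid(n: int = 100, lo: float = 1e-5, hi: float = 1e8) -> np.ndarray:
    """The default penalty grid: ``n`` values log-spaced on [lo, hi]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class CVScheme:
    """Fold assignment pairing each odd-numbered run with the following
    even-numbered run (1-2, 3-4, ...)."""

    folds: List[List[int]]  # run indices per fold

    @classmethod
    def paired_runs(cls, n_runs: int) -> "CVScheme":
        if n_runs < 2 or n_runs % 2:
            raise ValueError("paired-run scheme needs an even number of runs")
        return cls(folds=[[r, r + 1] for r in range(0, n_runs, 2)])

    @classmethod
    def single_runs(cls, n_runs: int) -> "CVScheme":
        return cls(folds=[[r] for r in range(n_runs)])

    def row_masks(self, run_of_row: np.ndarray) -> List[np.ndarray]:
        return [np.isin(run_of_row, f) for f in self.folds]


@dataclass
class EncodingResult:
    weights: np.ndarray  # (features, responses) fold-averaged
    lambdas: np.ndarray  # (folds, responses)
    accuracy: np.ndarray  # (responses,) Fisher-z of fold-mean r
    fold_r: np.ndarray  # (folds, responses)
    columns: Optional[List[str]] = None
    null_accuracy: Optional[np.ndarray] = None  # (n_scrambles, responses)
    z_accuracy: Optional[np.ndarray] = None


def _fold_svd(X: np.ndarray):
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U, s, Vt


def gcv_curve(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """GCV criterion ||y - yhat||^2 / (n (1 - tr(H)/n)^2) for every
    penalty in ``grid``; ``y`` may be (n,) or (n, m)."""
    y = np.atleast_2d(y.T).T  # (n, m)
    n = X.shape[0]
    U, s, _ = _fold_svd(X)
    uy = U.T @ y  # (k, m)
    resid_perp = (y**2).sum(axis=0) - (uy**2).sum(axis=0)
    out = np.empty((grid.size, y.shape[1]))
    for i, lam in enumerate(grid):
        shrink = lam / (s**2 + lam)  # residual factor per component
        rss = ((shrink[:, None] * uy) ** 2).sum(axis=0) + resid_perp
        tr_h = (s**2 / (s**2 + lam)).sum()
        out[i] = rss / (n * (1 - tr_h / n) ** 2)
    return out


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Ridge weights for per-response penalties; y (n, m), lam (m,)."""
    U, s, Vt = _fold_svd(X)
    uy = U.T @ y  # (k, m)
    d = s[:, None] / (s[:, None] ** 2 + lam[None, :])  # (k, m)
    return Vt.T @ (d * uy)  # (p, m)


def fit_cv(
    S: DesignMatrix | np.ndarray,
    a: np.ndarray,
    *,
    run_of_row: Optional[np.ndarray] = None,
    scheme: Optional[CVScheme] = None,
    grid: Optional[np.ndarray] = None,
) -> EncodingResult:
    """Cross-validated ridge fit of response(s) ``a`` on the design.

    Per fold, GCV on the training rows selects the penalty (searched over
    ``grid``), weights come from the optimal-penalty fit, and the test-fold
    prediction is correlated with the observed response.  ``a`` may be a
    single series (n,) or a matrix (n, m) of responses sharing the design.
    The response is centred per fold with the training mean.
    """
    if isinstance(S, DesignMatrix):
        X = S.S
        run_of_row = S.runs_of_rows()
        columns = S.columns
    else:
        X = np.asarray(S, dtype=float)
        columns = None
    if np.linalg.matrix_rank(X) == 0:
        raise ValueError("design matrix has rank zero")
    a = np.asarray(a, dtype=float)
    single = a.ndim == 1
    Y = a[:, None] if single else a
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design and response row counts differ")
    if run_of_row is None:
        raise ValueError("run_of_row required for array designs")
    if scheme is None:
        scheme = CVScheme.paired_runs(int(run_of_row.max()) + 1)
    if len(scheme.folds) < 2:
        raise ValueError("need at least two folds")
    grid = lambda_grid() if grid is None else np.asarray(grid)

    masks = scheme.row_masks(run_of_row)
    p, m = X.shape[1], Y.shape[1]
    weights = np.zeros((p, m))
    lambdas = np.empty((len(masks), m))
    fold_r = np.empty((len(masks), m))
    for k, test in enumerate(masks):
        train = ~test
        Xtr, Xte = X[train], X[test]
        mu = Y[train].mean(axis=0)
        Ytr, Yte = Y[train] - mu, Y[test] - mu
        crit = gcv_curve(Xtr, Ytr, grid)
        best = crit.argmin(axis=0)
        lam = grid[best]
        lambdas[k] = lam
        W = _ridge_solve(Xtr, Ytr, lam)
        weights += W / len(masks)
        pred = Xte @ W
        fold_r[k] = _colwise_corr(pred, Yte)
    acc = np.arctanh(np.clip(fold_r.mean(axis=0), -0.999999, 0.999999))
    res = EncodingResult(
        weights=weights, lambdas=lambdas, accuracy=acc, fold_r=fold_r, columns=columns
    )
    if single:
        res.weights = res.weights[:, 0]
        res.accuracy = res.accuracy[:1]
    return res


def _colwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
    out = np.zeros(A.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def null_calibrate(
    design: DesignMatrix,
    scrambles: ScrambleSet,
    a: np.ndarray,
    fitted: EncodingResult,
    *,
    scheme: Optional[CVScheme] = None,
) -> EncodingResult:
    """Recompute accuracy for every scrambled design with frozen penalties.

    The optimal per-fold penalties from the non-scrambled fit are reused;
    the observed accuracy is z-scored against the mean and standard
    deviation of the scrambled-accuracy distribution.  A degenerate null
    spread (< 1e-12) yields z = 0 with a log message.
    """
    if len(scrambles) < 1:
        raise ValueError("no surrogates supplied")
    a = np.asarray(a, dtype=float)
    single = a.ndim == 1
    Y = a[:, None] if single else a
    run_of_row = design.runs_of_rows()
    if scheme is None:
        scheme = CVScheme.paired_runs(design.n_runs)
    masks = scheme.row_masks(run_of_row)
    lambdas = np.atleast_2d(fitted.lambdas)
    m = Y.shape[1]
    null_acc = np.empty((len(scrambles), m))
    for i in range(len(scrambles)):
        Xs = scrambles.surrogate(i)
        fold_r = np.empty((len(masks), m))
        for k, test in enumerate(masks):
            train = ~test
            mu = Y[train].mean(axis=0)
            W = _ridge_solve(Xs[train], Y[train] - mu, lambdas[k])
            fold_r[k] = _colwise_corr(Xs[test] @ W, Y[test] - mu)
        null_acc[i] = np.arctanh(np.clip(fold_r.mean(axis=0), -0.999999, 0.999999))
    sd = null_acc.std(axis=0)
    z = np.zeros(m)
    ok = sd >= 1e-12
    obs = np.atleast_1d(fitted.accuracy)
    z[ok] = (obs[ok] - null_acc.mean(axis=0)[ok]) / sd[ok]
    if not ok.all():
        logger.warning("degenerate null spread for %d responses; z set to 0", (~ok).sum())
    fitted.null_accuracy = null_acc
    fitted.z_accuracy = z
    return fitted
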