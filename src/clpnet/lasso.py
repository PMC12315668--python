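"""L1-penalized least squares by cyclic coordinate descent.

Solves, for standardized inputs,

    min_b  (1/2n) * ||y - b0 - X b||^2  +  lambda * sum_j |b_j|

with the classical soft-thresholding coordinate update, zero
initialization, cyclic coordinate order, and warm starts along a
log-spaced penalty path.  Internally predictors are centered and scaled
to unit (population) SD and the response is centered; coefficients are
reported back on the caller's scale, so passing already-standardized
data makes the internal scaling the identity.

The solver works on the Gram matrix (X'X/n, X'y/n), which makes path and
cross-validation refits cheap for the small predictor counts used in
node-wise network estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # JIT-compiled inner loop when numba is present; plain Python otherwise
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

__all__ = [
    "soft_threshold",
    "PenaltyPath",
    "build_lambda_path",
    "lasso_fit",
    "lasso_path",
    "cv_select_lambda",
    "lasso_objective",
    "kkt_violation",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the last iterate."""

    def __init__(self, message, coef=None, intercept=None):
        super().__init__(message)
        self.coef = coef
        self.intercept = intercept


def soft_threshold(z: float, t: float) -> float:
    """sign(z) * max(|z| - t, 0); the proximal operator of t*|.|."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class PenaltyPath:
    """Log-spaced decreasing lambda grid starting at the all-zero point."""

    lambdas: np.ndarray
    n_lambdas: int = 100
    ratio_min: float = 1e-3

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(self.lambdas <= 0) or np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be positive and strictly decreasing")


def _standardize(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design and response shapes disagree")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing cells are not allowed in the solver")
    xm = X.mean(axis=0)
    xs = X.std(axis=0)  # population SD: unit-diagonal Gram
    if np.any(xs == 0):
        raise ValueError("constant predictor column")
    ym = y.mean()
    Xs = (X - xm) / xs
    yc = y - ym
    return Xs, yc, xm, xs, ym


def build_lambda_path(X, y, n_lambdas: int = 100, ratio_min: float = 1e-3) -> PenaltyPath:
    """Grid from lambda_max = max_j |<x_j, y>|/n down to ratio_min*lambda_max."""
    Xs, yc, *_ = _standardize(X, y)
    if np.std(yc) == 0:
        raise ValueError("constant response")
    n = Xs.shape[0]
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if lam_max <= 0:
        raise ValueError("response orthogonal to every predictor")
    lams = np.logspace(np.log10(lam_max), np.log10(lam_max * ratio_min), n_lambdas)
    return PenaltyPath(lams, n_lambdas=n_lambdas, ratio_min=ratio_min)


@_njit(cache=False)
def _cd_path_kernel(G, c, lams, tol, max_iter):  # pragma: no cover - jitted
    """Warm-started cyclic coordinate descent along a decreasing grid.

    Maintains the gradient g = c - G b (unit Gram diagonal assumed); the
    update for coordinate j is b_j <- S(g_j + b_j, lam).  Returns the
    coefficient matrix, the last iterate, and the index of the first
    lambda that failed to converge (-1 when all converged).
    """
    p = G.shape[0]
    L = lams.shape[0]
    b = np.zeros(p)
    g = c.copy()
    out = np.zeros((L, p))
    for li in range(L):
        lam = lams[li]
        converged = False
        for _ in range(max_iter):
            delta_max = 0.0
            for j in range(p):
                bj = b[j]
                zj = g[j] + bj
                if zj > lam:
                    bn = zj - lam
                elif zj < -lam:
                    bn = zj + lam
                else:
                    bn = 0.0
                d = bn - bj
                if d != 0.0:
                    b[j] = bn
                    for q in range(p):
                        g[q] -= G[q, j] * d
                    if d < 0.0:
                        d = -d
                    if d > delta_max:
                        delta_max = d
            if delta_max < tol:
                converged = True
                break
        if not converged:
            return out, b, li
        out[li] = b
    return out, b, -1


def _gram(Xs, yc):
    n = Xs.shape[0]
    return (Xs.T @ Xs) / n, (Xs.T @ yc) / n


def lasso_fit(X, y, lam: float, tol: float = 1e-8, max_iter: int = 10_000):
    """Fit at a single penalty (zero initialization); returns
    ``(coef, intercept)`` on the input scale."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Xs, yc, xm, xs, ym = _standardize(X, y)
    n, p = Xs.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    G, c = _gram(Xs, yc)
    coefs, last, fail = _cd_path_kernel(G, c, np.array([float(lam)]), tol, max_iter)
    if fail >= 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps",
            coef=last / xs)
    coef = coefs[0] / xs
    intercept = ym - xm @ coef
    return coef, float(intercept)


def lasso_path(X, y, lambdas, tol: float = 1e-8, max_iter: int = 10_000):
    """Warm-started fits along a decreasing penalty grid.

    Returns ``(coefs, intercepts)`` with ``coefs`` of shape
    (n_lambdas, p) on the input scale.
    """
    Xs, yc, xm, xs, ym = _standardize(X, y)
    G, c = _gram(Xs, yc)
    lams = np.ascontiguousarray(lambdas, dtype=float)
    raw, last, fail = _cd_path_kernel(G, c, lams, tol, max_iter)
    if fail >= 0:
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda index {fail}",
            coef=last / xs)
    coefs = raw / xs
    intercepts = ym - coefs @ xm
    return coefs, intercepts


def cv_select_lambda(X, y, path: PenaltyPath, k: int = 10, seed: int = 0,
                     rule: str = "min", folds=None):
    """k-fold cross-validated penalty selection.

    Participants are partitioned by a seeded permutation into ``k``
    near-equal folds (an explicit ``folds`` label array overrides this).
    For each lambda the mean held-out squared error across folds and its
    standard error are computed.  ``rule='min'`` returns the penalty with
    the smallest mean error (ties resolved toward the larger, sparser
    penalty); ``rule='one_se'`` the largest penalty within one SE of it.

    Returns ``(lambda, cv_mean, cv_se)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds is None:
        if k > n:
            raise ValueError("more folds than observations")
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % k
    else:
        folds = np.asarray(folds)
        if len(folds) != n:
            raise ValueError("fold labels must align with observations")
    lams = path.lambdas
    fold_ids = np.unique(folds)
    errs = np.empty((len(fold_ids), len(lams)))
    for fi, f in enumerate(fold_ids):
        test = folds == f
        coefs, intercepts = lasso_path(X[~test], y[~test], lams)
        pred = X[test] @ coefs.T + intercepts
        errs[fi] = np.mean((y[test, None] - pred) ** 2, axis=0)
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(len(fold_ids))
    i_min = int(np.argmin(cv_mean))  # first index = largest lambda on ties
    if rule == "min":
        i_sel = i_min
    elif rule == "one_se":
        within = cv_mean <= cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.argmax(within))  # largest lambda within one SE
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return float(lams[i_sel]), cv_mean, cv_se


# ---------------------------------------------------------------------------
# diagnostics


def lasso_objective(X, y, coef, intercept, lam) -> float:
    """(1/2n)||y - b0 - Xb||^2 + lam*||b||_1 on the caller's scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - intercept - X @ np.asarray(coef, dtype=float)
    n = len(y)
    return float(0.5 * np.mean(r**2) + lam * np.sum(np.abs(coef)))


def kkt_violation(X, y, coef, intercept, lam) -> float:
    """Maximal stationarity violation at a candidate solution.

    With g = -X'(y - b0 - Xb)/n computed on the internally standardized
    design, optimality requires |g_j| <= lam for zero coefficients and
    g_j = -lam*sign(b_j) for active ones; returns the largest excess.
    """
    Xs, yc, xm, xs, ym = _standardize(X, y)
    b = np.asarray(coef, dtype=float) * xs  # back to the internal scale
    g = -(Xs.T @ (yc - Xs @ b)) / Xs.shape[0]
    viol = np.where(b == 0, np.maximum(np.abs(g) - lam, 0.0),
                    np.abs(g + lam * np.sign(b)))
    return float(np.max(viol))
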