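"""Coordinate-descent solver for the lasso-penalized logistic path.

Minimises, for each penalty lambda on a decreasing grid (warm starts),

    (1/n) sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]  +  lambda * ||beta||_1

with eta = b0 + X beta and an unpenalized intercept, via iteratively
reweighted least squares (IRLS) around the current linear predictor and
cyclic coordinate descent with soft-thresholding on each weighted
quadratic subproblem.  X is expected standardized; lambda = 0 reduces to
the unpenalized Newton-type MLE.

The inner loops are numba-compiled when numba is available and fall back
to the identical pure-Python code otherwise (correct but slow).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_W_FLOOR = 1e-6
_ETA_CAP = 30.0


@njit(cache=False)
def _cd_sweep(
    X: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    beta: np.ndarray,
    wx2: np.ndarray,
    lam: float,
    n: int,
    p: int,
    active_only: bool,
) -> float:
    """One coordinate sweep; returns the largest coefficient change."""
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        num = 0.0
        for i in range(n):
            num += w[i] * X[i, j] * r[i]
        num = num / n + wx2[j] * bj
        if num > lam:
            bnew = (num - lam) / wx2[j]
        elif num < -lam:
            bnew = (num + lam) / wx2[j]
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bnew
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=False)
def _intercept_step(w: np.ndarray, r: np.ndarray, sw: float, n: int) -> float:
    num = 0.0
    for i in range(n):
        num += w[i] * r[i]
    d0 = num / sw
    if d0 != 0.0:
        for i in range(n):
            r[i] -= d0
    return d0


@njit(cache=False)
def _cd_path_impl(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    final_tol: float,
    max_outer: int,
    max_inner: int,
) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    n_lam = lambdas.shape[0]
    intercepts = np.empty(n_lam)
    coefs = np.empty((n_lam, p))

    pbar = y.mean()
    b0 = np.log(pbar / (1.0 - pbar))
    beta = np.zeros(p)
    eta = np.full(n, b0)

    for li in range(n_lam):
        lam = lambdas[li]
        lam_tol = final_tol if li == n_lam - 1 else tol
        for _outer in range(max_outer):
            b0_old = b0
            beta_old = beta.copy()

            # IRLS linearisation at the current eta
            w = np.empty(n)
            z = np.empty(n)
            for i in range(n):
                e = eta[i]
                if e > _ETA_CAP:
                    e = _ETA_CAP
                elif e < -_ETA_CAP:
                    e = -_ETA_CAP
                mu = 1.0 / (1.0 + np.exp(-e))
                wi = mu * (1.0 - mu)
                if wi < _W_FLOOR:
                    wi = _W_FLOOR
                w[i] = wi
                z[i] = eta[i] + (y[i] - mu) / wi
            sw = w.sum()
            wx2 = np.empty(p)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                wx2[j] = s / n

            # residual of the working response: r = z - b0 - X beta
            r = z - eta

            # cyclic CD with an active-set strategy: full sweeps establish
            # the support, then only nonzero coordinates are iterated
            remaining = max_inner
            while remaining > 0:
                remaining -= 1
                max_delta = _cd_sweep(X, w, r, beta, wx2, lam, n, p, False)
                d0 = _intercept_step(w, r, sw, n)
                b0 += d0
                if abs(d0) > max_delta:
                    max_delta = abs(d0)
                if max_delta < lam_tol:
                    break
                while remaining > 0:
                    remaining -= 1
                    md2 = _cd_sweep(X, w, r, beta, wx2, lam, n, p, True)
                    d0 = _intercept_step(w, r, sw, n)
                    b0 += d0
                    if abs(d0) > md2:
                        md2 = abs(d0)
                    if md2 < lam_tol:
                        break

            # eta for the next IRLS step: z - r == b0 + X beta
            for i in range(n):
                eta[i] = z[i] - r[i]

            diff = abs(b0 - b0_old)
            for j in range(p):
                dj = abs(beta[j] - beta_old[j])
                if dj > diff:
                    diff = dj
            if diff < lam_tol:
                break

        intercepts[li] = b0
        coefs[li] = beta
    return intercepts, coefs


def cd_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-5,
    final_tol: float | None = None,
    max_outer: int = 100,
    max_inner: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Lasso-logit path over a decreasing lambda grid with warm starts.

    Returns ``(intercepts, coefs)`` with ``coefs`` of shape
    ``(n_lambda, p)``.  On (quasi-)separable data at lambda = 0 the MLE
    diverges; iterations are capped, so returned coefficients are large
    but finite.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on n")
    if final_tol is None:
        final_tol = tol
    return _cd_path_impl(X, y, lambdas, tol, final_tol, max_outer, max_inner)
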