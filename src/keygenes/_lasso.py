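"""L1-penalized multinomial logistic regression along a penalty path.

Solves, for each penalty value lambda on a decreasing path,

    min_{W, b}  -(1/n) sum_i log softmax(X w + b)[y_i]  +  lambda * ||W||_1

with unpenalized intercepts b.  Each lambda is solved by accelerated
proximal gradient (FISTA) descent with monotone restarts, warm-started from
the previous solution.  A sequential strong rule screens features — a
feature enters the subproblem only if its null-gradient magnitude exceeds
2*lambda - lambda_prev — and the Karush-Kuhn-Tucker conditions are checked
on the full feature set afterwards, re-solving with any violators added, so
screening never changes the solution.

The softmax-loss gradient is (1/2n) X'X-Lipschitz, giving a safe fixed
step.  Starting from zero, the flat intercept direction (adding a constant
to all intercepts) is never entered, so intercepts stay sum-zero and runs
are exactly reproducible.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

try:  # compiled inner loop; the numpy path below is the reference behaviour
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@njit(cache=False)
def _fista_loop(
    Xs: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    lam: float,
    step: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """FISTA iterations with monotone restarts (compiled when numba is present)."""
    n, m = Xs.shape
    k = W.shape[0]
    p = m - 1
    thresh = lam * step
    prob = np.empty((n, k))

    def _loss(Wc):
        ll = 0.0
        for i in range(n):
            zmax = -1e300
            for kk in range(k):
                z = 0.0
                for j in range(m):
                    z += Xs[i, j] * Wc[kk, j]
                prob[i, kk] = z
                if z > zmax:
                    zmax = z
            s = 0.0
            for kk in range(k):
                e = np.exp(prob[i, kk] - zmax)
                prob[i, kk] = e
                s += e
            for kk in range(k):
                prob[i, kk] /= s
                if Y[i, kk] == 1.0:
                    ll += np.log(max(prob[i, kk], 1e-300))
        pen = 0.0
        for kk in range(k):
            for j in range(p):
                pen += abs(Wc[kk, j])
        return -ll / n + lam * pen

    def _prox(V):
        # gradient uses prob computed at V by the preceding _loss call
        out = np.empty((k, m))
        for kk in range(k):
            for j in range(m):
                g = 0.0
                for i in range(n):
                    g += (prob[i, kk] - Y[i, kk]) * Xs[i, j]
                w = V[kk, j] - step * g / n
                if j < p:
                    if w > thresh:
                        w -= thresh
                    elif w < -thresh:
                        w += thresh
                    else:
                        w = 0.0
                out[kk, j] = w
        return out

    V = W.copy()
    t = 1.0
    f_prev = _loss(W)
    for _ in range(max_iter):
        _loss(V)  # refresh prob at the momentum point
        W_new = _prox(V)
        f_new = _loss(W_new)
        if f_new > f_prev + 1e-15:  # momentum overshoot: restart at W
            V = W.copy()
            t = 1.0
            _loss(V)
            W_new = _prox(V)
            f_new = _loss(W_new)
        delta = 0.0
        wmax = 1.0
        for kk in range(k):
            for j in range(m):
                d = abs(W_new[kk, j] - W[kk, j])
                if d > delta:
                    delta = d
                a = abs(W_new[kk, j])
                if a > wmax:
                    wmax = a
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        coef = (t - 1.0) / t_new
        V = W_new + coef * (W_new - W)
        W = W_new
        t = t_new
        f_prev = f_new
        if delta < tol * wmax:
            break
    return W


def _fista(
    Xs: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    lam: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Minimize the penalized loss over the columns of ``Xs``.

    The last column of ``Xs`` is the intercept column and is not
    penalized.  ``W`` is (n_classes, n_cols); returns the minimizer.
    """
    n = Xs.shape[0]
    step = 2.0 * n / (np.linalg.norm(Xs, 2) ** 2)
    return _fista_loop(
        np.ascontiguousarray(Xs), np.ascontiguousarray(Y),
        np.ascontiguousarray(W), float(lam), step, float(tol), int(max_iter),
    )


def fit_multinomial_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the penalty path; returns (coefs, intercepts, classes_present).

    ``coefs`` has shape (len(lambdas), n_classes, n_features); classes
    absent from ``y`` keep zero rows (their probability is zero).  A fully
    sparse solution gets the exact intercept-only optimum, centered log
    class frequencies.
    """
    n, p = X.shape
    present = np.unique(y)
    k = len(present)
    if k < 2:
        raise ValueError("need at least two classes present")
    remap = {c: i for i, c in enumerate(present)}
    Y = np.zeros((n, k))
    Y[np.arange(n), [remap[c] for c in y]] = 1.0

    Xa = np.hstack([X, np.ones((n, 1))])
    log_prior = np.log(Y.mean(axis=0))
    log_prior -= log_prior.mean()

    coefs_out = np.zeros((len(lambdas), n_classes, p))
    icpts_out = np.zeros((len(lambdas), n_classes))

    W = np.zeros((k, p + 1))
    W[:, p] = log_prior
    prob = _softmax(Xa @ W.T)
    grad = np.max(np.abs((prob - Y).T @ X / n), axis=0)  # (p,) null scores
    lam_prev = float(lambdas[0])

    for li, lam in enumerate(lambdas):
        lam = float(lam)
        candidate = (grad >= 2.0 * lam - lam_prev) | (W[:, :p] != 0).any(axis=0)
        for _ in range(10):  # KKT refinement passes
            idx = np.nonzero(candidate)[0]
            if idx.size:
                cols = np.concatenate([idx, [p]])
                W_sub = _fista(Xa[:, cols], Y, W[:, cols].copy(), lam, tol, max_iter)
                W[:, :p] = 0.0
                W[:, idx] = W_sub[:, :-1]
                W[:, p] = W_sub[:, -1]
            prob = _softmax(Xa @ W.T)
            grad = np.max(np.abs((prob - Y).T @ X / n), axis=0)
            violators = (~candidate) & (grad > lam * (1.0 + 1e-9) + 1e-12)
            if not violators.any():
                break
            candidate |= violators
        if np.max(np.abs(W[:, :p]), initial=0.0) < 1e-8:
            # at the boundary penalty the KKT optimum is the null model;
            # snap stray epsilon coordinates and use the exact intercepts
            W[:, :p] = 0.0
            W[:, p] = log_prior
            prob = _softmax(Xa @ W.T)
            grad = np.max(np.abs((prob - Y).T @ X / n), axis=0)
        coefs_out[li][present] = W[:, :p]
        icpts_out[li][present] = W[:, p]
        lam_prev = lam
    return coefs_out, icpts_out, present
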