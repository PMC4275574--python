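"""Independent reference solvers used only to check the implementation.

These deliberately share no code path with the package: the graphical-LASSO
oracle is an ADMM scheme with an eigendecomposition proximal step, the
L1-SVM oracle is bound-constrained L-BFGS on the smooth split-variable
reformulation, and the L2-SVM oracle solves the (bias-free) box-constrained
dual QP.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def admm_graphical_lasso(S: np.ndarray, lam: float, rho: float = 1.0,
                         n_iter: int = 2000, tol: float = 1e-10):
    """ADMM solution of max logdet(X) - tr(XS) - lam * sum|X| (all entries)."""
    p = S.shape[0]
    X = np.eye(p)
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(n_iter):
        # X-update: proximal step via eigendecomposition
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        xi = (d + np.sqrt(d ** 2 + 4 * rho)) / (2 * rho)
        X = Q @ np.diag(xi) @ Q.T
        # Z-update: soft-threshold every entry (diagonal included)
        Z_old = Z
        A = X + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        U = U + X - Z
        r = np.linalg.norm(X - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        if r < tol and s < tol:
            break
    return X, Z


def glasso_objective(omega: np.ndarray, S: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return logdet - np.sum(omega * S) - lam * np.abs(omega).sum()


def l1_squared_hinge_oracle(X: np.ndarray, y: np.ndarray, C: float):
    """min ||w||_1 + C sum max(1 - y x'w, 0)^2 via split variables w = a - b,
    a, b >= 0 (objective is smooth in (a, b); L-BFGS-B handles the bounds)."""
    n, q = X.shape
    Yx = X * y[:, None]

    def fun(v):
        a, b = v[:q], v[q:]
        w = a - b
        margin = np.maximum(1.0 - Yx @ w, 0.0)
        obj = a.sum() + b.sum() + C * np.sum(margin ** 2)
        g_w = -2.0 * C * (Yx.T @ margin)
        grad = np.concatenate([1.0 + g_w, 1.0 - g_w])
        return obj, grad

    v0 = np.zeros(2 * q)
    res = minimize(fun, v0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * q,
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
    w = res.x[:q] - res.x[q:]
    return w, res.fun


def l1_svm_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray,
                     C: float) -> float:
    margin = np.maximum(1.0 - y * (X @ w), 0.0)
    return np.abs(w).sum() + C * np.sum(margin ** 2)


def l2_hinge_dual_oracle(X: np.ndarray, y: np.ndarray, C: float):
    """Bias-free L2 hinge SVM via its dual: max 1'a - 0.5 a'Qa, 0 <= a <= C,
    with Q = (yy') o (XX'); primal w = X' (a o y)."""
    n = X.shape[0]
    Q = (np.outer(y, y)) * (X @ X.T)

    def fun(a):
        return -(a.sum() - 0.5 * a @ Q @ a), -(np.ones(n) - Q @ a)

    res = minimize(fun, np.zeros(n), jac=True, method="L-BFGS-B",
                   bounds=[(0, C)] * n,
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
    w = X.T @ (res.x * y)
    return w, -res.fun


def l2_svm_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray,
                     C: float) -> float:
    margin = np.maximum(1.0 - y * (X @ w), 0.0)
    return 0.5 * np.dot(w, w) + C * margin.sum()


def random_pd_covariance(p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(p, 2 * p))
    S = A @ A.T / (2 * p)
    return (S + S.T) / 2
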