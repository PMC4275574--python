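"""Connectivity feature matrices and graphical-LASSO precision estimation.

Five symmetric ``n_p x n_p`` matrices summarize the statistical dependence
between regional time-series:

* covariance (Sigma),
* Pearson correlation (Phi),
* full inverse covariance (Pi = Sigma^-1),
* partial correlation (Theta, with Theta_ij = -Pi_ij / sqrt(Pi_ii Pi_jj)),
* sparse inverse covariance (Omega) estimated by graphical LASSO, i.e. the
  positive-definite maximizer of the penalized Gaussian log-likelihood
  ``log det(Omega) - tr(Omega Sigma) - lambda * ||Omega||_1`` where the L1
  norm sums the absolute values of *all* entries, diagonal included.

Off-diagonal zeros of Omega encode conditional independence between two
regions given all others (a Gaussian graphical model); the regularization
weight lambda is selected by the Bayesian Information Criterion on the
regularization path. The vectorized lower triangle of any of these matrices
is the feature vector fed to the classifiers.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .preprocess import RegionalTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "FeatureVector",
    "BicRecord",
    "LambdaSelection",
    "sample_covariance",
    "pearson_correlation",
    "full_inverse_covariance",
    "partial_correlation",
    "graphical_lasso",
    "glasso_objective",
    "bic_score",
    "select_lambda",
    "lower_index_map",
    "vectorize_lower",
    "devectorize_lower",
]

KINDS = ("covariance", "correlation", "inverse_covariance",
         "partial_correlation", "sparse_inverse_covariance")


@dataclass
class ConnectivityMatrix:
    """A symmetric connectivity matrix of a declared kind."""

    data: np.ndarray
    kind: str
    lambda_: float | None = None
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if (self.lambda_ is not None) != (self.kind == "sparse_inverse_covariance"):
            raise ValueError("lambda_ is set iff kind is sparse_inverse_covariance")

    @property
    def n_p(self) -> int:
        return self.data.shape[0]

    def support(self, include_diagonal: bool = False) -> np.ndarray:
        """Indices of exactly nonzero lower-triangle entries (vectorized order)."""
        vals = vectorize_lower(self).values
        idx = np.flatnonzero(vals != 0.0)
        if include_diagonal:
            raise NotImplementedError("diagonal is excluded from feature space")
        return idx


@dataclass
class FeatureVector:
    """Vectorized lower triangle of a connectivity matrix with its label.

    ``index_map`` lists the (i, j) region pairs (i > j, 0-based) in the
    canonical order: j ascending, then i ascending within j. Its length is
    q = n_p (n_p - 1) / 2.
    """

    values: np.ndarray
    label: int = 0
    index_map: list[tuple[int, int]] = field(default_factory=list)

    @property
    def q(self) -> int:
        return self.values.shape[0]


@dataclass
class BicRecord:
    """One point of the BIC trace along the graphical-LASSO path."""

    lambda_: float
    log_likelihood: float
    n_nonzero: int          # m(lambda), lower triangle incl. diagonal
    degrees_of_freedom: int  # d = m (m - 1) / 2
    bic: float


@dataclass
class LambdaSelection:
    """Outcome of BIC-based lambda selection over inner folds."""

    lambda_per_group: dict[int, float]
    pooled_lambda: float
    traces: list[dict] = field(default_factory=list)


def _as_matrix(ts_or_array) -> np.ndarray:
    if isinstance(ts_or_array, (RegionalTimeSeries,)):
        return ts_or_array.data
    return np.asarray(ts_or_array, dtype=float)


def sample_covariance(ts, unbiased: bool = False,
                      region_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Sample covariance of the regional time-series.

    Uses the maximum-likelihood 1/n_t scaling by default so that the
    graphical-LASSO likelihood is exact; set ``unbiased=True`` for the
    1/(n_t - 1) convention.
    """
    X = _as_matrix(ts)
    if X.shape[0] < 2:
        raise ValueError("need at least two time-points")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = region_labels[bad] if region_labels else str(bad)
        raise ValueError(f"region {name} has zero variance")
    Xc = X - X.mean(axis=0)
    n_t = X.shape[0]
    denom = n_t - 1 if unbiased else n_t
    S = Xc.T @ Xc / denom
    return ConnectivityMatrix((S + S.T) / 2.0, "covariance",
                              region_labels=region_labels)


def pearson_correlation(ts, region_labels: list[str] | None = None
                        ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix Phi (unit diagonal)."""
    cov = sample_covariance(ts, region_labels=region_labels)
    d = np.sqrt(np.diag(cov.data))
    corr = cov.data / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return ConnectivityMatrix((corr + corr.T) / 2.0, "correlation",
                              region_labels=region_labels)


def full_inverse_covariance(cov: ConnectivityMatrix,
                            max_condition: float = 1e12) -> ConnectivityMatrix:
    """Unregularized precision matrix Pi = Sigma^-1.

    Valid only when the covariance is well conditioned, which requires more
    time-points than regions; otherwise the graphical LASSO should be used.
    """
    if cov.kind != "covariance":
        raise ValueError("expects a covariance matrix")
    c = np.linalg.cond(cov.data)
    if not np.isfinite(c) or c > max_condition:
        raise np.linalg.LinAlgError(
            f"covariance is singular or ill-conditioned (cond={c:.3g}); "
            "use graphical_lasso for a regularized precision estimate")
    P = np.linalg.inv(cov.data)
    return ConnectivityMatrix((P + P.T) / 2.0, "inverse_covariance",
                              region_labels=cov.region_labels)


def partial_correlation(prec: ConnectivityMatrix) -> ConnectivityMatrix:
    """Partial correlation Theta_ij = -Pi_ij / sqrt(Pi_ii Pi_jj), unit diagonal."""
    if prec.kind not in ("inverse_covariance", "sparse_inverse_covariance"):
        raise ValueError("expects a precision (inverse covariance) matrix")
    d = np.diag(prec.data)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    s = np.sqrt(d)
    theta = -prec.data / np.outer(s, s)
    np.fill_diagonal(theta, 1.0)
    return ConnectivityMatrix((theta + theta.T) / 2.0, "partial_correlation",
                              region_labels=prec.region_labels)


def glasso_objective(omega: np.ndarray, sigma: np.ndarray,
                     lambda_: float) -> float:
    """Penalized Gaussian log-likelihood
    ``log det(Omega) - tr(Omega Sigma) - lambda * sum(|Omega|)`` (all entries).
    """
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return logdet - float(np.sum(omega * sigma)) - lambda_ * float(np.abs(omega).sum())


def graphical_lasso(cov: ConnectivityMatrix, lambda_: float,
                    tol: float = 1e-4, max_iter: int = 100,
                    on_nonconvergence: str = "warn") -> ConnectivityMatrix:
    """Sparse precision estimate maximizing the penalized log-likelihood.

    The penalty covers every entry of Omega including the diagonal. The
    stationarity conditions of that problem coincide with those of the
    off-diagonal-only problem after shifting the input covariance by
    ``lambda * I`` (the optimal working covariance has diagonal
    ``s_ii + lambda``), which is how the coordinate-descent solver is
    invoked. Sparsity comes from exact zeros of the solver, not from
    thresholding. ``lambda_ = 0`` requires an invertible covariance and
    returns its plain inverse.
    """
    if cov.kind != "covariance":
        raise ValueError("expects a covariance matrix")
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    S = cov.data
    if lambda_ == 0.0:
        inv = full_inverse_covariance(cov)
        return ConnectivityMatrix(inv.data, "sparse_inverse_covariance",
                                  lambda_=0.0, region_labels=cov.region_labels)
    shifted = S + lambda_ * np.eye(S.shape[0])
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, prec = _sk_graphical_lasso(shifted, alpha=lambda_, tol=tol,
                                          max_iter=max_iter)
        unconverged = [w for w in caught if "did not converge" in str(w.message)]
        if unconverged:
            msg = (f"graphical LASSO did not reach dual gap {tol} within "
                   f"{max_iter} iterations at lambda={lambda_}: "
                   f"{unconverged[0].message}")
            if on_nonconvergence == "raise":
                raise RuntimeError(msg)
            warnings.warn(msg, stacklevel=2)
    except FloatingPointError as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(
            f"graphical LASSO failed to converge at lambda={lambda_}: {exc}"
        ) from exc
    prec = (prec + prec.T) / 2.0
    eigmin = float(np.linalg.eigvalsh(prec)[0])
    if eigmin <= 0:  # pragma: no cover - guards solver breakdown
        raise RuntimeError(
            f"graphical LASSO returned a non-PD estimate (min eig {eigmin:.3g})")
    return ConnectivityMatrix(prec, "sparse_inverse_covariance",
                              lambda_=lambda_, region_labels=cov.region_labels)


def bic_score(omega: ConnectivityMatrix, cov: ConnectivityMatrix, n_t: int,
              count_symmetric_pairs_once: bool = True) -> BicRecord:
    """Bayesian Information Criterion of a precision estimate.

    ``BIC = -2 L + d log(n_t)`` with ``L = log det(Omega) - tr(Omega Sigma)``
    and ``d = m (m - 1) / 2`` where ``m`` counts the nonzero entries of
    Omega. By default symmetric pairs are counted once (lower triangle
    including the diagonal); set ``count_symmetric_pairs_once=False`` to
    count both copies of each off-diagonal nonzero.
    """
    if omega.data.shape != cov.data.shape:
        raise ValueError("shape mismatch between precision and covariance")
    sign, logdet = np.linalg.slogdet(omega.data)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    L = logdet - float(np.sum(omega.data * cov.data))
    tri = omega.data[np.tril_indices_from(omega.data)]
    m = int(np.count_nonzero(tri))
    if not count_symmetric_pairs_once:
        off = int(np.count_nonzero(omega.data[np.tril_indices_from(omega.data, -1)]))
        m += off  # add the upper-triangle copies
    d = m * (m - 1) // 2
    lam = omega.lambda_ if omega.lambda_ is not None else 0.0
    return BicRecord(lam, L, m, d, -2.0 * L + d * np.log(n_t))


def _concat_covariance(ts_list: list[RegionalTimeSeries]) -> tuple[ConnectivityMatrix, int]:
    X = np.vstack([t.data for t in ts_list])
    return sample_covariance(X), X.shape[0]


def _snap_to_grid(value: float, grid: list[float]) -> float:
    """Nearest grid value on the log10 scale; ties go to the larger (sparser) lambda."""
    logs = np.log10(np.asarray(grid, dtype=float))
    d = np.abs(logs - np.log10(value))
    best = d.min()
    candidates = [g for g, di in zip(grid, d) if di <= best + 1e-12]
    return max(candidates)


def select_lambda(ts_by_group: dict[int, list[RegionalTimeSeries]],
                  grid=(0.1, 0.01, 0.001),
                  tol: float = 1e-4, max_iter: int = 100) -> LambdaSelection:
    """BIC-based selection of the graphical-LASSO penalty.

    For every inner leave-one-subject-per-group-out fold, the retained
    subjects of each group are concatenated in time, Omega is estimated per
    grid value, and the BIC-minimizing lambda is recorded. Each group's
    winner is the modal lambda across folds; the pooled lambda is the
    arithmetic mean of the two winners snapped to the nearest grid value on
    the log scale (ties toward the larger, sparser value).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    groups = sorted(ts_by_group)
    sizes = {g: len(ts_by_group[g]) for g in groups}
    if min(sizes.values()) < 1:
        raise ValueError("need at least one subject per group")
    n_folds = min(sizes.values())
    if n_folds < 2:  # cannot leave one out and retain data
        n_folds = 1
    winners: dict[int, float] = {}
    traces: list[dict] = []
    for g in groups:
        votes: list[float] = []
        for fold in range(n_folds):
            if n_folds == 1:
                retained = ts_by_group[g]
            else:
                retained = [t for i, t in enumerate(ts_by_group[g]) if i != fold]
            try:
                cov, n_time = _concat_covariance(retained)
                records = [bic_score(graphical_lasso(cov, lam, tol, max_iter),
                                     cov, n_time) for lam in grid]
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"lambda selection fold {fold} (group {g}) "
                              f"failed: {exc}", stacklevel=2)
                continue
            bics = [r.bic for r in records]
            best = grid[int(np.argmin(bics))]
            votes.append(best)
            traces.append({"group": g, "fold": fold, "records": records,
                           "winner": best})
        if not votes:
            raise RuntimeError(f"all lambda-selection folds failed for group {g}")
        counts = Counter(votes)
        top = max(counts.values())
        winners[g] = max(lam for lam, c in counts.items() if c == top)
    pooled = _snap_to_grid(float(np.mean(list(winners.values()))), grid)
    return LambdaSelection(winners, pooled, traces)


def lower_index_map(n_p: int) -> list[tuple[int, int]]:
    """Canonical (i, j) order of the strictly-lower triangle: j ascending,
    then i ascending; q = n_p (n_p - 1) / 2 pairs."""
    return [(i, j) for j in range(n_p) for i in range(j + 1, n_p)]


def vectorize_lower(mat: ConnectivityMatrix, label: int | None = None
                    ) -> FeatureVector:
    """Vectorize the strictly-lower triangle in canonical order."""
    M = mat.data
    n_p = M.shape[0]
    idx = lower_index_map(n_p)
    rows = np.array([i for i, _ in idx])
    cols = np.array([j for _, j in idx])
    lbl = label if label is not None else 0
    return FeatureVector(M[rows, cols].copy(), lbl, idx)


def devectorize_lower(values: np.ndarray, n_p: int,
                      diagonal: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from canonical lower-triangle values."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != n_p * (n_p - 1) // 2:
        raise ValueError("length does not match n_p (n_p - 1) / 2")
    M = np.full((n_p, n_p), 0.0)
    for v, (i, j) in zip(values, lower_index_map(n_p)):
        M[i, j] = M[j, i] = v
    np.fill_diagonal(M, diagonal)
    return M
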