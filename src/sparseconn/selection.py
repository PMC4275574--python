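"""Nested LOSGO cross-validation with joint accuracy/stability selection.

The outer loop is leave-one-subject-per-group-out (LOSGO): each of the
``n_s`` folds holds out one patient and one control, so every subject is
tested exactly once. Inside each outer fold an inner LOSGO loop over the
remaining ``n_s - 1`` subject pairs selects the hyperparameters:

* the graphical-LASSO penalty lambda by the BIC, per group, on the
  concatenated training time-series (see `connectivity.select_lambda`);
* the SVM cost C jointly for accuracy and pattern stability. Stability is
  the chance-corrected mean support overlap across inner folds,
  ``O(s, s') = (|I_s ∩ I_s'| - |I_s||I_s'|/q) / max(|I_s|, |I_s'|)``,
  averaged over all fold pairs. Each inner fold votes for the C minimizing
  the distance to the ideal point,
  ``D = sqrt((1 - Acc)^2 + (1 - Obar)^2)``,
  and the modal vote wins (ties toward the smaller, sparser C).

The final model is refit on the whole dataset at the median of the per-fold
parameters (snapped toward the sparser grid point when between grid values).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import classify
from .connectivity import select_lambda
from .dataset import StudyData
from .inference import ConfusionTable, performance

__all__ = [
    "FoldPlan",
    "PipelineConfig",
    "FoldResult",
    "CVReport",
    "make_losgo_folds",
    "pairwise_overlap",
    "mean_stability",
    "selection_distance",
    "nested_cv",
    "refit_final",
]

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-5, 6))
DEFAULT_LAMBDA_GRID = (0.1, 0.01, 0.001)


@dataclass
class FoldPlan:
    """LOSGO fold layout: one (patient, control) index pair per fold."""

    pairs: list[tuple[int, int]]

    @property
    def n_folds(self) -> int:
        return len(self.pairs)


@dataclass
class PipelineConfig:
    """All knobs of the classification pipeline, with defaults matching the
    reference analysis where it states them (C grid 1e-5..1e5 in decade
    steps; lambda grid {0.1, 0.01, 0.001}; 100 permutations; FDR q 0.05)."""

    feature_kind: str = "sparse_inverse_covariance"
    penalty: str = "l1"
    C_grid: tuple = DEFAULT_C_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_perm: int = 100
    fdr_q: float = 0.05
    fdr_scope: str = "support"          # "support" or "all"
    aggregate_inner: bool = False        # aggregate-then-argmin alternative
    standardize: bool = False            # z-score features on training folds
    stratified_permutation: bool = False
    l2_trim_fraction: float = 0.01
    glasso_tol: float = 1e-4
    glasso_max_iter: int = 100
    svm_tol: float = 1e-6
    svm_max_iter: int = 10000

    def __post_init__(self) -> None:
        if not self.C_grid or not self.lambda_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")


@dataclass
class FoldResult:
    fold: int
    test_idx: tuple[int, int]
    test_subjects: tuple[str, str]
    chosen_C: float
    chosen_lambda: float | None
    y_true: tuple[int, int]
    y_pred: tuple[int, int]
    sparsity: float | None
    inner_stability: float
    support: np.ndarray
    inner_train_sets: list[tuple[int, ...]] = field(default_factory=list)


@dataclass
class CVReport:
    feature_kind: str
    penalty: str
    folds: list[FoldResult]
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: ConfusionTable
    accuracy: float        # percent
    sensitivity: float     # percent
    specificity: float     # percent
    sparsity_mean: float | None
    sparsity_sd: float | None
    stability_mean: float
    stability_sd: float
    outer_support_stability: float | None

    @property
    def chosen_Cs(self) -> list[float]:
        return [f.chosen_C for f in self.folds]

    @property
    def chosen_lambdas(self) -> list[float]:
        return [f.chosen_lambda for f in self.folds
                if f.chosen_lambda is not None]


def make_losgo_folds(labels, subject_ids=None) -> FoldPlan:
    """Pair each patient with a control by within-group sorted-id position.

    Requires balanced groups; every subject is held out exactly once.
    """
    labels = np.asarray(labels, dtype=int)
    if subject_ids is None:
        subject_ids = [f"sub{i:03d}" for i in range(labels.shape[0])]
    pat = np.flatnonzero(labels == 1)
    ctl = np.flatnonzero(labels == -1)
    if pat.size != ctl.size or pat.size == 0:
        raise ValueError(
            f"groups must be balanced and nonempty (got {pat.size} patients, "
            f"{ctl.size} controls)")
    pat = sorted(pat, key=lambda i: str(subject_ids[i]))
    ctl = sorted(ctl, key=lambda i: str(subject_ids[i]))
    return FoldPlan([(int(p), int(c)) for p, c in zip(pat, ctl)])


def pairwise_overlap(I_a, I_b, q: int) -> float:
    """Chance-corrected relative overlap of two support index sets.

    ``O = (|I_a ∩ I_b| - |I_a| |I_b| / q) / max(|I_a|, |I_b|)`` where the
    subtracted term is the hypergeometric expectation of the intersection of
    two random supports of those sizes. Empty sets give 0.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    A = np.asarray(I_a, dtype=int)
    B = np.asarray(I_b, dtype=int)
    na, nb = A.size, B.size
    if na == 0 and nb == 0:
        import warnings
        warnings.warn("both supports empty: overlap undefined, returning 0",
                      stacklevel=2)
        return 0.0
    if na == 0 or nb == 0:
        return 0.0
    inter = np.intersect1d(A, B, assume_unique=False).size
    expected = na * nb / q
    return (inter - expected) / max(na, nb)


def mean_stability(supports, q: int) -> float:
    """Mean pairwise overlap over all ordered fold pairs (s != s')."""
    n = len(supports)
    if n < 2:
        raise ValueError("need at least two supports")
    vals = [pairwise_overlap(supports[a], supports[b], q)
            for a in range(n) for b in range(a + 1, n)]
    return float(np.mean(vals))


def selection_distance(acc: float, stability: float) -> float:
    """Distance to the ideal point (accuracy 1, stability 1)."""
    return float(np.sqrt((1.0 - acc) ** 2 + (1.0 - stability) ** 2))


def _train(penalty: str, X, y, C: float, cfg: PipelineConfig
           ) -> classify.TrainedLinearModel:
    if penalty == "l1":
        return classify.train_l1_svm(X, y, C, cfg.svm_tol, cfg.svm_max_iter)
    return classify.train_l2_svm(X, y, C, cfg.svm_tol * 10, cfg.svm_max_iter)


def _support_of(model: classify.TrainedLinearModel, cfg: PipelineConfig
                ) -> np.ndarray:
    if model.penalty == "l1":
        return model.support
    return classify.l2_stability_support(model, cfg.l2_trim_fraction)


def _standardizer(X_train):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda X: (X - mu) / sd


def _pick_lambda(data: StudyData, train_idx, cfg: PipelineConfig) -> float:
    if len(cfg.lambda_grid) == 1:
        return float(cfg.lambda_grid[0])
    sel = select_lambda(data.timeseries_by_group(train_idx),
                        grid=cfg.lambda_grid, tol=cfg.glasso_tol,
                        max_iter=cfg.glasso_max_iter)
    return sel.pooled_lambda


def nested_cv(data: StudyData, config: PipelineConfig | None = None) -> CVReport:
    """Run the full nested LOSGO cross-validation and pool the predictions."""
    cfg = config or PipelineConfig()
    plan = make_losgo_folds(data.labels, data.subject_ids)
    n_s = plan.n_folds
    q = data.q
    C_grid = sorted(cfg.C_grid)
    y = data.labels
    fold_results: list[FoldResult] = []

    for k, test_pair in enumerate(plan.pairs):
        train_pairs = [p for i, p in enumerate(plan.pairs) if i != k]
        train_idx = np.array([i for p in train_pairs for i in p])
        lam = (_pick_lambda(data, train_idx, cfg)
               if cfg.feature_kind == "sparse_inverse_covariance" else None)
        X = data.feature_matrix(cfg.feature_kind, lam,
                                cfg.glasso_tol, cfg.glasso_max_iter)

        n_inner = len(train_pairs)
        inner_acc = np.zeros((n_inner, len(C_grid)))
        supports: list[list[np.ndarray]] = [[] for _ in C_grid]
        inner_sets: list[tuple[int, ...]] = []
        for j, inner_test in enumerate(train_pairs):
            inner_train = [i for p in train_pairs if p != inner_test
                           for i in p]
            if not inner_train:
                # degenerate geometry (one training pair): resubstitution
                inner_train = list(inner_test)
            inner_train = np.array(inner_train)
            inner_sets.append(tuple(int(i) for i in inner_train))
            Xtr, ytr = X[inner_train], y[inner_train]
            Xte = X[list(inner_test)]
            scale = _standardizer(Xtr) if cfg.standardize else (lambda Z: Z)
            for ci, C in enumerate(C_grid):
                model = _train(cfg.penalty, scale(Xtr), ytr, C, cfg)
                pred = classify.predict(model, scale(Xte))
                inner_acc[j, ci] = float(np.mean(pred == y[list(inner_test)]))
                supports[ci].append(_support_of(model, cfg))

        if n_inner >= 2:
            import warnings
            with warnings.catch_warnings():
                # tiny C values legitimately give empty supports; the
                # overlap of two empty supports is 0 by convention
                warnings.simplefilter("ignore", UserWarning)
                obar = np.array([mean_stability(supports[ci], q)
                                 for ci in range(len(C_grid))])
        else:  # single inner fold: stability undefined, select on accuracy
            obar = np.full(len(C_grid), np.nan)

        def _dist(acc_val, ci):
            if np.isnan(obar[ci]):
                return abs(1.0 - acc_val)
            return selection_distance(acc_val, obar[ci])

        if cfg.aggregate_inner:
            acc_bar = inner_acc.mean(axis=0)
            D = np.array([_dist(acc_bar[ci], ci) for ci in range(len(C_grid))])
            chosen_C = C_grid[int(np.argmin(D))]  # argmin takes first (smallest C)
        else:
            votes = []
            for j in range(n_inner):
                D = np.array([_dist(inner_acc[j, ci], ci)
                              for ci in range(len(C_grid))])
                votes.append(C_grid[int(np.argmin(D))])
            counts = Counter(votes)
            top = max(counts.values())
            chosen_C = min(c for c, n in counts.items() if n == top)

        ci = C_grid.index(chosen_C)
        Xtr, ytr = X[train_idx], y[train_idx]
        scale = _standardizer(Xtr) if cfg.standardize else (lambda Z: Z)
        model = _train(cfg.penalty, scale(Xtr), ytr, chosen_C, cfg)
        Xte = X[list(test_pair)]
        pred = classify.predict(model, scale(Xte))
        fold_results.append(FoldResult(
            fold=k, test_idx=test_pair,
            test_subjects=(data.subject_ids[test_pair[0]],
                           data.subject_ids[test_pair[1]]),
            chosen_C=chosen_C, chosen_lambda=lam,
            y_true=(int(y[test_pair[0]]), int(y[test_pair[1]])),
            y_pred=(int(pred[0]), int(pred[1])),
            sparsity=model.sparsity if cfg.penalty == "l1" else None,
            inner_stability=float(obar[ci]),
            support=_support_of(model, cfg),
            inner_train_sets=inner_sets))

    y_true = np.array([v for f in fold_results for v in f.y_true])
    y_pred = np.array([v for f in fold_results for v in f.y_pred])
    conf = ConfusionTable.from_predictions(y_true, y_pred)
    perf = performance(conf)
    sparsities = [f.sparsity for f in fold_results if f.sparsity is not None]
    stabilities = [f.inner_stability for f in fold_results
                   if not np.isnan(f.inner_stability)]
    outer_stab = (mean_stability([f.support for f in fold_results], q)
                  if n_s >= 2 else None)
    return CVReport(
        feature_kind=cfg.feature_kind, penalty=cfg.penalty, folds=fold_results,
        y_true=y_true, y_pred=y_pred, confusion=conf,
        accuracy=perf["accuracy"], sensitivity=perf["sensitivity"],
        specificity=perf["specificity"],
        sparsity_mean=float(np.mean(sparsities)) if sparsities else None,
        sparsity_sd=float(np.std(sparsities)) if sparsities else None,
        stability_mean=float(np.mean(stabilities)) if stabilities else np.nan,
        stability_sd=float(np.std(stabilities)) if stabilities else np.nan,
        outer_support_stability=outer_stab)


def _snap_down(value: float, grid) -> float:
    grid = sorted(grid)
    below = [g for g in grid if g <= value * (1 + 1e-12)]
    return below[-1] if below else grid[0]


def _snap_up(value: float, grid) -> float:
    grid = sorted(grid)
    above = [g for g in grid if g >= value * (1 - 1e-12)]
    return above[0] if above else grid[-1]


def refit_final(data: StudyData, config: PipelineConfig, report: CVReport
                ) -> tuple[classify.TrainedLinearModel, float | None]:
    """Retrain on the entire dataset at the median of the per-fold parameters.

    A median that falls between grid points snaps toward the sparser model:
    down for C (smaller C, stronger L1 pressure), up for lambda.
    """
    if not report.folds:
        raise ValueError("empty cross-validation report")
    C = _snap_down(float(np.median(report.chosen_Cs)), config.C_grid)
    lam = None
    if config.feature_kind == "sparse_inverse_covariance":
        lams = report.chosen_lambdas
        if not lams:
            raise ValueError("report carries no lambda choices")
        lam = _snap_up(float(np.median(lams)), config.lambda_grid)
    X = data.feature_matrix(config.feature_kind, lam,
                            config.glasso_tol, config.glasso_max_iter)
    scale = _standardizer(X) if config.standardize else (lambda Z: Z)
    model = _train(config.penalty, scale(X), data.labels, C, config)
    model.meta.update({"lambda": lam, "refit": "median-parameter, full data"})
    return model, lam
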