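"""Performance metrics, permutation tests and the discriminative network.

Classifier performance is summarized by accuracy, sensitivity and
specificity (patients are the positive class). Significance is assessed by
label permutation: the entire framework — nested cross-validation included —
is rerun on shuffled labels, giving a null distribution of the pooled
accuracy and, for the sparse classifier, of every connection weight of the
median-parameter refit. Permutation p-values are floored at ``1/n_perm``.
Per-connection p-values are two-sided on |w| and corrected by
Benjamini-Hochberg FDR; the surviving connections and their per-region
degrees form the discriminative network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import StudyData

__all__ = [
    "ConfusionTable",
    "PermutationNull",
    "DiscriminativeNetwork",
    "performance",
    "permutation_pvalue",
    "run_permutation_study",
    "permutation_test_accuracy",
    "permutation_test_weights",
    "node_degrees",
]


@dataclass
class ConfusionTable:
    """Counts with patients (+1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionTable":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fp=int(np.sum((y_true == -1) & (y_pred == 1))),
                   tn=int(np.sum((y_true == -1) & (y_pred == -1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == -1))))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def performance(conf: ConfusionTable) -> dict:
    """Accuracy, sensitivity and specificity in percent.

    ``sensitivity = TP/(TP+FN)`` (patients classified as patients),
    ``specificity = TN/(TN+FP)``. A zero denominator yields NaN (undefined),
    never 0.
    """
    def _pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": _pct(conf.tp + conf.tn, conf.n),
        "sensitivity": _pct(conf.tp, conf.tp + conf.fn),
        "specificity": _pct(conf.tn, conf.tn + conf.fp),
    }


def permutation_pvalue(n_ge: int, n_perm: int) -> float:
    """``p = max(1/n_perm, n_ge/n_perm)``: the attainable floor is 1/n_perm."""
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if not 0 <= n_ge <= n_perm:
        raise ValueError("n_ge must lie in [0, n_perm]")
    return max(1.0 / n_perm, n_ge / n_perm)


@dataclass
class PermutationNull:
    """Null distribution from label-permuted reruns of the pipeline."""

    n_perm: int
    seed: int
    observed: float                      # pooled accuracy (percent)
    null_accuracies: np.ndarray          # (n_perm,)
    p_value: float
    observed_weights: np.ndarray | None = None
    null_weights: np.ndarray | None = None   # (n_perm, q)
    perm_seeds: list[int] = field(default_factory=list)


@dataclass
class DiscriminativeNetwork:
    """FDR-screened connections of the refit sparse model."""

    edges: pd.DataFrame       # region_i, region_j, weight, p_value, significant
    node_degrees: pd.Series   # region -> number of significant edges
    n_perm: int
    fdr_q: float


def _permute_labels(labels: np.ndarray, rng: np.random.Generator,
                    stratified: bool, pairs=None) -> np.ndarray:
    if not stratified:
        return rng.permutation(labels)
    # stratified: independently swap the labels within each LOSGO pair
    out = labels.copy()
    for p, c in pairs:
        if rng.random() < 0.5:
            out[p], out[c] = out[c], out[p]
    return out


def run_permutation_study(data: StudyData, config=None, n_perm: int = 100,
                          seed: int = 0, collect_weights: bool = True,
                          progress: bool = False) -> PermutationNull:
    """Observed pipeline plus ``n_perm`` label-permuted reruns.

    Each permutation uniformly shuffles the subject labels (which preserves
    the group sizes), reruns the nested cross-validation and, when
    ``collect_weights`` is set, the median-parameter refit. Permutation
    ``b`` uses seed ``seed + b + 1``, logged for exact replay. Observed
    accuracies tied with a null count as "equal or higher".
    """
    from .selection import PipelineConfig, make_losgo_folds, nested_cv, refit_final

    cfg = config or PipelineConfig()
    report = nested_cv(data, cfg)
    obs_weights = None
    if collect_weights:
        model, _ = refit_final(data, cfg, report)
        obs_weights = model.weights
    pairs = make_losgo_folds(data.labels, data.subject_ids).pairs
    null_acc = np.empty(n_perm)
    null_w = np.empty((n_perm, data.q)) if collect_weights else None
    perm_seeds = []
    for b in range(n_perm):
        s = seed + b + 1
        perm_seeds.append(s)
        rng = np.random.default_rng(s)
        perm = _permute_labels(data.labels, rng, cfg.stratified_permutation,
                               pairs)
        pdata = data.with_labels(perm)
        prep = nested_cv(pdata, cfg)
        null_acc[b] = prep.accuracy
        if collect_weights:
            pmodel, _ = refit_final(pdata, cfg, prep)
            null_w[b] = pmodel.weights
        if progress:  # pragma: no cover - console feedback only
            print(f"permutation {b + 1}/{n_perm}: "
                  f"accuracy {null_acc[b]:.1f}%", flush=True)
    n_ge = int(np.sum(null_acc >= report.accuracy))
    return PermutationNull(
        n_perm=n_perm, seed=seed, observed=report.accuracy,
        null_accuracies=null_acc,
        p_value=permutation_pvalue(n_ge, n_perm),
        observed_weights=obs_weights, null_weights=null_w,
        perm_seeds=perm_seeds)


def permutation_test_accuracy(data: StudyData, config=None, n_perm: int = 100,
                              seed: int = 0) -> PermutationNull:
    """Permutation test of the pooled nested-CV accuracy."""
    return run_permutation_study(data, config, n_perm, seed,
                                 collect_weights=False)


def _l1_normalized(W: np.ndarray) -> np.ndarray:
    W = np.atleast_2d(W)
    norms = np.abs(W).sum(axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return W / norms


def permutation_test_weights(data: StudyData, config=None, n_perm: int = 100,
                             seed: int = 0, fdr_q: float | None = None,
                             region_labels=None,
                             null: PermutationNull | None = None,
                             statistic: str = "relative"
                             ) -> DiscriminativeNetwork:
    """Per-connection permutation test of the refit weight vector.

    Two-sided: the p-value of connection ``e`` is the floored fraction of
    permutations whose null statistic magnitude reaches the observed one (a
    zero observed weight therefore gets p = 1). The default statistic is the
    *relative* weight ``|w_e| / ||w||_1``: the decision function
    ``sign(w'x)`` identifies only the direction of ``w``, and refits on
    permuted labels carry systematically larger norms (less separable data
    pushes the squared-hinge solution outward), so comparing raw magnitudes
    confounds pattern with scale. ``statistic="raw"`` compares unnormalized
    weights. Benjamini-Hochberg FDR is applied over the refit support by
    default (``config.fdr_scope = "all"`` corrects over all q connections
    instead). A precomputed `PermutationNull` carrying weights can be passed
    to reuse its permutations.
    """
    from .selection import PipelineConfig

    cfg = config or PipelineConfig()
    if null is None:
        null = run_permutation_study(data, cfg, n_perm, seed,
                                     collect_weights=True)
    if null.observed_weights is None or null.null_weights is None:
        raise ValueError("permutation null carries no weight vectors")
    if statistic not in ("relative", "raw"):
        raise ValueError("statistic must be 'relative' or 'raw'")
    q_level = cfg.fdr_q if fdr_q is None else fdr_q
    w_obs = null.observed_weights
    n_perm = null.n_perm
    if statistic == "relative":
        W_stat = _l1_normalized(null.null_weights)
        w_stat = _l1_normalized(w_obs)[0]
    else:
        W_stat = null.null_weights
        w_stat = w_obs
    n_ge = np.sum(np.abs(W_stat) >= np.abs(w_stat)[None, :], axis=0)
    pvals = np.maximum(1.0 / n_perm, n_ge / n_perm)

    idx_map = data.index_map
    if region_labels is None:
        region_labels = [f"region{r:03d}" for r in range(data.n_regions)]
    support = np.flatnonzero(np.abs(w_obs) > 1e-8)
    significant = np.zeros(w_obs.shape[0], dtype=bool)
    if cfg.fdr_scope == "all":
        if pvals.size:
            rej, _, _, _ = multipletests(pvals, alpha=q_level, method="fdr_bh")
            significant = rej
    else:
        if support.size:
            rej, _, _, _ = multipletests(pvals[support], alpha=q_level,
                                         method="fdr_bh")
            significant[support] = rej
    rows = [{
        "region_i": region_labels[idx_map[e][0]],
        "region_j": region_labels[idx_map[e][1]],
        "i": idx_map[e][0], "j": idx_map[e][1],
        "weight": w_obs[e], "p_value": pvals[e],
        "significant": bool(significant[e]),
    } for e in support]
    edges = pd.DataFrame(rows, columns=["region_i", "region_j", "i", "j",
                                        "weight", "p_value", "significant"])
    degrees = node_degrees(edges, region_labels)
    return DiscriminativeNetwork(edges=edges, node_degrees=degrees,
                                 n_perm=n_perm, fdr_q=q_level)


def node_degrees(edges: pd.DataFrame, region_labels=None) -> pd.Series:
    """Number of significant edges incident to each region, descending."""
    counts: dict[str, int] = {}
    if region_labels is not None:
        counts = {r: 0 for r in region_labels}
    if len(edges):
        for _, row in edges[edges["significant"]].iterrows():
            counts[row["region_i"]] = counts.get(row["region_i"], 0) + 1
            counts[row["region_j"]] = counts.get(row["region_j"], 0) + 1
    s = pd.Series(counts, dtype=int, name="degree")
    return s.sort_values(ascending=False, kind="stable")
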