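"""Study-level container for per-subject features with caching.

`StudyData` owns the per-subject regional time-series (or precomputed
feature vectors), the class labels and subject identifiers. Connectivity
features are computed lazily per (kind, lambda) and cached; the cache is a
function only of the time-series, never of the labels, so label-permuted
copies created by `with_labels` share it. This makes permutation tests
(which rerun the whole nested cross-validation on shuffled labels) orders of
magnitude cheaper without any train/test leakage: every feature is computed
from one subject's own data alone.
"""

from __future__ import annotations

import numpy as np

from . import connectivity as conn
from .preprocess import RegionalTimeSeries

__all__ = ["StudyData"]

FEATURE_KINDS = ("covariance", "correlation", "inverse_covariance",
                 "partial_correlation", "sparse_inverse_covariance")


class StudyData:
    """Balanced two-group collection of subjects and their features."""

    def __init__(self, labels, subject_ids, timeseries=None, features=None,
                 index_map=None, _cache=None):
        self.labels = np.asarray(labels, dtype=int)
        self.subject_ids = list(subject_ids)
        self.timeseries: list[RegionalTimeSeries] | None = timeseries
        self._features = features      # dict kind -> (n_subjects, q) array
        self._index_map = index_map
        self._cache = _cache if _cache is not None else {}
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be coded -1 (control) / +1 (patient)")
        if len(self.subject_ids) != self.labels.shape[0]:
            raise ValueError("one subject id per label required")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_timeseries(cls, ts_list: list[RegionalTimeSeries]) -> "StudyData":
        labels = [t.group for t in ts_list]
        ids = [t.subject_id or f"sub{i:03d}" for i, t in enumerate(ts_list)]
        return cls(labels, ids, timeseries=list(ts_list))

    @classmethod
    def from_features(cls, X, labels, subject_ids=None, index_map=None,
                      kind: str = "sparse_inverse_covariance") -> "StudyData":
        X = np.asarray(X, dtype=float)
        if subject_ids is None:
            subject_ids = [f"sub{i:03d}" for i in range(X.shape[0])]
        return cls(labels, subject_ids, features={kind: X}, index_map=index_map)

    def with_labels(self, labels) -> "StudyData":
        """Copy with new labels, sharing the (label-independent) feature cache."""
        return StudyData(labels, self.subject_ids, self.timeseries,
                         self._features, self._index_map, self._cache)

    # -- basic properties --------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]

    @property
    def n_per_group(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_regions(self) -> int:
        if self.timeseries is not None:
            return self.timeseries[0].n_p
        q = next(iter(self._features.values())).shape[1]
        # invert q = p (p - 1) / 2
        return int(round((1 + np.sqrt(1 + 8 * q)) / 2))

    @property
    def q(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def index_map(self) -> list[tuple[int, int]]:
        if self._index_map is None:
            self._index_map = conn.lower_index_map(self.n_regions)
        return self._index_map

    # -- feature computation ----------------------------------------------
    def covariance(self, subject: int) -> conn.ConnectivityMatrix:
        key = ("cov", subject)
        if key not in self._cache:
            self._cache[key] = conn.sample_covariance(self.timeseries[subject])
        return self._cache[key]

    def feature_matrix(self, kind: str, lambda_: float | None = None,
                       glasso_tol: float = 1e-4,
                       glasso_max_iter: int = 100) -> np.ndarray:
        """(n_subjects, q) feature matrix of the requested connectivity kind."""
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        if self._features is not None and kind in self._features:
            # features supplied directly: they are fixed, lambda is moot
            return self._features[kind]
        if self.timeseries is None:
            raise ValueError(f"no time-series available to compute {kind!r}")
        if kind == "sparse_inverse_covariance":
            if lambda_ is None:
                raise ValueError("sparse_inverse_covariance requires lambda_")
            key = (kind, float(lambda_))
        else:
            key = (kind, None)
        if key not in self._cache:
            rows = []
            for s in range(self.n_subjects):
                cov = self.covariance(s)
                if kind == "covariance":
                    mat = cov
                elif kind == "correlation":
                    mat = conn.pearson_correlation(self.timeseries[s])
                elif kind == "inverse_covariance":
                    mat = conn.full_inverse_covariance(cov)
                elif kind == "partial_correlation":
                    mat = conn.partial_correlation(conn.full_inverse_covariance(cov))
                else:
                    mat = conn.graphical_lasso(cov, lambda_, tol=glasso_tol,
                                               max_iter=glasso_max_iter)
                rows.append(conn.vectorize_lower(mat).values)
            self._cache[key] = np.vstack(rows)
        return self._cache[key]

    def timeseries_by_group(self, subset: np.ndarray | None = None
                            ) -> dict[int, list[RegionalTimeSeries]]:
        """Group -> list of time-series, optionally restricted to a subset of
        subject indices (order follows the subset)."""
        if self.timeseries is None:
            raise ValueError("no time-series in this dataset")
        idx = np.arange(self.n_subjects) if subset is None else np.asarray(subset)
        out: dict[int, list[RegionalTimeSeries]] = {-1: [], 1: []}
        for i in idx:
            out[int(self.labels[i])].append(self.timeseries[i])
        return out
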