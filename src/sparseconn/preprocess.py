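"""Confound removal and high-pass filtering of regional BOLD time-series.

A subject's raw data is an ``n_t x n_p`` matrix of regional mean BOLD signals
(rows are scans, columns are atlas regions). Before connectivity estimation
the six rigid-body motion parameters (when available) are regressed out with
a residual-forming projector, and slow scanner drifts are removed by
projecting out a discrete-cosine (DCT) basis of periods longer than a cutoff
(default 128 s). An intercept is always removed so that downstream covariance
estimation sees zero-mean columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawTimeSeries",
    "RegionalTimeSeries",
    "regional_means",
    "residual_forming",
    "dct_drift_basis",
    "clean_timeseries",
]


@dataclass
class RawTimeSeries:
    """Unprocessed regional time-series for one subject.

    Parameters
    ----------
    data : ndarray of shape (n_t, n_p)
        BOLD signal, one column per region.
    tr_seconds : float
        Repetition time (time between scans) in seconds.
    subject_id : str
        Opaque subject identifier.
    group : int
        Class label: ``+1`` patient, ``-1`` control.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    group: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time-series must be a 2-D array with n_t >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series contains non-finite values")

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_p(self) -> int:
        return self.data.shape[1]


@dataclass
class RegionalTimeSeries:
    """Confound-removed, high-pass-filtered regional time-series."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    group: int = 0
    provenance: list[str] = field(default_factory=list)

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_p(self) -> int:
        return self.data.shape[1]


def regional_means(voxel_image: np.ndarray, parcellation: np.ndarray,
                   tr_seconds: float = 2.0, subject_id: str = "",
                   group: int = 0) -> RawTimeSeries:
    """Average a 4-D voxel image over each atlas region.

    Parameters
    ----------
    voxel_image : ndarray of shape (x, y, z, n_t)
        Voxel intensities over time.
    parcellation : ndarray of shape (x, y, z)
        Integer region labels; 0 denotes background and is ignored.

    Returns
    -------
    RawTimeSeries
        Column ``r`` holds the spatial mean over voxels with the ``r``-th
        smallest nonzero label, so columns follow ascending label order.
    """
    voxel_image = np.asarray(voxel_image, dtype=float)
    parcellation = np.asarray(parcellation)
    if voxel_image.ndim != 4:
        raise ValueError("voxel_image must be 4-D (x, y, z, t)")
    if parcellation.shape != voxel_image.shape[:3]:
        raise ValueError(
            f"parcellation grid {parcellation.shape} does not match image "
            f"grid {voxel_image.shape[:3]}")
    labels = np.unique(parcellation)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("parcellation contains no nonzero labels")
    n_t = voxel_image.shape[3]
    flat = voxel_image.reshape(-1, n_t)
    lab_flat = parcellation.reshape(-1)
    cols = np.empty((n_t, labels.size))
    for r, lab in enumerate(labels):
        mask = lab_flat == lab
        if not mask.any():
            raise ValueError(f"label {lab} has no voxels")
        cols[:, r] = flat[mask].mean(axis=0)
    return RawTimeSeries(cols, tr_seconds, subject_id, group)


def residual_forming(confounds: np.ndarray) -> np.ndarray:
    """Residual-forming projector ``R = I - C (C'C)^+ C'``.

    ``R`` is the symmetric idempotent matrix that maps any time-series onto
    the orthogonal complement of the column span of the confounds ``C``
    (n_t rows, n_c < n_t columns). Rank-deficient confound matrices are
    handled by the pseudoinverse.
    """
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] == 1 and C.shape[1] > 1:  # a single confound as a row
        C = C.T
    n_t, n_c = C.shape
    if n_c >= n_t:
        raise ValueError(f"need fewer confounds ({n_c}) than time-points ({n_t})")
    return np.eye(n_t) - C @ np.linalg.pinv(C.T @ C) @ C.T


def dct_drift_basis(n_t: int, tr_seconds: float,
                    cutoff_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis with periods longer than ``cutoff_seconds``.

    Returns the ``K = floor(2 * n_t * tr / cutoff)`` lowest-frequency DCT-II
    basis vectors (the constant term excluded; demeaning is handled
    separately), as an ``(n_t, K)`` matrix of mutually orthogonal columns.
    For the 180-scan, TR = 2 s acquisition with the 128 s cutoff this yields
    the conventional five regressors.
    """
    if n_t < 2:
        raise ValueError("need n_t >= 2")
    if cutoff_seconds <= 2 * tr_seconds:
        raise ValueError("cutoff must exceed twice the repetition time")
    K = int(np.floor(2.0 * n_t * tr_seconds / cutoff_seconds))
    if K == 0:
        warnings.warn("cutoff longer than twice the scan duration: "
                      "empty drift basis", stacklevel=2)
        return np.empty((n_t, 0))
    t = np.arange(n_t)
    k = np.arange(1, K + 1)
    basis = np.sqrt(2.0 / n_t) * np.cos(
        np.pi * np.outer(2 * t + 1, k) / (2.0 * n_t))
    return basis


def clean_timeseries(raw: RawTimeSeries, motion: np.ndarray | None = None,
                     cutoff_seconds: float = 128.0,
                     dct_k: int | None = None) -> RegionalTimeSeries:
    """Remove motion confounds, then slow drifts, from a raw time-series.

    The motion parameters (plus an intercept, always included) are projected
    out first with a residual-forming matrix; the DCT drift basis is then
    projected out of the result, matching the sequential order of the
    original procedure. ``dct_k`` overrides the cutoff-derived number of
    drift regressors (e.g. to force exactly five for any geometry).

    With no motion file and an empty drift basis the output is simply the
    column-centered copy of the input.
    """
    if np.any(raw.data.std(axis=0) == 0):
        bad = int(np.flatnonzero(raw.data.std(axis=0) == 0)[0])
        raise ValueError(f"region column {bad} has zero variance")
    data = raw.data
    prov: list[str] = []
    intercept = np.ones((raw.n_t, 1))
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != raw.n_t:
            raise ValueError("motion parameters must have n_t rows")
        R = residual_forming(np.hstack([intercept, motion]))
        data = R @ data
        prov.append(f"motion_residualized(n_c={motion.shape[1]}+intercept)")
    else:
        data = data - data.mean(axis=0)
        prov.append("centered")
    if dct_k is not None:
        t = np.arange(raw.n_t)
        k = np.arange(1, dct_k + 1)
        basis = np.sqrt(2.0 / raw.n_t) * np.cos(
            np.pi * np.outer(2 * t + 1, k) / (2.0 * raw.n_t))
        prov.append(f"dct_filtered(K={dct_k}, forced)")
    else:
        basis = dct_drift_basis(raw.n_t, raw.tr_seconds, cutoff_seconds)
        prov.append(f"dct_filtered(K={basis.shape[1]}, cutoff={cutoff_seconds}s)")
    if basis.shape[1] > 0:
        data = residual_forming(basis) @ data
    return RegionalTimeSeries(data, raw.tr_seconds, raw.subject_id,
                              raw.group, prov)
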