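"""Per-subject pairwise channel connectivity.

Resting-state functional connectivity is the Pearson correlation between the
band-limited Δ[oxy-Hb] time courses of every pair of measurement channels
(94 channels → 4371 pairs), computed over the retained (artifact-free)
samples only.  Fisher's variance-stabilizing transform z(r) = atanh(r) is
applied before any group-level statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .artifacts import AnalysisWindow
from .hemodynamics import HemoTimeSeries

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject correlation structure.

    ``r`` has unit diagonal; ``z`` is atanh(r) off-diagonal with NaN on the
    diagonal (z(1) is undefined).  Channels with zero variance over the
    retained samples have their rows/columns masked to NaN.
    """

    subject_id: str
    r: np.ndarray
    z: np.ndarray = field(repr=False)
    n_samples_used: int = 0

    @property
    def n_channels(self) -> int:
        return self.r.shape[0]


def count_pairs(n_channels: int) -> int:
    """Number of unordered channel pairs, C(n, 2)."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    return n_channels * (n_channels - 1) // 2


def fisher_z(r):
    """Fisher's z-transformation z(r) = atanh(r) = ½·ln((1+r)/(1−r)).

    Values with |r| ≥ 1 (degenerate inputs) are clipped to ±(1 − 1e−7) with
    a warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("|r| >= 1 clipped before Fisher transform", RuntimeWarning)
        r = np.clip(r, -_CLIP, _CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pair_index(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (row, col) 0-based indices in lexicographic pair order."""
    return np.triu_indices(n_channels, k=1)


def pair_labels(n_channels: int) -> list[tuple[int, int]]:
    """1-based (low, high) channel labels in the same order as ``pair_index``."""
    i, j = pair_index(n_channels)
    return [(int(a) + 1, int(b) + 1) for a, b in zip(i, j)]


class PairwiseConnectivity(TransformerMixin, BaseEstimator):
    """Compute a per-subject correlation matrix over retained samples.

    ``transform`` takes a ``[time, channel]`` array (optionally with a
    boolean retention mask given to ``fit``/``transform``) and returns the
    Fisher-z matrix; use :func:`pairwise_correlation` for the full domain
    container.
    """

    def __init__(self, use_fisher_z: bool = True):
        self.use_fisher_z = use_fisher_z

    def fit(self, X=None, y=None):
        self.n_features_in_ = None if X is None else np.asarray(X).shape[1]
        return self

    def transform(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        r = self.correlation(X, mask)
        if not self.use_fisher_z:
            return r
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
        np.fill_diagonal(z, np.nan)
        return z

    @staticmethod
    def correlation(X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if mask is not None:
            X = X[np.asarray(mask, dtype=bool)]
        if X.shape[0] < 3:
            raise ValueError("need at least 3 retained samples for correlation")
        sd = X.std(axis=0)
        dead = sd == 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} channel(s) with zero variance masked", RuntimeWarning
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
        r[dead, :] = np.nan
        r[:, dead] = np.nan
        keep = ~dead
        r[np.ix_(keep, keep)] = np.clip(r[np.ix_(keep, keep)], -1.0, 1.0)
        np.fill_diagonal(r, np.where(dead, np.nan, 1.0))
        return r


def pairwise_correlation(
    series: HemoTimeSeries,
    window: AnalysisWindow | None = None,
    signal: str = "oxy",
    min_samples: int = 100,
) -> ConnectivityMatrix:
    """Pearson r and Fisher z over retained samples for one subject.

    Retained segments are concatenated into a single pooled estimate (one r
    per pair per subject).  ``signal`` selects the chromophore; the analysis
    convention is Δ[oxy-Hb].
    """
    if signal not in ("oxy", "deoxy"):
        raise ValueError("signal must be 'oxy' or 'deoxy'")
    data = series.oxy if signal == "oxy" else series.deoxy
    mask = None
    if window is not None:
        mask = np.asarray(window.retained_mask, dtype=bool)
        if mask.shape[0] != data.shape[0]:
            raise ValueError("retention mask length does not match series")
    n_used = int(data.shape[0] if mask is None else mask.sum())
    if n_used < min_samples:
        raise ValueError(
            f"only {n_used} retained samples; need at least {min_samples}"
        )
    est = PairwiseConnectivity(use_fisher_z=False)
    r = est.correlation(data, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(
        subject_id=series.subject_id, r=r, z=z, n_samples_used=n_used
    )


def seed_map(matrix: ConnectivityMatrix, seed_channel: int) -> np.ndarray:
    """Fisher-z connectivity of one channel to all others (seed masked to NaN).

    ``seed_channel`` is 1-based, matching instrument channel labels.
    """
    if not 1 <= seed_channel <= matrix.n_channels:
        raise IndexError(
            f"seed channel {seed_channel} outside 1..{matrix.n_channels}"
        )
    row = matrix.z[seed_channel - 1].copy()
    row[seed_channel - 1] = np.nan
    return row
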