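"""Group-level connectivity statistics.

Per-pair Fisher-z values are compared across subjects with ordinary t
statistics which are then standardized by the null t-distribution's moments
(mean 0, standard deviation sqrt(df/(df−2))), yielding an approximately
standard-normal map statistic::

    z = (t − E[t]) / σ[t] = t / sqrt(df / (df − 2))

Three analyses are provided, all uncorrected for multiple comparisons by
convention (a Bonferroni option exists but is off by default):

* one-sample maps: is mean z(r) ≠ 0 within a group (df = n − 1);
* preterm vs full-term two-sample comparison, thresholded at |z| > 3.29
  (two-sided p < 0.001, one-sided p < 0.0005);
* developmental trends: Pearson correlation of z(r) with postmenstrual age
  at scan, thresholded at p < 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .connectivity import pair_labels


@dataclass(frozen=True)
class InferenceConfig:
    group_z_threshold: float = 3.29
    map_display_threshold: float = 0.0
    trend_p_threshold: float = 0.005
    two_sample_variance: str = "pooled"  # "pooled" | "welch"
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.group_z_threshold <= 0:
            raise ValueError("group_z_threshold must be positive")
        if not 0 < self.trend_p_threshold < 1:
            raise ValueError("trend_p_threshold must lie in (0, 1)")
        if self.two_sample_variance not in ("pooled", "welch"):
            raise ValueError("two_sample_variance must be 'pooled' or 'welch'")


def t_to_z(t, df):
    """Standardize a t statistic by the null t-distribution's moments.

    Requires df > 2 (the t distribution has no finite variance otherwise).
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.asarray(df) <= 2):
        raise ValueError("t-to-z conversion requires df > 2")
    out = t / np.sqrt(df / (df - 2.0))
    return float(out) if out.ndim == 0 else out


def z_threshold_for_p(p: float) -> float:
    """Upper-tail standard-normal quantile Φ⁻¹(1 − p)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return float(stats.norm.ppf(1.0 - p))


def two_sample_t(a, b, variance: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test, first sample minus second. Returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=(variance == "pooled"))
    df = (
        len(a) + len(b) - 2
        if variance == "pooled"
        else float(res.df)  # Welch–Satterthwaite
    )
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance: t statistic undefined")
    return float(res.statistic), float(df), float(res.pvalue)


class OneSampleZMap(BaseEstimator):
    """One-sample t-test of mean Fisher-z against zero, per channel pair.

    ``fit`` takes a ``[subjects, pairs]`` stack and exposes ``mean_z_``,
    ``t_``, ``df_``, ``z_`` and the display mask ``above_threshold_``.
    Pairs with zero across-subject variance are masked to NaN.
    """

    def __init__(self, config: InferenceConfig | None = None):
        self.config = config

    def fit(self, Z: np.ndarray, y=None):
        cfg = self.config if self.config is not None else InferenceConfig()
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[0] < 3:
            raise ValueError("need a [subjects >= 3, pairs] stack")
        n = Z.shape[0]
        mean = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        dead = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(dead, np.nan, mean / (sd / np.sqrt(n)))
        self.n_subjects_ = n
        self.df_ = n - 1
        self.mean_z_ = mean
        self.t_ = t
        self.z_ = t_to_z(np.where(dead, 0.0, t), self.df_)
        self.z_[dead] = np.nan
        self.above_threshold_ = self.z_ > cfg.map_display_threshold
        return self


class GroupComparison(BaseEstimator):
    """Two-sample comparison of Fisher-z stacks (group A minus group B).

    ``fit(Z_a, Z_b)`` exposes per-pair ``t_``, ``df_``, ``z_``,
    ``significant_`` (|z| above the threshold) and ``direction_``
    ("a_higher" / "b_higher").
    """

    def __init__(self, config: InferenceConfig | None = None):
        self.config = config

    def fit(self, Z_a: np.ndarray, Z_b: np.ndarray):
        cfg = self.config if self.config is not None else InferenceConfig()
        Z_a = np.asarray(Z_a, dtype=float)
        Z_b = np.asarray(Z_b, dtype=float)
        if Z_a.ndim != 2 or Z_b.ndim != 2 or Z_a.shape[1] != Z_b.shape[1]:
            raise ValueError("stacks must be [subjects, pairs] with equal pair axes")
        if Z_a.shape[0] < 3 or Z_b.shape[0] < 3:
            raise ValueError("each group needs at least 3 subjects")
        n1, n2 = Z_a.shape[0], Z_b.shape[0]
        m1, m2 = Z_a.mean(axis=0), Z_b.mean(axis=0)
        v1 = Z_a.var(axis=0, ddof=1)
        v2 = Z_b.var(axis=0, ddof=1)
        if cfg.two_sample_variance == "pooled":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full_like(m1, float(n1 + n2 - 2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            with np.errstate(invalid="ignore", divide="ignore"):
                df = (v1 / n1 + v2 / n2) ** 2 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
        dead = se == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(dead, np.nan, (m1 - m2) / se)
        z = np.full_like(t, np.nan)
        ok = ~dead & (df > 2)
        z[ok] = t_to_z(t[ok], df[ok])
        threshold = cfg.group_z_threshold
        if cfg.bonferroni:
            n_pairs = Z_a.shape[1]
            p_single = 2 * stats.norm.sf(threshold)
            threshold = z_threshold_for_p(p_single / (2 * n_pairs))
        self.mean_diff_ = m1 - m2
        self.t_ = t
        self.df_ = df
        self.z_ = z
        self.threshold_ = threshold
        self.significant_ = np.abs(np.nan_to_num(z)) > threshold
        self.direction_ = np.where(m1 >= m2, "a_higher", "b_higher")
        return self

    def to_frame(self, n_channels: int, a_label: str = "preterm",
                 b_label: str = "fullterm") -> pd.DataFrame:
        labels = pair_labels(n_channels)
        direction = np.where(
            self.direction_ == "a_higher", f"{a_label}_higher", f"{b_label}_higher"
        )
        return pd.DataFrame(
            {
                "ch_low": [p[0] for p in labels],
                "ch_high": [p[1] for p in labels],
                "t": self.t_,
                "df": self.df_,
                "z": self.z_,
                "direction": direction,
                "significant": self.significant_,
            }
        )


class PMATrend(BaseEstimator):
    """Pearson correlation of per-pair Fisher-z with postmenstrual age.

    ``fit(Z, pma_weeks)`` exposes ``r_``, ``p_`` (two-tailed, from
    t = r·sqrt((n−2)/(1−r²)) with df = n − 2) and ``significant_``.
    """

    def __init__(self, config: InferenceConfig | None = None):
        self.config = config

    def fit(self, Z: np.ndarray, pma_weeks: np.ndarray):
        cfg = self.config if self.config is not None else InferenceConfig()
        Z = np.asarray(Z, dtype=float)
        pma = np.asarray(pma_weeks, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != len(pma):
            raise ValueError("Z must be [subjects, pairs] aligned with pma_weeks")
        if len(pma) < 5:
            raise ValueError("need at least 5 subjects for a trend")
        if np.ptp(pma) == 0:
            raise ValueError("PMA values are all equal; trend undefined")
        n = len(pma)
        pc = pma - pma.mean()
        Zc = Z - Z.mean(axis=0)
        denom = np.sqrt((pc**2).sum() * (Zc**2).sum(axis=0))
        dead = denom == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(dead, np.nan, pc @ Zc / denom)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        threshold = cfg.trend_p_threshold
        if cfg.bonferroni:
            threshold = threshold / Z.shape[1]
        self.n_subjects_ = n
        self.df_ = n - 2
        self.r_ = r
        self.p_ = p
        self.significant_ = np.where(dead, False, p < threshold)
        return self

    def to_frame(self, n_channels: int, group: str = "") -> pd.DataFrame:
        labels = pair_labels(n_channels)
        return pd.DataFrame(
            {
                "ch_low": [p[0] for p in labels],
                "ch_high": [p[1] for p in labels],
                "group": group,
                "r_pma": self.r_,
                "p_value": self.p_,
                "significant": self.significant_,
            }
        )


def one_sample_map(Z: np.ndarray, config: InferenceConfig | None = None) -> OneSampleZMap:
    """Fit a one-sample group map on a [subjects, pairs] Fisher-z stack."""
    return OneSampleZMap(config=config).fit(Z)


def two_sample_compare(
    Z_a: np.ndarray, Z_b: np.ndarray, config: InferenceConfig | None = None
) -> GroupComparison:
    """Fit the preterm-vs-full-term style comparison (A minus B)."""
    return GroupComparison(config=config).fit(Z_a, Z_b)


def pma_trend(
    Z: np.ndarray, pma_weeks: np.ndarray, config: InferenceConfig | None = None
) -> PMATrend:
    """Fit the developmental-trend analysis within one group."""
    return PMATrend(config=config).fit(Z, pma_weeks)
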