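"""Motion-artifact detection, exclusion-window construction, and subject QC.

Neonatal motion (Moro reflexes, spontaneous smiles) produces sudden baseline
jumps and slow U / inverted-U spikes in the hemoglobin series.  Genuine
hemodynamics show *anti*-correlated oxy/deoxy fluctuations, whereas motion
moves both chromophores together, so artifacts are detected where the
sliding-window oxy/deoxy correlation — pooled across channels — turns
strongly positive AND the signal (or its derivative) shows a large robust
amplitude excursion.  Detection runs on the unfiltered hemoglobin series:
artifacts are broadband and the narrow analysis band would smear jumps.

Each confirmed artifact peak excises a fixed window from 20 s before to
30 s after the peak; subjects retaining less than 150 s of data are
excluded from group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from .hemodynamics import HemoTimeSeries


@dataclass(frozen=True)
class ArtifactPolicy:
    """Detector thresholds and exclusion rules (all tunable)."""

    corr_window_s: float = 10.0
    corr_threshold: float = 0.5
    amp_threshold_mads: float = 5.0
    pre_exclude_s: float = 20.0
    post_exclude_s: float = 30.0
    min_retained_s: float = 150.0
    merge_gap_s: float = 10.0

    def __post_init__(self) -> None:
        if self.corr_window_s <= 0:
            raise ValueError("corr_window_s must be positive")
        if not -1 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in [-1, 1]")
        if self.amp_threshold_mads <= 0:
            raise ValueError("amp_threshold_mads must be positive")
        if self.pre_exclude_s < 0 or self.post_exclude_s < 0:
            raise ValueError("exclusion margins must be >= 0")
        if self.min_retained_s < 0:
            raise ValueError("min_retained_s must be >= 0")


@dataclass(frozen=True)
class ArtifactEvent:
    """One detected (or planted) motion artifact with its exclusion interval."""

    peak_time_s: float
    kind: str  # "jump" | "spike"
    score: float
    exclusion_start_s: float
    exclusion_end_s: float


@dataclass
class AnalysisWindow:
    """Per-sample retention mask for one subject after artifact excision."""

    subject_id: str
    retained_mask: np.ndarray
    sample_interval_s: float
    n_artifacts: int

    @property
    def retained_duration_s(self) -> float:
        return float(self.retained_mask.sum() * self.sample_interval_s)


def _robust_z(x: np.ndarray) -> np.ndarray:
    """Per-channel robust z-score: (x − median) / (1.4826·MAD)."""
    med = np.median(x, axis=0, keepdims=True)
    mad = np.median(np.abs(x - med), axis=0, keepdims=True)
    scale = 1.4826 * mad
    scale[scale == 0] = np.inf
    return (x - med) / scale


def _sliding_correlation(x: np.ndarray, y: np.ndarray, win: int) -> np.ndarray:
    """Centered sliding-window Pearson correlation per channel, [time, channel]."""
    mx = uniform_filter1d(x, win, axis=0, mode="nearest")
    my = uniform_filter1d(y, win, axis=0, mode="nearest")
    mxx = uniform_filter1d(x * x, win, axis=0, mode="nearest")
    myy = uniform_filter1d(y * y, win, axis=0, mode="nearest")
    mxy = uniform_filter1d(x * y, win, axis=0, mode="nearest")
    cov = mxy - mx * my
    vx = np.maximum(mxx - mx * mx, 0.0)
    vy = np.maximum(myy - my * my, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


class MotionArtifactDetector(BaseEstimator):
    """Sliding oxy/deoxy-correlation motion-artifact detector.

    ``fit`` computes the per-sample detector statistics on one recording and
    stores the detected events in ``events_`` and the retention mask in
    ``retained_mask_``.
    """

    def __init__(self, policy: ArtifactPolicy | None = None):
        self.policy = policy

    def _resolved_policy(self) -> ArtifactPolicy:
        return self.policy if self.policy is not None else ArtifactPolicy()

    def fit(self, series: HemoTimeSeries, y=None):
        policy = self._resolved_policy()
        fs = 1.0 / series.sample_interval_s
        win = int(round(policy.corr_window_s * fs))
        if series.n_samples < win:
            raise ValueError(
                f"recording ({series.duration_s:.1f} s) shorter than the "
                f"correlation window ({policy.corr_window_s:.1f} s)"
            )
        win += win % 2 == 0  # odd length: symmetric window

        corr = _sliding_correlation(series.oxy, series.deoxy, win)
        corr_pooled = np.median(corr, axis=1)

        # amplitude path on a locally detrended signal: a jump's slow
        # relaxation (minutes) would otherwise inflate the robust scale and
        # hide later events
        bwin = max(int(round(30.0 * fs)), 3)
        detrended = series.oxy - uniform_filter1d(series.oxy, bwin, axis=0, mode="nearest")
        rz = _robust_z(detrended)
        # smooth derivative over ~0.5 s so single-sample steps register
        dwin = max(int(round(0.5 * fs)), 1)
        drz = _robust_z(np.gradient(uniform_filter1d(series.oxy, dwin, axis=0), axis=0))
        excursion = np.maximum(np.abs(rz), np.abs(drz))
        score = np.median(excursion, axis=1)

        flags = (corr_pooled > policy.corr_threshold) & (score > policy.amp_threshold_mads)

        events = []
        runs = _runs(flags)
        runs = _merge_runs(runs, gap=int(round(policy.merge_gap_s * fs)))
        duration = series.duration_s
        for start, stop in runs:
            peak_idx = start + int(np.argmax(score[start:stop]))
            peak_t = peak_idx * series.sample_interval_s
            events.append(
                ArtifactEvent(
                    peak_time_s=peak_t,
                    kind=_classify(series.oxy, peak_idx, fs),
                    score=float(score[peak_idx]),
                    exclusion_start_s=max(0.0, peak_t - policy.pre_exclude_s),
                    exclusion_end_s=min(duration, peak_t + policy.post_exclude_s),
                )
            )
        events.sort(key=lambda e: e.peak_time_s)
        self.events_ = events
        self.score_ = score
        self.corr_pooled_ = corr_pooled
        self.retained_mask_ = build_analysis_window(series, events, policy).retained_mask
        return self

    def detect(self, series: HemoTimeSeries) -> list[ArtifactEvent]:
        return self.fit(series).events_


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as [start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``gap`` samples."""
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _classify(oxy: np.ndarray, peak_idx: int, fs: float) -> str:
    """Jump vs spike: does the channel-median signal stay displaced after the peak?"""
    off = int(round(5 * fs))
    span = int(round(10 * fs))
    n = oxy.shape[0]
    before = oxy[max(0, peak_idx - off - span): max(1, peak_idx - off)]
    after = oxy[min(n - 1, peak_idx + off): min(n, peak_idx + off + span)]
    if len(before) == 0 or len(after) == 0:
        return "spike"
    pooled = np.median(oxy, axis=1)
    sd = 1.4826 * np.median(np.abs(pooled - np.median(pooled)))
    shift = abs(
        np.median(np.median(after, axis=1)) - np.median(np.median(before, axis=1))
    )
    return "jump" if sd > 0 and shift > 2 * sd else "spike"


def detect_artifacts(
    series: HemoTimeSeries, policy: ArtifactPolicy | None = None
) -> list[ArtifactEvent]:
    """Detect motion artifacts on an (unfiltered) hemoglobin series."""
    return MotionArtifactDetector(policy=policy).detect(series)


def build_analysis_window(
    series: HemoTimeSeries,
    events: list[ArtifactEvent],
    policy: ArtifactPolicy | None = None,
) -> AnalysisWindow:
    """Union the per-event exclusion intervals into a retention mask."""
    policy = policy if policy is not None else ArtifactPolicy()
    n = series.n_samples
    dt = series.sample_interval_s
    mask = np.ones(n, dtype=bool)
    for ev in events:
        start = max(0.0, ev.peak_time_s - policy.pre_exclude_s)
        end = min(series.duration_s, ev.peak_time_s + policy.post_exclude_s)
        # sample i covers [i·dt, (i+1)·dt); epsilon guards float grid edges
        i0 = int(np.floor(start / dt + 1e-9))
        i1 = min(n, int(np.ceil(end / dt - 1e-9)))
        mask[i0:i1] = False
    return AnalysisWindow(
        subject_id=series.subject_id,
        retained_mask=mask,
        sample_interval_s=dt,
        n_artifacts=len(events),
    )


def qc_subject(
    window: AnalysisWindow, policy: ArtifactPolicy | None = None
) -> tuple[bool, str]:
    """Include a subject iff enough artifact-free data survives excision."""
    policy = policy if policy is not None else ArtifactPolicy()
    retained = window.retained_duration_s
    include = retained >= policy.min_retained_s
    verdict = "include" if include else "exclude"
    reason = (
        f"{verdict}: retained {retained:.1f} s "
        f"(required >= {policy.min_retained_s:.1f} s)"
    )
    return include, reason


def detector_performance(
    truth_times_s: list[float],
    events: list[ArtifactEvent],
    tol_s: float = 5.0,
) -> tuple[int, int, int]:
    """Score detected events against ground truth: (hits, misses, false alarms).

    A planted artifact counts as caught when a detected peak lies within
    ``tol_s`` of it or when it falls inside a detected exclusion interval
    (its data is excised either way — nearby events legitimately merge into
    one detection).  A detection with no planted artifact within its
    exclusion interval is a false alarm.
    """
    hits = 0
    for t in truth_times_s:
        caught = any(
            abs(ev.peak_time_s - t) <= tol_s
            or ev.exclusion_start_s <= t <= ev.exclusion_end_s
            for ev in events
        )
        hits += caught
    misses = len(truth_times_s) - hits
    false = sum(
        not any(
            abs(ev.peak_time_s - t) <= tol_s
            or ev.exclusion_start_s <= t <= ev.exclusion_end_s
            for t in truth_times_s
        )
        for ev in events
    )
    return hits, misses, false


def artifact_census(windows: list[AnalysisWindow], groups: dict[str, str]):
    """Per-group distribution of artifact counts (counts and percentages)."""
    import pandas as pd

    unmapped = [w.subject_id for w in windows if w.subject_id not in groups]
    if unmapped:
        raise KeyError(f"subjects missing from group map: {unmapped}")
    rows = [
        {"subject_id": w.subject_id, "group": groups[w.subject_id], "n_artifacts": w.n_artifacts}
        for w in windows
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "group", "n_artifacts"])
    if df.empty:
        return pd.DataFrame(columns=["group", "n_artifacts", "n_subjects", "pct"])
    census = (
        df.groupby(["group", "n_artifacts"]).size().rename("n_subjects").reset_index()
    )
    totals = df.groupby("group").size()
    census["pct"] = [
        100.0 * r.n_subjects / totals[r.group] for r in census.itertuples()
    ]
    return census
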