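"""Synthetic neonatal cohort generator.

Emulates resting-state optical-topography recordings from preterm and
full-term neonates scanned at term-equivalent postmenstrual age (PMA):

* band-limited (0.01–0.08 Hz) hemodynamic fluctuations with a planted
  correlation structure — interhemispheric (homotopic) background
  connectivity plus arbitrary per-edge effects with group differences and
  linear PMA trends;
* anti-correlated oxy/deoxy dynamics (deoxy = negative coupling × oxy plus
  independent band-limited noise);
* cardiac and respiratory sinusoidal nuisance outside the analysis band;
* white measurement noise;
* whole-head motion artifacts — sudden baseline jumps with slow exponential
  relaxation and slowly-varied U / inverted-U raised-cosine spikes — whose
  oxy and deoxy excursions are positively correlated;
* emission as dual-wavelength optical densities through the forward
  modified Beer–Lambert model.

Ground truth (per-subject artifact events and per-edge target correlations)
is returned alongside the recordings so that detector performance and
parameter recovery can be measured exactly.  Identical spec + seed
reproduces identical output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hemodynamics import BandpassFilter, ExtinctionTable, OpticalRecording, mbll_forward
from .layout import ChannelLayout, default_layout

#: PMA (weeks) at which group/PMA effects are anchored — roughly the cohort mean.
PMA_REFERENCE_WEEKS = 39.5

# Observed demographic ranges used by the samplers (weeks / days).
PRETERM_GA_RANGE = (23.1, 36.7)
FULLTERM_GA_RANGE = (37.0, 41.3)
PRETERM_PMA_RANGE = (37.1, 42.1)
FULLTERM_PMA_RANGE = (37.5, 42.1)
FULLTERM_CA_RANGE_DAYS = (2, 8)


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics for one infant.

    PMA = GA + CA/7; the preterm/full-term split is at GA 37 weeks.
    """

    subject_id: str
    group: str  # "preterm" | "fullterm"
    ga_weeks: float
    ca_days: int
    pma_weeks: float
    head_circumference_cm: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("preterm", "fullterm"):
            raise ValueError(f"group must be 'preterm' or 'fullterm', got {self.group!r}")
        if abs(self.pma_weeks - (self.ga_weeks + self.ca_days / 7.0)) > 0.15:
            raise ValueError("pma_weeks inconsistent with ga_weeks + ca_days/7")
        if (self.group == "preterm") != (self.ga_weeks < 37.0):
            raise ValueError("group label inconsistent with GA 37-week split")


@dataclass(frozen=True)
class EdgeEffect:
    """Planted connectivity effect on one channel pair.

    The target Pearson correlation for a subject is::

        r = base_r + group_delta_r·[group == preterm]
                   + pma_slope_per_week·(pma − 39.5)
    """

    pair: tuple[int, int]  # 1-based channel indices, low < high
    base_r: float
    group_delta_r: float = 0.0
    pma_slope_per_week: float = 0.0

    def __post_init__(self) -> None:
        low, high = self.pair
        if not (1 <= low < high):
            raise ValueError(f"pair must be ordered 1-based indices, got {self.pair}")
        reach = abs(self.base_r) + abs(self.group_delta_r) + 3 * abs(self.pma_slope_per_week)
        if reach >= 1:
            raise ValueError(
                f"edge effect on {self.pair} can leave (-1, 1): "
                f"|base|+|delta|+3|slope| = {reach:.3f}"
            )

    def target_r(self, group: str, pma_weeks: float) -> float:
        r = self.base_r + self.pma_slope_per_week * (pma_weeks - PMA_REFERENCE_WEEKS)
        if group == "preterm":
            r += self.group_delta_r
        return float(np.clip(r, -0.999, 0.999))


@dataclass(frozen=True)
class ArtifactSpec:
    """Motion-artifact process: Poisson count of whole-head events.

    ``jump_fraction`` of events are sudden baseline steps (relaxing back with
    a 120 s time constant); the rest are slow raised-cosine U / inverted-U
    spikes of half-width ``spike_halfwidth_s``.  Amplitudes are expressed
    relative to the hemodynamic signal standard deviation.
    """

    rate_per_recording: float = 1.1
    jump_fraction: float = 0.4
    amplitude_scale: float = 8.0
    spike_halfwidth_s: float = 4.0
    jump_relaxation_s: float = 120.0

    def __post_init__(self) -> None:
        if self.rate_per_recording < 0:
            raise ValueError("rate_per_recording must be >= 0")
        if not 0 <= self.jump_fraction <= 1:
            raise ValueError("jump_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the study conditions: 25 preterm + 24 full-term infants,
    5-minute recordings sampled every 100 ms, homotopic background
    connectivity, negative oxy/deoxy coupling, cardiac (2.5 Hz) and
    respiratory (0.8 Hz) nuisance, and roughly one motion artifact per
    recording.  Hemoglobin amplitude has no published value for this
    population and is a free scale (mM·mm).
    """

    n_preterm: int = 25
    n_fullterm: int = 24
    duration_s: float = 300.0
    sample_interval_s: float = 0.1
    edge_effects: tuple[EdgeEffect, ...] = ()
    background_homotopic_r: float = 0.5
    oxy_deoxy_coupling: float = -0.4
    cardiac_hz: float = 2.5
    respiratory_hz: float = 0.8
    cardiac_amplitude: float = 0.5  # relative to signal_scale
    respiratory_amplitude: float = 0.3
    noise_sd: float = 0.25  # white measurement noise, relative to signal_scale
    signal_scale: float = 0.02  # latent hemodynamic SD in mM·mm (free scale)
    deoxy_noise_sd: float = 0.5  # independent deoxy noise, relative to signal_scale
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    n_channels: int = 94
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_preterm < 2 or self.n_fullterm < 2:
            raise ValueError("n_preterm and n_fullterm must each be >= 2")
        if self.duration_s < 150:
            raise ValueError("duration_s must be >= 150 s")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if self.oxy_deoxy_coupling >= 0:
            raise ValueError("oxy_deoxy_coupling must be negative")
        if not -1 < self.background_homotopic_r < 1:
            raise ValueError("background_homotopic_r must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_preterm + self.n_fullterm


@dataclass(frozen=True)
class GroundTruthArtifact:
    subject_id: str
    peak_time_s: float
    kind: str  # "jump" | "spike"
    amplitude: float


def pma_sampler(group: str, rng: np.random.Generator) -> tuple[float, int, float]:
    """Draw (GA weeks, CA days, PMA weeks) consistent with the cohort demographics.

    Preterm infants are scanned at term-equivalent age: PMA is drawn
    uniformly over the observed 37.1–42.1-week range and CA follows from
    PMA − GA.  Full-term neonates are scanned 2–8 days after birth.
    """
    if group == "preterm":
        ga = rng.uniform(*PRETERM_GA_RANGE)
        pma_target = rng.uniform(*PRETERM_PMA_RANGE)
        ca = int(round((pma_target - ga) * 7))
        ca = max(ca, 1)
        pma = ga + ca / 7.0
        pma = float(np.clip(pma, *PRETERM_PMA_RANGE))
    elif group == "fullterm":
        lo, hi = FULLTERM_PMA_RANGE
        ca = int(rng.integers(FULLTERM_CA_RANGE_DAYS[0], FULLTERM_CA_RANGE_DAYS[1] + 1))
        ga = rng.uniform(max(FULLTERM_GA_RANGE[0], lo - ca / 7.0),
                         min(FULLTERM_GA_RANGE[1], hi - ca / 7.0))
        pma = ga + ca / 7.0
    else:
        raise ValueError(f"unknown group {group!r}")
    return float(ga), int(ca), float(pma)


def _nearest_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-definite correlation matrix."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() > eps:
        return R
    w = np.clip(w, eps, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def _target_correlation_matrix(
    spec: CohortSpec, layout: ChannelLayout, group: str, pma_weeks: float
) -> np.ndarray:
    R = np.eye(spec.n_channels)
    for left, right in layout.homotopic_pairs:
        R[left - 1, right - 1] = R[right - 1, left - 1] = spec.background_homotopic_r
    for eff in spec.edge_effects:
        i, j = eff.pair[0] - 1, eff.pair[1] - 1
        if j >= spec.n_channels:
            raise ValueError(f"edge effect pair {eff.pair} outside 1..{spec.n_channels}")
        r = eff.target_r(group, pma_weeks)
        R[i, j] = R[j, i] = r
    return _nearest_correlation(R)


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, n_series: int, filt: BandpassFilter
) -> np.ndarray:
    """Unit-variance noise confined to the analysis band (edge-padded filtering)."""
    pad = min(n_samples, 600)
    x = rng.standard_normal((n_samples + 2 * pad, n_series))
    y = filt.transform(x)[pad:-pad] if pad else filt.transform(x)
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    return y / sd


def _artifact_waveform(
    times_s: np.ndarray, peak_time_s: float, kind: str, spec: ArtifactSpec
) -> np.ndarray:
    """Unit-amplitude artifact time course (peak magnitude 1)."""
    if kind == "jump":
        dt = times_s - peak_time_s
        wave = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / spec.jump_relaxation_s), 0.0)
    else:  # raised-cosine spike spanning ±spike_halfwidth_s
        dt = np.abs(times_s - peak_time_s)
        hw = spec.spike_halfwidth_s
        wave = np.where(dt <= hw, 0.5 * (1 + np.cos(np.pi * dt / hw)), 0.0)
    return wave


def generate_subject_series(
    spec: CohortSpec,
    subject: SubjectRecord,
    layout: ChannelLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthArtifact], np.ndarray]:
    """Generate (oxy, deoxy, artifacts, target_R) for one subject in mM·mm."""
    n = int(round(spec.duration_s / spec.sample_interval_s))
    times = np.arange(n) * spec.sample_interval_s
    fs = 1.0 / spec.sample_interval_s
    filt = BandpassFilter(sample_rate_hz=fs).fit()

    R = _target_correlation_matrix(spec, layout, subject.group, subject.pma_weeks)
    L = np.linalg.cholesky(R)
    latent = _band_limited_noise(rng, n, spec.n_channels, filt) @ L.T
    oxy = spec.signal_scale * latent
    deoxy = spec.oxy_deoxy_coupling * oxy + (
        spec.signal_scale
        * spec.deoxy_noise_sd
        * _band_limited_noise(rng, n, spec.n_channels, filt)
    )

    # physiological nuisance: common phase across channels, jittered gain
    for f_hz, amp, deoxy_ratio in (
        (spec.cardiac_hz, spec.cardiac_amplitude, 0.3),
        (spec.respiratory_hz, spec.respiratory_amplitude, 0.3),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        gains = rng.uniform(0.5, 1.5, size=spec.n_channels)
        wave = np.sin(2 * np.pi * f_hz * times + phase)
        comp = spec.signal_scale * amp * wave[:, None] * gains[None, :]
        oxy += comp
        deoxy += deoxy_ratio * comp

    # whole-head motion artifacts with positively correlated oxy/deoxy excursions
    art = spec.artifact_spec
    events: list[GroundTruthArtifact] = []
    n_events = int(rng.poisson(art.rate_per_recording))
    margin = max(art.spike_halfwidth_s, 5.0)
    for _ in range(n_events):
        peak = float(rng.uniform(margin, spec.duration_s - margin))
        kind = "jump" if rng.uniform() < art.jump_fraction else "spike"
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        amplitude = (
            sign * art.amplitude_scale * spec.signal_scale * rng.uniform(0.75, 1.25)
        )
        wave = _artifact_waveform(times, peak, kind, art)
        chan_gain = rng.uniform(0.6, 1.4, size=spec.n_channels)
        bump = amplitude * wave[:, None] * chan_gain[None, :]
        oxy += bump
        deoxy += 0.5 * bump  # same sign: positive oxy/deoxy correlation
        events.append(
            GroundTruthArtifact(
                subject_id=subject.subject_id,
                peak_time_s=peak,
                kind=kind,
                amplitude=amplitude,
            )
        )
    events.sort(key=lambda e: e.peak_time_s)

    # white measurement noise on both chromophores
    oxy = oxy + spec.signal_scale * spec.noise_sd * rng.standard_normal(oxy.shape)
    deoxy = deoxy + spec.signal_scale * spec.noise_sd * rng.standard_normal(deoxy.shape)
    return oxy, deoxy, events, R


def generate_cohort(
    spec: CohortSpec,
    layout: ChannelLayout | None = None,
    extinction: ExtinctionTable | None = None,
) -> tuple[list[SubjectRecord], list[OpticalRecording], list[GroundTruthArtifact], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns subject metadata, dual-wavelength optical recordings (one per
    subject), ground-truth artifact events, and a per-subject edge table of
    planted target correlations for every homotopic pair and every
    explicitly planted edge.
    """
    layout = layout if layout is not None else default_layout(spec.n_channels)
    if layout.n_channels != spec.n_channels:
        raise ValueError("layout channel count does not match spec.n_channels")
    extinction = extinction if extinction is not None else ExtinctionTable()

    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(spec.n_subjects)

    subjects: list[SubjectRecord] = []
    recordings: list[OpticalRecording] = []
    artifacts: list[GroundTruthArtifact] = []
    edge_rows: list[dict] = []

    groups = ["preterm"] * spec.n_preterm + ["fullterm"] * spec.n_fullterm
    tracked_pairs = sorted(
        {tuple(p) for p in layout.homotopic_pairs} | {e.pair for e in spec.edge_effects}
    )
    for idx, group in enumerate(groups):
        sid = f"sub-{idx + 1:03d}"
        ga, ca, pma = pma_sampler(group, meta_rng)
        hc = float(np.clip(meta_rng.normal(33.6, 1.5), 30.0, 37.5))
        subject = SubjectRecord(
            subject_id=sid,
            group=group,
            ga_weeks=round(ga, 1),
            ca_days=ca,
            pma_weeks=round(ga, 1) + ca / 7.0,
            head_circumference_cm=round(hc, 1),
        )
        rng = np.random.default_rng(subject_seeds[idx])
        oxy, deoxy, events, R = generate_subject_series(spec, subject, layout, rng)
        od = mbll_forward(oxy, deoxy, extinction)
        recordings.append(
            OpticalRecording(
                subject_id=sid,
                od=od,
                sample_interval_s=spec.sample_interval_s,
                wavelengths_nm=extinction.wavelengths_nm,
            )
        )
        subjects.append(subject)
        artifacts.extend(events)
        for low, high in tracked_pairs:
            edge_rows.append(
                {
                    "subject_id": sid,
                    "ch_low": low,
                    "ch_high": high,
                    "target_r": R[low - 1, high - 1],
                }
            )
    edge_table = pd.DataFrame(edge_rows, columns=["subject_id", "ch_low", "ch_high", "target_r"])
    return subjects, recordings, artifacts, edge_table


def demo_edge_effects(layout: ChannelLayout | None = None) -> tuple[EdgeEffect, ...]:
    """A study-like scenario: enhanced homotopic temporal/parietal connectivity in
    preterm infants, an enhanced left temporal–parietal edge in full-term
    neonates, and a positive PMA trend on a temporal homotopic edge."""
    layout = layout if layout is not None else default_layout()
    t_pairs = [p for p in layout.homotopic_pairs
               if layout.channel_region[p[0]] == "temporal-L"]
    p_pairs = [p for p in layout.homotopic_pairs
               if layout.channel_region[p[0]] == "parietal-L"]
    tL = layout.channels_in("temporal-L")[0]
    pL = layout.channels_in("parietal-L")[0]
    return (
        EdgeEffect(pair=t_pairs[0], base_r=0.45, group_delta_r=0.25),
        EdgeEffect(pair=p_pairs[0], base_r=0.45, group_delta_r=0.25),
        EdgeEffect(pair=(min(tL, pL), max(tL, pL)), base_r=0.45, group_delta_r=-0.25),
        EdgeEffect(pair=t_pairs[1], base_r=0.5, pma_slope_per_week=0.08),
    )


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
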