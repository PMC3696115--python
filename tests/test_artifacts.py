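"""Motion-artifact detection, exclusion windows, QC, and the artifact census."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsconn.artifacts import (
    AnalysisWindow,
    ArtifactEvent,
    ArtifactPolicy,
    artifact_census,
    build_analysis_window,
    detect_artifacts,
    qc_subject,
)
from nirsconn.cohort import _artifact_waveform, ArtifactSpec
from nirsconn.hemodynamics import HemoTimeSeries

from conftest import make_clean_series

# distributions of artifact counts per infant reported for the two groups
PRETERM_COUNTS = {0: 12, 1: 2, 2: 8, 3: 2, 4: 1}
FULLTERM_COUNTS = {0: 9, 1: 6, 2: 7, 3: 2}


def _event(peak, duration=300.0, policy=None):
    policy = policy or ArtifactPolicy()
    return ArtifactEvent(
        peak_time_s=peak,
        kind="spike",
        score=10.0,
        exclusion_start_s=max(0.0, peak - policy.pre_exclude_s),
        exclusion_end_s=min(duration, peak + policy.post_exclude_s),
    )


def _series(duration=300.0, n_channels=2):
    n = int(duration / 0.1)
    return HemoTimeSeries(
        subject_id="s", oxy=np.zeros((n, n_channels)),
        deoxy=np.zeros((n, n_channels)), sample_interval_s=0.1,
    )


def _add_artifact(series, peak_s, kind, amplitude, seed=0):
    spec = ArtifactSpec()
    wave = _artifact_waveform(series.times_s, peak_s, kind, spec)
    gains = np.random.default_rng(seed).uniform(0.6, 1.4, series.n_channels)
    bump = amplitude * wave[:, None] * gains[None, :]
    series.oxy += bump
    series.deoxy += 0.5 * bump
    return series


class TestDetection:
    def test_clean_recordings_mostly_event_free(self):
        false_counts = [
            len(detect_artifacts(make_clean_series(seed=s, coupling=-0.3)))
            for s in range(10)
        ]
        assert sum(c == 0 for c in false_counts) >= 9

    def test_planted_jump_detected_and_localized(self):
        series = make_clean_series(seed=7)
        _add_artifact(series, 100.0, "jump", 8 * 0.02)
        events = detect_artifacts(series)
        assert len(events) == 1
        assert events[0].peak_time_s == pytest.approx(100.0, abs=2.0)
        assert events[0].kind == "jump"

    def test_exclusion_interval_is_minus20_plus30(self):
        series = make_clean_series(seed=8)
        _add_artifact(series, 100.0, "spike", 8 * 0.02)
        events = detect_artifacts(series)
        assert len(events) == 1
        assert events[0].exclusion_start_s == pytest.approx(80.0, abs=2.0)
        assert events[0].exclusion_end_s == pytest.approx(130.0, abs=2.0)

    def test_spike_classified_as_spike(self):
        series = make_clean_series(seed=9)
        _add_artifact(series, 150.0, "spike", 8 * 0.02)
        events = detect_artifacts(series)
        assert len(events) == 1 and events[0].kind == "spike"

    def test_short_recording_rejected(self):
        short = _series(duration=5.0)
        with pytest.raises(ValueError, match="window"):
            detect_artifacts(short)


class TestAnalysisWindow:
    def test_no_events_retains_everything(self):
        window = build_analysis_window(_series(300.0), [])
        assert window.retained_duration_s == pytest.approx(300.0)
        assert window.n_artifacts == 0

    def test_edge_clamped_event(self):
        window = build_analysis_window(_series(300.0), [_event(10.0)])
        # exclusion [0, 40]: clamp at the recording start
        assert window.retained_duration_s == pytest.approx(260.0, abs=0.2)

    def test_nearby_events_union_not_double_counted(self):
        events = [_event(100.0), _event(120.0)]
        window = build_analysis_window(_series(300.0), events)
        # union [80, 150]: 70 s excised
        assert window.retained_duration_s == pytest.approx(230.0, abs=0.2)
        assert window.n_artifacts == 2

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=300.0), max_size=6),
        st.floats(min_value=200.0, max_value=400.0),
    )
    def test_mask_matches_per_sample_union_oracle(self, peaks, duration):
        series = _series(duration)
        events = [_event(p, duration=duration) for p in peaks if p < duration]
        window = build_analysis_window(series, events)
        dt = 0.1
        times = series.times_s
        oracle = np.ones(series.n_samples, dtype=bool)
        for ev in events:
            lo = max(0.0, ev.peak_time_s - 20.0)
            hi = min(duration, ev.peak_time_s + 30.0)
            # sample i covers [i·dt, (i+1)·dt); excluded iff it intersects
            # [lo, hi) (epsilon-tolerant at exact grid alignment)
            oracle &= ~((times < hi - 1e-9) & (times + dt > lo + 1e-9))
        np.testing.assert_array_equal(window.retained_mask, oracle)


class TestQC:
    @pytest.mark.parametrize("retained_s,included", [
        (150.1, True),   # observed cohort minimum
        (149.0, False),
        (380.3, True),   # observed cohort maximum
    ])
    def test_minimum_retained_rule(self, retained_s, included):
        n = int(round(retained_s / 0.1))
        window = AnalysisWindow(
            subject_id="s", retained_mask=np.ones(n, dtype=bool),
            sample_interval_s=0.1, n_artifacts=0,
        )
        decision, reason = qc_subject(window)
        assert decision is included
        assert "retained" in reason and "150.0" in reason


def _windows_from_counts(counts, prefix):
    windows, groups = [], {}
    i = 0
    for n_art, n_subj in counts.items():
        for _ in range(n_subj):
            sid = f"{prefix}{i}"
            windows.append(AnalysisWindow(
                subject_id=sid, retained_mask=np.ones(10, dtype=bool),
                sample_interval_s=0.1, n_artifacts=n_art,
            ))
            groups[sid] = "preterm" if prefix == "p" else "fullterm"
            i += 1
    return windows, groups


class TestCensus:
    def test_zero_artifact_shares_match_reported_distributions(self):
        wp, gp = _windows_from_counts(PRETERM_COUNTS, "p")
        wf, gf = _windows_from_counts(FULLTERM_COUNTS, "f")
        census = artifact_census(wp + wf, {**gp, **gf})
        pre0 = census[(census.group == "preterm") & (census.n_artifacts == 0)]
        ful0 = census[(census.group == "fullterm") & (census.n_artifacts == 0)]
        assert pre0.pct.iloc[0] == pytest.approx(48.0)
        assert ful0.pct.iloc[0] == pytest.approx(37.5)

    def test_percentages_sum_to_100_per_group(self):
        wp, gp = _windows_from_counts(PRETERM_COUNTS, "p")
        wf, gf = _windows_from_counts(FULLTERM_COUNTS, "f")
        census = artifact_census(wp + wf, {**gp, **gf})
        sums = census.groupby("group").pct.sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_empty_cohort_gives_empty_census(self):
        assert artifact_census([], {}).empty

    def test_unmapped_subject_rejected(self):
        w, _ = _windows_from_counts({0: 1}, "p")
        with pytest.raises(KeyError, match="missing"):
            artifact_census(w, {})


def test_policy_validation():
    with pytest.raises(ValueError):
        ArtifactPolicy(corr_window_s=0)
    with pytest.raises(ValueError):
        ArtifactPolicy(amp_threshold_mads=-1)
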