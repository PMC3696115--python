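"""Optical-density ↔ hemoglobin conversion and band-limited fluctuation extraction.

Continuous-wave optical topography measures changes in optical density (OD)
at two near-infrared wavelengths.  Under the modified Beer–Lambert law the
OD change at wavelength λ is a linear combination of the concentration
changes of oxygenated and deoxygenated hemoglobin::

    ΔOD_λ = ε_λ,oxy · Δ[oxy-Hb]·L + ε_λ,deoxy · Δ[deoxy-Hb]·L

where ε are molar extinction coefficients and L the (unknown) effective
pathlength.  With two wavelengths this is a 2×2 linear system per sample and
channel.  Because the differential pathlength factor for the neonatal head
is not known here, all hemoglobin quantities carry pathlength folded in and
are reported in mM·mm; no division by a pathlength is ever performed.

Resting-state fluctuations are extracted with a zero-phase Butterworth
band-pass whose −3 dB points sit at the band edges (0.01–0.08 Hz by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

#: Molar extinction coefficients for (oxy-Hb, deoxy-Hb) at 785 and 830 nm in
#: mM⁻¹·mm⁻¹, converted from standard in-vitro hemoglobin compilations
#: (values quoted there in cm⁻¹·M⁻¹: 785 nm — 735 / 1098; 830 nm — 974 / 693).
#: These are conventions, not results; override via ``ExtinctionTable``.
DEFAULT_EXTINCTION = np.array(
    [
        [0.0735, 0.1098],  # 785 nm: oxy, deoxy
        [0.0974, 0.0693],  # 830 nm: oxy, deoxy
    ]
)

DEFAULT_WAVELENGTHS = (785.0, 830.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """2×2 extinction matrix, rows = wavelengths, columns = (oxy, deoxy), mM⁻¹·mm⁻¹."""

    eps: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        object.__setattr__(self, "eps", eps)
        cond = np.linalg.cond(eps)
        if not np.isfinite(cond) or cond >= 100:
            raise np.linalg.LinAlgError(
                f"extinction matrix is ill-conditioned (cond={cond:.3g} >= 100); "
                "oxy/deoxy separation would be numerically unstable"
            )


@dataclass
class OpticalRecording:
    """Dual-wavelength optical-density change series for one subject.

    ``od`` is indexed ``[time, channel, wavelength]`` (dimensionless), with the
    wavelength axis ordered as ``wavelengths_nm``.
    """

    subject_id: str
    od: np.ndarray
    sample_interval_s: float = 0.1
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[2] != 2:
            raise ValueError("od must be [time, channel, wavelength] with 2 wavelengths")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains missing/non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sample_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_s


@dataclass
class HemoTimeSeries:
    """Δ[oxy-Hb] / Δ[deoxy-Hb] series (× pathlength, mM·mm) for one subject."""

    subject_id: str
    oxy: np.ndarray
    deoxy: np.ndarray
    sample_interval_s: float = 0.1
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.shape != self.deoxy.shape or self.oxy.ndim != 2:
            raise ValueError("oxy and deoxy must be [time, channel] with equal shapes")

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[1]

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sample_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_s


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: −3 dB corners at (low_hz, high_hz), Butterworth, zero-phase."""

    low_hz: float = 0.01
    high_hz: float = 0.08
    family: str = "butterworth"
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.family != "butterworth":
            raise ValueError(f"unsupported filter family: {self.family!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


class BeerLambertConverter(TransformerMixin, BaseEstimator):
    """Modified Beer–Lambert conversion between OD changes and hemoglobin changes.

    ``transform`` maps ``[time, channel, 2]`` optical densities to hemoglobin
    ``[time, channel, 2]`` (last axis: oxy, deoxy); ``inverse_transform`` is
    the exact forward model.  Stateless apart from validating and caching the
    extinction matrix in ``fit``.
    """

    def __init__(self, extinction: ExtinctionTable | None = None):
        self.extinction = extinction

    def fit(self, X=None, y=None):
        table = self.extinction if self.extinction is not None else ExtinctionTable()
        self.extinction_ = table
        self.inv_eps_ = np.linalg.inv(table.eps)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """OD ``[time, channel, 2]`` → hemoglobin ``[time, channel, 2]`` (mM·mm)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected [time, channel, 2] optical densities")
        return X @ self.inv_eps_.T

    def inverse_transform(self, H: np.ndarray) -> np.ndarray:
        """Hemoglobin ``[time, channel, 2]`` → OD ``[time, channel, 2]``."""
        H = np.asarray(H, dtype=float)
        if H.ndim != 3 or H.shape[2] != 2:
            raise ValueError("expected [time, channel, 2] hemoglobin series")
        return H @ self.extinction_.eps.T


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth band-pass on ``[time, channel]`` arrays.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the squared design response and band-interior features are
    not time-shifted.
    """

    def __init__(
        self,
        low_hz: float = 0.01,
        high_hz: float = 0.08,
        order: int = 3,
        zero_phase: bool = True,
        sample_rate_hz: float = 10.0,
    ):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order
        self.zero_phase = zero_phase
        self.sample_rate_hz = sample_rate_hz

    def fit(self, X=None, y=None):
        nyq = self.sample_rate_hz / 2.0
        if not 0 < self.low_hz < self.high_hz < nyq:
            raise ValueError(
                f"need 0 < low_hz < high_hz < Nyquist ({nyq} Hz); "
                f"got ({self.low_hz}, {self.high_hz})"
            )
        self.sos_ = signal.butter(
            self.order,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=self.sample_rate_hz,
            output="sos",
        )
        return self

    def _check_duration(self, n_samples: int) -> None:
        duration = n_samples / self.sample_rate_hz
        required = 2.0 / self.low_hz
        if duration < required:
            raise ValueError(
                f"recording too short for band-pass at {self.low_hz} Hz: "
                f"{duration:.1f} s < required minimum {required:.1f} s "
                "(two cycles of the low band edge)"
            )

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
            squeeze = True
        else:
            squeeze = False
        self._check_duration(X.shape[0])
        if self.zero_phase:
            out = signal.sosfiltfilt(self.sos_, X, axis=0)
        else:
            out = signal.sosfilt(self.sos_, X, axis=0)
        # edge transients leave a tiny residual mean; DC is outside the band
        # by construction, so remove it exactly
        out = out - out.mean(axis=0, keepdims=True)
        return out[:, 0] if squeeze else out

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Effective magnitude response at ``freqs_hz`` (squared if zero-phase)."""
        _, h = signal.sosfreqz(self.sos_, worN=np.asarray(freqs_hz, dtype=float),
                               fs=self.sample_rate_hz)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


def mbll_inverse(
    recording: OpticalRecording, table: ExtinctionTable | None = None
) -> HemoTimeSeries:
    """Recover Δ[oxy-Hb], Δ[deoxy-Hb] (mM·mm) from dual-wavelength OD changes."""
    table = table if table is not None else ExtinctionTable()
    if tuple(recording.wavelengths_nm) != tuple(table.wavelengths_nm):
        raise ValueError(
            f"wavelength mismatch: recording {recording.wavelengths_nm} vs "
            f"extinction table {table.wavelengths_nm}"
        )
    conv = BeerLambertConverter(extinction=table).fit()
    hemo = conv.transform(recording.od)
    return HemoTimeSeries(
        subject_id=recording.subject_id,
        oxy=hemo[:, :, 0],
        deoxy=hemo[:, :, 1],
        sample_interval_s=recording.sample_interval_s,
    )


def mbll_forward(
    oxy: np.ndarray, deoxy: np.ndarray, table: ExtinctionTable | None = None
) -> np.ndarray:
    """Forward model: hemoglobin ``[time, channel]`` pairs → OD ``[time, channel, 2]``."""
    table = table if table is not None else ExtinctionTable()
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy shapes differ")
    hemo = np.stack([oxy, deoxy], axis=-1)
    conv = BeerLambertConverter(extinction=table).fit()
    return conv.inverse_transform(hemo)


def bandpass(series: HemoTimeSeries, spec: FilterSpec | None = None) -> HemoTimeSeries:
    """Extract the low-frequency fluctuation band from a hemoglobin series."""
    spec = spec if spec is not None else FilterSpec()
    filt = BandpassFilter(
        low_hz=spec.low_hz,
        high_hz=spec.high_hz,
        order=spec.order,
        zero_phase=spec.zero_phase,
        sample_rate_hz=1.0 / series.sample_interval_s,
    ).fit()
    out = HemoTimeSeries(
        subject_id=series.subject_id,
        oxy=filt.transform(series.oxy),
        deoxy=filt.transform(series.deoxy),
        sample_interval_s=series.sample_interval_s,
        band=(spec.low_hz, spec.high_hz),
    )
    return out
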