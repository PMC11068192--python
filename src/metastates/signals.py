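"""Narrow-band filtering, analytic-signal phase, and node frequencies.

BOLD-like series are detrended, band-pass filtered in a low-frequency band
(default 0.04-0.07 Hz) with a zero-phase second-order Butterworth filter,
and Hilbert-transformed to obtain each node's instantaneous phase.  The
per-node natural frequency fed to the Hopf model is the spectral peak of the
filtered signal within the band, averaged across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PhaseSeries",
    "FrequencyVector",
    "DEFAULT_BAND_HZ",
    "bandpass_filter",
    "instantaneous_phase",
    "estimate_node_frequencies",
]

#: Analysis band in Hz for slow BOLD oscillations.
DEFAULT_BAND_HZ = (0.04, 0.07)


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phases theta(n, t) in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray  # (N, T)
    tr_seconds: float

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", p)
        if p.ndim != 2:
            raise ValueError("phases must be a 2-D (nodes x time) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("phases must be finite")
        if np.any(p <= -np.pi) or np.any(p > np.pi):
            raise ValueError("phases must be wrapped to (-pi, pi]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]

    @property
    def t_points(self) -> int:
        return self.phases.shape[1]


@dataclass(frozen=True)
class FrequencyVector:
    """Per-node oscillation frequencies f_n in Hz, confined to a band."""

    f_hz: np.ndarray  # (N,)
    band: tuple[float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.f_hz, dtype=float)
        object.__setattr__(self, "f_hz", f)
        object.__setattr__(self, "band", (float(self.band[0]), float(self.band[1])))
        lo, hi = self.band
        if np.any(f < lo - 1e-12) or np.any(f > hi + 1e-12):
            raise ValueError("all frequencies must lie within the band")


def _check_band(band: tuple[float, float], tr_seconds: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low < high:
        raise ValueError(f"band must satisfy 0 < low < high; got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"band upper edge {high} Hz violates the Nyquist limit "
            f"{nyquist} Hz for TR = {tr_seconds} s"
        )
    return low, high


def bandpass_filter(
    series: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    *,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of each node's time series.

    Each row is demeaned and linearly detrended, then filtered forward and
    backward (``sosfiltfilt``) with a Butterworth design of the given order,
    so the output has no phase lag.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    low, high = _check_band(band, tr_seconds)
    if x.shape[1] < 6 * order:
        raise ValueError(
            f"need at least {6 * order} timepoints for an order-{order} filter"
        )
    fs = 1.0 / tr_seconds
    detrended = sps.detrend(x, axis=1, type="linear")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, detrended, axis=1)


def instantaneous_phase(filtered: np.ndarray, tr_seconds: float = 2.0) -> PhaseSeries:
    """Phase of the analytic (Hilbert) signal per node, wrapped to (-pi, pi].

    The input is assumed band-limited (contract of ``bandpass_filter``); an
    all-zero node has no defined phase and raises.
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    dead = np.flatnonzero(np.all(np.abs(x) < 1e-300, axis=1))
    if dead.size:
        raise ValueError(f"phase undefined for all-zero node(s) {dead.tolist()}")
    analytic = sps.hilbert(x, axis=1)
    phases = np.angle(analytic)
    # np.angle returns [-pi, pi]; fold the closed lower edge onto +pi
    phases = np.where(phases <= -np.pi, phases + 2 * np.pi, phases)
    return PhaseSeries(phases=phases, tr_seconds=float(tr_seconds))


def estimate_node_frequencies(cohort, band: tuple[float, float] = DEFAULT_BAND_HZ) -> FrequencyVector:
    """Average per-subject spectral peak of the filtered signal, per node.

    For each subject the series is band-pass filtered and a periodogram is
    taken (frequency resolution 1/(T*TR)); the in-band peak location of each
    node is averaged across subjects and clamped into the band.
    """
    if cohort.n_subjects == 0:
        raise ValueError("cohort is empty")
    low, high = _check_band(band, cohort.tr_seconds)
    fs = 1.0 / cohort.tr_seconds
    peaks = []
    for s, series in enumerate(cohort.series):
        filt = bandpass_filter(series, cohort.tr_seconds, (low, high))
        freqs, pxx = sps.periodogram(filt, fs=fs, axis=1)
        in_band = (freqs >= low) & (freqs <= high)
        if not np.any(in_band):
            raise ValueError(
                f"no periodogram bins inside the band for subject {s}; "
                "series too short for this band"
            )
        band_pxx = pxx[:, in_band]
        flat = (band_pxx.max(axis=1) <= 0) | (
            np.ptp(band_pxx, axis=1) <= 1e-30 * band_pxx.max(axis=1)
        )
        if np.any(flat):
            raise ValueError(
                f"flat in-band spectrum for subject {s}, "
                f"node(s) {np.flatnonzero(flat).tolist()}"
            )
        peaks.append(freqs[in_band][np.argmax(band_pxx, axis=1)])
    f_hz = np.clip(np.mean(peaks, axis=0), low, high)
    return FrequencyVector(f_hz=f_hz, band=(low, high))
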