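"""EEG state profiling: band-pass filtering, averaged-periodogram power
spectra with width at mid-height, amplitude probability distributions, and
the sliding-FFT time-frequency representation.

The spectral conventions mirror the acquisition described for the study
system: 1 kHz sampling, a 0.5-300 Hz analysis band, and a 4 s sliding FFT
window stepped by 0.5 s for the spectrogram. The power spectrum is a
Welch-style averaged periodogram with 4 s Hann segments and 50% overlap;
the width at mid-height (WHM) is measured on a 3-bin moving-average
smoothed spectrum as the contiguous frequency span around the global
maximum where power stays at or above half the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import kurtosis as _kurtosis

from .errors import DataError, DegenerateInputError

__all__ = [
    "EEGTrace",
    "Spectrum",
    "AmplitudeDistribution",
    "Spectrogram",
    "bandpass",
    "power_spectrum",
    "amplitude_distribution",
    "spectrogram",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class EEGTrace:
    """Sampled single-channel EEG (microvolts)."""

    samples: np.ndarray
    fs_hz: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs_hz <= 0:
            raise DataError("sampling rate must be positive")
        if self.samples.size < 1:
            raise DataError("empty trace")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class Spectrum:
    """Averaged-periodogram power spectrum on [0, fs/2]."""

    freqs_hz: np.ndarray
    power: np.ndarray
    whm_hz: float


@dataclass
class AmplitudeDistribution:
    """Normalized amplitude histogram plus its excess kurtosis."""

    bin_edges: np.ndarray
    probability: np.ndarray
    excess_kurtosis: float


@dataclass
class Spectrogram:
    """Sliding-FFT log-amplitude map, max-normalized for display."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    log_amplitude: np.ndarray  # time x frequency
    window_s: float = 4.0
    step_s: float = 0.5


def bandpass(trace: EEGTrace, low_hz: float = 0.5, high_hz: float = 300.0, order: int = 4) -> EEGTrace:
    """Zero-phase Butterworth band-pass; the applied band is recorded."""
    nyq = trace.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise DataError(f"band ({low_hz}, {high_hz}) outside (0, Nyquist={nyq}) range")
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass", output="sos", fs=trace.fs_hz)
    return EEGTrace(signal.sosfiltfilt(sos, trace.samples), trace.fs_hz, (low_hz, high_hz))


def _whm(freqs: np.ndarray, power: np.ndarray, smooth_bins: int = 3) -> float:
    """Width of the contiguous half-maximum region around the global peak,
    with linear interpolation of the crossing points."""
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        power = np.convolve(power, kernel, mode="same")
    imax = int(np.argmax(power))
    half = power[imax] / 2.0
    lo = imax
    while lo > 0 and power[lo - 1] >= half:
        lo -= 1
    hi = imax
    while hi < len(power) - 1 and power[hi + 1] >= half:
        hi += 1
    f_lo = freqs[lo]
    if lo > 0:
        f_lo = np.interp(half, [power[lo - 1], power[lo]], [freqs[lo - 1], freqs[lo]])
    f_hi = freqs[hi]
    if hi < len(power) - 1:
        f_hi = np.interp(half, [power[hi + 1], power[hi]], [freqs[hi + 1], freqs[hi]])
    return float(f_hi - f_lo)


def power_spectrum(
    trace: EEGTrace,
    segment_s: float = 4.0,
    window: str = "hann",
    overlap: float = 0.5,
    whm_smooth_bins: int = 3,
) -> Spectrum:
    """Welch averaged periodogram with ``segment_s`` segments.

    The returned ``whm_hz`` is the spectral width at mid-height measured on
    the smoothed spectrum.
    """
    nperseg = int(round(segment_s * trace.fs_hz))
    if trace.samples.size < nperseg:
        raise DataError("trace shorter than one estimation segment")
    freqs, power = signal.welch(
        trace.samples,
        fs=trace.fs_hz,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    return Spectrum(freqs, power, _whm(freqs, power, whm_smooth_bins))


def dominant_low_peaks(spec: Spectrum, max_hz: float = 10.0, n_peaks: int = 2) -> list[float]:
    """Frequencies of the ``n_peaks`` largest local power maxima below
    ``max_hz``, sorted ascending."""
    sel = spec.freqs_hz < max_hz
    p = spec.power[sel]
    f = spec.freqs_hz[sel]
    idx, _ = signal.find_peaks(p)
    if len(idx) < n_peaks:
        raise DataError(f"fewer than {n_peaks} local maxima below {max_hz} Hz")
    top = idx[np.argsort(p[idx])[::-1][:n_peaks]]
    return sorted(float(f[i]) for i in top)


def amplitude_distribution(trace: EEGTrace, n_bins: int = 101) -> AmplitudeDistribution:
    """Normalized histogram of sample amplitudes plus excess kurtosis."""
    if n_bins < 3:
        raise DataError("need at least 3 bins")
    x = trace.samples
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant trace has a zero-width amplitude histogram")
    counts, edges = np.histogram(x, bins=n_bins)
    prob = counts / counts.sum()
    return AmplitudeDistribution(edges, prob, float(_kurtosis(x, fisher=True)))


def spectrogram(trace: EEGTrace, window_s: float = 4.0, step_s: float = 0.5) -> Spectrogram:
    """Sliding-FFT time-frequency map.

    One Hann-tapered FFT magnitude per ``window_s`` window stepped by
    ``step_s``; the number of time bins is
    ``floor((duration - window) / step) + 1``. Amplitudes are log10 and
    normalized to the per-record maximum.
    """
    w = int(round(window_s * trace.fs_hz))
    s = int(round(step_s * trace.fs_hz))
    n = trace.samples.size
    if n < w:
        raise DataError("trace shorter than one spectrogram window")
    n_bins = (n - w) // s + 1
    taper = np.hanning(w)
    mags = np.empty((n_bins, w // 2 + 1))
    for i in range(n_bins):
        seg = trace.samples[i * s : i * s + w]
        mags[i] = np.abs(np.fft.rfft(seg * taper))
    log_amp = np.log10(mags + 1e-12)
    log_amp = log_amp - log_amp.max()
    times = (np.arange(n_bins) * s + w / 2.0) / trace.fs_hz
    freqs = np.fft.rfftfreq(w, d=1.0 / trace.fs_hz)
    return Spectrogram(times, freqs, log_amp, window_s, step_s)


def write_trace_csv(trace: EEGTrace, path) -> None:
    """Write a trace as a two-column CSV (time_s, amplitude_uV)."""
    t = np.arange(trace.samples.size) / trace.fs_hz
    pd.DataFrame({"time_s": t, "amplitude_uV": trace.samples}).to_csv(path, index=False)


def read_trace_csv(path) -> EEGTrace:
    """Read a (time_s, amplitude_uV) CSV; the sampling rate is inferred
    from the median time step."""
    df = pd.read_csv(path)
    if not {"time_s", "amplitude_uV"} <= set(df.columns):
        raise DataError("trace CSV needs time_s and amplitude_uV columns")
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    if dt <= 0:
        raise DataError("non-increasing time column")
    return EEGTrace(df["amplitude_uV"].to_numpy(), 1.0 / dt)
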