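"""Narrowband components and amplitude envelopes.

A narrowband component f_w(X) is extracted with a zero-phase (forward-backward)
Butterworth band-pass; its amplitude envelope g_w(X) = |f_w(X) + i H(f_w(X))|
is the modulus of the analytic signal (H the Hilbert transform). Spectral
utilities (averaged periodogram, log-log slope, alpha-SNR surrogate) live here
as well.

Frequency units: band edges may be given as fraction of the Nyquist frequency
(the canonical internal unit), fraction of the sampling rate, or hertz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import Signal

__all__ = [
    "BandSpec",
    "BandEnvelope",
    "bandpass",
    "envelope",
    "band_envelope",
    "power_spectrum",
    "spectral_slope",
    "alpha_snr",
]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification.

    lo, hi : band edges, in ``unit``.
    unit : 'nyquist' (fraction of fs/2), 'sampling' (fraction of fs), or 'hz'.
    order : Butterworth order per pass; forward-backward filtering doubles the
        effective order.
    zero_phase : forward-backward (filtfilt) if True, single-pass otherwise.
    """

    lo: float
    hi: float
    unit: str = "nyquist"
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.unit not in {"nyquist", "sampling", "hz"}:
            raise ValueError(f"unknown frequency unit {self.unit!r}")
        if not (0 < self.lo < self.hi):
            raise ValueError(f"need 0 < lo < hi, got lo={self.lo}, hi={self.hi}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    def nyquist_edges(self, fs: float = 1.0) -> tuple[float, float]:
        """Band edges as fractions of the Nyquist frequency fs/2."""
        if self.unit == "nyquist":
            lo, hi = self.lo, self.hi
        elif self.unit == "sampling":
            lo, hi = 2.0 * self.lo, 2.0 * self.hi
        else:
            lo, hi = self.lo / (fs / 2.0), self.hi / (fs / 2.0)
        if hi >= 1.0:
            raise ValueError(
                f"band edge {self.hi} {self.unit} is at or above the Nyquist frequency"
            )
        if lo <= 0.0:
            raise ValueError(f"band edge {self.lo} {self.unit} is non-positive")
        return lo, hi


def _as_array(signal: Signal | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(signal, Signal):
        return signal.samples, signal.fs
    x = np.asarray(signal, dtype=float)
    return x, 1.0


def bandpass(signal: Signal | np.ndarray, band: BandSpec, fs: float | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output has the input's length."""
    x, fs_sig = _as_array(signal)
    lo, hi = band.nyquist_edges(fs if fs is not None else fs_sig)
    sos = scipy.signal.butter(band.order, [lo, hi], btype="bandpass", output="sos")
    if band.zero_phase:
        return scipy.signal.sosfiltfilt(sos, x, axis=-1)
    return scipy.signal.sosfilt(sos, x, axis=-1)


def envelope(signal: Signal | np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic signal of a narrowband input."""
    x, _ = _as_array(signal)
    return np.abs(scipy.signal.hilbert(x, axis=-1))


def band_envelope(
    signal: Signal | np.ndarray, band: BandSpec, fs: float | None = None
) -> np.ndarray:
    """Composition envelope(bandpass(signal, band))."""
    return envelope(bandpass(signal, band, fs=fs))


class BandEnvelope(BaseEstimator, TransformerMixin):
    """Transformer extracting the narrowband amplitude envelope g_w(X).

    Stateless; ``transform`` accepts a 1-D series or a 2-D array of shape
    (n_signals, n_times) and returns envelopes of the same shape.

    Parameters
    ----------
    lo, hi : band edges in ``unit``.
    unit : 'nyquist', 'sampling' or 'hz'.
    order : Butterworth order per pass (effective order doubles with
        zero-phase filtering).
    zero_phase : forward-backward filtering.
    fs : sampling rate, needed when unit='hz' and the input is a bare array.
    """

    def __init__(
        self,
        lo: float = 0.29,
        hi: float = 0.31,
        unit: str = "sampling",
        order: int = 2,
        zero_phase: bool = True,
        fs: float = 1.0,
    ):
        self.lo = lo
        self.hi = hi
        self.unit = unit
        self.order = order
        self.zero_phase = zero_phase
        self.fs = fs

    def _band(self) -> BandSpec:
        return BandSpec(
            lo=self.lo, hi=self.hi, unit=self.unit, order=self.order, zero_phase=self.zero_phase
        )

    def fit(self, X, y=None):
        self._band().nyquist_edges(self.fs)  # validate
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, Signal):
            return band_envelope(X, self._band())
        X = np.asarray(X, dtype=float)
        return band_envelope(X, self._band(), fs=self.fs)


def power_spectrum(
    signal: Signal | np.ndarray, segment_length: int = 1024, fs: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) power spectral density.

    Satisfies Parseval approximately: sum(psd) * df ~ var(signal).
    """
    x, fs_sig = _as_array(signal)
    fs_eff = fs if fs is not None else fs_sig
    if segment_length > x.size:
        raise ValueError(
            f"segment_length={segment_length} exceeds signal length {x.size}"
        )
    freq, psd = scipy.signal.welch(x, fs=fs_eff, nperseg=segment_length)
    return freq, psd


def spectral_slope(
    signal: Signal | np.ndarray,
    segment_length: int = 1024,
    fs: float | None = None,
    fmin: float | None = None,
    fmax: float | None = None,
) -> float:
    """Log-log slope of the Welch PSD over [fmin, fmax] (DC excluded)."""
    freq, psd = power_spectrum(signal, segment_length=segment_length, fs=fs)
    mask = (freq > 0) & (psd > 0)
    if fmin is not None:
        mask &= freq >= fmin
    if fmax is not None:
        mask &= freq <= fmax
    return float(np.polyfit(np.log(freq[mask]), np.log(psd[mask]), 1)[0])


def alpha_snr(signal: Signal, segment_length: int | None = None) -> float:
    """Alpha-band SNR surrogate: power in 8-13 Hz over power in 5-16 Hz.

    A signal-quality proxy for oscillatory components: how far the alpha peak
    stands above the 1/f^gamma background. Requires fs high enough to resolve
    16 Hz.
    """
    if signal.fs <= 32.0:
        raise ValueError(
            f"sampling rate {signal.fs} Hz too low to resolve the 16 Hz band edge"
        )
    if segment_length is None:
        segment_length = min(len(signal), int(round(signal.fs * 10)))
    freq, psd = power_spectrum(signal, segment_length=segment_length)
    df = freq[1] - freq[0]
    alpha = psd[(freq >= 8.0) & (freq <= 13.0)].sum() * df
    wide = psd[(freq >= 5.0) & (freq <= 16.0)].sum() * df
    if wide <= 0:
        raise ValueError("no power in the 5-16 Hz reference band")
    return float(alpha / wide)
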