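"""Spectral synthesis of power-law (1/f^e) noise.

Shared by the passive-filtering generator, the per-avalanche noise term of the
avalanche model, and test fixtures (long-memory noise with a prescribed Hurst
exponent). The method is the standard FFT one: take Gaussian white noise,
multiply its amplitude spectrum by f^(-e/2) (DC bin zeroed), invert, and
standardize.
"""

from __future__ import annotations

import numpy as np


def spectral_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """One realization of zero-mean, unit-variance noise with periodogram ~ f^-exponent.

    Parameters
    ----------
    n : length in samples (>= 1).
    exponent : spectral exponent e >= 0 of the target power spectrum 1/f^e.
    rng : numpy Generator.

    Returns
    -------
    1-D float array of length ``n``; for ``n == 1`` a single zero (the
    standardization is degenerate).
    """
    return spectral_noise_batch(1, n, exponent, rng)[0]


def spectral_noise_batch(
    count: int, n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """``count`` independent rows of length-``n`` power-law noise, standardized per row."""
    if n < 1:
        raise ValueError(f"noise length must be >= 1, got {n}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if exponent < 0:
        raise ValueError(f"spectral exponent must be >= 0, got {exponent}")
    if n == 1:
        # draw and discard so the rng stream advances consistently
        rng.standard_normal((count, 1))
        return np.zeros((count, 1))
    white = rng.standard_normal((count, n))
    spec = np.fft.rfft(white, axis=1)
    freq = np.fft.rfftfreq(n)
    amp = np.zeros_like(freq)
    amp[1:] = freq[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * amp, n=n, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    std = out.std(axis=1, keepdims=True)
    np.divide(out, std, out=out, where=std > 0)
    return out


def periodogram_slope(
    x: np.ndarray, fs: float = 1.0, fmin: float | None = None, fmax: float | None = None
) -> float:
    """Least-squares slope of the log-log periodogram of ``x``.

    Convenience used in tests and diagnostics; excludes the DC bin.
    """
    x = np.asarray(x, dtype=float)
    freq = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    mask = freq > 0
    if fmin is not None:
        mask &= freq >= fmin
    if fmax is not None:
        mask &= freq <= fmax
    lf, lp = np.log(freq[mask]), np.log(power[mask])
    slope = np.polyfit(lf, lp, 1)[0]
    return float(slope)
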