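"""Passive-filtering (PF) generator: white noise shaped to a 1/w^gamma spectrum.

Under the passive-filtering hypothesis the 1/f^gamma spectrum of macroscopic
recordings arises from linear filtering of short-memory activity through the
extracellular medium. Since short-memory (exponentially distributed) bursts
have the long-range properties of white noise, the observed signal is modelled
directly as Gaussian white noise passed through a 1/w^(gamma/2) amplitude
filter (spectral synthesis), standardized to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._spectral import spectral_noise
from .signals import Signal

__all__ = ["PFParams", "simulate_pf"]


@dataclass(frozen=True)
class PFParams:
    """gamma: spectral exponent of the target 1/w^gamma spectrum; T: length; seed."""

    gamma: float
    T: int = 15_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")

    def with_seed(self, seed: int) -> "PFParams":
        return replace(self, seed=int(seed))


def simulate_pf(params: PFParams) -> Signal:
    """Zero-mean, unit-variance signal with periodogram ~ w^-gamma.

    gamma = 0 reduces to Gaussian white noise.
    """
    rng = np.random.default_rng(params.seed)
    x = spectral_noise(params.T, params.gamma, rng)
    meta = {"generator": "pf", "gamma": params.gamma, "T": params.T, "seed": params.seed}
    return Signal(samples=x, fs=1.0, meta=meta)
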