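"""Critical-dynamics (CD) generator: linear superposition of power-law avalanches.

The model: at every integer time step, ``q`` avalanches are initiated. Each has
a lifetime L drawn from a truncated power law p(L) ~ L^-alpha on [1, L_c], a
deterministic height multiplier h = L^beta, and a unit-mean temporal profile
a(t) = b(t) + c(t) eps(t), where b is a parabola peaking at the avalanche
midpoint, c = b, and eps is colored noise with power spectrum ~ w^-(beta+1),
the spectrum of activity fluctuations within a critical avalanche. The recorded
signal X(t) is the sample-wise sum of all active avalanches. Avalanches are
also initiated over a pre-history of L_c steps before the retained window so
the retained segment is stationary; an additional ``burn_in`` prefix (default
L_c) is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from ._spectral import spectral_noise, spectral_noise_batch
from .signals import Signal

__all__ = [
    "CDParams",
    "sample_lifetimes",
    "truncated_powerlaw_cdf",
    "truncated_powerlaw_mean",
    "colored_noise",
    "avalanche_profile",
    "make_avalanche",
    "simulate_cd",
    "active_counts",
]

# shortest avalanche that carries its own noise realization; below this the
# spectral synthesis is degenerate and the profile is used noise-free
_MIN_NOISE_LEN = 4

# number of sample-contributions buffered before a bincount flush
_FLUSH_SIZE = 4_000_000


@dataclass(frozen=True)
class CDParams:
    """Parameters of the avalanche-superposition generator.

    alpha : lifetime exponent (> 1) of p(L) ~ L^-alpha.
    beta : height exponent (>= 0); avalanche height h = L^beta.
    L_c : lifetime cutoff in samples (>= 1), proportional to system size.
    q : avalanches initiated per time step (>= 0).
    T : total simulated length in samples (before discarding burn-in).
    burn_in : retained samples additionally discarded from the start
        (default: L_c, mirroring the discard of the first L_c points).
    seed : RNG seed.
    noise_on : include the c(t)*eps(t) stochastic term of the avalanche shape.
    """

    alpha: float
    beta: float
    L_c: int = 10_000
    q: int = 5
    T: int = 40_000
    burn_in: int | None = None
    seed: int = 0
    noise_on: bool = True

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError(f"alpha must be > 1, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.L_c < 1:
            raise ValueError(f"L_c must be >= 1, got {self.L_c}")
        if self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        b = self.effective_burn_in
        if not (1 <= b <= self.T):
            raise ValueError(
                f"burn_in must satisfy 1 <= burn_in <= T, got burn_in={b}, T={self.T}"
            )
        if self.T <= b:
            raise ValueError(f"T={self.T} must exceed burn_in={b}")

    @property
    def effective_burn_in(self) -> int:
        return int(self.L_c if self.burn_in is None else self.burn_in)

    def with_seed(self, seed: int) -> "CDParams":
        return replace(self, seed=int(seed))


def truncated_powerlaw_cdf(L: np.ndarray | float, alpha: float, L_c: float) -> np.ndarray:
    """CDF of the density ~ L^-alpha truncated to [1, L_c]."""
    L = np.asarray(L, dtype=float)
    if L_c == 1:
        return np.where(L >= 1, 1.0, 0.0)
    num = 1.0 - np.clip(L, 1.0, L_c) ** (1.0 - alpha)
    return num / (1.0 - L_c ** (1.0 - alpha))


def truncated_powerlaw_mean(alpha: float, L_c: float) -> float:
    """E[L] for the truncated power law on [1, L_c]."""
    if L_c == 1:
        return 1.0
    z = 1.0 - L_c ** (1.0 - alpha)
    if alpha == 2.0:
        return float(np.log(L_c) / z)
    return float((alpha - 1.0) / (alpha - 2.0) * (1.0 - L_c ** (2.0 - alpha)) / z)


def sample_lifetimes(
    alpha: float, L_c: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` real-valued lifetimes from p(L) ~ L^-alpha on [1, L_c].

    Inverse-CDF sampling: L = (1 - u (1 - L_c^(1-alpha)))^(1/(1-alpha)), u ~ U(0,1).
    """
    if not alpha > 1:
        raise ValueError(f"alpha must be > 1 (density not normalizable), got {alpha}")
    if L_c < 1:
        raise ValueError(f"L_c must be >= 1, got {L_c}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    u = rng.random(count)
    if L_c == 1:
        return np.ones(count)
    return (1.0 - u * (1.0 - L_c ** (1.0 - alpha))) ** (1.0 / (1.0 - alpha))


def colored_noise(n: int, spectral_exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance noise with periodogram ~ w^-spectral_exponent."""
    return spectral_noise(n, spectral_exponent, rng)


def avalanche_profile(n: int) -> np.ndarray:
    """Noise-free unit avalanche of ``n`` samples: parabola b(t) = -4(t-1/2)^2 + 1
    evaluated at midpoints t_i = (i - 1/2)/n, normalized to sample mean exactly 1."""
    if n < 1:
        raise ValueError(f"length must be >= 1, got {n}")
    t = (np.arange(1, n + 1) - 0.5) / n
    b = -4.0 * (t - 0.5) ** 2 + 1.0
    return b / b.mean()


def make_avalanche(L: float, params: CDParams, rng: np.random.Generator) -> np.ndarray:
    """Unit avalanche (height multiplier NOT applied) of length ceil(L).

    With ``noise_on`` the profile is b + c*eps with c = b and eps colored noise of
    spectral exponent beta + 1; expected time-average is 1. Lengths below 4 samples
    are returned noise-free (the spectral synthesis is degenerate there).
    """
    if L < 1:
        raise ValueError(f"lifetime must be >= 1, got {L}")
    n = int(np.ceil(L))
    b = avalanche_profile(n)
    if not params.noise_on or n < _MIN_NOISE_LEN:
        return b
    eps = colored_noise(n, params.beta + 1.0, rng)
    return b * (1.0 + eps)


def _simulate_buffer(params: CDParams) -> np.ndarray:
    """Full superposition buffer over time steps t in [1 - L_c, T]."""
    p = params
    rng = np.random.default_rng(p.seed)
    L_c, T, q = int(p.L_c), int(p.T), int(p.q)
    n_buf = T + L_c  # t = 1 - L_c ... T  ->  index t + L_c - 1
    buf = np.zeros(n_buf)
    if q == 0:
        return buf
    n_av = q * n_buf
    starts = np.repeat(np.arange(1 - L_c, T + 1), q)
    life = sample_lifetimes(p.alpha, p.L_c, n_av, rng)
    n_len = np.ceil(life).astype(np.int64)
    height = life**p.beta

    order = np.argsort(n_len, kind="stable")
    n_sorted = n_len[order]
    uniq, first = np.unique(n_sorted, return_index=True)
    bounds = np.append(first, n_sorted.size)

    pend_idx: list[np.ndarray] = []
    pend_w: list[np.ndarray] = []
    pending = 0

    def flush() -> None:
        nonlocal pending
        if not pend_idx:
            return
        idx = np.concatenate(pend_idx)
        w = np.concatenate(pend_w)
        buf[:] += np.bincount(idx, weights=w, minlength=n_buf)
        pend_idx.clear()
        pend_w.clear()
        pending = 0

    for k, m in enumerate(uniq):
        sel = order[bounds[k] : bounds[k + 1]]
        m = int(m)
        count = sel.size
        prof = avalanche_profile(m)
        if p.noise_on and m >= _MIN_NOISE_LEN:
            eps = spectral_noise_batch(count, m, p.beta + 1.0, rng)
            contrib = height[sel, None] * (prof * (1.0 + eps))
        else:
            contrib = height[sel, None] * prof[None, :]
        pos = (starts[sel] + L_c - 1)[:, None] + np.arange(m)
        mask = pos < n_buf  # clip avalanches running past the simulated horizon
        pend_idx.append(pos[mask])
        pend_w.append(contrib[mask])
        pending += int(mask.sum())
        if pending >= _FLUSH_SIZE:
            flush()
    flush()
    return buf


def simulate_cd(params: CDParams) -> Signal:
    """Simulate the avalanche superposition X(t) and return the retained segment.

    The output has length ``T - burn_in``: avalanches are initiated at every time
    step of [1 - L_c, T] (the pre-history makes the retained window stationary)
    and the first ``burn_in`` retained samples are discarded as warm-up.
    """
    p = params
    buf = _simulate_buffer(p)
    b = p.effective_burn_in
    out = buf[b + p.L_c :]
    meta: dict[str, Any] = {
        "generator": "cd",
        "alpha": p.alpha,
        "beta": p.beta,
        "L_c": p.L_c,
        "q": p.q,
        "T": p.T,
        "burn_in": b,
        "seed": p.seed,
        "noise_on": p.noise_on,
    }
    return Signal(samples=out, fs=1.0, meta=meta)


def active_counts(params: CDParams) -> np.ndarray:
    """Per-retained-time-step count of avalanches with nonzero contribution.

    Bookkeeping of the same simulation (same seed, same lifetime draws): an
    avalanche started at s with integer length m covers time steps s .. s+m-1.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    L_c, T, q = int(p.L_c), int(p.T), int(p.q)
    n_buf = T + L_c
    if q == 0:
        return np.zeros(T - p.effective_burn_in, dtype=np.int64)
    n_av = q * n_buf
    starts = np.repeat(np.arange(1 - L_c, T + 1), q)
    life = sample_lifetimes(p.alpha, p.L_c, n_av, rng)
    n_len = np.ceil(life).astype(np.int64)
    lo = starts + L_c - 1
    hi = np.minimum(lo + n_len, n_buf)
    delta = np.bincount(lo, minlength=n_buf + 1)
    np.subtract.at(delta, hi, 1)
    counts = np.cumsum(delta[:-1])
    return counts[p.effective_burn_in + L_c :].astype(np.int64)
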