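"""Meta-universality classes of avalanche criticality.

The pair of critical exponents (alpha, beta) — lifetime law p(L) ~ L^-alpha,
height law h = L^beta — partitions into four classes by the long-range
behavior of narrowband amplitude envelopes:

    MU1 : alpha <= 2                              H_amp = 0.5, rho -> 0
    MU2 : alpha > 2, beta > alpha - 3             H_amp = beta/2 - alpha/2 + 2, rho -> 1
    MU3 : alpha > 2, (alpha-3)/2 < beta <= alpha-3  H_amp = 0.5, rho -> 1 (low freq.)
    MU4 : alpha > 2, beta <= (alpha-3)/2          H_amp = 0.5, rho -> 0

The raw-signal exponent is H_raw = beta - alpha/2 + 2 in MU1-MU3 and 0.5 in
MU4. Passive filtering (PF) predicts H_raw > 0.5 but H_amp = 0.5 and rho -> 0.
Filtered-avalanche exponents: alpha' = alpha, beta' = beta/2, and the size
exponents follow (alpha - 1)/(tau - 1) = beta + 1 (likewise primed).

Within MU2 the relations (H_raw, H_amp) <-> (alpha, beta) are bijective:
beta = 2 (H_raw - H_amp), alpha = 2 (beta + 2 - H_raw).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MU_LABELS",
    "MUPrediction",
    "classify_mu",
    "predict",
    "invert_mu2",
    "consistent_classes",
]

MU_LABELS = ("MU1", "MU2", "MU3", "MU4", "PF")


def classify_mu(alpha, beta):
    """Meta-universality class label(s) for exponents alpha > 1, beta >= 0.

    Boundary ties follow the defining inequalities: MU1 includes alpha = 2,
    MU3 includes beta = alpha - 3, MU4 includes beta = (alpha - 3)/2.
    Vectorized: array inputs return an array of labels.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(a <= 1):
        raise ValueError("alpha must be > 1")
    if np.any(b < 0):
        raise ValueError("beta must be >= 0")
    out = np.where(
        a <= 2,
        "MU1",
        np.where(b > a - 3, "MU2", np.where(b > (a - 3) / 2, "MU3", "MU4")),
    )
    if np.isscalar(alpha) and np.isscalar(beta):
        return str(out)
    return out


@dataclass(frozen=True)
class MUPrediction:
    """Theoretical signature of a critical exponent pair.

    mu : class label.
    h_raw, h_amp : predicted raw-signal and envelope Hurst exponents.
    rho_limit : limiting rho_DCCA between distinct band envelopes (0 or 1).
    rho_low_freq_only : the rho limit holds only for low band frequencies (MU3).
    alpha_f, beta_f : filtered-avalanche exponents alpha' = alpha, beta' = beta/2.
    tau, tau_f : avalanche-size exponents of the raw and filtered avalanches.
    """

    mu: str
    h_raw: float
    h_amp: float
    rho_limit: int
    rho_low_freq_only: bool
    alpha_f: float
    beta_f: float
    tau: float
    tau_f: float


def predict(alpha: float, beta: float) -> MUPrediction:
    """Full theoretical prediction for one (alpha, beta) pair."""
    mu = classify_mu(float(alpha), float(beta))
    h_raw = 0.5 if mu == "MU4" else beta - alpha / 2.0 + 2.0
    h_amp = beta / 2.0 - alpha / 2.0 + 2.0 if mu == "MU2" else 0.5
    rho_limit = 1 if mu in ("MU2", "MU3") else 0
    return MUPrediction(
        mu=mu,
        h_raw=float(h_raw),
        h_amp=float(h_amp),
        rho_limit=rho_limit,
        rho_low_freq_only=(mu == "MU3"),
        alpha_f=float(alpha),
        beta_f=float(beta) / 2.0,
        tau=1.0 + (alpha - 1.0) / (beta + 1.0),
        tau_f=1.0 + (alpha - 1.0) / (beta / 2.0 + 1.0),
    )


def invert_mu2(h_raw: float, h_amp: float) -> tuple[float, float]:
    """Invert the MU2 relations: (H_raw, H_amp) -> (alpha, beta).

    beta = 2 (H_raw - H_amp); alpha = 2 (beta + 2 - H_raw). Valid where the
    recovered pair lies in the MU2 region.
    """
    beta = 2.0 * (h_raw - h_amp)
    alpha = 2.0 * (beta + 2.0 - h_raw)
    return float(alpha), float(beta)


def consistent_classes(
    h_amp_est: float,
    rho_tail_est: float,
    gradient_est: float | None = None,
    h_amp_band: float = 0.05,
    rho_high: float = 0.5,
    allow_low_freq_mu3: bool = True,
) -> set[str]:
    """Model classes compatible with empirical (H_amp, largest-scale rho, gradient).

    Logic: only MU2 can produce H_amp > 0.5, so an elevated envelope exponent
    pins the class to {MU2}. A null H_amp with high rho (rising with n, if a
    gradient is supplied) matches MU3; a null H_amp with small rho matches the
    null classes {PF, MU1, MU4}, which are indistinguishable by these
    statistics.

    Parameters
    ----------
    h_amp_band : half-width of the H_amp ~ 0.5 significance band.
    rho_high : threshold above which largest-scale rho counts as "high".
    allow_low_freq_mu3 : MU3's rho limit holds only for low band frequencies;
        set False when the analysed bands are known to be too high for the MU3
        limit to apply.
    """
    for name, v in (("h_amp_est", h_amp_est), ("rho_tail_est", rho_tail_est)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    out: set[str] = set()
    if h_amp_est > 0.5 + h_amp_band:
        out.add("MU2")
        return out
    null_h = abs(h_amp_est - 0.5) <= h_amp_band
    if null_h and rho_tail_est >= rho_high and allow_low_freq_mu3:
        if gradient_est is None or gradient_est > 0:
            out.add("MU3")
    if null_h and rho_tail_est < rho_high and "MU3" not in out:
        out.update({"PF", "MU1", "MU4"})
    return out
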