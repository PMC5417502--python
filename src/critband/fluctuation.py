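"""Detrended fluctuation and cross-correlation analysis.

DFA: integrate the mean-subtracted series to a profile x(t), split the profile
into floor(N/n) disjoint windows of length n, least-squares detrend each with a
degree-d polynomial (d = 1 by default), and form the grand mean of squared
residuals F^2(n). The log-log slope of F(n) against n estimates the Hurst
exponent H; H > 0.5 signals long-range temporal correlations.

DCCA replaces squared residuals with cross-products of the residuals of two
profiles, giving signed detrended covariances F^2_DCCA(n); the detrended
cross-correlation coefficient is

    rho_DCCA(n) = F^2_DCCA(n) / (F_DFA(n; x) * F_DFA(n; y)),

a scale-dependent, trend-robust analogue of the Pearson correlation. The tail
gradient — the OLS slope of rho against log n over the largest k scales
(k = 11 by default) — indicates whether rho is still rising toward its
asymptotic limit at the largest scales available.

Estimators follow the scikit-learn protocol (``fit`` + trailing-underscore
attributes); module-level ``dfa``/``dcca``/``rho_dcca`` are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator

from .signals import Signal

__all__ = [
    "WindowPlan",
    "log_spaced_windows",
    "DetrendedFluctuation",
    "DetrendedCrossCorrelation",
    "dfa",
    "dcca",
    "rho_dcca",
    "tail_gradient",
]

_RHO_SLACK = 1e-9


def log_spaced_windows(n_min: int, n_max: int, num: int = 30) -> np.ndarray:
    """Strictly increasing, deduplicated log-spaced integer window sizes."""
    if not (1 < n_min < n_max):
        raise ValueError(f"need 1 < n_min < n_max, got {n_min}, {n_max}")
    sizes = np.unique(np.round(np.geomspace(n_min, n_max, num)).astype(int))
    return sizes


@dataclass(frozen=True)
class WindowPlan:
    """Window sizes, detrending degree, and the size range used for slope fits."""

    sizes: np.ndarray
    detrend_degree: int = 1
    fit_range: tuple[float, float] | None = None  # inclusive (min, max); None = all

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        if sizes.ndim != 1 or sizes.size == 0:
            raise ValueError("sizes must be a non-empty 1-D sequence")
        if np.any(np.diff(sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if self.detrend_degree < 0:
            raise ValueError("detrend_degree must be >= 0")
        if sizes.min() <= self.detrend_degree + 1:
            raise ValueError(
                f"min window size {sizes.min()} must exceed detrend degree + 1 = "
                f"{self.detrend_degree + 1}"
            )
        object.__setattr__(self, "sizes", sizes)

    def fit_mask(self) -> np.ndarray:
        if self.fit_range is None:
            return np.ones(self.sizes.size, dtype=bool)
        lo, hi = self.fit_range
        return (self.sizes >= lo) & (self.sizes <= hi)

    @classmethod
    def logspaced(
        cls,
        n_min: int,
        n_max: int,
        num: int = 30,
        detrend_degree: int = 1,
        fit_range: tuple[float, float] | None = None,
    ) -> "WindowPlan":
        return cls(
            sizes=log_spaced_windows(n_min, n_max, num),
            detrend_degree=detrend_degree,
            fit_range=fit_range,
        )


def _profile(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.cumsum(x - x.mean())


def _detrended_residuals(profile: np.ndarray, n: int, degree: int) -> np.ndarray:
    """Residuals of per-window polynomial detrending, shape (n_windows, n).

    Windows are disjoint, taken from the start; the trailing remainder is
    discarded. The within-window abscissa is scaled to [0, 1] for conditioning
    (residuals are invariant to the abscissa scaling).
    """
    k = profile.size // n
    if k < 1:
        raise ValueError(f"window size {n} exceeds profile length {profile.size}")
    seg = profile[: k * n].reshape(k, n)
    t = np.arange(n, dtype=float) / n
    V = np.vander(t, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return seg - (seg @ Q) @ Q.T


def _cross_fluctuation(
    px: np.ndarray, py: np.ndarray, plan: WindowPlan
) -> np.ndarray:
    """F^2(n) per window size: grand mean of residual cross-products (Eq. of DCCA);
    with px is py this is exactly the squared DFA fluctuation."""
    out = np.empty(plan.sizes.size)
    for i, n in enumerate(plan.sizes):
        rx = _detrended_residuals(px, int(n), plan.detrend_degree)
        ry = rx if py is px else _detrended_residuals(py, int(n), plan.detrend_degree)
        out[i] = np.mean(rx * ry)
    return out


def _fit_hurst(
    sizes: np.ndarray, fluct: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    usable = mask & (fluct > 0)
    if usable.sum() < 2:
        return float("nan"), float("nan")
    res = scipy.stats.linregress(np.log(sizes[usable]), np.log(fluct[usable]))
    return float(res.slope), float(res.stderr)


class DetrendedFluctuation(BaseEstimator):
    """DFA estimator of the Hurst exponent.

    Parameters
    ----------
    n_min, n_max, num : log-spaced window-size grid (ignored if ``window_sizes``
        is given).
    window_sizes : explicit strictly increasing integer window sizes.
    degree : detrending polynomial degree d (default 1, i.e. DFA-1; exponents
        up to ~2 are then measurable).
    fit_range : inclusive (min, max) window-size range for the slope fit;
        None uses every size.

    Fitted attributes
    -----------------
    window_sizes_ : the window grid used.
    fluctuations_sq_ : squared fluctuations F^2(n) (the directly computed
        quantity; ``dcca(x, x)`` reproduces it bit-for-bit).
    fluctuations_ : F(n) >= 0 per window size.
    hurst_ : OLS slope of log F(n) vs log n over the fit range.
    hurst_stderr_ : standard error of that slope.
    """

    def __init__(
        self,
        n_min: int = 16,
        n_max: int = 4096,
        num: int = 30,
        window_sizes=None,
        degree: int = 1,
        fit_range: tuple[float, float] | None = None,
    ):
        self.n_min = n_min
        self.n_max = n_max
        self.num = num
        self.window_sizes = window_sizes
        self.degree = degree
        self.fit_range = fit_range

    def _plan(self) -> WindowPlan:
        if self.window_sizes is not None:
            sizes = np.asarray(self.window_sizes, dtype=int)
        else:
            sizes = log_spaced_windows(self.n_min, self.n_max, self.num)
        return WindowPlan(sizes=sizes, detrend_degree=self.degree, fit_range=self.fit_range)

    def fit(self, X, y=None):
        """Estimate F(n) and the Hurst exponent of a 1-D series (or Signal)."""
        x = X.samples if isinstance(X, Signal) else np.asarray(X, dtype=float)
        plan = self._plan()
        if plan.sizes.max() > x.size:
            raise ValueError(
                f"max window size {plan.sizes.max()} exceeds series length {x.size}"
            )
        if 2 * plan.sizes.max() > x.size:
            warnings.warn(
                "series shorter than twice the largest window; the largest-scale "
                "fluctuation rests on a single window",
                stacklevel=2,
            )
        px = _profile(x)
        f2 = _cross_fluctuation(px, px, plan)
        self.plan_ = plan
        self.window_sizes_ = plan.sizes
        self.fluctuations_sq_ = f2
        self.fluctuations_ = np.sqrt(np.maximum(f2, 0.0))
        self.hurst_, self.hurst_stderr_ = _fit_hurst(
            plan.sizes, self.fluctuations_, plan.fit_mask()
        )
        return self


class DetrendedCrossCorrelation(BaseEstimator):
    """DCCA / rho_DCCA estimator for a pair of equal-length series.

    Parameters as :class:`DetrendedFluctuation`, plus ``tail_k``: the number of
    largest scales over which the tail gradient of rho vs log n is fit.

    Fitted attributes
    -----------------
    window_sizes_ : window grid.
    covariances_ : signed detrended covariances F^2_DCCA(n).
    fluctuations_x_, fluctuations_y_ : per-series F(n).
    rho_ : rho_DCCA(n); NaN where a denominator vanishes.
    tail_gradient_ : OLS slope of rho against log n over the largest ``tail_k``
        scales.
    hurst_x_, hurst_y_ : per-series Hurst estimates over the fit range.
    """

    def __init__(
        self,
        n_min: int = 16,
        n_max: int = 4096,
        num: int = 30,
        window_sizes=None,
        degree: int = 1,
        fit_range: tuple[float, float] | None = None,
        tail_k: int = 11,
    ):
        self.n_min = n_min
        self.n_max = n_max
        self.num = num
        self.window_sizes = window_sizes
        self.degree = degree
        self.fit_range = fit_range
        self.tail_k = tail_k

    def fit(self, X, y):
        """Estimate F^2_DCCA(n) and rho_DCCA(n) for series ``X`` and ``y``."""
        x = X.samples if isinstance(X, Signal) else np.asarray(X, dtype=float)
        yy = y.samples if isinstance(y, Signal) else np.asarray(y, dtype=float)
        if x.shape != yy.shape:
            raise ValueError(f"length mismatch: {x.shape} vs {yy.shape}")
        plan = DetrendedFluctuation(
            n_min=self.n_min,
            n_max=self.n_max,
            num=self.num,
            window_sizes=self.window_sizes,
            degree=self.degree,
            fit_range=self.fit_range,
        )._plan()
        if plan.sizes.max() > x.size:
            raise ValueError(
                f"max window size {plan.sizes.max()} exceeds series length {x.size}"
            )
        px, py = _profile(x), _profile(yy)
        f2x = _cross_fluctuation(px, px, plan)
        f2y = _cross_fluctuation(py, py, plan)
        f2xy = _cross_fluctuation(px, py, plan)
        denom = np.sqrt(f2x * f2y)
        rho = np.full(plan.sizes.size, np.nan)
        ok = denom > 0
        rho[ok] = f2xy[ok] / denom[ok]
        over = np.abs(rho[ok]) - 1.0
        if np.any(over > _RHO_SLACK):
            raise FloatingPointError(
                f"|rho_DCCA| exceeds 1 by {over.max():.3e} (> {_RHO_SLACK}); "
                "this indicates a numerical defect"
            )
        rho[ok] = np.clip(rho[ok], -1.0, 1.0)
        mask = plan.fit_mask()
        self.plan_ = plan
        self.window_sizes_ = plan.sizes
        self.covariances_ = f2xy
        self.fluctuations_x_ = np.sqrt(np.maximum(f2x, 0.0))
        self.fluctuations_y_ = np.sqrt(np.maximum(f2y, 0.0))
        self.rho_ = rho
        self.hurst_x_, _ = _fit_hurst(plan.sizes, self.fluctuations_x_, mask)
        self.hurst_y_, _ = _fit_hurst(plan.sizes, self.fluctuations_y_, mask)
        if np.isfinite(rho).sum() >= 2:
            self.tail_gradient_ = tail_gradient(plan.sizes, rho, k=self.tail_k)
        else:
            self.tail_gradient_ = float("nan")
        return self


def tail_gradient(sizes, rho_values, k: int = 11) -> float:
    """OLS slope of rho against log n over the largest ``k`` window sizes.

    Positive values indicate rho_DCCA(n) still rising toward its limit at the
    largest observable scales. If fewer than ``k`` sizes are available, all are
    used; fewer than 2 usable (finite) points is an error.
    """
    sizes = np.asarray(sizes, dtype=float)
    rho_values = np.asarray(rho_values, dtype=float)
    if sizes.shape != rho_values.shape:
        raise ValueError("sizes and rho_values must have equal shapes")
    k_eff = min(int(k), sizes.size)
    s, r = sizes[-k_eff:], rho_values[-k_eff:]
    ok = np.isfinite(r)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable points for the tail gradient")
    return float(scipy.stats.linregress(np.log(s[ok]), r[ok]).slope)


def dfa(
    series,
    window_sizes=None,
    n_min: int = 16,
    n_max: int = 4096,
    num: int = 30,
    degree: int = 1,
    fit_range: tuple[float, float] | None = None,
) -> DetrendedFluctuation:
    """Run DFA; returns the fitted :class:`DetrendedFluctuation` estimator."""
    return DetrendedFluctuation(
        n_min=n_min,
        n_max=n_max,
        num=num,
        window_sizes=window_sizes,
        degree=degree,
        fit_range=fit_range,
    ).fit(series)


def dcca(x, y, window_sizes=None, degree: int = 1, **kwargs) -> np.ndarray:
    """Signed detrended covariances F^2_DCCA(n) for a pair of series."""
    est = DetrendedCrossCorrelation(
        window_sizes=window_sizes, degree=degree, **kwargs
    ).fit(x, y)
    return est.covariances_


def rho_dcca(x, y, window_sizes=None, degree: int = 1, **kwargs) -> DetrendedCrossCorrelation:
    """Run DCCA; returns the fitted :class:`DetrendedCrossCorrelation` estimator."""
    return DetrendedCrossCorrelation(
        window_sizes=window_sizes, degree=degree, **kwargs
    ).fit(x, y)
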