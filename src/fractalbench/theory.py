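"""Closed-form theory of the fGn/fBm continuum.

Fractional Gaussian noise (fGn) and fractional Brownian motion (fBm) form a
single family of long-range correlated Gaussian processes indexed by the
Hurst exponent ``H`` in (0, 1).  The same family can be parameterised in the
spectral domain by the exponent ``beta`` of the 1/f^beta power law, in the
ARFIMA domain by the fractional differencing parameter ``d``, or by the
unified scaling exponent ``alpha`` in (0, 2) (``alpha = H`` for fGn,
``alpha = H + 1`` for fBm; ``alpha = 1`` is the 1/f boundary).

This module provides the exact linear conversions between these metrics, the
closed-form autocovariance functions of fGn and fBm, and the finite-length
expected lag-1 autocorrelation of a discretely sampled fBm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Metric",
    "SignalClass",
    "ScalingExponent",
    "AutocovarianceCurve",
    "METRIC_RANGES",
    "convert_exponent",
    "classify_alpha",
    "fgn_autocovariance",
    "fbm_autocovariance",
    "fgn_autocovariance_curve",
    "fbm_expected_lag1_autocorr",
]


class Metric(str, enum.Enum):
    """Exponent metric of a long-range correlated process."""

    H_FGN = "H_fGn"  # Hurst exponent of a stationary fGn, in (0, 1)
    H_FBM = "H_fBm"  # Hurst exponent of a nonstationary fBm, in (0, 1)
    ALPHA = "alpha"  # unified scaling exponent, in (0, 2)
    BETA = "beta"  # spectral exponent of the 1/f^beta law, in (-1, 3)
    D = "d"  # ARFIMA fractional differencing parameter, in (-0.5, 1.5)


class SignalClass(str, enum.Enum):
    """fGn / fBm classification of a process by its alpha exponent."""

    FGN = "fGn"
    FBM = "fBm"
    BOUNDARY = "boundary"


#: Open validity interval of each metric.  d > 0.5 is meaningful only under
#: the "difference, estimate, add one" convention for fBm series.
METRIC_RANGES: dict[Metric, tuple[float, float]] = {
    Metric.H_FGN: (0.0, 1.0),
    Metric.H_FBM: (0.0, 1.0),
    Metric.ALPHA: (0.0, 2.0),
    Metric.BETA: (-1.0, 3.0),
    Metric.D: (-0.5, 1.5),
}


@dataclass(frozen=True)
class ScalingExponent:
    """A scaling exponent tagged with the metric it is expressed in."""

    value: float
    metric: Metric

    def __post_init__(self) -> None:
        lo, hi = METRIC_RANGES[self.metric]
        if not (lo < self.value < hi):
            raise ValueError(
                f"{self.metric.value} value {self.value} outside the open "
                f"interval ({lo}, {hi})"
            )

    @property
    def alpha(self) -> float:
        """Value of this exponent on the unified alpha scale."""
        return _to_alpha(self)

    @property
    def signal_class(self) -> SignalClass:
        return classify_alpha(self.alpha)


def _to_alpha(x: ScalingExponent) -> float:
    if x.metric is Metric.ALPHA:
        return x.value
    if x.metric is Metric.H_FGN:
        return x.value
    if x.metric is Metric.H_FBM:
        return x.value + 1.0
    if x.metric is Metric.BETA:
        return (x.value + 1.0) / 2.0
    if x.metric is Metric.D:
        return x.value + 0.5
    raise AssertionError(f"unhandled metric {x.metric}")


def _from_alpha(alpha: float, target: Metric) -> float:
    if target is Metric.ALPHA:
        return alpha
    if target is Metric.BETA:
        return 2.0 * alpha - 1.0
    if target is Metric.D:
        return alpha - 0.5
    # H metrics need the signal class; the boundary has no H representation.
    if target is Metric.H_FGN:
        if alpha >= 1.0:
            raise ValueError(
                f"alpha={alpha} is not an fGn exponent; H_fGn undefined"
            )
        return alpha
    if target is Metric.H_FBM:
        if alpha <= 1.0:
            raise ValueError(
                f"alpha={alpha} is not an fBm exponent; H_fBm undefined"
            )
        return alpha - 1.0
    raise AssertionError(f"unhandled metric {target}")


def convert_exponent(
    x: ScalingExponent, target: Metric | str
) -> ScalingExponent:
    """Convert a scaling exponent to another metric.

    The conversions are the linear identities of the fGn/fBm continuum:
    ``alpha = (beta + 1)/2``, ``alpha = d + 1/2``, ``beta = 2H - 1`` (fGn),
    ``beta = 2H + 1`` (fBm), ``alpha = H`` (fGn), ``alpha = H + 1`` (fBm).
    Conversion to an H metric fails at the 1/f boundary (``alpha = 1``) and
    for the wrong signal class, since H carries class semantics.

    Parameters
    ----------
    x : ScalingExponent
        Exponent to convert, valid in its own metric.
    target : Metric or str
        Metric to convert to.

    Returns
    -------
    ScalingExponent
        Equivalent exponent in the target metric.  Idempotent when
        ``target == x.metric``.
    """
    target = Metric(target)
    if target is x.metric:
        return x
    return ScalingExponent(_from_alpha(_to_alpha(x), target), target)


def classify_alpha(alpha: float) -> SignalClass:
    """Classify an alpha exponent as fGn (< 1), fBm (> 1) or boundary (= 1)."""
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"alpha={alpha} outside the open interval (0, 2)")
    if alpha < 1.0:
        return SignalClass.FGN
    if alpha > 1.0:
        return SignalClass.FBM
    return SignalClass.BOUNDARY


def _check_H(H: float) -> None:
    if not (0.0 < H < 1.0):
        raise ValueError(f"H={H} outside the open interval (0, 1)")


def fgn_autocovariance(H, tau, V=1.0):
    """Autocovariance gamma(tau) of a unit-spaced fGn with variance ``V``.

    gamma(tau) = (V/2) [ (tau+1)^{2H} - 2 tau^{2H} + |tau-1|^{2H} ].

    Positive at lag 1 for persistent noise (H > 0.5), negative for
    antipersistent noise (H < 0.5), and exactly zero for white noise
    (H = 0.5, tau >= 1).  Accepts scalar or array ``tau``.
    """
    _check_H(H)
    if V <= 0:
        raise ValueError(f"variance V={V} must be positive")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be nonnegative")
    h2 = 2.0 * H
    out = 0.5 * V * ((tau + 1.0) ** h2 - 2.0 * tau**h2 + np.abs(tau - 1.0) ** h2)
    return out if out.ndim else float(out)


def fbm_autocovariance(H, t, s, V=1.0):
    """Autocovariance gamma(t, s) of an fBm started at B(0) = 0.

    gamma(t, s) = (V/2) [ t^{2H} + s^{2H} - |t-s|^{2H} ]; at ``t == s`` this
    is ``V t^{2H}``, the defining power-law growth of the fBm variance.
    """
    _check_H(H)
    if V <= 0:
        raise ValueError(f"variance V={V} must be positive")
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(t < 0) or np.any(s < 0):
        raise ValueError("times must be nonnegative")
    h2 = 2.0 * H
    out = 0.5 * V * (t**h2 + s**h2 - np.abs(t - s) ** h2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AutocovarianceCurve:
    """Autocovariance values of a stationary process on integer lags 0..L.

    Invariants checked at construction: the lag-0 value equals the variance
    and every autocorrelation has magnitude at most one.
    """

    lags: np.ndarray
    values: np.ndarray
    variance: float

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape:
            raise ValueError("lags and values must have the same shape")
        if np.any(lags < 0):
            raise ValueError("lags must be nonnegative")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        i0 = np.nonzero(lags == 0)[0]
        if i0.size and not math.isclose(values[i0[0]], self.variance):
            raise ValueError("value at lag 0 must equal the variance")
        if np.any(np.abs(values) > self.variance * (1 + 1e-12)):
            raise ValueError("|autocorrelation| exceeds 1 at some lag")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    @property
    def autocorrelation(self) -> np.ndarray:
        return self.values / self.variance


def fgn_autocovariance_curve(
    H: float, max_lag: int, V: float = 1.0
) -> AutocovarianceCurve:
    """fGn autocovariance evaluated on lags 0..max_lag as a checked curve."""
    lags = np.arange(max_lag + 1)
    return AutocovarianceCurve(lags, fgn_autocovariance(H, lags, V), V)


def fbm_expected_lag1_autocorr(H: float, N: int) -> float:
    """Expected lag-1 autocorrelation of a length-``N`` discrete fBm.

    For an fBm observed at N unit-spaced points the finite-length expected
    lag-1 autocorrelation is

        rho(1) = 1 - N (N - 1) / ( 2 * sum_{t=1}^{N-1} (N - t) t^{2H} ).

    The formula explains the apparent breakdown of integrated near-white
    noise: as H -> 0 it tends to 0 (the "fBm" is indistinguishable from
    white noise), while as H -> 1 it tends to 1.  At H = 0.5 it reduces to
    ``1 - 3/(N + 1)``, the classical mean-removed random-walk value.

    Parameters
    ----------
    H : float
        Hurst exponent of the increment process, in (0, 1).
    N : int
        Series length; at least 16 (the finite-size expression is not
        meaningful for very short series).
    """
    _check_H(H)
    if N < 16:
        raise ValueError(f"N={N} too short; need N >= 16")
    t = np.arange(1, N, dtype=float)
    denom = 2.0 * np.sum((N - t) * t ** (2.0 * H))
    return 1.0 - (N * (N - 1.0)) / denom
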