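"""Synthetic fGn/fBm series generators.

Three generation methods are provided:

* Davies–Harte circulant embedding (``davies_harte_fgn``): exact fGn — the
  output is Gaussian with *exactly* the theoretical fGn autocovariance.
* Spectral synthesis (``ssm_series``): Fourier coefficients with amplitudes
  drawn to follow the target 1/f^beta power law and uniform random phases.
* ARFIMA(0, d, 0) simulation (``arfima_fgn``): fractionally integrated white
  noise realised as a truncated MA(infinity) filter.

fBm series are obtained by cumulative summation of the corresponding fGn
(``integrate_series``); ``generate_series`` dispatches on the unified alpha
exponent and handles the integration convention of each method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .theory import fgn_autocovariance

__all__ = [
    "RandomStreams",
    "Series",
    "CirculantSpectrum",
    "MACoefficients",
    "circulant_spectrum",
    "davies_harte_fgn",
    "ssm_series",
    "arfima_coefficients",
    "arfima_fgn",
    "integrate_series",
    "difference_series",
    "generate_series",
    "GENERATORS",
]

GENERATORS = ("DH", "SSM", "ARFIMA")


class RandomStreams:
    """Seeded random source used by all generators.

    Wraps one PCG64 stream; Gaussian and uniform draws are taken from it
    sequentially, so a fixed seed yields bit-identical series from every
    generator (each generator documents its draw order).
    """

    def __init__(self, seed) -> None:
        if isinstance(seed, np.random.SeedSequence):
            self.seed: Optional[int] = None
            self._rng = np.random.default_rng(seed)
        else:
            self.seed = int(seed)
            self._rng = np.random.default_rng(self.seed)

    def normal(self, n: int) -> np.ndarray:
        """Next ``n`` standard Gaussian draws (W_gn)."""
        return self._rng.standard_normal(n)

    def uniform(self, n: int) -> np.ndarray:
        """Next ``n`` uniform draws on [0, 1) (W_un)."""
        return self._rng.random(n)


@dataclass
class Series:
    """A univariate real series plus generation provenance."""

    values: np.ndarray
    generator: str = "external"  # DH | SSM | ARFIMA | external
    target_alpha: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if values.size < 2:
            raise ValueError("a series needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("series values must all be finite")
        self.values = values

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CirculantSpectrum:
    """Nonnegative eigenvalues of the circulant embedding of an fGn covariance."""

    weights: np.ndarray
    embedding_size: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != self.embedding_size:
            raise ValueError("weight vector length must equal embedding size")
        if np.any(w < 0):
            raise ValueError("circulant spectrum has negative weights")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class MACoefficients:
    """Truncated MA(infinity) coefficients of an ARFIMA(0, d, 0) filter."""

    d: float
    coefficients: np.ndarray

    @property
    def order(self) -> int:
        return self.coefficients.size - 1


def _check_power_of_two(N: int) -> None:
    if N < 2 or (N & (N - 1)) != 0:
        raise ValueError(f"length N={N} must be a power of 2")


def circulant_spectrum(H: float, N_out: int) -> CirculantSpectrum:
    """Spectral weights of the circulant embedding for an fGn of length N_out.

    The unit-variance fGn autocovariance gamma(0..N_out) is mirrored into a
    circulant sequence of size ``M = 2 N_out`` and Fourier transformed.  The
    resulting eigenvalues must be nonnegative for the embedding to define a
    valid Gaussian process; negligible negative round-off (> -1e-9) is
    clipped to zero, anything worse raises.
    """
    _check_power_of_two(N_out)
    M = 2 * N_out
    gamma = fgn_autocovariance(H, np.arange(N_out + 1))
    # circulant first row: gamma(0..N), gamma(N-1..1)
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(c).real
    if np.any(lam < -1e-9):
        raise ValueError(
            f"invalid covariance sequence: circulant eigenvalue "
            f"{lam.min():.3e} < -1e-9 for H={H}"
        )
    return CirculantSpectrum(np.clip(lam, 0.0, None), M)


def davies_harte_fgn(H: float, N: int, rng: RandomStreams) -> Series:
    """Exact fractional Gaussian noise via circulant embedding.

    Randomised spectral amplitudes are built from ``2 N`` independent
    Gaussian draws (one for the DC eigenvalue, pairs for the conjugate-
    symmetric interior frequencies, one for Nyquist — drawn as a single
    block in that order), weighted by the square roots of the circulant
    eigenvalues, and inverse transformed.  The first ``N`` points have
    exactly the theoretical fGn autocovariance with unit variance.
    """
    spec = circulant_spectrum(H, N)
    M = spec.embedding_size
    lam = spec.weights
    z = rng.normal(M)
    a = np.empty(M, dtype=complex)
    a[0] = np.sqrt(lam[0] / M) * z[0]
    k = np.arange(1, M // 2)
    a[k] = np.sqrt(lam[k] / (2.0 * M)) * (z[2 * k - 1] + 1j * z[2 * k])
    a[M // 2] = np.sqrt(lam[M // 2] / M) * z[M - 1]
    a[M - k] = np.conj(a[k])
    x = np.fft.fft(a).real[:N]
    return Series(x, generator="DH", target_alpha=H, seed=rng.seed)


def ssm_series(beta: float, N: int, rng: RandomStreams) -> Series:
    """Spectral synthesis: random-phase Fourier coefficients with 1/f^beta power.

    For f = 1..N/2 the amplitude is ``r(f) = W_gn(f) / f^(beta/2)`` and the
    phase ``phi(f) = 2 pi W_un(f)`` (Gaussian block drawn first, then the
    uniform block).  Interior coefficients are extended with Hermitian
    symmetry (conjugate mirror), the Nyquist coefficient keeps only its real
    part and the DC term is zero, so the inverse transform is real up to
    round-off, which is asserted tiny and discarded.
    """
    if N < 4 or N % 2:
        raise ValueError(f"SSM length N={N} must be even and >= 4")
    if not (-1.0 < beta < 3.0):
        raise ValueError(f"beta={beta} outside the open interval (-1, 3)")
    half = N // 2
    f = np.arange(1, half + 1, dtype=float)
    r = rng.normal(half) / f ** (beta / 2.0)
    phi = 2.0 * np.pi * rng.uniform(half)
    coef = r * np.cos(phi) + 1j * r * np.sin(phi)
    X = np.zeros(N, dtype=complex)
    X[1:half] = coef[:-1]
    X[half] = coef[-1].real  # Nyquist must be real for a real series
    X[half + 1:] = np.conj(X[half - 1:0:-1])
    x = np.fft.ifft(X)
    resid = np.abs(x.imag).max()
    if resid > 1e-9:
        raise AssertionError(f"imaginary residue {resid:.2e} exceeds 1e-9")
    return Series(x.real, generator="SSM", target_alpha=(beta + 1.0) / 2.0,
                  seed=rng.seed)


def arfima_coefficients(d: float, K: int) -> MACoefficients:
    """MA coefficients a_0..a_K of the ARFIMA(0, d, 0) filter.

    a_k = Gamma(k + d) / (Gamma(k + 1) Gamma(d)), computed by the
    overflow-free recurrence a_0 = 1, a_k = a_{k-1} (k - 1 + d) / k.
    For d = 0 the filter is the identity (a_k = 0 for k >= 1).
    """
    if not (-0.5 < d < 0.5):
        raise ValueError(f"d={d} outside the open interval (-0.5, 0.5)")
    if K < 1:
        raise ValueError(f"truncation order K={K} must be >= 1")
    a = np.empty(K + 1)
    a[0] = 1.0
    for k in range(1, K + 1):
        a[k] = a[k - 1] * (k - 1 + d) / k
    return MACoefficients(d=d, coefficients=a)


def arfima_fgn(d: float, N: int, rng: RandomStreams, K: int = 100) -> Series:
    """ARFIMA(0, d, 0) series: unit-Gaussian innovations through the MA filter.

    ``N + K`` innovations are drawn and convolved with a_0..a_K; the first
    ``K`` outputs are discarded as burn-in so every retained point sees the
    full filter.
    """
    if N < 2:
        raise ValueError(f"N={N} must be >= 2")
    ma = arfima_coefficients(d, K)
    eps = rng.normal(N + K)
    x = np.convolve(eps, ma.coefficients)[K:K + N]
    return Series(x, generator="ARFIMA", target_alpha=d + 0.5, seed=rng.seed)


def integrate_series(s: Series) -> Series:
    """Cumulative sum (fGn -> fBm); length preserved."""
    return Series(np.cumsum(s.values), generator=s.generator,
                  target_alpha=s.target_alpha, seed=s.seed)


def difference_series(s: Series) -> Series:
    """First differences (fBm -> fGn); length N - 1."""
    if s.n < 3:
        raise ValueError("need at least 3 points to difference")
    return Series(np.diff(s.values), generator=s.generator,
                  target_alpha=s.target_alpha, seed=s.seed)


def generate_series(method: str, alpha: float, N: int,
                    rng: RandomStreams) -> Series:
    """Generate a series with target scaling exponent ``alpha`` in (0, 2).

    Dispatch:

    * ``DH``: exact fGn with H = alpha for alpha < 1; for alpha > 1 an fGn
      with H = alpha - 1 is generated and integrated.  alpha = 1 is invalid
      (the boundary has no H).
    * ``ARFIMA``: fGn with d = alpha - 1/2 for alpha < 1; for alpha > 1,
      d = alpha - 3/2 then integration.  alpha = 1 is invalid (|d| < 0.5).
    * ``SSM``: direct synthesis at beta = 2 alpha - 1; any alpha in (0, 2)
      including the 1/f boundary alpha = 1.
    """
    method = method.upper()
    if method not in GENERATORS:
        raise ValueError(f"unknown generator {method!r}; choose from {GENERATORS}")
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"alpha={alpha} outside the open interval (0, 2)")
    if method == "SSM":
        s = ssm_series(2.0 * alpha - 1.0, N, rng)
    elif method == "DH":
        if alpha == 1.0:
            raise ValueError("DH cannot generate the 1/f boundary (alpha=1)")
        if alpha < 1.0:
            s = davies_harte_fgn(alpha, N, rng)
        else:
            s = integrate_series(davies_harte_fgn(alpha - 1.0, N, rng))
    else:  # ARFIMA
        if alpha == 1.0:
            raise ValueError("ARFIMA cannot generate the 1/f boundary (alpha=1)")
        if alpha < 1.0:
            s = arfima_fgn(alpha - 0.5, N, rng)
        else:
            s = integrate_series(arfima_fgn(alpha - 1.5, N, rng))
    s.target_alpha = alpha
    return s
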