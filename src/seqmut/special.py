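"""Real-argument special functions: Mittag-Leffler and Lerch transcendent.

Only the real domains the limit laws need are supported (the amplitude laws
evaluate ``E_{a,b}`` on the negative half-line with ``0 < a <= 1``, and the
per-step Laplace maps evaluate ``Phi(z, s, a)`` for ``z <= 0``, integer
``s >= 1`` and ``0 < a < 1``).

Mittag-Leffler evaluation switches between the power series (small ``|z|``),
a real integral representation (moderate negative ``z``) and the algebraic
asymptotic series (large negative ``z``); crossovers were chosen by error
balancing against a high-precision series oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, rgamma

__all__ = ["mittag_leffler", "lerch_phi", "lerch_phi_asymptotic"]

_SERIES_CUTOFF = 2.0    # |z| below which the power series is used
_ASYMP_CUTOFF = 200.0   # -z above which the asymptotic series is used


def _ml_series(a: float, b: float, z: float, kmax: int = 2000) -> float:
    """Power series sum_k z^k / Gamma(ak + b); stable for |z| <= ~2 and for
    all z >= 0 (positive terms).  Requires b > 0 (always true here)."""
    if z == 0.0:
        return float(rgamma(b))
    total = 0.0
    logz = math.log(abs(z))
    neg = z < 0.0
    for k in range(kmax):
        lt = k * logz - gammaln(a * k + b)
        term = math.exp(lt) if lt < 709.0 else math.inf
        if neg and k % 2 == 1:
            term = -term
        total += term
        if k > 2 and abs(term) < 1e-17 * max(abs(total), 1e-300) and k > abs(z):
            break
    return total


def _ml_integral(a: float, b: float, z: float) -> float:
    """Integral representation for z < 0, 0 < a < 1, b <= 1 (no residue term
    is needed on the negative real axis)."""
    sin_b = math.sin(math.pi * (1.0 - b))
    sin_ba = math.sin(math.pi * (1.0 - b + a))
    cos_a = math.cos(math.pi * a)
    p = (1.0 - b) / a

    def kernel(r: float) -> float:
        if r == 0.0:
            return 0.0
        num = r * sin_b - z * sin_ba
        den = r * r - 2.0 * r * z * cos_a + z * z
        return math.exp(p * math.log(r) - r ** (1.0 / a)) * num / den

    upper = 1.5 * 46.0 ** a  # exp(-r^{1/a}) ~ 1e-20 beyond
    pts = [min(abs(z), upper)] if abs(z) < upper else None
    val, _ = quad(kernel, 0.0, upper, limit=400, epsabs=1e-15, epsrel=1e-12, points=pts)
    return val / (math.pi * a)


def _ml_asymptotic(a: float, b: float, z: float, kmax: int = 60) -> float:
    """Algebraic expansion E_{a,b}(z) ~ -sum_{k>=1} z^{-k}/Gamma(b-ak) for
    z -> -inf with 0 < a < 1 (and a = 1 with b <= 1)."""
    total = 0.0
    prev = math.inf
    for k in range(1, kmax + 1):
        term = -rgamma(b - a * k) * z ** (-k)
        if abs(term) > prev:  # past optimal truncation
            break
        total += term
        prev = abs(term) if term != 0.0 else prev
    return total


def _ml_scalar(a: float, b: float, z: float) -> float:
    if a <= 0:
        raise ValueError("mittag_leffler requires a > 0")
    if a == 1.0 and b == 1.0:
        return math.exp(z)
    if z >= -_SERIES_CUTOFF:
        return _ml_series(a, b, z)
    if a >= 1.0:
        # only reached for a == 1 with b != 1 in practice
        if -z >= 30.0:
            return _ml_asymptotic(a, b, z)
        return _ml_series(a, b, z)
    if b > 1.0:
        # reduce b into (b-a <= 1] via E_{a,b}(z) = (E_{a,b-a}(z) - 1/Gamma(b-a))/z
        return (_ml_scalar(a, b - a, z) - rgamma(b - a)) / z
    if -z >= _ASYMP_CUTOFF:
        return _ml_asymptotic(a, b, z)
    return _ml_integral(a, b, z)


def mittag_leffler(a: float, b: float, z) -> float | np.ndarray:
    """Two-parameter Mittag-Leffler function ``E_{a,b}(z)`` for real ``z``.

    ``E_{1,1}(z) = exp(z)``; ``E_{a,a}(-x^a)`` builds the density of the
    one-parameter Mittag-Leffler probability law used for the random
    amplitudes; negative arguments are the main use.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 0:
        return _ml_scalar(a, b, float(z))
    return np.array([_ml_scalar(a, b, x) for x in z.ravel()]).reshape(z.shape)


def _lerch_series(z: float, s: int, a: float, kmax: int = 400) -> float:
    total = 0.0
    zk = 1.0
    for k in range(kmax):
        term = zk / (k + a) ** s
        total += term
        zk *= z
        if abs(zk) < 1e-18 * max(abs(total), 1e-300):
            break
    return total


def _lerch_integral(z: float, s: int, a: float) -> float:
    """25.14.5-type representation
    Phi(z,s,a) = (1/Gamma(s)) int_0^inf t^{s-1} e^{-at} / (1 - z e^{-t}) dt,
    valid for z < 1; used for z <= -0.5 where the series converges slowly or
    not at all."""

    def kernel(t: float) -> float:
        if t <= 0.0:
            return 1.0 / (1.0 - z) if s == 1 else 0.0
        return t ** (s - 1) * math.exp(-a * t) / (1.0 - z * math.exp(-t))

    # the integrand transitions from ~ -1/z to ~ e^{-at} around t = log(-z);
    # integrate the two regimes separately for full adaptive resolution
    tz = math.log(-z) if z < -1.0 else 0.0
    upper = tz + (45.0 + 10.0 * s) / a
    val = 0.0
    if tz > 0.0:
        part, _ = quad(kernel, 0.0, tz, limit=400, epsabs=1e-15, epsrel=1e-12)
        val += part
    part, _ = quad(kernel, tz, upper, limit=400, epsabs=1e-15, epsrel=1e-12)
    val += part
    return val / math.gamma(s)


def lerch_phi(z: float, s: int, a: float) -> float:
    """Lerch transcendent ``Phi(z, s, a)`` for ``z <= 0``, integer ``s >= 1``
    and ``0 < a < 1`` (the domain needed by the fitness-increase Laplace
    map)."""
    if z > 0:
        raise ValueError("lerch_phi supports z <= 0 only")
    if not (isinstance(s, (int, np.integer)) and s >= 1):
        raise ValueError("lerch_phi requires a positive integer s")
    if not 0 < a < 1:
        raise ValueError("lerch_phi requires a in (0, 1)")
    if z == 0.0:
        return a ** (-float(s))
    if abs(z) <= 0.5:
        return _lerch_series(z, int(s), a)
    return _lerch_integral(z, int(s), a)


def lerch_phi_asymptotic(z: float, s: int, a: float) -> float:
    """Leading z -> -inf behaviour
    ``pi/sin(pi a) * (-z)^{-a} (log(-z))^{s-1}/(s-1)!``; exposed for
    validation against :func:`lerch_phi`, not used in production evaluation.
    """
    if z >= -1.0:
        raise ValueError("asymptotic form requires z << -1")
    return (
        math.pi
        / math.sin(math.pi * a)
        * (-z) ** (-a)
        * math.log(-z) ** (s - 1)
        / math.factorial(s - 1)
    )
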