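"""Probability laws of the limit theory.

Two laws summarise the large-time, small-mutation-rate behaviour of a linear
mutational path:

* the *amplitude law*: ``Z_n(t) ~ V_n t^{r_n-1} e^{delta_n t}`` where ``V_n``
  follows a (Pillai-type) Mittag-Leffler distribution with Laplace transform
  ``E[e^{-theta V_n}] = (1 + (omega_n theta)^gamma)^{-1}``, tail parameter
  ``gamma = lambda_1/delta_n`` and scale ``omega_n``.  ``gamma = 1`` is the
  exponential distribution with mean ``omega_n``; ``gamma < 1`` is heavy
  tailed with infinite mean (an ``x^{gamma-1}`` singularity at the origin and
  an ``x^{-gamma-1}`` tail);

* the *arrival law*: the first type-``n`` cell appears at a logistic time
  with scale ``1/lambda_1`` and median given by :func:`seqmut.model.median_arrival`.

This module also evaluates the pre-limit (finite mutation rate) amplitude
transform by composing the per-step Laplace maps ``h_n`` and inverting it
numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import logistic

from .model import ArrivalLaw, FitnessProfile, MutationPath
from .special import lerch_phi, mittag_leffler

__all__ = [
    "AmplitudeLaw",
    "InfiniteMeanError",
    "amplitude_law",
    "amplitude_pdf",
    "amplitude_cdf",
    "amplitude_sf",
    "amplitude_quantile",
    "amplitude_mean",
    "amplitude_sample",
    "arrival_pdf",
    "arrival_cdf",
    "arrival_sf",
    "arrival_sample",
    "prob_exceed",
    "h_step",
    "compose_laplace",
    "finite_nu_amplitude_cdf",
]


class InfiniteMeanError(ValueError):
    """Moment query on a heavy-tailed amplitude law (tail < 1)."""


@dataclass(frozen=True)
class AmplitudeLaw:
    """Mittag-Leffler law of the random amplitude ``V_n``."""

    tail: float   # gamma = lambda_1/delta_n in (0, 1]
    scale: float  # omega_n > 0
    n: int = 0    # type index (0 when constructed directly)

    def __post_init__(self):
        if not 0.0 < self.tail <= 1.0:
            raise ValueError(f"tail parameter must be in (0, 1], got {self.tail}")
        if not self.scale > 0.0:
            raise ValueError(f"scale parameter must be positive, got {self.scale}")

    def laplace(self, theta):
        """``E[e^(-theta V_n)] = (1 + (omega theta)^gamma)^-1``."""
        theta = np.asarray(theta, dtype=float)
        return 1.0 / (1.0 + (self.scale * theta) ** self.tail)


def amplitude_law(profile: FitnessProfile, n: int) -> AmplitudeLaw:
    """Amplitude law of type ``n`` (1-based) from a fitness profile."""
    return AmplitudeLaw(tail=profile.tail(n), scale=float(profile.omega[n - 1]), n=n)


def amplitude_pdf(law: AmplitudeLaw, x):
    """Density ``f(x) = (x/w)^{g-1} E_{g,g}(-(x/w)^g)/w`` for ``x > 0``."""
    x = np.asarray(x, dtype=float)
    g, w = law.tail, law.scale
    y = x / w
    with np.errstate(divide="ignore"):
        out = np.where(
            y > 0,
            y ** (g - 1.0) * mittag_leffler(g, g, -np.maximum(y, 1e-300) ** g) / w,
            0.0 if g == 1.0 else np.inf,
        )
    return out if out.ndim else float(out)


def amplitude_sf(law: AmplitudeLaw, x):
    """Survival ``P(V > x) = E_{g,1}(-(x/w)^g)``."""
    x = np.asarray(x, dtype=float)
    y = np.maximum(x, 0.0) / law.scale
    out = mittag_leffler(law.tail, 1.0, -(y ** law.tail))
    return np.clip(out, 0.0, 1.0) if np.ndim(out) else min(max(out, 0.0), 1.0)


def amplitude_cdf(law: AmplitudeLaw, x):
    return 1.0 - amplitude_sf(law, x)


def amplitude_quantile(law: AmplitudeLaw, q: float) -> float:
    """Quantile by root-finding on the CDF."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    hi = law.scale
    while amplitude_cdf(law, hi) < q:
        hi *= 4.0
    lo = hi / 4.0
    while amplitude_cdf(law, lo) > q and lo > 1e-300:
        lo /= 4.0
    return brentq(lambda x: amplitude_cdf(law, x) - q, lo, hi, xtol=1e-14, rtol=1e-12)


def amplitude_mean(law: AmplitudeLaw) -> float:
    if law.tail < 1.0:
        raise InfiniteMeanError(
            f"the amplitude law with tail {law.tail} < 1 has a power-law "
            "x^(-tail-1) tail and therefore an infinite mean; only tail = 1 "
            "(exponential) has finite moments"
        )
    return law.scale


def amplitude_sample(law: AmplitudeLaw, n_samples: int, seed=None, rng=None) -> np.ndarray:
    """Exact sampler via the product representation
    ``V = w * Exp(1)^{1/g} * S_g`` with ``S_g`` one-sided ``g``-stable from
    the Chambers-Mallows-Stuck / Kanter trigonometric construction."""
    rng = np.random.default_rng(seed) if rng is None else rng
    g, w = law.tail, law.scale
    e = rng.exponential(size=n_samples)
    if g == 1.0:
        return w * e
    u = rng.uniform(0.0, np.pi, size=n_samples)
    wexp = rng.exponential(size=n_samples)
    stable = (
        np.sin(g * u)
        / np.sin(u) ** (1.0 / g)
        * (np.sin((1.0 - g) * u) / wexp) ** ((1.0 - g) / g)
    )
    return w * e ** (1.0 / g) * stable


# ---------------------------------------------------------------------------
# logistic arrival law


def arrival_pdf(law: ArrivalLaw, t):
    return logistic.pdf(t, loc=law.median, scale=law.scale)


def arrival_cdf(law: ArrivalLaw, t):
    return logistic.cdf(t, loc=law.median, scale=law.scale)


def arrival_sf(law: ArrivalLaw, t):
    """``P(tau_n > t) = [1 + exp((t - median)/scale)]^{-1}``."""
    return logistic.sf(t, loc=law.median, scale=law.scale)


def arrival_sample(law: ArrivalLaw, n_samples: int, seed=None, rng=None) -> np.ndarray:
    rng = np.random.default_rng(seed) if rng is None else rng
    return rng.logistic(loc=law.median, scale=law.scale, size=n_samples)


def prob_exceed(profile: FitnessProfile, law: AmplitudeLaw, t: float, k: float) -> float:
    """``P(Z_n(t) > k) ~ P(V_n > k t^{1-r_n} e^{-delta_n t})``.

    The scaled threshold is computed in log space: for large ``t`` it can
    underflow, in which case the probability is 1.
    """
    if k <= 0:
        return 1.0
    i = law.n - 1 if law.n >= 1 else 0
    delta, r = profile.delta[i], profile.r[i]
    log_thr = math.log(k) + (1.0 - r) * math.log(t) - delta * t
    if log_thr < -700.0:
        return 1.0
    return float(amplitude_sf(law, math.exp(log_thr)))


# ---------------------------------------------------------------------------
# pre-limit Laplace transform of the amplitude


def h_step(profile: FitnessProfile, path: MutationPath, n: int, theta: float) -> float:
    """Per-step Laplace map ``h_n(theta)`` relating the amplitude transforms
    of type ``n+1`` and type ``n``:

    * ``nu_n theta/(delta_n - lambda_{n+1})`` below the running max,
    * ``nu_n theta/r_n`` at the running max,
    * ``nu_n theta (r_n-1)! lambda_{n+1}^{-r_n} Phi(-theta a_{n+1}/l_{n+1}, r_n, 1-delta_n/lambda_{n+1})``
      above it (Lerch transcendent).

    Each map is nonnegative, increasing, and vanishes at 0.
    """
    if not 1 <= n <= profile.n_types - 1:
        raise IndexError(f"step index {n} outside 1..{profile.n_types - 1}")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    i = n - 1
    nu, lam_next = path.nu[i], profile.lam[i + 1]
    case = profile.case[i]
    if case == "decrease":
        return nu * theta / (profile.delta[i] - lam_next)
    if case == "equal":
        return nu * theta / profile.r[i]
    r = int(profile.r[i])
    alpha_next = path.alpha[i + 1]
    a = 1.0 - profile.delta[i] / lam_next
    phi = lerch_phi(-theta * alpha_next / lam_next, r, a)
    return nu * theta * math.factorial(r - 1) * lam_next ** (-r) * phi


def compose_laplace(profile: FitnessProfile, path: MutationPath, n: int, theta: float) -> float:
    """Laplace transform ``E[exp(-theta V_n*)]`` of the pre-limit amplitude,
    by composing ``h_1 ∘ ... ∘ h_{n-1}`` (innermost map applied first) into
    the exponential transform of ``V_1`` (mean ``alpha_1/lambda_1``)."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    comp = float(theta)
    for m in range(n - 1, 0, -1):
        comp = h_step(profile, path, m, comp)
    return 1.0 / (1.0 + comp * path.alpha[0] / profile.lam[0])


@lru_cache(maxsize=32)
def _stehfest_weights(n_terms: int) -> tuple[float, ...]:
    """Gaver-Stehfest weights for an even number of terms (exact rational
    arithmetic, converted to float)."""
    if n_terms % 2 or n_terms < 2:
        raise ValueError("n_terms must be a positive even integer")
    from fractions import Fraction

    m = n_terms // 2
    weights = []
    for k in range(1, n_terms + 1):
        total = Fraction(0)
        for j in range((k + 1) // 2, min(k, m) + 1):
            total += (
                Fraction(j ** (m + 1), math.factorial(m))
                * math.comb(m, j)
                * math.comb(2 * j, j)
                * math.comb(j, k - j)
            )
        weights.append((-1) ** (k + m) * total)
    return tuple(float(w) for w in weights)


def finite_nu_amplitude_cdf(
    profile: FitnessProfile,
    path: MutationPath,
    n: int,
    x: float,
    n_terms: int = 18,
    err_tol: float = 1e-3,
) -> float:
    """CDF of the pre-limit amplitude ``V_n*`` by numerically inverting its
    Laplace transform.

    Uses Gaver-Stehfest inversion, which samples the transform only at real
    positive points (the per-step maps are defined on the real axis); the
    result is approximate with accuracy limited by float64 cancellation in
    the weights (roughly 1e-7 at the default 14 terms for smooth transforms).
    Convergence is checked by comparing against the (n_terms-2)-term result;
    disagreement beyond ``err_tol`` raises with diagnostics.
    """
    if x < 0:
        raise ValueError("x must be nonnegative")
    if x == 0.0:
        return 0.0

    def invert(nt: int) -> float:
        w = _stehfest_weights(nt)
        ln2_x = math.log(2.0) / x
        total = 0.0
        for k in range(1, nt + 1):
            s = k * ln2_x
            total += w[k - 1] * compose_laplace(profile, path, n, s) / s
        return ln2_x * total

    val = invert(n_terms)
    check = invert(n_terms - 2)
    err = abs(val - check)
    if err > err_tol:
        raise RuntimeError(
            f"Laplace inversion did not converge at x={x}: "
            f"{n_terms}-term and {n_terms - 2}-term estimates differ by "
            f"{err:.3g} (> {err_tol}); try more terms or a different x range"
        )
    return min(max(val, 0.0), 1.0)
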