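"""Mutation-rate inference for n-mutation fluctuation assays.

Replicate cultures grow from a single sensitive cell for time ``t`` and are
then exposed to a selective agent; the number of replicates without
resistant cells and the resistant-cell counts are recorded.  When ``k``
mutations confer resistance, resistant cells are type ``n = k + 1`` (type 1
is the founding population; mind this off-by-one against conventions that
count mutations).

Two estimators of the per-mutation rate ``nu``, both assuming neutral
mutations (``lambda_1 = lambda_2 = ...``, ``nu_1 = nu_2 = ... = nu``) and
externally measured ``alpha_1`` and ``lambda_1``:

* the **p0 method** — the number of replicates without resistance is
  binomial with success probability equal to the logistic no-arrival
  probability ``P(tau_n > t)``, whose median is the closed-form neutral
  median arrival time; preferred when a nontrivial fraction of replicates
  has no resistant cells;
* the **mutant-count method** — resistant counts follow
  ``Z_n(t) ~ V_n t^{n-1} e^{lambda_1 t}`` with ``V_n`` exponential of mean
  ``omega_n = (alpha_1/lambda_1) nu^{n-1}/(n-1)!``; preferred when all
  replicates carry sizeable mutant numbers.  Zero counts enter as the
  logistic no-arrival mass (a mixture; set ``zeros="condition"`` to instead
  condition on positivity).

Maximisation is over ``log10 nu`` on a bounded bracket; confidence
intervals are profile-likelihood intervals at a drop of 1.92 log-units
(asymptotic 95%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "AssayData",
    "EstimateResult",
    "neutral_median",
    "neutral_omega",
    "p0_probability",
    "p0_loglik",
    "p0_estimate",
    "count_loglik",
    "count_mle",
    "method_advisor",
]

_CI_DROP = 1.92  # chi2(1)/2 at 95%
_DEFAULT_BRACKET = (-8.0, -0.5)  # log10 nu search range


@dataclass(frozen=True)
class AssayData:
    """Replicate outcomes of an n-mutation fluctuation assay."""

    counts: np.ndarray  # resistant-cell count per replicate
    t: float            # growth time before selection
    n_target: int       # resistant type index (k mutations -> n_target = k+1)
    alpha1: float       # division rate of the founding type (measured)
    lam1: float         # net growth rate of the founding type (measured)
    neutral: bool = True

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(counts) < 1:
            raise ValueError("counts must be a 1-D array with >= 1 replicate")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.t > 0:
            raise ValueError("growth time must be positive")
        if self.n_target < 2:
            raise ValueError("n_target must be >= 2 (at least one mutation)")
        if not (self.alpha1 > 0 and 0 < self.lam1 <= self.alpha1):
            raise ValueError("require alpha1 > 0 and 0 < lam1 <= alpha1")
        object.__setattr__(self, "counts", counts)

    @property
    def n_replicates(self) -> int:
        return len(self.counts)

    @property
    def n_zero(self) -> int:
        return int((self.counts == 0).sum())

    @property
    def frac_zero(self) -> float:
        return self.n_zero / self.n_replicates


@dataclass
class EstimateResult:
    """Point estimate of the mutation rate with a profile-likelihood CI."""

    nu: float
    ci: tuple[float, float]
    method: str
    loglik: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def log10_nu(self) -> float:
        return math.log10(self.nu)

    def __post_init__(self):
        if not self.nu > 0:
            raise ValueError("estimated nu must be positive")
        lo, hi = self.ci
        if not lo <= self.nu <= hi:
            raise ValueError("confidence interval must contain the estimate")


def neutral_median(nu: float, n: int, alpha1: float, lam1: float) -> float:
    """Median arrival time of type ``n`` on the neutral path:
    ``(1/l1) log( l1^2 (n-2)! / (a1 [log(1/nu)/l1]^{n-2} nu^{n-1}) )``."""
    if not 0 < nu < 1:
        raise ValueError("neutral median requires 0 < nu < 1")
    m = n - 2  # r-index of the seeding type n-1
    return (
        2.0 * math.log(lam1)
        + math.lgamma(m + 1)
        - math.log(alpha1)
        - m * (math.log(math.log(1.0 / nu)) - math.log(lam1))
        - (n - 1) * math.log(nu)
    ) / lam1


def neutral_omega(nu: float, n: int, alpha1: float, lam1: float) -> float:
    """Amplitude scale on the neutral path:
    ``omega_n = (alpha1/lam1) nu^{n-1}/(n-1)!``."""
    return alpha1 / lam1 * nu ** (n - 1) / math.gamma(n)


def p0_probability(data: AssayData, nu: float) -> float:
    """Probability that a replicate has no resistant cells at time ``t``:
    the logistic no-arrival probability
    ``P(tau_n > t) = [1 + exp(lam1 (t - median))]^{-1}``."""
    thalf = neutral_median(nu, data.n_target, data.alpha1, data.lam1)
    x = data.lam1 * (data.t - thalf)
    if x > 700:
        return math.exp(-x)
    return 1.0 / (1.0 + math.exp(x))


def p0_loglik(data: AssayData, nu: float) -> float:
    """Binomial log-likelihood of the zero-replicate count."""
    p0 = p0_probability(data, nu)
    z, k = data.n_zero, data.n_replicates
    eps = 1e-300
    return z * math.log(max(p0, eps)) + (k - z) * math.log(max(1.0 - p0, eps))


def _mixture_zero_logp(data: AssayData, nu: float) -> float:
    return math.log(max(p0_probability(data, nu), 1e-300))


def count_loglik(data: AssayData, nu: float, zeros: str = "mixture") -> float:
    """Log-likelihood of the mutant counts.

    Positive counts are exponential with mean
    ``omega_n(nu) t^{n-1} e^{lam1 t}``; zero counts contribute the logistic
    no-arrival probability (``zeros="mixture"``, default) or are dropped
    with the likelihood conditioned on positivity (``zeros="condition"``).
    """
    if zeros not in ("mixture", "condition"):
        raise ValueError("zeros must be 'mixture' or 'condition'")
    n, t = data.n_target, data.t
    log_mean = (
        math.log(neutral_omega(nu, n, data.alpha1, data.lam1))
        + (n - 1) * math.log(t)
        + data.lam1 * t
    )
    pos = data.counts[data.counts > 0]
    mean = math.exp(log_mean)
    ll = float(-len(pos) * log_mean - pos.sum() / mean)
    if zeros == "mixture":
        p0 = p0_probability(data, nu)
        ll += data.n_zero * math.log(max(p0, 1e-300))
        ll += len(pos) * math.log(max(1.0 - p0, 1e-300))
    return ll


def _profile_ci(fun, x_hat: float, ll_max: float, bracket) -> tuple[float, float]:
    """Profile-likelihood interval on log10 nu: crossings of
    ``fun(x) = ll_max - 1.92`` on each side of the optimum (bracket edge if
    the likelihood never drops)."""
    lo_edge, hi_edge = bracket
    target = ll_max - _CI_DROP

    def g(x):
        return fun(x) - target

    lo = lo_edge
    if g(lo_edge) < 0:
        lo = brentq(g, lo_edge, x_hat, xtol=1e-10)
    hi = hi_edge
    if g(hi_edge) < 0:
        hi = brentq(g, x_hat, hi_edge, xtol=1e-10)
    return 10.0 ** lo, 10.0 ** hi


def _maximize(fun, bracket) -> tuple[float, float]:
    res = minimize_scalar(lambda x: -fun(x), bounds=bracket, method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x), float(-res.fun)


def p0_estimate(data: AssayData, bracket=_DEFAULT_BRACKET) -> EstimateResult:
    """Estimate ``nu`` from the zero-replicate fraction (p0 method).

    Degenerate data yield one-sided bounds: with no resistant replicate at
    all only an upper bound on ``nu`` is identified; with resistance in
    every replicate the zero count carries little information and only a
    lower bound is returned (flagged "p0 uninformative").
    """
    diagnostics = {"frac_zero": data.frac_zero, "warnings": []}

    def ll(x):
        return p0_loglik(data, 10.0 ** x)

    k = data.n_replicates
    if data.n_zero == k:
        # all replicates without resistance: one-sided upper bound
        p_bound = math.exp(-_CI_DROP / k)  # k log p0 = -1.92
        nu_u = _invert_p0(data, p_bound, bracket)
        diagnostics["warnings"].append(
            "all replicates lack resistance: nu is only bounded above"
        )
        diagnostics["bound"] = "upper"
        return EstimateResult(nu=10.0 ** bracket[0], ci=(0.0, nu_u),
                              method="p0", loglik=ll(bracket[0]),
                              diagnostics=diagnostics)
    if data.n_zero == 0:
        p_bound = 1.0 - math.exp(-_CI_DROP / k)  # k log(1-p0) = -1.92
        nu_l = _invert_p0(data, p_bound, bracket)
        diagnostics["warnings"].append(
            "p0 uninformative: every replicate shows resistance, the zero "
            "count carries limited information; nu is only bounded below"
        )
        diagnostics["bound"] = "lower"
        warnings.warn(diagnostics["warnings"][-1], RuntimeWarning, stacklevel=2)
        return EstimateResult(nu=10.0 ** bracket[1], ci=(nu_l, math.inf),
                              method="p0", loglik=ll(bracket[1]),
                              diagnostics=diagnostics)

    x_hat, ll_max = _maximize(ll, bracket)
    ci = _profile_ci(ll, x_hat, ll_max, bracket)
    return EstimateResult(nu=10.0 ** x_hat, ci=ci, method="p0", loglik=ll_max,
                          diagnostics=diagnostics)


def _invert_p0(data: AssayData, p_target: float, bracket) -> float:
    """nu at which the no-resistance probability equals ``p_target``
    (p0 is decreasing in nu)."""
    def g(x):
        return p0_probability(data, 10.0 ** x) - p_target

    lo, hi = bracket
    if g(lo) < 0:
        return 10.0 ** lo
    if g(hi) > 0:
        return 10.0 ** hi
    return 10.0 ** brentq(g, lo, hi, xtol=1e-10)


def count_mle(data: AssayData, bracket=_DEFAULT_BRACKET, zeros: str = "mixture",
              ci: str = "bootstrap", n_boot: int = 199,
              seed: int = 0) -> EstimateResult:
    """Estimate ``nu`` by maximum likelihood on the mutant counts.

    The default confidence interval is a nonparametric bootstrap over
    replicates (percentile, ``n_boot`` resamples): the exponential amplitude
    law is a large-time approximation and the real count distribution is
    heavier tailed, so the curvature-based profile interval (``ci="profile"``)
    understates the sampling variability of the estimator.  The reported
    interval is the union of the bootstrap percentile interval with the
    profile interval, so it is never narrower than the likelihood-based one.
    """
    if ci not in ("bootstrap", "profile"):
        raise ValueError("ci must be 'bootstrap' or 'profile'")
    diagnostics = {"frac_zero": data.frac_zero, "warnings": [], "zeros": zeros,
                   "ci": ci}
    if (data.counts == 0).all():
        # no information in the exponential part; fall back to the p0 bound
        diagnostics["warnings"].append(
            "all counts are zero: only an upper bound on nu is identified"
        )
        res = p0_estimate(data, bracket=bracket)
        return EstimateResult(nu=res.nu, ci=res.ci, method="counts",
                              loglik=res.loglik, diagnostics=diagnostics)

    def ll(x):
        return count_loglik(data, 10.0 ** x, zeros=zeros)

    x_hat, ll_max = _maximize(ll, bracket)
    interval = _profile_ci(ll, x_hat, ll_max, bracket)
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        k = data.n_replicates
        boots = []
        for _ in range(n_boot):
            resampled = AssayData(
                counts=rng.choice(data.counts, size=k, replace=True),
                t=data.t, n_target=data.n_target,
                alpha1=data.alpha1, lam1=data.lam1,
            )
            if (resampled.counts > 0).any():
                def llb(x, d=resampled):
                    return count_loglik(d, 10.0 ** x, zeros=zeros)
                xb, _ = _maximize(llb, bracket)
                boots.append(xb)
        if len(boots) >= 20:
            lo, hi = np.quantile(boots, [0.025, 0.975])
            interval = (min(10.0 ** lo, interval[0]), max(10.0 ** hi, interval[1]))
        else:
            diagnostics["warnings"].append(
                "too few informative bootstrap resamples; profile interval used"
            )
    thalf = neutral_median(10.0 ** x_hat, data.n_target, data.alpha1, data.lam1)
    if data.t < thalf + 2.0 / data.lam1:
        diagnostics["warnings"].append(
            "growth time is close to the median arrival time: the large-time "
            "amplitude law poorly describes the counts; prefer the p0 method"
        )
    x_hat = min(max(x_hat, math.log10(interval[0])), math.log10(interval[1]))
    return EstimateResult(nu=10.0 ** x_hat, ci=interval, method="counts",
                          loglik=ll_max, diagnostics=diagnostics)


def method_advisor(data: AssayData, zero_threshold: float = 0.10):
    """Recommend an estimator from the zero-replicate fraction.

    If more than ``zero_threshold`` of replicates lack resistance the p0
    method is preferred; if (almost) all replicates have mutants, the counts
    carry the information.  Returns ``(method, rationale)``.
    """
    fz = data.frac_zero
    if fz == 1.0:
        return "p0", (
            "all replicates lack resistance; the p0 method yields an upper "
            "bound on the mutation rate"
        )
    if fz > zero_threshold:
        return "p0", (
            f"{100 * fz:.0f}% of replicates lack resistance (> "
            f"{100 * zero_threshold:.0f}%); the zero fraction is informative"
        )
    return "counts", (
        f"only {100 * fz:.0f}% of replicates lack resistance; the zero count "
        "carries limited information, use the mutant counts"
    )
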