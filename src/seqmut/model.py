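"""Linear mutational paths and their deterministic bookkeeping.

A population starts from a single supercritical "type 1" cell.  Type ``n``
cells divide at rate ``alpha_n``, die at rate ``beta_n`` and mutate to type
``n+1`` at rate ``nu_n`` (the mutating cell is retained, so a mutation event
adds one type ``n+1`` cell without removing the parent).  At large times the
type ``n`` population behaves as ``Z_n(t) ~ V_n t^{r_n-1} exp(delta_n t)``
where ``delta_n`` is the running-max net growth rate over types ``1..n`` and
``r_n`` counts how often that maximum is attained.  This module computes all
deterministic quantities of that description: the fitness sequences
``lambda_n, delta_n, r_n``, the scale parameters ``omega_n`` of the
Mittag-Leffler amplitude ``V_n`` (three-case recursion), and the median
arrival times of the logistic arrival-time law, both by the direct formula
and by the incremental recursion.

Type indices are 1-based throughout the public API (type 1 is the founding
population); array storage is an internal detail.
"""

from __future__ import annotations

import json
import math
import tomllib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegimeError",
    "MutationPath",
    "FitnessProfile",
    "ArrivalLaw",
    "fitness_profile",
    "omega_recursion",
    "median_arrival",
    "median_recursion",
    "surviving_lineage_path",
    "compare_paths",
]


class RegimeError(ValueError):
    """The small-mutation-rate / large-time asymptotics are invalid here.

    Raised instead of returning NaN so callers (and the CLI) can report
    "asymptotics invalid for these rates" rather than silently propagating
    nonsense.
    """


@dataclass(frozen=True)
class MutationPath:
    """Per-type rate triples defining a linear evolutionary path.

    Parameters
    ----------
    alpha, beta, nu
        Division, death and mutation rates (1/time), one entry per type.
        ``nu`` may have one entry fewer than ``alpha``; the mutation rate of
        the final type is unused and stored as 0.
    labels
        Optional per-type names.
    """

    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    nu: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __init__(self, alpha, beta, nu, labels=None):
        alpha = tuple(float(a) for a in np.atleast_1d(alpha))
        beta = tuple(float(b) for b in np.atleast_1d(beta))
        nu = list(float(v) for v in np.atleast_1d(nu))
        n = len(alpha)
        if len(beta) != n:
            raise ValueError(f"alpha has {n} entries but beta has {len(beta)}")
        if len(nu) == n - 1:
            nu = nu + [0.0]
        if len(nu) != n:
            raise ValueError(f"alpha has {n} entries but nu has {len(nu)} (need {n} or {n-1})")
        if labels is not None:
            labels = tuple(str(s) for s in labels)
            if len(labels) != n:
                raise ValueError("labels length must match the number of types")
        if min(alpha) < 0 or min(beta) < 0 or min(nu) < 0:
            raise ValueError("all rates must be nonnegative")
        if not alpha[0] > beta[0]:
            raise ValueError(
                "type 1 must be supercritical (alpha_1 > beta_1); "
                f"got alpha_1={alpha[0]}, beta_1={beta[0]}"
            )
        for i in range(n - 1):
            if not nu[i] > 0:
                raise ValueError(
                    f"nu_{i + 1} must be positive, otherwise type {i + 2} is unreachable"
                )
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "nu", tuple(nu))
        object.__setattr__(self, "labels", labels)

    @property
    def n_types(self) -> int:
        return len(self.alpha)

    @property
    def lam(self) -> np.ndarray:
        """Net growth rates ``lambda_n = alpha_n - beta_n``."""
        return np.asarray(self.alpha) - np.asarray(self.beta)

    def rates_of(self, n: int) -> tuple[float, float, float]:
        """``(alpha_n, beta_n, nu_n)`` for 1-based type index ``n``."""
        if not 1 <= n <= self.n_types:
            raise IndexError(f"type index {n} outside 1..{self.n_types}")
        return self.alpha[n - 1], self.beta[n - 1], self.nu[n - 1]

    def label_of(self, n: int) -> str:
        if self.labels is not None:
            return self.labels[n - 1]
        return f"type {n}"

    def to_dict(self) -> dict:
        d = {"alpha": list(self.alpha), "beta": list(self.beta), "nu": list(self.nu)}
        if self.labels is not None:
            d["labels"] = list(self.labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MutationPath":
        return cls(d["alpha"], d["beta"], d["nu"], d.get("labels"))

    @classmethod
    def from_file(cls, filename) -> "MutationPath":
        """Read a parameter file (JSON or TOML with keys alpha, beta, nu)."""
        d = load_parameters(filename)
        return cls.from_dict(d)


def load_parameters(filename) -> dict:
    """Load a JSON or TOML parameter file into a dict (keys alpha/beta/nu,
    optional labels and tie_tol)."""
    name = str(filename)
    if name.endswith(".toml"):
        with open(name, "rb") as fh:
            d = tomllib.load(fh)
    else:
        with open(name) as fh:
            d = json.load(fh)
    missing = {"alpha", "beta", "nu"} - set(d)
    if missing:
        raise ValueError(f"parameter file {name} is missing keys: {sorted(missing)}")
    return d


@dataclass(frozen=True)
class ArrivalLaw:
    """Logistic law of the arrival time tau_n of the first type-``n`` cell.

    ``P(tau_n > t) ~ [1 + exp((t - median)/scale)]^{-1}`` with
    ``scale = 1/lambda_1``; location and scale fully determine the law, so
    the variance is always ``pi^2 scale^2 / 3`` regardless of ``n``.
    """

    n: int
    median: float
    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")


# case codes for the step from type n to n+1, comparing lambda_{n+1} to delta_n
CASE_DECREASE = "decrease"  # delta_n > lambda_{n+1}: stay below max fitness
CASE_EQUAL = "equal"        # delta_n = lambda_{n+1}: tie with max fitness
CASE_INCREASE = "increase"  # delta_n < lambda_{n+1}: new max fitness


@dataclass(frozen=True)
class FitnessProfile:
    """Derived fitness sequences for a :class:`MutationPath`.

    All arrays are indexed 0-based internally; accessors take 1-based type
    indices.  ``case[i]``, ``gamma[i]``, ``phi[i]``, ``kappa[i]`` describe
    the step from type ``i+1`` to type ``i+2``.
    """

    path: MutationPath
    lam: np.ndarray          # lambda_n
    delta: np.ndarray        # running-max fitness
    r: np.ndarray            # attainment counts
    case: tuple[str, ...]    # per-step classification (length N-1)
    gamma: np.ndarray        # delta_n / delta_{n+1}       (length N-1)
    phi: np.ndarray          # lambda_{n+1} / alpha_{n+1}  (length N-1)
    kappa: np.ndarray        # kappa_n per step            (length N-1)
    log_kappa: np.ndarray    # log kappa_n, for log-space recursions
    omega: np.ndarray        # amplitude scale parameters
    log_omega: np.ndarray
    tie_tol: float
    warn_steps: tuple[int, ...] = ()  # 1-based steps flagged mildly deleterious

    @property
    def n_types(self) -> int:
        return len(self.lam)

    def tail(self, n: int) -> float:
        """Mittag-Leffler tail parameter ``lambda_1/delta_n`` of ``V_n``."""
        return float(self.delta[0] / self.delta[n - 1])


def _classify(lam_next: float, delta_n: float, tie_tol: float) -> str:
    scale = max(abs(delta_n), abs(lam_next))
    if abs(lam_next - delta_n) <= tie_tol * scale:
        return CASE_EQUAL
    return CASE_INCREASE if lam_next > delta_n else CASE_DECREASE


def fitness_profile(
    path: MutationPath,
    tie_tol: float = 1e-9,
    warn_margin: float = 0.05,
    compute_omega: bool = True,
) -> FitnessProfile:
    """Compute the fitness bookkeeping for a path.

    Equality ``lambda_{n+1} = delta_n`` is decided with relative tolerance
    ``tie_tol`` because the limit laws change discontinuously across the
    three cases.  Steps with ``0 < delta_n - lambda_{n+1} < warn_margin * delta_n``
    are flagged (mildly deleterious mutations inflate the scale parameter and
    the approximation degrades there).

    Intermediate types may be subcritical or critical; only type 1 must be
    supercritical, which :class:`MutationPath` already enforces.
    """
    lam = path.lam.astype(float)
    if not lam[0] > 0:
        raise ValueError("supercriticality violation: lambda_1 must be positive")
    n_types = len(lam)

    delta = np.empty(n_types)
    r = np.empty(n_types, dtype=int)
    cases: list[str] = []
    warn_steps: list[int] = []
    delta[0], r[0] = lam[0], 1
    for i in range(n_types - 1):
        case = _classify(lam[i + 1], delta[i], tie_tol)
        cases.append(case)
        if case == CASE_INCREASE:
            delta[i + 1], r[i + 1] = lam[i + 1], 1
        elif case == CASE_EQUAL:
            delta[i + 1], r[i + 1] = delta[i], r[i] + 1
        else:
            delta[i + 1], r[i + 1] = delta[i], r[i]
            gap = delta[i] - lam[i + 1]
            if gap < warn_margin * delta[i]:
                warn_steps.append(i + 1)
                warnings.warn(
                    f"step {i + 1}->{i + 2} is mildly deleterious "
                    f"(0 < delta_{i + 1} - lambda_{i + 2} = {gap:.3g} < "
                    f"{warn_margin:.2g}*delta): the scale parameter is inflated and "
                    "the large-time approximation may be poor",
                    RuntimeWarning,
                    stacklevel=2,
                )

    gamma = delta[:-1] / delta[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(
            np.asarray(path.alpha[1:]) > 0,
            lam[1:] / np.asarray(path.alpha[1:]),
            np.nan,
        )

    kappa = np.empty(n_types - 1)
    log_kappa = np.empty(n_types - 1)
    for i, case in enumerate(cases):
        if case == CASE_DECREASE:
            kappa[i] = 1.0 / (delta[i] - lam[i + 1])
            log_kappa[i] = -math.log(delta[i] - lam[i + 1])
        elif case == CASE_EQUAL:
            kappa[i] = 1.0 / r[i]
            log_kappa[i] = -math.log(r[i])
        else:
            # kappa_n = phi^{1-gamma} lambda^{-r} gamma^{-(r-1)} pi/sin(pi gamma),
            # with gamma = delta_n/lambda_{n+1} in (0,1); equals the constant c_n
            # of the omega recursion.  Kept in log space: the omega recursion
            # raises it to the power lambda_{n+1}/delta_n which can overflow.
            g, p, l, ri = gamma[i], phi[i], lam[i + 1], r[i]
            if not 0.0 < g < 1.0:
                raise RegimeError(
                    f"step {i + 1}->{i + 2}: delta_n/lambda_(n+1)={g} must lie "
                    "strictly in (0,1) in the fitness-increase case"
                )
            log_kappa[i] = (
                (1.0 - g) * math.log(p)
                - ri * math.log(l)
                - (ri - 1) * math.log(g)
                + math.log(math.pi / math.sin(math.pi * g))
            )
            kappa[i] = math.exp(log_kappa[i])

    profile = FitnessProfile(
        path=path,
        lam=lam,
        delta=delta,
        r=r,
        case=tuple(cases),
        gamma=gamma,
        phi=phi,
        kappa=kappa,
        log_kappa=log_kappa,
        omega=np.full(n_types, np.nan),
        log_omega=np.full(n_types, np.nan),
        tie_tol=tie_tol,
        warn_steps=tuple(warn_steps),
    )
    if compute_omega:
        omega, log_omega = omega_recursion(profile, path)
        profile.omega[:] = omega
        profile.log_omega[:] = log_omega
    return profile


def omega_recursion(profile: FitnessProfile, path: MutationPath):
    """Scale parameters ``omega_n`` of the amplitude law, by the three-case
    recursion starting from ``omega_1 = alpha_1/lambda_1``.

    Returns ``(omega, log_omega)``; the recursion runs in log space because
    the fitness-increase branch raises its argument to ``lambda_{n+1}/delta_n``
    which can overflow for strong drivers.
    """
    n_types = profile.n_types
    log_omega = np.empty(n_types)
    log_omega[0] = math.log(path.alpha[0]) - math.log(profile.lam[0])
    for i, case in enumerate(profile.case):
        nu = path.nu[i]
        if case == CASE_DECREASE:
            log_omega[i + 1] = math.log(nu) - math.log(profile.delta[i] - profile.lam[i + 1]) + log_omega[i]
        elif case == CASE_EQUAL:
            log_omega[i + 1] = math.log(nu) - math.log(profile.r[i]) + log_omega[i]
        else:
            if nu >= 1.0:
                raise RegimeError(
                    f"step {i + 1}->{i + 2}: fitness-increase branch requires "
                    f"nu_{i + 1} < 1 (log(1/nu) > 0); got nu={nu}"
                )
            log_lognu = (profile.r[i] - 1) * math.log(math.log(1.0 / nu)) if profile.r[i] > 1 else 0.0
            log_omega[i + 1] = (profile.lam[i + 1] / profile.delta[i]) * (
                math.log(nu) + log_lognu + profile.log_kappa[i] + log_omega[i]
            )
    with np.errstate(over="ignore"):
        omega = np.exp(log_omega)
    return omega, log_omega


def median_arrival(profile: FitnessProfile, path: MutationPath, n: int) -> ArrivalLaw:
    """Logistic law of ``tau_n`` (first type-``n`` cell), by the direct median
    formula

        t_half = (1/delta) log( delta / (omega nu [log(1/nu)/delta]^{r-1}) )

    with ``delta, r, omega, nu`` of the seeding type ``n-1``, and scale
    ``1/lambda_1``.  Raises :class:`RegimeError` when the mutation rates are
    not small enough for the asymptotic law (non-positive median).
    """
    if not 2 <= n <= profile.n_types:
        raise IndexError(f"target type {n} must be in 2..{profile.n_types}")
    i = n - 2  # 0-based index of the seeding type n-1
    nu = path.nu[i]
    if nu >= 1.0:
        raise RegimeError(f"nu_{n - 1}={nu} >= 1: arrival asymptotics invalid")
    delta, r = profile.delta[i], profile.r[i]
    log_arg = (
        math.log(delta)
        - profile.log_omega[i]
        - math.log(nu)
        - (r - 1) * (math.log(math.log(1.0 / nu)) - math.log(delta))
    )
    median = log_arg / delta
    if median <= 0:
        raise RegimeError(
            f"median arrival time of type {n} is non-positive "
            f"({median:.3g}): mutation rates are not small enough for the "
            "asymptotic arrival law"
        )
    return ArrivalLaw(n=n, median=median, scale=1.0 / profile.lam[0])


def median_recursion(profile: FitnessProfile, path: MutationPath) -> np.ndarray:
    """Median arrival times for every type ``2..N`` by the incremental
    recursion (general multi-attainment form), independent of the direct
    formula in :func:`median_arrival`.

    Returns an array ``m`` with ``m[i]`` the median of ``tau_{i+2}``.
    """
    n_types = profile.n_types
    if n_types < 2:
        return np.empty(0)
    for nu in path.nu[: n_types - 1]:
        if nu >= 1.0:
            raise RegimeError(f"nu={nu} >= 1: arrival asymptotics invalid")
    medians = np.empty(n_types - 1)
    d1 = profile.delta[0]
    medians[0] = (2.0 * math.log(d1) - math.log(path.alpha[0]) - math.log(path.nu[0])) / d1
    # step from t_half^(n) to t_half^(n+1) for n = 2..N-1 (1-based types);
    # the branch compares lambda_n with delta_{n-1}, i.e. case index n-2.
    for n in range(2, n_types):
        i = n - 1        # 0-based index of type n
        prev = i - 1     # 0-based index of type n-1
        nu_n, nu_prev = path.nu[i], path.nu[prev]
        l_n, l_prev = math.log(1.0 / nu_n), math.log(1.0 / nu_prev)
        d_n, d_prev = profile.delta[i], profile.delta[prev]
        r_n, r_prev = profile.r[i], profile.r[prev]
        case = profile.case[prev]
        if case == CASE_DECREASE:
            inc = (
                math.log(d_n - profile.lam[i])
                - math.log(nu_n)
                + (r_n - 1) * (math.log(l_prev) - math.log(l_n))
            ) / d_n
        elif case == CASE_EQUAL:
            inc = (
                math.log(r_prev)
                + math.log(d_n)
                - math.log(nu_n)
                + (r_prev - 1) * math.log(l_prev)
                - (r_n - 1) * math.log(l_n)
            ) / d_n
        else:
            inc = (
                math.log(d_n) - math.log(nu_n) - (r_n - 1) * (math.log(l_n) - math.log(d_n))
            ) / d_n - (r_prev * math.log(d_prev) + profile.log_kappa[prev]) / d_prev
        medians[n - 1] = medians[n - 2] + inc
    for n, m in enumerate(medians, start=2):
        if m <= 0:
            raise RegimeError(
                f"median arrival time of type {n} is non-positive ({m:.3g}): "
                "mutation rates are not small enough for the asymptotic law"
            )
    return medians


def surviving_lineage_path(
    path: MutationPath,
    profile: FitnessProfile | None = None,
    steps: int | list[int] | None = None,
) -> MutationPath:
    """Adjust mutation rates so downstream arrival laws describe the first
    type-``n+1`` cell whose lineage survives forever.

    Replaces ``nu_n`` by ``nu_n * lambda_{n+1}/alpha_{n+1}`` (the survival
    probability factor of a type-``n+1`` lineage).  ``steps`` selects which
    1-based steps to adjust (default: all).  Requires ``lambda_{n+1} > 0``
    for every adjusted step: otherwise all type-``n+1`` lineages eventually
    go extinct and no surviving-lineage arrival time exists.
    """
    lam = path.lam
    n_steps = path.n_types - 1
    if steps is None:
        step_list = list(range(1, n_steps + 1))
    elif np.isscalar(steps):
        step_list = [int(steps)]
    else:
        step_list = [int(s) for s in steps]
    nu = list(path.nu)
    for s in step_list:
        if not 1 <= s <= n_steps:
            raise IndexError(f"step {s} outside 1..{n_steps}")
        if not lam[s] > 0:
            raise RegimeError(
                f"all lineages of type {s + 1} eventually go extinct "
                f"(lambda_{s + 1} = {lam[s]:.3g} <= 0); no surviving-lineage "
                "arrival time exists"
            )
        nu[s - 1] = nu[s - 1] * lam[s] / path.alpha[s]
    return MutationPath(path.alpha, path.beta, nu, path.labels)


def compare_paths(
    paths: list[MutationPath],
    n: int,
    tie_tol: float = 1e-9,
    labels: list[str] | None = None,
) -> list[dict]:
    """Rank linear paths by the median arrival time of their type ``n``.

    Returns a list of dicts (path index, label, median, rank) sorted by
    median; exact ties share a rank.  Regime errors from individual paths
    propagate.
    """
    if labels is None:
        labels = [f"path {i + 1}" for i in range(len(paths))]
    entries = []
    for i, p in enumerate(paths):
        prof = fitness_profile(p, tie_tol=tie_tol)
        law = median_arrival(prof, p, n)
        entries.append({"index": i, "label": labels[i], "median": law.median})
    entries.sort(key=lambda e: e["median"])
    rank = 0
    for j, e in enumerate(entries):
        if j > 0 and math.isclose(e["median"], entries[j - 1]["median"], rel_tol=1e-12):
            e["rank"] = entries[j - 1]["rank"]
        else:
            rank = j + 1
            e["rank"] = rank
    return entries
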