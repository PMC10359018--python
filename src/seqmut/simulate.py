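"""Stochastic simulation of the multitype branching process.

Three samplers with one contract:

* :func:`simulate_exact` — event-driven (Gillespie) simulation of the exact
  process: a type-``n`` cell waits an exponential time with parameter
  ``alpha_n + beta_n + nu_n`` and then divides, dies, or mutates.  A
  mutation *adds* one type-``n+1`` cell and keeps the parent.
* :func:`simulate_hybrid` — exact events while every type count is below a
  switch threshold, Poisson tau-leaping (Poisson births/mutations, binomial
  deaths) above it; needed because the limit-law regimes reach population
  sizes far beyond event-driven reach.
* :func:`sample_limit_model` — the approximate model: ``Z_1* = V_1 e^{l1 t}``
  with ``V_1`` exponential, each next type seeded by an inhomogeneous
  Poisson process with intensity ``nu_n V_n* t^{r_n-1} e^{delta_n t}``,
  clones growing by the closed-form single-cell birth-death law.

All samplers are bit-reproducible given a seed; replicate runs spawn
independent child streams from one ``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .fluctuation import AssayData
from .model import FitnessProfile, MutationPath

__all__ = [
    "Trajectory",
    "simulate_exact",
    "simulate_hybrid",
    "replicate_final_counts",
    "sample_limit_model",
    "simulate_assay",
]


@dataclass
class Trajectory:
    """One realisation: observation times, per-type counts and first-arrival
    times (``inf`` if a type never appeared)."""

    times: np.ndarray          # observation times (grid + arrival instants)
    counts: np.ndarray         # shape (n_types, len(times)), integers
    arrivals: np.ndarray       # tau_n per type; tau_1 = 0
    seed: object = None
    path: MutationPath | None = None
    mode: str = "exact"
    n_rejected: int = 0        # rejected type-1-extinct realisations

    def to_frame(self, replicate: int = 0):
        """Long-format table (replicate, time, type, count)."""
        import pandas as pd

        n_types, n_times = self.counts.shape
        return pd.DataFrame(
            {
                "replicate": replicate,
                "time": np.repeat(self.times, n_types),
                "type": np.tile(np.arange(1, n_types + 1), n_times),
                "count": self.counts.T.ravel(),
            }
        )


class EventBudgetError(RuntimeError):
    """Projected event count exceeds the budget; use the hybrid simulator."""


def _run_one(
    rng: np.random.Generator,
    alpha: np.ndarray,
    beta: np.ndarray,
    nu: np.ndarray,
    t_end: float,
    switch_threshold: float,
    tau_cap: float,
    grid: np.ndarray | None,
    stop_type: int | None,
    max_events: int,
):
    """Single realisation.  Returns (final_counts, arrivals, grid_counts,
    extra_times, extra_counts, type1_extinct)."""
    n_types = len(alpha)
    z = np.zeros(n_types, dtype=np.int64)
    z[0] = 1
    arrivals = np.full(n_types, np.inf)
    arrivals[0] = 0.0
    crate = alpha + beta + nu  # per-cell total event rate
    t = 0.0
    gi = 0
    grid_counts = None if grid is None else np.zeros((n_types, len(grid)), dtype=np.int64)
    extra_times: list[float] = []
    extra_counts: list[np.ndarray] = []
    extinct1 = False
    stop_idx = None if stop_type is None else stop_type - 1

    def fill_grid_list(up_to: float, state):
        nonlocal gi
        if grid_counts is None:
            return
        while gi < len(grid) and grid[gi] <= up_to:
            grid_counts[:, gi] = state
            gi += 1

    # ---- exact event-driven phase (pure-scalar inner loop) -------------
    events = 0
    uniform = rng.random
    exponential = rng.exponential
    zl = z.tolist()
    al, bl, cl = alpha.tolist(), beta.tolist(), crate.tolist()
    arr = arrivals.tolist()
    stopped = False
    while True:
        if stop_idx is not None and arr[stop_idx] < math.inf:
            stopped = True
            break
        if max(zl) >= switch_threshold:
            break
        total = 0.0
        for i in range(n_types):
            total += zl[i] * cl[i]
        if total == 0.0:
            break
        t_next = t + exponential() / total
        if t_next >= t_end:
            t = t_end
            break
        fill_grid_list(t_next, zl)
        t = t_next
        events += 1
        if events > max_events:
            raise EventBudgetError(
                f"exact simulation exceeded {max_events} events at t={t:.3g} "
                "(population too large); use simulate_hybrid"
            )
        u = uniform() * total
        i = 0
        acc = zl[0] * cl[0]
        while u > acc and i < n_types - 1:
            i += 1
            acc += zl[i] * cl[i]
        v = uniform() * cl[i]
        if v < al[i]:
            zl[i] += 1
        elif v < al[i] + bl[i]:
            zl[i] -= 1
            if i == 0 and zl[0] == 0:
                extinct1 = True
        else:
            # mutation: parent retained, one type-(i+1) cell added
            zl[i + 1] += 1
            if arr[i + 1] == math.inf:
                arr[i + 1] = t
                extra_times.append(t)
                extra_counts.append(np.asarray(zl, dtype=np.int64))
    z = np.asarray(zl, dtype=np.int64)
    arrivals = np.asarray(arr)

    # ---- leaping phase -------------------------------------------------
    # Mutation retains the parent, so each type evolves as a pure
    # birth-death process given its mutational inflow; the per-step
    # transition is therefore sampled EXACTLY from the closed-form
    # single-cell law (extinction + geometric, i.e. binomial survivors plus
    # a negative-binomial excess).  Mutants produced within a step are
    # Poisson with the exact integrated-population mean z (e^{l dt}-1)/l;
    # the step cap only limits the seeding/arrival time resolution.
    if t < t_end and not stopped and z.max() >= switch_threshold:
        dt0 = tau_cap / float(crate.max())

        def step_params(dt: float):
            lam = alpha - beta
            with np.errstate(divide="ignore", invalid="ignore"):
                elt = np.exp(lam * dt)
                den = alpha * elt - beta
                p0 = np.where(lam != 0.0, beta * (elt - 1.0) / den, 0.0)
                q = np.where(lam != 0.0, alpha * (elt - 1.0) / den, 0.0)
                integ = np.where(lam != 0.0, (elt - 1.0) / np.where(lam != 0, lam, 1.0), dt)
            crit = lam == 0.0
            if crit.any():
                adt = alpha[crit] * dt
                p0[crit] = adt / (1.0 + adt)
                q[crit] = p0[crit]
            return p0, np.clip(q, 0.0, 1.0 - 1e-15), integ

        p0_0, q_0, integ_0 = step_params(dt0)
        while t < t_end:
            dt = min(dt0, t_end - t)
            fill_grid_list(t + dt, z)
            p0_, q_, integ_ = (p0_0, q_0, integ_0) if dt == dt0 else step_params(dt)
            alive = rng.binomial(z, 1.0 - p0_)
            z_new = alive.copy()
            grow = (alive > 0) & (q_ > 0.0)
            for i in np.nonzero(grow)[0]:
                z_new[i] += rng.negative_binomial(alive[i], 1.0 - q_[i])
            muts = rng.poisson(nu * z * integ_)
            for i in np.nonzero(muts[:-1] > 0)[0]:
                m = int(muts[i])
                # clones seeded within the step grow (or die) over their
                # residual time; seeding times are ~uniform at this resolution
                tau_rem = dt * rng.random(m)
                z_new[i + 1] += _birth_death_sizes(
                    rng, alpha[i + 1], beta[i + 1], tau_rem
                ).sum()
                if not np.isfinite(arrivals[i + 1]):
                    arrivals[i + 1] = t + dt - float(tau_rem.max())
            t += dt
            newly = (z == 0) & (z_new > 0)
            if newly.any():
                for i in np.nonzero(newly)[0]:
                    if not np.isfinite(arrivals[i]):
                        arrivals[i] = t
                        extra_times.append(t)
                        extra_counts.append(z_new.copy())
            z = z_new
            if z[0] == 0:
                extinct1 = True
            if stop_idx is not None and np.isfinite(arrivals[stop_idx]):
                break
            if z.sum() == 0:
                break

    if grid_counts is not None:
        while gi < len(grid):
            grid_counts[:, gi] = z
            gi += 1
    return z, arrivals, grid_counts, extra_times, extra_counts, extinct1


def _simulate(
    path: MutationPath,
    t_end: float,
    seed,
    rng,
    condition_on_type1_survival: bool,
    record_grid,
    stop_at_type,
    switch_threshold: float,
    tau_cap: float,
    max_events: int,
    mode: str,
) -> Trajectory:
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    alpha = np.asarray(path.alpha, dtype=float)
    beta = np.asarray(path.beta, dtype=float)
    nu = np.asarray(path.nu, dtype=float).copy()
    nu[-1] = 0.0  # the final type's mutation rate is unused
    if record_grid is None or (np.isscalar(record_grid) and record_grid == 0):
        grid = None
    elif np.isscalar(record_grid):
        grid = np.linspace(0.0, t_end, int(record_grid))
    else:
        grid = np.asarray(record_grid, dtype=float)

    n_rejected = 0
    while True:
        z, arrivals, grid_counts, et, ec, extinct1 = _run_one(
            rng, alpha, beta, nu, t_end, switch_threshold, tau_cap, grid,
            stop_at_type, max_events,
        )
        if condition_on_type1_survival and extinct1:
            n_rejected += 1
            continue
        break

    if grid_counts is None:
        times = np.asarray(et)
        counts = (
            np.asarray(ec).T if ec else np.zeros((path.n_types, 0), dtype=np.int64)
        )
        if len(times) == 0:
            times = np.asarray([t_end])
            counts = z[:, None]
    else:
        times = np.concatenate([grid, np.asarray(et)])
        counts = np.concatenate(
            [grid_counts, np.asarray(ec).T if ec else np.zeros((path.n_types, 0), dtype=np.int64)],
            axis=1,
        )
        order = np.argsort(times, kind="stable")
        times, counts = times[order], counts[:, order]
    return Trajectory(
        times=times,
        counts=counts,
        arrivals=arrivals,
        seed=seed,
        path=path,
        mode=mode,
        n_rejected=n_rejected,
    )


def simulate_exact(
    path: MutationPath,
    t_end: float,
    seed=None,
    rng=None,
    condition_on_type1_survival: bool = False,
    record_grid=200,
    stop_at_type: int | None = None,
    max_events: int = 20_000_000,
) -> Trajectory:
    """Exact event-driven simulation up to ``t_end``.

    With ``condition_on_type1_survival`` realisations whose type-1 lineage
    dies out before ``t_end`` are rejected and redrawn (the rejection count
    is recorded); this approximates conditioning on eternal survival with a
    bias of order ``exp(-lambda_1 t_end)``.  ``stop_at_type`` ends the run as
    soon as that type first appears (for arrival-time studies).
    """
    return _simulate(
        path, t_end, seed, rng, condition_on_type1_survival, record_grid,
        stop_at_type, math.inf, 0.05, max_events, "exact",
    )


def simulate_hybrid(
    path: MutationPath,
    t_end: float,
    seed=None,
    rng=None,
    condition_on_type1_survival: bool = False,
    record_grid=200,
    stop_at_type: int | None = None,
    switch_threshold: float = 500,
    tau_cap: float = 0.05,
    max_events: int = 20_000_000,
) -> Trajectory:
    """Exact events while all counts are below ``switch_threshold``, then
    Poisson tau-leaping with steps capped so the expected per-type relative
    change per step is at most ``tau_cap``.  ``switch_threshold=inf``
    reduces to :func:`simulate_exact` path-for-path under the same seed.
    """
    if not switch_threshold >= 1:
        raise ValueError("switch_threshold must be >= 1")
    return _simulate(
        path, t_end, seed, rng, condition_on_type1_survival, record_grid,
        stop_at_type, switch_threshold, tau_cap, max_events, "hybrid",
    )


def replicate_final_counts(
    path: MutationPath,
    t_end: float,
    n_replicates: int,
    seed=None,
    mode: str = "hybrid",
    condition_on_type1_survival: bool = False,
    stop_at_type: int | None = None,
    switch_threshold: float = 500,
    tau_cap: float = 0.05,
    max_events: int = 20_000_000,
):
    """Run many replicates, recording only final counts and arrival times.

    Returns ``(counts, arrivals, n_rejected)`` with ``counts`` of shape
    ``(n_replicates, n_types)``.  Each replicate uses an independent child
    stream of ``seed``.
    """
    if mode not in ("exact", "hybrid"):
        raise ValueError("mode must be 'exact' or 'hybrid'")
    threshold = math.inf if mode == "exact" else switch_threshold
    alpha = np.asarray(path.alpha, dtype=float)
    beta = np.asarray(path.beta, dtype=float)
    nu = np.asarray(path.nu, dtype=float).copy()
    nu[-1] = 0.0
    counts = np.empty((n_replicates, path.n_types), dtype=np.int64)
    arrivals = np.empty((n_replicates, path.n_types))
    n_rejected = 0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for j, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        while True:
            z, arr, *_, extinct1 = _run_one(
                rng, alpha, beta, nu, t_end, threshold, tau_cap, None,
                stop_at_type, max_events,
            )
            if condition_on_type1_survival and extinct1:
                n_rejected += 1
                continue
            break
        counts[j] = z
        arrivals[j] = arr
    return counts, arrivals, n_rejected


# ---------------------------------------------------------------------------
# approximate (limit) model


def _birth_death_sizes(rng, alpha: float, beta: float, tau: np.ndarray) -> np.ndarray:
    """Sizes at elapsed times ``tau`` of independent single-cell birth-death
    clones: extinct with probability ``beta(e^{lt}-1)/(alpha e^{lt}-beta)``,
    otherwise geometric (standard birth-death closed form)."""
    lam = alpha - beta
    tau = np.asarray(tau, dtype=float)
    if lam != 0.0:
        elt = np.exp(np.minimum(lam * tau, 700.0))
        p0 = beta * (elt - 1.0) / (alpha * elt - beta)
        q = alpha * (elt - 1.0) / (alpha * elt - beta)
    else:
        p0 = alpha * tau / (1.0 + alpha * tau)
        q = p0
    q = np.clip(np.broadcast_to(q, tau.shape), 0.0, 1.0 - 1e-15)
    p0 = np.broadcast_to(p0, tau.shape)
    out = np.zeros(len(tau), dtype=np.int64)
    alive = rng.random(len(tau)) >= p0
    if alive.any():
        out[alive] = rng.geometric(1.0 - q[alive])
    return out


def _seed_times(rng, n: int, r: int, delta: float, t: float) -> np.ndarray:
    """Times from the inhomogeneous Poisson seeding density prop. to
    ``s^{r-1} e^{delta s}`` on [0, t]: closed-form inversion for the
    exponential part, thinning by ``(s/t)^{r-1}`` for the polynomial part."""
    out = np.empty(n)
    todo = np.arange(n)
    expm = math.expm1(delta * t) if delta * t < 600 else None
    while len(todo):
        q = rng.random(len(todo))
        if expm is not None:
            s = np.log1p(q * expm) / delta
        else:  # seeds concentrate at the end; exponential tilt dominates
            s = t + np.log(q) / delta
        if r > 1:
            accept = rng.random(len(todo)) < (np.maximum(s, 0.0) / t) ** (r - 1)
        else:
            accept = np.ones(len(todo), dtype=bool)
        out[todo[accept]] = s[accept]
        todo = todo[~accept]
    return out


def sample_limit_model(
    path: MutationPath,
    profile: FitnessProfile,
    n: int,
    t: float,
    n_samples: int,
    seed=None,
    rng=None,
) -> np.ndarray:
    """Samples of ``Z_n*(t)`` under the approximate model.

    ``V_1`` is exponential with mean ``alpha_1/lambda_1`` (the type-1
    amplitude conditioned on survival); each subsequent type is seeded by a
    Poisson process with intensity ``nu_k V_k* s^{r_k-1} e^{delta_k s}`` and
    its clones grow as independent birth-death processes.  Intermediate
    amplitudes are read off as ``V_k* = Z_k*(t) t^{-(r_k-1)} e^{-delta_k t}``.
    Returns floats for ``n = 1`` (the deterministic-growth amplitude times
    ``e^{lambda_1 t}``) and integer counts for ``n >= 2``.
    """
    if not 1 <= n <= path.n_types:
        raise IndexError(f"target type {n} outside 1..{path.n_types}")
    rng = np.random.default_rng(seed) if rng is None else rng
    lam1 = profile.lam[0]
    v = rng.exponential(scale=path.alpha[0] / lam1, size=n_samples)
    if n == 1:
        return v * math.exp(lam1 * t)
    z = None
    for k in range(1, n):
        i = k - 1
        delta, r, nu = float(profile.delta[i]), int(profile.r[i]), path.nu[i]
        # integral of s^{r-1} e^{delta s} over [0, t]
        integral, _ = quad(lambda s: s ** (r - 1) * math.exp(delta * s), 0.0, t,
                           limit=200)
        lam_total = nu * v * integral
        n_seeds = rng.poisson(lam_total)
        total = int(n_seeds.sum())
        owners = np.repeat(np.arange(n_samples), n_seeds)
        times = _seed_times(rng, total, r, delta, t)
        sizes = _birth_death_sizes(rng, path.alpha[k], path.beta[k], t - times)
        z = np.bincount(owners, weights=sizes, minlength=n_samples).astype(np.int64)
        if k + 1 < n:
            d_next, r_next = float(profile.delta[k]), int(profile.r[k])
            v = z * math.exp(-d_next * t) * t ** (-(r_next - 1))
    return z


def simulate_assay(
    path: MutationPath,
    t_growth: float,
    n_target: int,
    n_replicates: int,
    seed=None,
    mode: str = "hybrid",
    switch_threshold: float = 500,
    tau_cap: float = 0.05,
) -> AssayData:
    """Simulate a fluctuation assay: grow each replicate from one type-1
    cell for ``t_growth``, then record the number of target-type (resistant)
    cells.  ``n_target = k + 1`` when ``k`` mutations confer resistance."""
    counts, _, _ = replicate_final_counts(
        path, t_growth, n_replicates, seed=seed, mode=mode,
        switch_threshold=switch_threshold, tau_cap=tau_cap,
    )
    return AssayData(
        counts=counts[:, n_target - 1],
        t=t_growth,
        n_target=n_target,
        alpha1=path.alpha[0],
        lam1=float(path.lam[0]),
    )
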