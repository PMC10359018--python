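# Methods

## Model

A continuous-time multitype branching process on a linear path of types
1 → 2 → … → N.  Every cell acts independently; a type-*n* cell waits an
exponential time with parameter α<sub>n</sub> + β<sub>n</sub> + ν<sub>n</sub>
and then divides ((n) → (n),(n)), dies ((n) → ∅), or mutates
((n) → (n),(n+1)) with probabilities proportional to the rates.  Two
modelling choices matter and are enforced throughout:

* **mutation retains the parent** — a mutation event adds one type-(n+1)
  cell and leaves the type-*n* count unchanged.  This is asserted in the
  simulator tests because it is the single most likely mis-implementation,
  and it is also what makes each type a pure birth-death process given its
  mutational inflow (exploited by the hybrid simulator below);
* **the founder type is supercritical and conditioned on survival**
  (α₁ > β₁, Z₁(t) > 0).  Intermediate types may be subcritical, critical,
  or supercritical without restriction.

Derived sequences: λ<sub>n</sub> = α<sub>n</sub> − β<sub>n</sub>,
δ<sub>n</sub> = max<sub>i≤n</sub> λ<sub>i</sub>,
r<sub>n</sub> = #{i ≤ n : λ<sub>i</sub> = δ<sub>n</sub>}.

## Limit laws

For large t (and, wherever the running-max fitness increases, small
mutation rates):

* Z<sub>n</sub>(t) ≈ V<sub>n</sub> t<sup>r<sub>n</sub>−1</sup>e<sup>δ<sub>n</sub>t</sup>
  with V<sub>n</sub> Mittag-Leffler: E e<sup>−θV<sub>n</sub></sup> =
  (1 + (ω<sub>n</sub>θ)<sup>γ</sup>)<sup>−1</sup>, γ = λ₁/δ<sub>n</sub> ∈ (0,1].
  The scale recursion starts at ω₁ = α₁/λ₁ and per step multiplies by
  ν<sub>n</sub>/(δ<sub>n</sub>−λ<sub>n+1</sub>) (deleterious step),
  ν<sub>n</sub>/r<sub>n</sub> (neutral step), or applies
  ω<sub>n+1</sub> = [ν<sub>n</sub>(log ν<sub>n</sub><sup>−1</sup>)<sup>r<sub>n</sub>−1</sup> κ<sub>n</sub> ω<sub>n</sub>]<sup>λ<sub>n+1</sub>/δ<sub>n</sub></sup>
  (fitness-increasing step), with
  κ<sub>n</sub> = φ<sub>n+1</sub><sup>1−γ<sub>n</sub></sup> λ<sub>n+1</sub><sup>−r<sub>n</sub></sup> γ<sub>n</sub><sup>−(r<sub>n</sub>−1)</sup> π/sin(πγ<sub>n</sub>),
  γ<sub>n</sub> = δ<sub>n</sub>/λ<sub>n+1</sub>, φ<sub>n+1</sub> = λ<sub>n+1</sub>/α<sub>n+1</sub>.
* τ<sub>n+1</sub> is logistic with scale 1/λ₁ and median
  t<sub>½</sub><sup>(n+1)</sup> = δ<sub>n</sub><sup>−1</sup> log{ δ<sub>n</sub> / (ω<sub>n</sub>ν<sub>n</sub>[δ<sub>n</sub><sup>−1</sup>log ν<sub>n</sub><sup>−1</sup>]<sup>r<sub>n</sub>−1</sup>) }.
  An equivalent incremental recursion (three cases mirroring the ω
  recursion) is implemented independently; the two routes agreeing to 1e-9
  relative across randomized parameter sets is a standing test.
* Replacing ν<sub>n</sub> by ν<sub>n</sub>λ<sub>n+1</sub>/α<sub>n+1</sub>
  converts the arrival law of the first type-(n+1) cell into that of the
  first type-(n+1) cell with a surviving lineage (requires λ<sub>n+1</sub> > 0).

**Case classification and tolerances.**  The three branches are
discontinuous in λ<sub>n+1</sub> − δ<sub>n</sub>, so ties are decided with a
relative tolerance `tie_tol` (default 1e-9).  Mildly deleterious steps
(0 < δ<sub>n</sub> − λ<sub>n+1</sub> < 0.05 δ<sub>n</sub> by default) inflate
ω and trigger a warning — the asymptotics converge slowly there.  The ω
recursion runs in log space because the fitness-increase branch raises its
argument to λ<sub>n+1</sub>/δ<sub>n</sub>, which overflows for strong
drivers.  Regime violations (ν ≥ 1 where log ν⁻¹ is needed, non-positive
medians) raise `RegimeError` rather than returning NaN, so callers can
report "asymptotics invalid for these rates".

**Ordered-limit caveat.**  The fitness-increase branch of the median
recursion privileges the final mutation rate inside a log(ν⁻¹) factor; this
is an artefact of taking the small-rate limits in reverse type order.
Alternative limit orderings could change log-log corrections; at the
parameter scales exercised here the effect is below the Monte-Carlo
resolution of the validation suite.

## Special functions

* **Mittag-Leffler function** E<sub>a,b</sub>(z), real z, 0 < a ≤ 1:
  power series for z ≥ −2 (and all z ≥ 0), a real integral representation
  (kernel r<sup>(1−b)/a</sup>e<sup>−r<sup>1/a</sup></sup> against a rational
  factor) for −200 < z < −2, and the algebraic expansion
  −Σ z<sup>−k</sup>/Γ(b−ak) truncated at its smallest term beyond.
  Crossovers were set by error balancing; accuracy is ≲1e-10 relative on the
  negative axis (tested against two independent high-precision oracles:
  arbitrary-precision series summation and a Stieltjes mixture-kernel
  quadrature).  b > 1 is reduced into b ≤ 1 by the standard recurrence.
* **Lerch transcendent** Φ(z,s,a), z ≤ 0, integer s ≥ 1, a ∈ (0,1):
  direct series for |z| ≤ 0.5, otherwise the integral representation
  (1/Γ(s))∫t<sup>s−1</sup>e<sup>−at</sup>/(1−ze<sup>−t</sup>)dt, split at
  t = log(−z) where the integrand changes character.  Accuracy ≲1e-8
  relative out to z = −1e8.  The z → −∞ asymptote
  π/sin(πa)·(−z)<sup>−a</sup>(log −z)<sup>s−1</sup>/(s−1)! is exposed only
  as a validation target, not used in evaluation.

**Amplitude sampling** uses the exact product representation
V = ω·Exp(1)<sup>1/γ</sup>·S<sub>γ</sub> with the one-sided stable variate
from the Chambers–Mallows–Stuck/Kanter trigonometric construction — chosen
over inverse-CDF interpolation because it is exact and O(1) per draw.
Moment queries on heavy-tailed laws (γ < 1) raise an explanatory error
instead of returning infinity silently.

**Pre-limit amplitude transform.**  The finite-ν Laplace transform of
V<sub>n</sub>* is the composition of per-step maps h₁∘…∘h<sub>n−1</sub>
applied to the exponential transform of V₁ (h<sub>n−1</sub> innermost);
the fitness-increase map involves Φ.  Its CDF is recovered by
Gaver–Stehfest inversion (default 18 terms, weights in exact rational
arithmetic).  Gaver–Stehfest was chosen over contour methods because it
samples the transform only at real positive points — the package
deliberately implements the special functions on the real domains the model
needs — at the cost of float64-limited accuracy (~1e-6 centrally, worse in
far tails).  Convergence is estimated by comparing consecutive term counts
and non-convergence raises with diagnostics.

## Simulators

* **Exact (Gillespie)**: per-event sampling of the next reaction among all
  types; bit-reproducible given a seed; an event budget raises a pointed
  error suggesting the hybrid simulator.  "Survives forever" conditioning
  is approximated by rejecting realisations whose type-1 lineage dies
  before the horizon; the residual bias is O(e<sup>−λ₁t</sup>).
* **Hybrid**: exact events while all counts are below a switch threshold
  (default 500), then leaping with a fixed step
  dt = tau_cap/max(α+β+ν) (default cap 0.05).  Because mutation retains
  the parent, each type's birth-death update over a step has a closed-form
  exact transition — binomial survivors (extinction probability
  β(e<sup>λdt</sup>−1)/(αe<sup>λdt</sup>−β)) plus a negative-binomial
  excess from the geometric offspring law — so the leap introduces **no**
  discretisation bias in the counts; an Euler-style Poisson-birth/binomial-
  death update was rejected because its per-step compounding error
  (O((λdt)²) per step) accumulated to ~10% over the validation horizons.
  Mutant seeding per step is Poisson with the exact integrated-population
  mean z(e<sup>λdt</sup>−1)/λ, and within-step clones grow over their
  residual time; the step cap therefore only limits seeding/arrival
  resolution.  Two residual approximations remain: inflow uses the
  conditional mean of ∫z ds (ignoring its within-step fluctuation — a
  Jensen-type effect on P(no mutant) that is negligible once the zero/
  nonzero decision happens in the exact phase, i.e. for thresholds ≳500),
  and arrival times are resolved to one step.
* **Limit model**: V₁ ~ Exp(mean α₁/λ₁); each next type seeded by an
  inhomogeneous Poisson process with intensity
  ν<sub>n</sub>V<sub>n</sub>*t<sup>r<sub>n</sub>−1</sup>e<sup>δ<sub>n</sub>t</sup>
  (closed-form inversion of the exponential tilt, thinning for the
  polynomial factor) and clone sizes from the closed-form birth-death law;
  intermediate amplitudes are read off as the scaled counts at the
  observation time.  Agreement of this sampler with the hybrid simulator
  for n > 2 at small ν is hypothesised but not proven in general; the
  cross-simulator tests treat disagreement beyond tolerance as a finding.

## Fluctuation-assay inference

The assay model is the neutral path (all λ equal, single rate ν) with
α₁ and λ₁ measured externally (growth-curve assays); they are required
inputs and never co-estimated.  *k* mutations conferring resistance means
the resistant type is n = k+1 — the off-by-one against "number of
mutations" is stated everywhere it can bite.  Closed neutral forms:
ω<sub>n</sub> = (α₁/λ₁)ν<sup>n−1</sup>/(n−1)! and
t<sub>½</sub><sup>(n)</sup> = λ₁<sup>−1</sup> log{λ₁²(n−2)! / (α₁[λ₁<sup>−1</sup>log ν<sup>−1</sup>]<sup>n−2</sup>ν<sup>n−1</sup>)}.

* **p0 method**: the zero-replicate count is Binomial(k, P(τ<sub>n</sub> > t))
  with the logistic no-arrival probability; MLE over log₁₀ν on [−8, −0.5]
  and a profile-likelihood 95% interval (drop 1.92).  Degenerate data give
  one-sided bounds: all-zero ⇒ upper bound on ν; no zeros ⇒ lower bound,
  flagged "p0 uninformative".
* **Count method**: positive counts exponential with mean
  ω<sub>n</sub>(ν)t<sup>n−1</sup>e<sup>λ₁t</sup>; zero counts contribute the
  logistic no-arrival mass (a mixture — the choice is configurable;
  `zeros="condition"` conditions on positivity instead, which also yields
  the clean closed-form stationarity "fitted mean = sample mean").
  The default interval is a **nonparametric bootstrap over replicates**
  (percentile, 199 resamples, union with the profile interval): the
  exponential amplitude law is a large-time approximation and real counts
  are heavier tailed, so the curvature-based profile interval understates
  the estimator's sampling variability (measured coverage ~67% where ~95%
  is nominal); the bootstrap restores ~90–95% coverage in the method's
  valid regime while leaving the documented failure regime
  (t ≈ t<sub>½</sub>) clearly non-covering.  `ci="profile"` restores the
  pure likelihood interval.
* **Advisor**: p0 when more than 10% of replicates lack resistance
  (configurable), counts otherwise; all-zero data route to the p0 upper
  bound.

## Synthetic data and what passing tests show

All validation data are generated by the package's own simulators at the
regimes the theory targets: two-type amplitude regimes with tail parameters
0.25/0.5/1.0 (observation times 5/7/12, rates as in the worked examples), a
down-up fitness path for arrival times (ν = 0.01), and neutral no-death
assays (α = 1, t = 10, 100 replicates, ν between 10⁻³ and 10⁻¹·⁵).
Replicate counts (1000–2000 for distributional KS tests, 60 assays per
inference setting, 2000 replicates for the scaled-amplitude mean) were
chosen so Monte-Carlo error sits comfortably below the asserted tolerances
on a single CPU.  The generator emulates the branching-process model
exactly; it does **not** emulate real-laboratory complications — plating
efficiency, phenotypic lag, cell-sorting noise, density dependence, or
non-linear genotype graphs — so passing tests certify the mathematics and
the implementation, not robustness of inference on wet-lab data.

## Known limitations

* All limit laws assume small mutation rates wherever the running-max
  fitness increases; at ν = 0.01 the fitness-increase ω carries visible
  O(1/log ν⁻¹) corrections (the arrival-law KS tests absorb a ~0.3-time-
  unit median shift, and exceedance probabilities for types past an
  increase step are accurate only deeper into the asymptotic regime).
* Mildly deleterious steps (small δ−λ gap) have inflated scales and slow
  convergence; the profile warns but does not refuse.
* The finite-ν amplitude distribution where δ<sub>n</sub> < λ<sub>n+1</sub>
  is validated only against its own small-ν limit (no independent
  characterisation is available); Gaver–Stehfest accuracy there is the
  float64 bound above.
* The inference module implements the neutral estimator only; unequal
  growth rates flow through the general machinery (`model`,
  `distributions`) but not through `fluctuation`.
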