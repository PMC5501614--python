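# Methods

## The models

Participation in a short-lived online behaviour ("fad") is modelled with
four compartments: susceptible S, new participants I, continuing
participants J, and removed R, in a closed population rescaled to N = 1.
New participants attract more attention than continuing ones, and the
I → J transition (constant rate ε, per week) is what makes the fad-free
state unstable enough to produce the rise-and-collapse shapes seen in
search-interest data.  No one returns to susceptibility.

**Complex (threshold) contagion.**  Each susceptible canvasses C contacts
drawn uniformly with replacement.  Adoption fires when at least τ_i of them
are new participants, or fewer than τ_i are new but at least τ_j are
continuing.  With contact categories (I, J, other) the per-canvass adoption
probability is a two-part trinomial tail; quitting fires when at least τ_r
of a continuing participant's contacts are also continuing (a binomial
tail).  The ODE system is

    dS/dt = −f(I,J)·S
    dI/dt =  f(I,J)·S − ε·I
    dJ/dt =  ε·I − g₂(J)·J
    dR/dt =  g₂(J)·J

with f = β·P(adoption canvass fires) and g₂ = P(quit canvass fires).
The per-capita −ε·I form follows from the underlying event rates (each of
the I individuals leaves at rate ε); R is carried explicitly so that
conservation is assertable.  C is fixed at 10 throughout fitting — it is
not identifiable from aggregate curves, only the (β, τ) combination is.
In the regime C = τ_i = 2 the early growth obeys dI/dt ≈ I², i.e. the
finite-time blow-up curve 1/(1−t): super-exponential takeoff is the
signature that separates this mechanism from mass action.

**Simple (mass-action) contagion.**  Force of adoption β_i·I + β_j·J,
constant quit rate γ; early growth is exponential.

**Stochastic version.**  The same rates drive a continuous-time Markov
chain on integer counts, simulated exactly with the direct method (sample
an exponential waiting time from the total rate, pick the event
proportionally).  Rates use compartment fractions I/N, J/N with the
rescaled parameters, so the fraction-space ODE is the large-N limit with
identical parameter values; the ensemble mean converges with error
O(N^{−1/2}), which the convergence study verifies by regression.

## Observation model

Weekly search-interest values y_t (percent of peak, 0–100) are modelled as

    y_t ~ Gamma(mean = A·μ(t + Δt), shape = r),    μ = I + J,

independent across weeks (mean–shape parameterisation: shape r, scale
m/r).  A carries the population/measurement scale (this is what lets N be
rescaled to 1), Δt aligns model time with calendar time (larger Δt moves
the curve left), and r sets the noise level.  Zero weeks are treated as
**left-censored at 0.5**: the data source rounds sub-unit volumes down to
zero, so a zero means Y < 0.5 and contributes log P(Y ≤ 0.5) to the
likelihood.  Replacing zeros with a small positive constant instead turns
every quiet pre-onset week into a catastrophic outlier (thousands of
log-units at r = 200 against a model mean of ~0.015) and drags every fit
away from the generating parameters; censoring is also exactly the
sampling dual of the generator's integer rounding.  Model means are
floored at 10⁻⁶·A to keep the density finite before fad onset.

## Fitting

Continuous parameters are maximised in transformed coordinates (log for
positive parameters, raw for Δt).  The workhorse is L-BFGS-B driven by a
fully compiled objective that returns the value and a forward-difference
gradient in one call; a Powell pass finishes the incumbent, since the
direction-set method handles the final descent along curved valley floors
that stall gradient steps.  (Powell alone needs many thousands of
evaluations to cross these valleys, which at grid scale systematically
misranks threshold cells.)  Rates above 50/week are rejected outright —
weekly data cannot identify them and the corresponding stiff solves would
dominate runtime.  Restart points draw rates and I0 from a scrambled Sobol
sequence over the log-box (rates 0.1–10/week, I0 10⁻⁶–10⁻²), then set
(A, Δt) by aligning the drawn model's peak with the data peak; a
deterministic moderate start (all rates 1/week) is always included.

The integer thresholds of the complex model are handled by an exhaustive
grid walked with a continuation scheme so that cells are compared at equal
optimisation effort: (1) a full multistart fit in a central anchor cell;
(2) a sweep of every cell from the anchor optimum plus fresh aligned
starts, each run to a coarse convergence tolerance (early-exit ftol) so
cheap cells stop early while promising ones descend fully; (3) polish of
the leading cells; (4) integer coordinate descent to neighbouring cells
from the incumbent, catching corner cells the sweep underestimated.
Cells trailing the incumbent by more than 50 log-units are pruned.  The
default grid is the full {1..C}³; the validation studies restrict it to
{1..4}³, matching the range the synthetic generator draws from.

Two-population fits (for two-peak series) share the threshold triple and
the Gamma shape r across sub-populations and fit everything else
independently: k = 15 free parameters for the mass-action pair, 14 for the
threshold pair, against 8 and 9 for single populations.  A series is
flagged two-peaked when, after 3-point moving-average smoothing, two local
maxima above 20% of the peak are separated by a trough below 50% of the
smaller one.

Model comparison uses AIC = 2k − 2 ln L*, graded on ΔAIC = AIC_simple −
AIC_complex: ≥10 very strong (***), ≥6 strong (**), ≥2 positive (*),
within ±2 no significant evidence (.), ≤−2 strong evidence against (−).
The boundaries are configurable.

## Forecasting

A fitted fad can forecast a new one that plausibly spreads by the same
mechanism: the dynamical parameters (rates and thresholds) transfer frozen,
and only (A, Δt, I0, r) are refit on the target's early weeks — the
population scale, calendar alignment, seeding and noise level are
properties of the new fad, the dynamics are the transferred hypothesis.
The prediction band is the central 95% interval of the Gamma observation
law at each week, with one correction to the naive plug-in: the maximised
shape r-hat understates residual spread when only a dozen early weeks
constrain four free nuisances, so the band uses the degrees-of-freedom-
corrected shape r-hat·(T−p)/T (p = 4), the Gamma analogue of dividing by
n−p rather than n when estimating a variance.  The mean stays at the
maximum-likelihood value and no posterior parameter uncertainty is
propagated.  Peak reporting gives the argmax week of the mean and the
full width at half maximum in weeks.

## Synthetic data

The generator is the likelihood's sampling dual: solve the ODE, form the
weekly means A·μ(t+Δt), draw independent Gamma observations, rescale so
the realised maximum is 100, and round to integers (values below 0.5
become the zero weeks real exports contain).  Rescaling by the realised
maximum multiplies every amplitude by one common random factor — exactly
what percent-of-peak quoting does to real data — and leaves the shape r
untouched.  The benchmark suite draws rates log-uniformly from 0.1–10 per
week, thresholds from {1..4}, I0 from 10⁻⁵–10⁻³, r from {20, 50, 200},
makes a fraction of series two-population, and redraws until a series is
"fad-like": more than 15 non-zero weeks (the corpus inclusion rule), an
interior peak, and a rise of at least 5× over the first week.  What the
generator does **not** emulate: search-term contamination (unrelated
queries sharing the fad's phrase), trend seasonality, and the week-to-week
correlation of sampling noise in real exports — so passing recovery
studies demonstrate correctness of the machinery under the model's own
assumptions, not robustness to those artefacts.

## Validation studies and their conditions

All studies live in `fadspread.studies`, seeded end to end; the analysis
drivers, the test suite and `scripts/acceptance.py` call the same code.

* **Threshold oracle** — closed-form tails (regularized incomplete beta
  route) against brute-force trinomial/binomial enumeration for every
  C ≤ 10 and threshold combination; agreement to 10⁻¹².
* **Early-growth limits** — the integrated models against 1/(1−t) and e^t
  in the corresponding regimes on t ∈ [0, 0.9], N = 10⁷.
* **Stochastic–ODE convergence** — ensembles at N = 10², 10³, 10⁴, 10⁵
  (200/200/200/100 runs; the high-N ensembles are floor-limited by
  Monte-Carlo error of the ensemble mean, which the run counts keep below
  the signal), supremum distance to the ODE, log–log slope vs. the
  theoretical −1/2.
* **Parameter recovery** — 20 replicates per mechanism at r = 200, T = 40,
  unquantized (the study isolates recovery under the Gamma noise model;
  integer rounding is a separate artefact, handled by censoring when
  present).  Study parameters: threshold model β = 4, τ = (2,2,2),
  ε = 0.5, I0 = 10⁻³ — chosen so the takeoff spans several weekly samples,
  which is what identifies the threshold; mass action β_i = 1.0,
  β_j = 0.3, γ = 0.25, ε = 0.4, I0 = 10⁻³.
* **Mechanism selection** — 50 labelled series per mechanism at r = 50,
  scored by the sign of ΔAIC.
* **Forecast coverage** — 50 replicates; dynamics transferred at the
  generating values, nuisances refit on the first 12 weeks, held-out weeks
  13–40 scored against the 95% band (zero weeks at their censoring value).
* **Nesting / AIC identities** — a two-peak series, one- vs two-population
  fits, and exact recomputation of AIC from (k, ln L*).

## Known limitations

* **Identifiability of the mass-action rates.**  A single 40-week
  rise-and-fall curve with free (A, Δt, I0, r) supports only part of the
  parameter vector.  At the study truth the Cramér–Rao bound gives
  asymptotic relative standard deviations ≈ 0.17 for γ but ≈ 0.7 for ε
  and ≈ 1.0 for β_i + β_j: the ε-direction is a profile-likelihood ridge
  (20-fold changes in ε cost under 3 log-units), because the I/J split is
  visible only through the curvature its delay induces.  No estimator can
  recover those two to 20% under these conditions; the recovery study
  reports their medians honestly, and they fail that bar.  The threshold
  model is better pinned: its τ grid and the super-exponential takeoff
  identify β, ε and τ_i well (τ_i recovery ≈ 95%).
* **Equivocal mechanism draws.**  Roughly one in ten threshold-model
  parameter draws from the suite ranges produces a slow, low-threshold fad
  whose realised curve mass action explains equally well; AIC then
  (correctly) refuses to prefer the generating mechanism, which caps the
  achievable mechanism-recovery rate slightly above 0.9 on the
  complex-generated side.
* The multimodality detector is a heuristic; both one- and two-population
  fits remain available on demand regardless of the flag.
* The plug-in prediction band ignores parameter uncertainty; with very few
  early weeks the refit shape r is itself noisy, and coverage is validated
  only on self-generated data.
* Fixed C = 10 is a convention, not an estimate.

## Numerical choices

The public ODE route is scipy's adaptive RK45 with dense output at
relative tolerance 10⁻⁸.  Inside the optimiser, a compiled (numba)
Cash–Karp RK45 with the same error-control logic lands exactly on a
0.25-week output grid (0.5-week in the lighter selection configuration) at
rtol 10⁻⁶ — far below observation noise — while the public compiled route
uses 10⁻⁷; weekly means are read off by linear interpolation, and tests
assert the compiled and scipy routes agree to better than 10⁻⁵ in μ.  The
censored-Gamma objective, including a compiled regularized incomplete
gamma, lives entirely in the kernel so one optimiser step costs seven
solves and no Python.  Event-driven
simulation preallocates 3N + 2 records (each individual makes at most
three moves) and refuses N > 10⁷.  Model times before 0 (possible when
Δt < 0) clamp to the initial state.  Negative compartment values from
round-off are clamped to zero before forming μ.
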