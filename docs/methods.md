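# Methods

## Model and assumptions

The simulator implements a well-mixed compartment model of targeted
radionuclide therapy of a disseminated blood cancer. Its assumptions, in
brief: one-step radionuclide decay (adequate for ^225^Ac, whose daughters
are short-lived); irreversible antibody–receptor binding (high-affinity,
rapidly internalizing antibodies); plasma and marrow as one well-mixed
volume; a homogeneous cancer-cell population with constant proliferation
rate, equal radiosensitivity, and equal receptor numbers; irreparable
damage at a rate proportional to dose rate (α-particle double-strand
breaks); degradation of antibodies on cell death with release of
radioactive fragments that clear faster than intact antibodies; toxicity
attributed only to decays of nuclides not anchored to cancer cells; no
pharmacologic effect of the antibody itself; identical kinetics for active
and inert antibodies; no binding to normal cells.

Units are chosen so the parameter table applies verbatim: days, ml, pmol,
nM, cell counts in 10⁷-cell units. Hence the cure threshold 0.01 cell is
N_cur = 1e-9 and the lethal burden 10¹¹ cells is C_d = 1e4. The lethal
blood-decay amount A_bl_cr = 0.0175 pmol is the activity equivalent of
≈230 nCi of ^225^Ac via n·N_A·(λ/86400)/37; the same single conversion
constant is used everywhere activities appear.

## Numerical treatment

* **Injections as jumps.** The system is integrated piecewise between
  injection times (LSODA, default rtol 1e-8 / atol 1e-12) and plasma
  concentrations jump at each bolus; δ-functions never enter the vector
  field. Injections closer than 1e-6 day to each other or to the interval
  ends are merged — they are physically simultaneous, and micro-segments
  stall step-size selection.
* **D→0 singularity.** The damaged-cell receptor-fraction equations contain
  a damage-transfer term ∝ RD·N/D. The integrator evolves the absolute
  receptor amounts FD = D·f_FD and AD = D·f_AD, whose equations are
  regular at D = 0; fractions are recovered by division when D > 1e-12 and
  reported as the fresh-damage limit (f_FD = f_FN, f_AD = f_AN) below it.
* **Events.** Crossings of C_d (death; on total burden N+D), of A_bl_cr
  (toxicity) and of an eradication floor (N < 1e-3·N_cur, at which point
  the cure outcome is decided and further integration of a vanishing N is
  pointless) are located by the solver's event machinery. Toxicity is a
  death cause only if the crossing precedes the cancer death — the animal
  dies *when* the lethal decay amount is reached, so decays accumulated
  after a cancer death do not count.
* **Viable-cell minimum.** N_min is tracked on a dense output grid
  (default 20 points/day) and refined by bounded scalar minimization on
  the solver's dense output around the grid argmin. Cure is declared when
  N_min < N_cur even if N later regrows (continuum regrowth from below
  one cell is an artifact; cured mice are censored alive in trials).
* **Conservation check.** With clearance rates off, the total undecayed
  nuclide amount aV + pV + γ(f_AN·N + f_AD·D) decays exactly at λ; the
  test suite verifies drift < 1e-6 relative over 30 days.
* Population-scale loops (trials, MTD search) use relaxed solver settings
  (rtol 1e-6, atol 1e-10, coarse grids, no minimum refinement): endpoint
  times and cure flags need far less resolution than trajectory studies.
  The ODE right-hand side is JIT-compiled with numba when available, with
  an identical pure-NumPy fallback.

## Closed-form estimates

For a pure bolus A small against the receptor pool, binding completes
within hours and the minimal surviving fraction N_m/N0 admits closed
forms in x = αA/(νN0) and r = ρ/λ:

* self-damage only (k_s=1): [(x/r)^r · e^(r−x)]^(1/(1+r)),
* cross-fire only (k_s=0): (x/r)^r · e^(2r−x).

Both tend to the classical instantaneous-irradiation survival e^(−x) as
ρ→0. Solving each for N_m = N_cur at the reference parameters gives 269.7
and 75.9 radioconjugates per initial cell, matching the ODE bisection
values (271.6 and 76.0) to ~1%. The agreement with the ODE is tested at
doses yielding deep kill (surviving fractions ~1e-4–1e-11); it degrades
below ~1e-3 pmol where a non-negligible share of nuclides decays before
anchoring, the small-dose limit of the estimates' validity.

The decays-in-blood fraction of a curative dose is estimated as
λ/(λ+κc+konγN0/V) (intact antibodies) plus ωλ/((λ+ω)(λ+κp)) (fragments);
at reference parameters fragments carry 96.5% of blood decays. Worst-case
maximal safe doses evaluate these branches at the range corners (κc at its
minimum for the intact branch; ω maximal, κp minimal for the fragment
branch) — corner evaluation is exact because each branch is monotone in
each parameter. Between the two capacity limits the bound assumes the
anchored amount is min(A, B/(η+1)) for binding capacity B: the interior
interpolation is this package's construction; the two limits (≈362 and
≈1763 nCi) are range-corner facts independent of η.

## Capacity estimation from diagnostic kinetics

A diagnostic dose occupying ≪1% of receptors leaves plasma at
k_obs = λ + κc + kon·γN0/V; ordinary least squares on log-concentration
recovers γN0 = (k_obs − λ − κc)·V/kon, floored at zero. The synthetic
fixture generator runs the *full* model, not the asymptotic exponential,
and applies multiplicative log-normal noise. Default sampling uses 8
points over the first hour (0.0025–0.04 d): proliferation grows the
receptor pool by ~2% over a 0.1-day window and would bias the estimate
upward by the same amount, so sampling is front-loaded into the binding
phase; the window is configurable. Noiseless recovery is accurate to 0.6%;
with 5% noise the median error over 100 replicates is ~1.4%.

## Dose searches

* **Minimal curative dose.** Brent root search on log(N_min(A)/N_cur)
  with a geometrically expanded bracket, relative dose tolerance 1e-4
  (1e-2 inside population sweeps), horizon 365 d. A post-hoc certificate
  (0.99·A_cur fails to cure) guards the monotonicity assumption; with
  k_f = 0 and injected antibodies exceeding the receptor pool no finite
  dose cures, and the failure is reported rather than silently bracketed.
* **Maximum tolerated dose.** Population bisection to 0.5 nCi between a
  certified-safe floor (blood decays are bounded by A times the sum of the
  worst-case intact and fragment fractions over the *sampled* parameter
  values) and a doubling upper bracket. Mice are ranked by blood-decay
  load at the floor dose and only the top-k (default 50) most
  toxicity-prone candidates drive the bisection; the result is certified
  on the full population, and the search resumes with any offender
  included if the ranking missed one (not observed in practice).
* **Per-mouse optimal single dose.** The individual toxicity-limit dose is
  bisected first; if the limit dose cures, the minimal curative dose is
  returned, padded by twice the search tolerance (the exact root is
  knife-edge — at evaluation settings differing from search settings the
  cure flag can flip); otherwise survival time is maximized over the
  tolerated interval by bounded golden-section search, checked against the
  interval endpoint.

## Virtual populations and trials

Varied parameters (κc, κp, γ, V, ρ, ω, α, kf, N0) are drawn independently
and log-uniformly from their physiologic ranges — they span up to two
orders of magnitude — while k_s, whose range [0, 1] contains zero, is
drawn uniformly; λ, kon and ν stay fixed. The drug impurity is η = 1780,
the value implied by a 1.85 kBq/µg labeling ratio for a 148 kDa IgG
(the molar mass is an assumption of this package, recorded as a named
constant). Survival and toxicity curves are empirical daily fractions; no
parametric survival modeling is attempted. The generator emulates
between-mouse parameter variability only: it does not model within-tumor
heterogeneity of radiosensitivity, receptor expression, measurement error
in anything but the diagnostic PK curve, or parameter correlations — so
population-level results (e.g. the ≈370 nCi MTD on 1000 mice at the
default seeds) depend on the independence and log-uniform choices, and
passing tests bound behavior under those sampling assumptions, not under
real biological covariance.

## Multi-dose machinery

The auxiliary idealized model assumes instantaneous binding and
permanently saturated receptors with active occupancy φ ≤ 1/(η+1); the
damage rate collapses to αλγφ/ν (independent of k_s when occupancies are
equal), giving the long-term curability condition αλγ/(ν(η+1)) > ρ and a
required continuous dosing rate γφ(λ(N+D) + ρN). Continuous profiles are
discretized into boluses that carry the profile's integral over each
interval (total activity conserved).

Universal schedule families are parameterized by the first antibody amount
c1·γN0 + c0 (pmol), follow-up fraction c2, interval τ and dose count K,
with every bolus capped at the worst-case maximal safe dose for the
mouse's capacity. Optimization is a coarse grid search (defaults
c2 ∈ {0.05…0.5}, τ ∈ {3…30} d, K ∈ {1,4,8}) maximizing one-year survival
on a training population, ties broken toward fewer injections. This is a
deliberately simple surrogate for a formal optimal-control treatment; its
acceptance is therefore property-based: optimized families must not lose
to the fixed MTD in any k_s stratum, and the largest survival gain must
occur in the high-k_s group (observed: +0.21 one-year survival there,
with the winning family using a saturating first dose and K = 8 small
follow-ups). The k_s strata — low [0, 0.2), intermediate [0.2, 0.6),
high [0.6, 1] — are this package's choice and configurable.

## Problem sizes and tolerances in the shipped tests

Unit and property tests run on single trajectories or populations of ≤ 25
mice. The heavier study-scale checks use: 200 virtual mice for the
curative-dose sweep (cells born during treatment < 50% of N0, within
3–25% for ≥ 90% of draws; activity share on viable cells always below
1/ln(N0/N_cur)); 120 training mice for schedule optimization over a
2×3×3 family grid; 1000 mice for the MTD search. Quantitative
reproductions assert: exact-arithmetic quantities to ≤1%, ODE-bisection
per-cell curative counts to 10%, the large-impurity blood-decay overshoot
(η = 10⁶ as the limit surrogate) to 15%, and the population MTD to 15% —
the last reflecting that the original sampling scheme of the virtual
population is not fully specified, so only sampling-tolerance agreement
is claimed.

## Known limitations

* Single-nuclide, one-step decay; no decay chains or daughter
  redistribution.
* No spatial structure: cross-fire weighting is a lumped parameter, not a
  microdosimetric calculation; no organ-level dosimetry in Gy.
* Toxicity is a single cumulative blood-decay threshold; marrow kinetics
  and recovery between fractions are not modeled, which matters for
  multi-dose toxicity more than for single doses.
* The homogeneous-cancer assumption ignores the radiosensitivity
  heterogeneity that dose-escalation data suggest; conclusions about
  absolute curative doses are model-internal.
* The multi-dose optimizer explores a small family grid, not the full
  schedule space; reported gains are lower bounds on what schedule
  optimization could achieve.
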