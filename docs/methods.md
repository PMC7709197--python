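# Methods

## The model

A sealed micro-batch container of volume *V* (ml) starts at protein
concentration *C₀* (mg ml⁻¹).  Three coupled processes are modelled:

**Nucleation.**  The expected number of new crystals per hour is
*I(C)·V*, with the classical-nucleation-theory rate law

    I(C) = A₂ · C · exp(−A₃ / ln²(C/C_e)),   I(C ≤ C_e) = 0.

A₂ (attachment frequency prefactor) and A₃ (thermodynamic barrier) are
treated as condition-specific constants.  The function is continuous at
C_e (the barrier diverges), and in double precision it underflows to
exactly zero slightly above C_e — harmless, since those rates are
physically negligible anyway.

**Growth.**  Each crystal's longest dimension grows at
dL/dt = A₁·(C − C_e), independent of its size (valid in the
low-supersaturation regime the tool targets).  There is no dissolution
branch: the rate clamps at zero below solubility.  New crystals start at
L = 0; because the growth law is size-independent, a nucleus of realistic
(sub-µm) critical size would change final sizes negligibly.

**Depletion.**  A crystal is a rectangular parallelepiped with fixed aspect
ratios a : b : c (longest side first, a = 1), so its volume is a·b·c·L³.
Protein enters the lattice at density C_s (g ml⁻¹), fixed by the Matthews
coefficient: C_s = 10²¹/(V_M·N_A)·10³ g ml⁻¹, which is 0.902 for
V_M = 1.84 Å³ Da⁻¹.  Each step removes
C_s·a·b·c·Σ ΔLₖ³ / V from the solution concentration.  The solution volume
V is held constant: crystal volume is not subtracted from it (≤0.3% effect
at the volume fractions involved).

Out of scope by construction: spatial gradients and convection, Ostwald
ripening, dissolution, temperature dependence, and any dependence of the
four constants on precipitant composition — they are constants of one
condition.

## Parameter estimation

All fits are straight lines (plain least squares — no weighting of the
point estimates), matching how these plots are read in practice:

1. **Growth onset** (`fit_growth_onset`): L vs t per container; the slope
   is the growth rate, the horizontal intercept the nucleation onset.  An
   optional index window selects the early linear regime.
2. **Growth law** (`fit_growth_law`): rate vs C₀ across containers,
   restricted to C₀ ≤ `linear_max_conc` (default 15 mg ml⁻¹; the growth
   mode visibly changes above that for the lysozyme benchmark, so the
   cutoff is a required, visible parameter, not auto-detected).  Slope = A₁,
   horizontal intercept = C_e.
3. **Nucleation rate** (`fit_nucleation_rate`): cumulative count (t_k, k)
   per container; slope / V = I in ml⁻¹ h⁻¹.  Rates are always normalised
   per ml (the rate law's unit); the per-container slope is exposed as an
   accessor because small-volume reports are often quoted per container.
4. **Nucleation law** (`fit_nucleation_params`): ln(I/C) vs 1/ln²(C/C_e);
   slope = −A₃, intercept Y_sec gives A₂ = exp(Y_sec).

**Standard errors.**  Derived ratios (C_e, onset time) use the first-order
delta method on the full OLS covariance; A₂'s SE is exp-transformed from
the intercept SE.  Two places deliberately do *not* use the textbook
iid-error OLS formula, because it is provably miscalibrated there:

* Cumulative counts are a counting process: deviations from the mean line
  are a scaled Brownian motion, so residuals are strongly correlated and
  the iid formula understates the slope variability several-fold.  For a
  Poisson process the least-squares slope has asymptotic relative SD
  √(6/5 · 1/n) (n = number of events; the 6/5 arises from integrating the
  min(s,t) covariance kernel against the regression weights).
  `fit_nucleation_rate` reports that SE.  Monte Carlo: empirical
  rel SD·√n → 1.10 ≈ √1.2, and 2·SE intervals cover at ~95% where the
  naive formula covered at 10–40%.
* The transformed nucleation ordinates ln(I/C) inherit the *relative* SE
  of each I estimate, which differs by factors of ~4 between concentration
  levels (event counts differ greatly).  When the per-point SEs are
  supplied, `fit_nucleation_params` keeps the OLS point estimate but
  computes the slope/intercept SEs from the known per-point variances.

Coverage facts worth knowing when designing a campaign: with only three
concentration levels the residual degrees of freedom are 1 and nominal
±2·SE intervals cover at roughly 70% for *any* correctly implemented
estimator (a Student-t small-sample effect, not a defect); with ~10 points
per regression the intervals are calibrated.  Joint "all four parameters
within 2 SE" events sit near 85–90% even asymptotically (two weakly
dependent parameter pairs at ~95% each), so the validation suite asserts
per-parameter coverage ≥90%, which the calibrated SEs meet.

## Numerical integration

Explicit Euler on a fixed grid Δt (default 0.1 h), with the update order
nucleate → grow → deplete:

* **Deterministic mode** integrates the expected-nuclei accumulator
  ∫I(C)·V dt and spawns one crystal whenever it crosses the next integer;
  the birth time is linearly interpolated inside the step, which makes
  initiation times insensitive to Δt.  This reproduces whole-number crystal
  counts directly.
* **Stochastic mode** draws Poisson(I·V·Δt) nuclei per step with an
  explicit seed; nucleation really is a stochastic process, and replicate
  spread around the deterministic count is the honest uncertainty
  statement.  Note the deterministic count is the *floor* of the expected
  integral, so it sits about half a count below the stochastic mean by
  construction; the validation suite therefore compares the stochastic
  mean to the deterministic count within 3 replicate standard deviations.

Because dL/dt is identical for all crystals, lengths are
L_k(t) = G(t) − G(birth_k) with G the cumulative growth.  `simulate`
carries only Z, ΣG_b and ΣG_b², from which ΣL and ΣL² — and hence the
exact depletion increment 3gΣL² + 3g²ΣL + Zg³ — follow in O(1) per step.
`step` is the plain per-crystal reference transition; the test suite checks
the two paths agree to 1e-9 and that both match an independently written
brute-force Euler loop.  Mass conservation
(C·V + C_s·abc·ΣL³ = C₀·V) holds to ~1e-10 relative by construction; a
step that would drive C negative beyond tolerance raises a step-size error
rather than silently clamping.

Termination: at the horizon (default 4380 h ≈ six months, a typical
observation span), or early once the supersaturation has collapsed below
1e-6 of its initial value ("equilibrated") — after that, nothing can
change.  Condition scans default to a 60 000 h horizon because a
single-crystal 400 µl batch needs ~20 000 h to consume its protein; early
termination keeps large horizons cheap.  Δt = 0.1 h is converged for the
few-µl scenarios (halving it changes counts by 0 and sizes by <0.5%);
0.5 h suffices for the slow 400 µl scenarios.

## Benchmark reproduction and the rounding knife-edge

With the published lysozyme/NaCl/PEG 4000 constants (C_e 4.51, A₁ 0.11,
A₂ 8.47, A₃ 1.49, C_s 0.901, habit 1.00 : 0.84 : 0.77) the simulator
reproduces the benchmark micro-batch outcomes: 0 and 6 and 10 crystals at
5/10/15 mg ml⁻¹, first-crystal sizes within ~1%, initiation times within
~1%, and the 400 µl single-crystal scenario (1 crystal, 1.12 mm vs 1.09
published, initiation 1676 h vs 1600).

The crystal counts at 20 and 25 mg ml⁻¹ land at 22 and 37 against the
published 21 and 36.  This is a rounding artefact of the published
parameter table, not a model discrepancy: the converged expected-nuclei
integrals are 22.60 and 38.0 — just above the integer — and re-running
with A₁ = 0.115, which rounds to the published "0.11", reproduces *all*
published counts, sizes and times essentially exactly.  The same applies
to the "+5% concentration → 10 crystals" scenario (8 crystals under the
rounded constants).  The package deliberately runs the published rounded
values rather than back-fitted ones; the affected validation cases are
kept failing with this explanation rather than loosened.

## Synthetic campaigns

`xtalplan.synthetic` generates data with exactly the statistical structure
the estimators assume: per container a nucleation onset drawn from the
exponential waiting time of the Poisson process at rate I(C₀)·V, then
linear growth with additive Gaussian measurement noise on length only
(truncated at zero), and homogeneous-Poisson onset tables over the
horizon.  Defaults mirror the benchmark capillary experiment: levels
9/12/15 mg ml⁻¹ (the linear growth region), 2 µl containers, two per
level, six-month horizon.  The observation cadence (24 h) and length noise
(2 µm) are not experimentally reported; they were chosen once as realistic
for daily stereomicroscope measurement of 10–500 µm crystals.

What the generator does *not* emulate — and therefore what passing
recovery tests do not demonstrate about real data: concentration depletion
during the observation window (real containers stop nucleating after the
first crystals grow; the homogeneous generator keeps producing events, so
synthetic event counts are larger than real ones), onset-measurement
discretisation, multiple crystals interacting within one container, and
any model misspecification of the rate laws themselves.  A
depletion-aware stress test can be built by driving the generator's rates
from `simulate` trajectories.

## Degenerate inputs and tie-breaks

Two-point fits are exact with zero SE (zero residual degrees of freedom).
Identical abscissae raise a degenerate-fit error; concentrations at or
below C_e are rejected wherever a logarithm needs them.  A negative fitted
growth slope is flagged, not raised.  The k-th onset contributes the
cumulative point (t_k, k), with no half-count offset.  Scan rows are
ordered by (volume, concentration) and failed cells are marked in an
`error` column without aborting the sweep.  Reported "size" is always the
longest dimension; the 1 mm³ target is expressed as a target edge length
of the longest side.

## Budget arithmetic

The crystal is idealised as a cube of edge *a* mm: molecules =
a³·10²¹/(V_M·M), mass = a³·10²¹/(V_M·N_A) grams (the molecular weight
cancels), required volume = mass/(C − C_e).  N_A = 6.02214×10²³.  The
diffusion migration time uses the one-dimensional mean-square displacement
x² = 2Dt; D is a user input (measuring or approximating it from solution
composition is out of scope).
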