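# Methods

## The two-phase kinetic system

All six rate laws describe transfer of a trace component between a
well-stirred aqueous phase and a suspended solid at constant phase
ratio *r* (volume of water per mass of sorbent, L/kg). Two closures
reduce every law to a scalar autonomous ODE in the loading *q*:

* mass balance: `c = c0 − (q − q0)/r` — what leaves the water is on
  the solid; aliquot withdrawal is treated as non-perturbing (it
  removes suspension, not selectively one phase), so no volume
  bookkeeping is done;
* linear isotherm: `q* = Kd·c`, `c* = q/Kd` — valid at tracer-level
  concentrations (~10⁻¹¹ mol/L here), far below any site saturation.

Substituting both, every driving force becomes proportional to the
distance from the common equilibrium loading
`q_eq = Kd·(c0 + q0/r)/(1 + Kd/r)`:

    q* − q = A·(q_eq − q),     c − c* = A·(q_eq − q)/Kd,     A = 1 + Kd/r.

Hence all models share the same equilibrium (a tested invariant) and
differ only in the shape factor multiplying that distance.

## Dimensionless reduction and integration

With `u = (q − q0)/(q_eq − q0)` each model reads `du/dt = κ·Φ(u)`
where Φ depends only on `A = 1 + Kd/r` (and `q0`), and κ is a
per-minute rate constant. Two consequences drive the implementation:

* **Unit convention.** Coefficients are reported in cm³·g⁻¹·min⁻¹
  (≡ L·kg⁻¹·min⁻¹) for every model, but the q-driven laws (DM, RLD,
  GD) need min⁻¹ internally: κ = K/r. The c-driven laws (FD, ID, CR)
  use K directly; the isotherm substitution contributes the 1/Kd, so
  κ = K/Kd in the reduced equation. This is the only dimensionally
  consistent reading of the reported coefficient table, and it
  reproduces the reported half-life means within their σ_es.
* **One solve per conditions.** Since κ only rescales time,
  `u(t; K) = U(κ·t)` with `U` the unit-κ solution. `U` is integrated
  once per (model, conditions) pair with `scipy.solve_ivp` (LSODA,
  rtol 1e-10, atol 1e-12, dense output) up to `u = 1 − 1e-12`, cached
  (`lru_cache` keyed on the frozen conditions), and evaluated at
  rescaled times thereafter. A coefficient fit therefore costs one ODE
  solve plus cheap dense-output evaluations; this is what makes the
  1000-replicate recovery studies run in seconds.

Numerical choices:

* **Start-up singularity.** RLD, ID and GD diverge at zero net loading
  (the reacted shell has zero thickness; the rate is an integrable
  `u ~ √τ` singularity). Integration starts at `u(0) = ε = 1e-8`;
  halving ε moves the half-life by ~1e-11 relative (tested < 1e-3).
  DM, FD and CR are regular at u = 0 and start exactly there, so the
  DM trajectory matches its closed-form exponential to better than
  1e-9 relative.
* **Desorption states.** For q above q* the shell factor `1 − q/q*` is
  clamped below at 1e-15 and the GD bracket `q* − q0` at 0; the sign
  of the rate is then carried entirely by the driving-force factor, so
  dq/dt < 0 strictly for q > q_eq (reversibility) without dividing by
  zero or squaring a negative bracket into the wrong sign.
* **Mass balance** is enforced structurally: c(t) is recovered from
  the balance after integrating q(t), so conservation holds to machine
  precision (asserted at 1e-8 in the tests).
* **Half-life** is located by the solver's event machinery on
  `u = 1/2` of the unit-κ solution, then rescaled: `t½ = τ½/κ`. It is
  defined against the model equilibrium `q_eq`, not the last observed
  point.

## Coefficient fitting and model discrimination

Only one parameter per curve is free: Kd is fixed beforehand, either
given or estimated from the equilibrium plateau as
`Kd = r·f_eq/(1 − f_eq)` with `f_eq` the mean sorbed fraction over
points at t ≥ 7 h (configurable window). The χ² objective

    χ²(K) = Σ_i (y_i − ŷ_i(K))²/s_q,i²

is minimized over log₁₀K by bounded Brent search on
[guess − 6, guess + 3] decades around a moment-based initial guess
(reading the earliest informative point as an exponential rise). The
reported σ(K) comes from the local curvature, σ = √(2/χ″). Fits are
flagged non-identifiable when the objective is flat up to the upper
search bound (e.g. a curve already at equilibrium at the first
sample). Fitting happens in sorbed-fraction (%) space,
`f = (q − q0)/(r·c0)·100`, the quantity the experiment measures.

When no per-point uncertainties are supplied, the default policy is
`s_q = max(0.05·y, 0.5)` percentage points — counting-dominated
relative error with a floor for near-zero points.

Model discrimination follows the WSOS/DF statistic, χ²/(n_p − n) with
n = 1, acceptable in [0.1, 20] inclusive. Two structural facts matter
when reading rankings: ID and RLD are the same one-parameter family
under the closures (K_ID = K_RLD·Kd/r), as are DM and FD — so
"ID and RLD both acceptable" is the expected signature of
shell-diffusion-controlled data, and ties are broken by the canonical
model order DM < FD < ID < RLD < CR < GD. The CR law's two reported
constants enter only as a product, so a single composite coefficient
K′ = K_CR·k_CR is fitted (identifiability).

## Derived physical quantities

The coefficient–diffusivity inversions are
`D = K·R²·h_s/3` (RLD, ID), `D = K·δ·R·h_s/3` (FD, needs a film
thickness δ) and `D = 2·K·R²/π²` (GD); DM and CR have no
diffusivity relation. By convention `R` is the particle *equivalent
diameter* in cm (nHAp 21.7 nm, nTiO₂ 5.3 nm): that substitution
reproduces the reported D values from the reported coefficients
(back-check: 5.03e-1·(2.17e-6)²·3.17/3 = 2.50e-12 cm²/min), while a
true radius would not; `R_eff_cm` is an explicit field so a radius
convention can be configured. The specific mass h_s defaults to the
midpoint of the reported density range (nHAp 3.14–3.21 → 3.175,
nTiO₂ 3.90–4.30 → 4.10 g/cm³) and is overridable — the reported nTiO₂
D corresponds to a value near the upper end of its range, so the
midpoint lands ~4% low, inside the reported σ_es.

## Synthetic experiments

The generator emulates the batch radiotracer protocol: 25 sampling
times (0, 1…10, 15…60 min, then 2, 3, 4, 5, 7, 10, 24 h), r = 1000
L/kg (1 g/L sorbent), tracer-level c0, truth from the integrated
reacted-layer model at the reference coefficients, uptake past 90%
within the first hour. Noise modes:

* **Gaussian (default):** additive with sd `max(0.05·f, 0.5)`
  percentage points, clamped to [0, 100]; the declared s_q equals the
  sd actually used, so fits against generated data are correctly
  specified by construction. Near the ~95% plateau the clamp truncates
  the upper noise tail, deflating the empirical spread ~13% below s_q
  at those points and pulling the Monte-Carlo WSOS/DF mean slightly
  below 1 (measured ≈ 0.88, tested within [0.8, 1.2]).
* **Poisson:** supernatant/pellet counts at a configurable expected
  total per aliquot (default intent ~10⁴), routed through the same
  activity-split formula as the laboratory; converges to the truth as
  counts → ∞. The decay flag attenuates the expected counts over the
  24 h protocol (Ra-223 T½ = 11.4 d); both phases of an aliquot decay
  identically, so the expected fraction is decay-invariant — a tested
  property, and the reason fractions need no decay correction.

What the generator does *not* emulate: centrifugation losses or
incomplete phase separation, daughter-nuclide ingrowth in the counting
window, pH drift, or inter-replicate variability of Kd (each synthetic
experiment has one true Kd). Passing the recovery and calibration
tests therefore shows the estimator is correct for the stated noise
model, not that real curves carry no systematic error; on real data
the WSOS/DF values are expected to be larger than 1, as imperfect s_q
estimates and protocol effects enter the residuals.

## Problem sizes

The Monte-Carlo test batteries use 200 realizations for goodness-of-
fit calibration and the acceptable-model pattern, and 1000 for
coefficient recovery — enough that the tested bands (≥90%/≥95% rates,
mean WSOS/DF in [0.8, 1.2], median error < 10%) are stable to well
under their width across seeds, while the whole suite stays fast
thanks to the cached dimensionless solutions.

## Known limitations

* Only sorption trajectories are integrated (q0 < q_eq); pointwise
  desorption rates are defined and correctly signed, but a desorption
  *time course* is out of scope.
* The linear isotherm means no site saturation, no multi-component
  competition, no pH-dependent surface speciation; the temperature
  enters only as metadata.
* The equilibrium-plateau Kd estimator assumes the 24-h tail is at
  equilibrium; for systems slower than these (t½ < 1 min) the window
  would need widening.
* Replicate summaries use the population (divide-by-N) standard
  deviation σ_es to match the reference tables' convention; with three
  replicates this understates the sample sd by ~22%.
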