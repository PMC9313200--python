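# Methods

## Scope and model structure

`enfetsim` models an enzymatic BioFET as two decoupled blocks: an
enzyme block that maps an initial analyte concentration A0 to an ionic
product concentration [P] at a chosen measurement time, and a FET block
that maps [P] to a saturation drain current. The coupling is one-way
(the transistor does not perturb the chemistry) and quasi-static: the
current is evaluated at the product concentration reached at t_meas,
not co-integrated with it.

## Enzyme block

The rate law is the power law v = k [A]^n obtained from the
Michaelis–Menten or Hill surface in its limiting regimes. The closed
forms implemented are

- general n ≠ 1: [A](t) = (A0^(1−n) + (n−1)kt)^(1/(1−n)),
- n = 1: [A](t) = A0 e^(−kt),
- [P](t) = A0 − [A](t), v(t) = k[A](t)^n.

Numerical choices:

- **Order degeneracy.** |n − 1| < 1e−9 routes to the exponential
  branch; the general expression divides by (1 − n) and loses all
  precision at the removable singularity. Just outside the window
  (n = 1 ± 1e−8) the general branch agrees with the exponential to
  better than 1e−5 relative, so the switch is seamless.
- **Exhaustion clamp.** For n < 1 the raw expression turns negative
  (or complex) past t_ex = A0^(1−n)/((1−n)k). Mass balance fixes the
  physical continuation: [A] = 0, [P] = A0, v = 0 from t_ex on. All
  outputs are additionally clipped to [0, A0], which also suppresses
  last-bit excursions of the floating-point power.
- **Units.** Concentrations are mol/L and time is seconds at every
  public boundary; k carries (mol/L)^(1−n) s⁻¹ as dictated by n (the
  `KineticsSpec.k_units` property spells it out). Mixing mM- and
  M-based constants is the dominant failure mode in this model family,
  so a single convention is enforced rather than auto-detected.
- **Inversion.** `time_to_fraction` inverts the closed form
  analytically for every order, so it is exact up to round-off and
  mutually inverse with `product_concentration` to 1e−9 relative.

The **ODE oracle** integrates d[A]/dt = −k·max(A,0)^n with LSODA at
rtol 1e−11 (atol A0·1e−15) from t = 0, with a terminal event at A = 0
so sub-first-order kinetics stop exactly at exhaustion rather than
fighting the non-Lipschitz right-hand side. It exists to validate the
closed forms (agreement to 1e−6 relative over randomized orders
n ∈ [0, 4] is part of the test suite) and is deliberately not the
production path.

Non-goals: stochastic (Gillespie) kinetics, coupled multi-substrate
systems, enzyme inactivation. Multi-substrate global order is treated
only as the sum of independently estimated per-substrate orders.

## Rate laws and parameter extraction

- **Lineweaver–Burk** is ordinary *unweighted* least squares of 1/v on
  1/[A]. Unweighted is a deliberate fidelity choice — it is the
  classic graphical construction — even though it over-weights
  low-rate points under relative noise; the direct nonlinear MM fit
  (`fit_mm_nonlinear`) is exposed as a cross-check. A non-positive
  intercept or slope is reported as a fit failure (the data contradict
  a Michaelis–Menten law) rather than returning unphysical constants.
- **Hill fitting** runs Levenberg–Marquardt from a fixed start grid
  h ∈ {0.3, 1, 2, 4} spanning negative through strongly positive
  cooperativity, keeping the lowest-residual solution. The grid is
  fixed so the fit is bit-reproducible; no random restarts.
- **Initial-rate order estimation** fits a quadratic to the first
  max(4, 20%) points of each progress curve and takes its slope at
  t = 0 as v0 — a second-order local model absorbs the leading
  curvature of [P](t) without overfitting — then regresses log v0 on
  log A0 (slope = n, intercept = log k, standard errors from the
  linear regression, delta method for k).

## FET block

Electrostatics is cm-based throughout (F/cm², C/cm²); concentrations
convert to mol/cm³ only inside the charge formulas. Parameter choices
that matter:

- **Two signed valences.** `z_nernst` (electrode redox couple, enters
  V_N logarithmically) and `z_q` (charge per adsorbed product ion,
  enters Q_c and ΔV_T linearly) are independent fields. The worked
  Ag/O⁻ glucose numbers are only mutually consistent with
  z_nernst = −2 and |z_q| = 1, so collapsing them into one valence
  would silently break one half of the chain.
- **Log normalisation.** The Nernst logarithm needs a dimensionless
  argument; `c_ref` makes the convention explicit, with default
  1 mmol/L — the value that calibrates the Ag-electrode potentials
  (0.876 V at 1 μM, 0.790 V at 1 mM).
- **Helmholtz layer.** The rigid-layer model places all product ions
  within one thickness t_H of the electrode: Q_c = z_q e [P] N_A t_H,
  C_H = ε_H/t_H, ΔV_T = Q_c/C_H. t_H is a free constant per
  simulation (default 100 nm, suited to micromolar ion ranges) with no
  built-in concentration dependence; ε_H defaults to vacuum. Diffuse
  (Gouy–Chapman) ion tails are out of scope — they would enter as a
  correction to Q_c without changing the equations' shape.
- **Saturation only.** I_D = K/2 (V_GS − V_T)² is meaningless outside
  strong inversion, so V_GS ≤ V_T raises `OperatingRegimeError` naming
  the violated condition and, in chained evaluation, the offending
  concentration. Transfer-curve and design evaluation flag such rows
  (`in_regime = False`, NaN/None current) instead of dropping or
  clipping them: bias selection is the designer's decision. Triode
  and subthreshold conduction, channel-length modulation and
  temperature dependence (beyond the thermal-voltage field) are not
  modelled.

## Design procedure

`design_enfet` operationalises "analyte well above/below K_M" as a
ratio of 10 (`regime_ratio`, user-visible): min(A)/K_M ≥ 10 selects
zero order, max(A)/K_M ≤ 0.1 selects first (or h-) order, and a range
straddling K_M raises `AmbiguousRegimeError` unless the caller passes
an explicit regime — a deliberate refusal to guess. t_meas defaults to
the 99%-conversion time of the slowest end of the range, the only
self-consistent choice when no measurement time is specified: reported
products then track A0 closely. The W/L back-solve inverts
K = (W/L) μ_c C_tot exactly, so re-composing the aspect factor from the
reported geometry reproduces the target to 1e−12 relative.

## Synthetic data generator

The generator emulates the two bench datasets the extraction routines
consume: initial-rate tables drawn from an MM/Hill truth on a
user-chosen concentration grid, and early-time progress curves at
several A0 (auto-grid: 10 points over one tenth of the 10%-conversion
time, keeping conversion ≲1% so the quadratic initial-rate model is
essentially unbiased). Noise is none, multiplicative Gaussian
(default flavour, 1% scale in the test fixtures — initial-rate readout
error is typically relative) or additive Gaussian, always through a
local `numpy` generator seeded from the fixture spec; identical specs
give identical bytes.

What the generator does **not** emulate: instrument drift, correlated
residuals, product inhibition, pH/temperature excursions, or sampling
jitter. Passing fits on these fixtures therefore demonstrate
correctness of the estimators under the stated noise model, not
robustness to every pathology of real kinetics assays.

## Problem sizes

Everything here is closed-form or small-scale regression: the test
suite uses grids of 10–80 points, tens of random kinetics specs
against the ODE oracle, and 20-point fitting designs, which keeps the
full suite around a second while exercising every operation and
invariant.

## Known limitations

- The millimolar-range threshold shift used in the worked drain-current
  excursion (1.14 V at 1 mM) is an operating value supplied to the
  chain, not derivable from the linear Helmholtz expression with the
  same 100-nm t_H (which would give ~109 V); it back-solves to
  t_H ≈ 10 nm. The model deliberately has no t_H([P]) law, so
  thickness at each concentration regime is the user's input.
- Single-substrate kinetics only; the Hill exponent is identified with
  the effective reaction order in the dilute regime.
- The square-law FET model carries no short-channel corrections; for
  sub-100-nm nodes the aspect factor should be treated as an effective,
  calibrated parameter.
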