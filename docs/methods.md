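# Methods

This note documents the models, estimators and numerical choices behind
`alesense`, and what the synthetic-data tests do and do not demonstrate.

## 1. Black-box growth stoichiometry

Aerobic growth on a single carbon source, without product formation, is
described per C-mole by

    rs·CH2.67O + ro·O2 + rn·NH3 → rx·CH1.77O0.49N0.24 + rc·CO2 + rw·H2O.

Degrees of reduction are γC=4, γH=1, γO=−2 (γO2=−4), γN=−3, which makes
the DoR of NH₃ zero, so the nitrogen rate drops out of the carbon and
electron balances and the 2×2 system

    C:    rs = rx + CER
    DoR:  rs·γs = rx·γx + 4·OUR

is solved for rx and rs, with OUR/CER as positive magnitudes and rx
positive during growth (the published equivalent uses signed consumption
rates; only the sign convention differs). With γs = 4.67 and γx = 4.19 the
coefficients are a_xo = 4/0.48 ≈ 8.333 and a_xc = −4.67/0.48 ≈ −9.729; the
widely printed rounded values (8.32, 9.71, 8.71) agree within 0.02 and are
available via `default_rate_model()`.

**Nitrogen-index discrepancy.** The published biomass formula carries
N₀.₂₄, but the printed DoR of 4.19 is consistent with N₀.₂ (N₀.₂₄ would
give 4.07), while the printed C-mole mass 24.996 g mol⁻¹ is consistent
with N₀.₂₄. The package therefore keeps two composition constants:
`BIOMASS_ECOLI_DOR` (N=0.2) feeds the electron balance and
`BIOMASS_ECOLI` (N=0.24) the molar mass, reproducing both printed
constants simultaneously. Both are overridable.

The H and O balances make the system over-determined; they are *not* used
for reconciliation — only C + DoR are solved. Atomic weights are fixed at
C=12.011, H=1.008, O=15.999, N=14.007 g mol⁻¹, which reproduces
30.701/24.996 g mol⁻¹ at three decimals.

## 2. Gas balance

OUR and CER follow from the inert-gas balance (inflow inert fraction
equals outflow inert flow), with inflow fixed at atmospheric composition
(y_O2 = 0.2091, y_CO2 = 0.0004), molar volume 24.465 L mol⁻¹ (25 °C,
1 atm, dried gas) and working volume 0.575 L. Dissolved O₂/CO₂
accumulation is neglected (pH and temperature controlled). `invert_rates`
is the exact algebraic inverse and is what the simulator uses to emit
off-gas fractions, so estimator and generator cannot share hidden errors:
the inversion-consistency test closes the loop through two independent
code paths.

## 3. Soft-sensor pipeline

Stages, in order, with defaults:

1. **Segmentation.** Explicit phase annotations (simulator output) take
   precedence. Signal-based fallback reconstructs the passaging trigger:
   batch end at the first upward crossing of the smoothed DO above 75 %
   air saturation after a 1-h minimum batch time, *armed* only after the
   DO has been below threshold − 5 points. The hysteresis arming is
   needed because the DO crosses the threshold downward slowly early in a
   batch (sensor noise would otherwise fake upward crossings), while the
   depletion spike rises tens of points per minute. Refill completion is
   the conductivity re-contact (> 200, an opaque sensor unit), or the DO
   falling back below threshold when conductivity is absent. A trailing
   batch without a trigger is kept and flagged incomplete.
2. **Smoothing.** Trailing moving average, window 6 samples (90 s at the
   15-s grid).
3. **Inert-ratio correction.** The raw off-gas fractions are exponentials
   divided by a slowly varying inert-ratio denominator; the corrected
   concentrations y·I_in/I_out are exactly offset-exponential during
   exponential growth. Fitting these (default `fit_space="inert_corrected"`)
   makes the later baseline anchor unbiased; fitting raw fractions is
   available for comparison and carries a ≈2 % μ bias under realistic
   conditions.
4. **Exponential fit + gate.** Each channel is fitted to a·e^(b·t)+c by
   nonlinear least squares (deterministic initialisation: c from the first
   sample, a from the span, b from a log-linear pre-fit of the second
   half). Batches whose O₂ *or* CO₂ fit has R² < 0.98 are discarded
   (boundary inclusive: R² = 0.98 keeps). R² is defined on the fitted
   samples, 0 for zero-variance input; a non-converging fit counts as
   failed, not as an exception. For batches ≥ 2 the first 10 min are
   excluded (reactor-exchange artifacts, including the CO₂ stripping
   spike), and the fit window ends `peak_backoff_samples` (default 6, one
   smoothing window) before the smoothed-CO₂ maximum — the off-gas peak
   marks substrate depletion, after which the trace no longer follows the
   growth exponential, and the trailing moving average delays the apparent
   peak by about one window.
5. **Joint rate-constant refit.** After gating, the two channels are
   refitted jointly with a shared b. Rationale: rx = 8.33·OUR − 9.73·CER
   differences two terms each ~8× larger than rx itself, so a relative
   mismatch δ between independently fitted rate constants perturbs the
   growth exponent of rx by ≈8δ. Sharing b (both channels are driven by
   the same biomass exponential) removed essentially all of the per-batch
   μ̂ scatter in simulation (≈0.015 → ≈0.004 h⁻¹ at default noise).
6. **Baseline correction.** For batches ≥ 2 the fitted additive offset c
   is set to the inflow concentration of the respective gas, removing
   additive sensor drift accumulated across days. Anchoring the *offset*
   is exact for an offset-exponential trace; anchoring the fitted value at
   batch start (`anchor="start"`) instead also cancels the inoculum's real
   initial conversion and biases μ̂ upward by ~10 % — it is implemented
   for comparison, not used by default. The first batch is left
   uncorrected (drift reference point).
7. **Integration.** OUR/CER evaluated from the corrected fits on the full
   batch grid; rx, rs via the rate model (solver-derived by default, the
   published rounded coefficients by option); cx by cumulative trapezoid
   (cx0 below), cs likewise from s0 = 15 g L⁻¹, with the first
   zero-crossing of cs reported as the depletion index (located within
   ≈1 % of the batch duration in simulation).
8. **Growth rate.** μ̂ is the least-squares slope of ln cx over the
   trailing `window_fraction` of the analysed batch (default 0.5; 0.6 is a
   documented alternative), skipping lag and transition phases.
9. **Inoculum anchor.** Rate integration determines cx only up to the
   additive constant cx0. The configured default is 0.2 g L⁻¹ (the
   inoculation target; the refill process in practice scatters the true
   value ≈0.15–0.4 g L⁻¹). Because an additive mismatch bends ln cx, the
   default `cx0_mode="estimate"` re-anchors the trajectory so that its own
   exponential+offset fit has zero offset, making μ̂ independent of the
   jitter; `cx0_mode="fixed"` uses the configured value literally.
10. **Evolutionary accounting.** N = cx·Vr/m_cell with
    m_cell = 2.90·10⁻¹³ g; N₀ from the batch-start cx, N_end from the cx
    at the depletion index (end of exponential phase, before any
    post-depletion artifacts). Generations n = log₂(N_end/N₀); CCD via
    Σ N₀(2ⁿ−1), which equals Σ(N_end − N₀) algebraically — the identity is
    asserted in tests as an internal cross-check. Discarded or incomplete
    batches are excluded from the across-batch sequences and reported.

**Stability rule.** A trailing window of 3 per-batch μ̂ values is stable
when its SD is below 0.01 h⁻¹, its least-squares slope is at most
+0.005 h⁻¹ per batch, and — "no *further* upward trend" — the mean of all
later μ̂ does not exceed the window mean by more than the SD threshold.
The suffix clause is essential: a 3-point window cannot distinguish a
0.01 h⁻¹-per-batch adaptation ramp from noise, and without it detection
fires mid-adaptation. The stable growth rate μ_stable is the mean μ̂ from
the first batch of the detected window to the end of the run; relative
fitness divides it by a configured reference (e.g. a control group's
stable rate).

## 4. Repeated-batch process simulator

The generator produces the full multichannel recording plus ground truth.
Per batch, fixed-step classical Runge–Kutta on the 15-s output grid
integrates

    dcx/dt = μ_eff·cx,  dcs/dt = −μ_eff·cx/Y_xs,
    μ_eff = μ_batch · cs/(Ks+cs) · (1 − e^(−t/τ_lag)),

and true rates follow from the exact stoichiometric model; off-gas
fractions from the exact gas-balance inverse, passed through a first-order
gas-phase/analyzer lag (30 s). The truth channels `our`/`cer` are defined
*at the analyzer* (post-lag) — that is the quantity the inert-gas balance
measures — while `our_bio`/`cer_bio` hold the instantaneous biological
rates; an exponential through a first-order filter keeps its rate
constant, so μ estimation is unaffected by the lag. DO follows
dDO/dt = kLa·(DO* − DO) − (DO*/c_O2,sat)·OUR with a stirrer-cascade
controller that scales kLa within [60, 1200] h⁻¹ to hold DO at a 30 %
setpoint while demand allows; when the substrate runs out the demand
collapses and DO spikes — the passaging trigger (arming + crossing, as in
the analysis) ends the batch after the 1-h minimum, with a 24-h guard that
truncates and warns if depletion never comes.

Across batches: μ_batch(i) = μ_stable − (μ_stable − μ_init)·e^(−i/τ_adapt)
(default 0.30 → 0.61 h⁻¹, τ_adapt = 5 batches; a mutagenised culture is
emulated by raising the ceiling, e.g. 0.70 h⁻¹); lag time constant
τ_lag(i) = lag0·decay^(i−1) (default 2.2 h, decay 0.7). Drain/refill gaps
of 42.22 ± 3.86 min separate batches (flat sensors, gas washing out,
conductivity low until refill completion; the recording ends on a final
gap, as a run stopped during the last exchange). The refill resets
substrate to 15 g L⁻¹ and the inoculum to 0.2 g L⁻¹ with lognormal jitter
(σ = 0.2, reproducing the observed 0.15–0.4 g L⁻¹ spread). Measurement
model: Gaussian sensor noise (O₂ 0.02, CO₂ 0.01, DO 0.5 percentage points,
pH 0.01, conductivity 1), a per-batch random-walk drift on both gas
channels (step 0.005 points), and an additive decaying CO₂ stripping
transient (0.25 points, τ = 2 min) at the start of every batch after the
first.

Parameter defaults the studied process states directly: s0, cx0, DO
threshold/minimum batch time, exchange duration, 15-s sampling, gas spec.
Kinetic parameters it does not state are literature-typical for *E. coli*
on glycerol: Ks = 0.01 g L⁻¹ (half-saturation in the tens of mg L⁻¹),
Y_xs = 0.45 g g⁻¹, c_O2,sat = 0.25 mmol L⁻¹. The lag defaults
(2.2 h, ×0.7 per batch) are calibrated so early batches last ~10–12 h,
late batches ~6 h, and the batch-2 → batch-22 duration decline is ~41–45 %,
matching the printed process characteristics of the system the simulator
emulates.

**What the simulator does not emulate:** biofilm and foaming, pump
hydraulics and level-sensor details, acid/base dynamics (pH held at
set-point), dissolved-gas accumulation, medium depletion of the supply
reservoir, and any population-genetic structure — the growth-rate law is a
deterministic phenomenological ramp, not a model of mutation supply and
fixation. Passing the round-trip tests therefore shows the *analytics* are
correct and noise-robust under realistic measurement artifacts; it does
not validate biological claims about real evolution experiments, and
quantities that depend on absolute biomass (e.g. total CCD) inherit the
simulator's yield assumptions.

## 5. Numerical choices and degenerate inputs

- Trapezoidal integration throughout (second-order; the convergence test
  checks the O(dt²) error law). RK4 for the simulator ODEs at the output
  grid — dynamics are non-stiff at these rates.
- Exponential fits clip the exponent argument at ±700 to avoid overflow
  during optimisation; the solver rejects equal substrate/biomass degrees
  of reduction (singular balance) with a specific error.
- Zero-variance traces fit as b = 0 with R² defined 0 (gate discards).
- Stability SD is the population SD (ddof = 0) of the raw window values.
- All randomness flows from a single `numpy` Generator seeded from the
  run configuration; identical seeds give byte-identical outputs (file
  writes use fixed numeric formatting).

## 6. Problem sizes

The test suite and the acceptance script run 22-batch simulated runs
(~40 000 samples, ~160 h of process time) for end-to-end checks, 3-batch
runs for inversion/spike checks, triplicate 22-batch runs for the
duration-decline statistic, and 1000 random batch lists for the CCD
identity; a full run simulates in ~1 s and analyses in ~1 s on one CPU.

## 7. Known limitations

- The growth-rate estimator is slightly conservative: the Monod tail and
  the finite fit window leave a ≈1 % low bias at default settings, and the
  stability rule necessarily fires while the adaptation law is still
  ≈2 % below its ceiling; μ_stable therefore under-reports the asymptotic
  μ by ≈2–3 % on simulated runs.
- The quality gate treats both channels conservatively (either failing R²
  discards the batch).
- Depletion localisation by the cs zero-crossing is accurate to ≈1 % of
  the batch duration, not to single samples.
- The DO-fallback segmentation locates batch ends a few samples late
  (trailing-average delay); phase annotations, when present, are exact.
- No reconciliation of the redundant H/O balances, and no uncertainty
  quantification on μ̂ beyond the log-fit R².
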