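# Methods

## Model

Basement-membrane protein level P(t) (arbitrary protein units, Pu) is
governed by first-order production-degradation kinetics,

    dP/dt = S_p M(t) − D_p P,

with M(t) the developmental mRNA level (arbitrary mRNA units, Mu), S_p
the synthesis rate per unit mRNA (Pu Mu⁻¹ h⁻¹) and D_p the degradation
rate (h⁻¹). The protein half-life is ln2/D_p. The model deliberately
excludes feedback regulation: the observed logistic saturation of the
protein level emerges from the balance of a transcription pulse and
first-order decay, not from set-point control.

Time is measured in hours from embryonic stage 15 (≈ 11 h 20 min after
egg laying); embryo birth is t = −10 h, the imaging window ends at
t = 16 h. Stage-binned mRNA series use the conversion: an embryonic 2-h
bin "embryo XX-YYh" maps to XX − 10 h (so "embryo 00-02h" → −10 h,
"embryo 10-12h" → 0 h), "larva L1" → 14 h, "larva L2" → 38 h. The
lower-bound (not midpoint) bin mapping is used because it reproduces
those anchor points exactly.

## Estimation chain

1. **Preprocessing.** Raw whole-embryo traces are smoothed with a
   15-frame centered moving average; at boundaries the window shrinks
   symmetrically (partial windows) so trace length and the t = 0 anchor
   are preserved. The mean of ≥ 5 no-fluorophore control embryos,
   linearly interpolated onto the trace's clock, is subtracted:
   F = F_Raw − ⟨F_NoFP⟩. Smoothing precedes subtraction by default (the
   order is configurable; the two operations nearly commute since the
   control mean is itself smoothed). Negative F values are permitted —
   residual background is absorbed downstream by the logistic baseline.

2. **Logistic characterization.** F(t) is fitted with the four-parameter
   Hill form F = Span/(1 + 10^(HillSlope·(LogEC50 − t))) + Bottom, which
   is identically the logistic K/(1 + e^(r(t_i − t))) + B under K = Span,
   t_i = LogEC50, r = HillSlope·ln10, B = Bottom. The baseline-free
   protein curve is P_L(t) = K/(1 + e^(r(t_i − t))). Initialization:
   Span = range, Bottom = min, LogEC50 = half-range crossing (the first
   sample when the trace starts above half-range), HillSlope from the
   local slope at the crossing. Span and HillSlope are bounded positive;
   a fit pinned at the slope bound is reported as failed rather than
   returned. Unweighted least squares (trust-region-reflective, to honor
   the bounds) is used throughout. An optional `fix_bottom` pins B — for
   background-free simulated curves whose saturating shape would
   otherwise push the unconstrained fit onto the exponential-limit ridge
   (K → ∞, B → −∞), since a pure saturating exponential is the boundary
   of the logistic family.

3. **mRNA interpolation.** The coarse series is fitted with
   M(t) = (1 − q(t))·M1(t) + q(t)·M2(t), M1 = a1·exp(−((t−b1)/c1)²),
   M2 = a2·exp(−((t−b2)/c2)²) + d2, with q a linear ramp between two
   breakpoints. The breakpoints default to the two component centers and
   are refined as free parameters (the ramp's exact definition is an
   open choice; refining it costs two parameters and removes the
   arbitrariness). A small multistart over component placements and two
   width scales guards against local minima. With only the 14 standard
   stage bins (two of them beyond embryogenesis) the curve between L1
   and L2 is under-determined; fits are therefore judged at the data
   points, and parameter-recovery tests use densely sampled series.

4. **Anterograde fit.** The ODE is integrated from M(t) on a fixed
   2-min grid over [−10, 16] h with P*(−10) = 0, and (S_p, D_p) minimize
   Σ(P*(t) − P_L(t))². The fitted logistic curve — not the raw trace —
   is the default target; raw-trace fitting is available and is what the
   CI-calibration experiment uses (see below). Because P* is linear in
   S_p, the optimizer is seeded by profiling S_p over a log-spaced D_p
   scan; a 3×3 log-spaced multistart around that seed guards against
   local minima. A fit that pins D_p at zero is flagged (`at_bound`) and
   warned about, not silently returned.

5. **Retrograde fit.** M*(t) = ((r + D_p)KP − rP²)/(S_p K) with
   P = P_L(t) is matched to the interpolated M(t) on [−10, 30] h — past
   the protein-imaging window, with P_L extrapolated by its fitted form.
   M* is linear in 1/S_p and D_p/S_p, so an exact linear least-squares
   solution seeds the nonlinear refinement that provides the CIs.

6. **Confidence intervals.** For all nonlinear fits, 95% CIs are
   linearized intervals from the estimated Jacobian at the optimum:
   cov = s²(JᵀJ)⁻¹ with s² = SSE/(n − p), CI = β ± t₀.₉₇₅,ₙ₋ₚ·se.

7. **Decay estimators.** Pulse-chase: a line through the 15–20 h window;
   D_p = −slope/p0 with p0 the fitted level at the window start
   (`reference="start"`) or the window-mean level (`reference="mean"`).
   For an exponential the secant slope equals −D_p × (mean level)
   exactly, so "mean" is unbiased for pure decay while "start"
   under-reads D_p by ≈ D_p·(window length)/2 — a conservative
   convention, retained as the default because it reads the rate at the
   window start. Two-timepoint: t½ = Δt·ln2/ln(level_a/level_b),
   invariant under common rescaling. Photoconversion decay: exponential
   fit from the trace maximum onward, optional additive floor (off by
   default) for an immobile fraction.

## Numerical choices

* **Fixed-step integrator: Heun (explicit trapezoid) at dt = 2 min**,
  the sampling step of the time-lapse data. Forward Euler at this step
  leaves a first-order bias (≈ +0.8% on D_p) that is commensurate with
  the statistical error of a 2%-noise fit and measurably deflates CI
  coverage; Heun's second-order accuracy pushes the discretization bias
  to ~10⁻⁵ while staying on exactly the data grid, and its fixed point
  for constant M is the exact steady state S_p M/D_p. The synthetic-data
  generator never uses this scheme: it integrates with an adaptive
  8th-order Runge-Kutta method at rtol 10⁻¹⁰, so closed-loop tests
  compare two genuinely independent forward models.
* **Relative error for curves through zero** (integrator checks, fit
  round-trips) is measured against the curve amplitude max|P|, since
  pointwise relative error is undefined at P = 0.
* **CI calibration** is assessed with the anterograde model fitted to
  raw noisy traces. Fitting the smoothed logistic target instead would
  make the residuals reflect logistic-vs-ODE model mismatch rather than
  measurement noise, and Jacobian CIs are only meaningful against the
  noise that actually entered the estimate.
* Degenerate inputs: M ≡ 0 makes (S_p, D_p) unidentifiable and raises;
  S_p = 0 invalidates the retrograde closed form and raises; D_p ≤ 0 has
  no half-life and raises; an exponential-decay fit whose fitted loss
  over the whole window is < 10⁻⁴ is flagged as non-decaying rather
  than reported with an astronomically long half-life.

## Synthetic data

The generator produces every input from explicit ground truth
(`SyntheticScenario`): per-embryo fluorescence traces
P(t) + autofluorescence + i.i.d. Gaussian noise, ≥ 5 no-fluorophore
control traces (autofluorescence + noise), stage-binned mRNA tables
sampled from the continuous program, pulse-chase and photoconversion
traces. Noise sd is expressed as a fraction of the noise-free plateau
(default 2%) — additive Gaussian is the simplest testable choice, as no
empirical noise model is available. Autofluorescence defaults to a
constant 10 a.u. Optional mean-preserving log-normal jitter on the rates
(CV-parameterized, off by default) produces embryo-to-embryo spread. The
ODE integrates from t = −10 h with P = 0, but traces are recorded from
t = 0 (`record_from`), mirroring imaging that starts at stage 15.

**Transcription programs are derived self-consistently.** The method's
empirical premise is that measured accumulation curves are logistic;
under the turnover ODE this pins the transcription program to the
retrograde closed form M(t) = ((r + D_p)KP_L − rP_L²)/(S_p K) — a
biologically typical pulse (induction tracking the rise, overshoot to
K(r + D_p)²/(4rS_p), relaxation to the homeostatic balance KD_p/S_p) —
which is projected onto the double-Gaussian interpolant family. Two
frozen regimes are provided: Perlecan-like (K = 100 Pu, r = 0.40 h⁻¹,
t_i = 6 h, S_p = 0.4, half-life 7 h) and Collagen-IV-like (K = 200 Pu,
r = 0.45 h⁻¹, t_i = 5 h, S_p = 0.45, half-life 10 h; ~2:1 stoichiometry
and earlier induction). `perl_scenario(half_life_h)` re-derives the
program for other turnover regimes with the protein phenotype held
fixed. Mis-matched programs — e.g. mRNA rising proportionally to the
protein itself, or re-rising strongly after the protein has plateaued —
either make D_p unidentifiable (the lag between M and P is what
identifies it) or violate the logistic premise; they are reproducible
with custom scenarios but are outside the benchmarked conditions.

What passing closed-loop tests therefore show: the estimators recover
known rates from data that satisfy the model's own assumptions, with
realistic sampling, background and noise. What they do not show:
robustness to features of real embryos that the generator does not
emulate — photobleaching, non-Gaussian or autocorrelated imaging noise,
fluorophore maturation delay, reporter-specific turnover, segmentation
artifacts, or mRNA measurements from pooled embryos that differ
systematically from the imaged individuals.

## Problem sizes

Benchmarked conditions use 10 embryos per ensemble at 2-min sampling
over [0, 16] h (481 points/trace), ground-truth half-lives
{7, 10, 14} h, 2% plateau noise, and 100 replicates for CI-calibration
experiments — small enough to run the whole suite in well under a
minute per ensemble while leaving the median estimators meaningful.

## Known limitations

* The anterograde default fits the logistic curve, not the raw data, so
  its estimate inherits a small structural bias wherever the true ODE
  solution is not exactly logistic (a few percent at half-life 7–14 h
  under the benchmarked regimes; the retrograde direction is nearly
  unbiased there). This mirrors the method's design, which treats the
  logistic fit as the measured phenotype.
* Anterograde/retrograde agreement is necessary, not sufficient: both
  directions share the interpolated M(t), so a common error in the mRNA
  model shifts both estimates coherently.
* The pulse-chase "start" convention's conservative bias grows linearly
  with window length × D_p (≈ +13% on half-life at 14 h truth with the
  5-h window).
* The photoconversion estimator reports an effective rate that includes
  unbinding/diffusion; it bounds degradation from above (half-life from
  below) by construction.
* Retrograde fitting extrapolates P_L to t = 30 h, twice the imaging
  horizon; it is reliable only when the protein has genuinely reached
  homeostasis within the imaged window.
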