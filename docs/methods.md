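# Methods

## The superposition model

The quantification rests on one modelling assumption: at each
characteristic wavenumber νᵢ, the height Δs of the vibrational peak in the
baseline-corrected reflectance spectrum decomposes additively into a
constant pure-water contribution and concentration-dependent contributions
of the two dissolved monosaccharides,

    Δs(νᵢ) = kᵢ + φᵢ(c_glucose) + ψᵢ(c_fructose).

φᵢ and ψᵢ are polynomials of order 1–3 with zero constant term. The zero
constant term is not a fitting choice but a structural consequence of the
model: at zero concentration the analyte must contribute nothing, so the
constraint is built into the design matrix (a Vandermonde matrix without
the constant column) rather than imposed through a pseudo-observation.

Solving for unknown concentrations means finding x = [c_g, c_f]ᵀ that
minimises ‖F(x)‖² with Fᵢ(x) = φᵢ(x₁) + ψᵢ(x₂) − (Δsm(νᵢ) − kᵢ), over the
n = 3 panel wavenumbers (n ≥ 2 is required for identifiability of two
unknowns; n = 3 overdetermines the system and motivates the
ill-conditioning flag, below). Negative solutions are physically
infeasible and are clipped *after* the unconstrained minimisation:
x\* = max(argmin ‖F‖², 0). Clip-after-argmin, not a bound-constrained
argmin — the two differ whenever the unconstrained minimum lies outside
the positive quadrant, and the pre-clip solution is retained as a
diagnostic of how far outside it was.

## Baseline correction

The ALSS smoother minimises Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²zᵢ)² with weights
wᵢ = p for points above the current baseline and 1−p below, iterated to a
fixed point of the weight vector. Second differences are taken on the index
grid (the standard Whittaker convention), which ties λ to the sampling
density; the default λ = 500 refers to a 1 cm⁻¹ grid and must be re-tuned
for other spacings. The modification: all grid points inside configurable
exclusion windows get weight exactly zero. They keep their grid positions,
so the smoothness penalty bridges the window with a smooth interpolant —
this, rather than deleting the points, is what produces a plausible
baseline *under* the analyte lines.

Numerical details:

- Each weight iteration solves a symmetric positive-definite pentadiagonal
  system via a banded Cholesky factorisation (`scipy.linalg.solveh_banded`);
  the test suite checks it against a dense solve of the same system to
  1e−8 relative.
- Weight convention: p is the weight of points *above* the baseline
  (Eilers–Boelens). With p = 0.99 the baseline hugs the upper envelope of
  the data outside the excluded band. The mirrored convention is reachable
  as 1−p.
- Residuals within τ = 1e−8·max(1, max|y|) of zero are treated as "below".
  Without this tie band, data the smoother fits exactly (a constant, a
  straight line) flips weights on solver rounding jitter — which scales
  with the conditioning of the penalty system, around 1e−11 at λ = 500 on
  300 points — and the iteration never reaches a fixed point. Real ALSS
  residuals are orders of magnitude above τ, so the band changes nothing
  else.
- Initial weights are 1 on all non-excluded points; iteration stops at a
  weight fixed point (threshold `tol`) or after `max_iter` = 50 rounds, in
  which case the result is returned flagged `converged=False`.
- Degenerate inputs: a fully excluded grid is a configuration error; an
  exclusion window that misses the grid is ignored with a logged warning.

The extracted peak amplitudes depend strongly on (λ, p) even though peak
positions do not — the reason the parameters are global constants of an
analysis, never per-spectrum choices. `baseline_sensitivity` quantifies
this for any spectrum.

## Features

Replicates are averaged pointwise before baseline correction (the smoother
then sees the set's representative spectrum; on low-noise simulations the
opposite order agrees to within the replicate standard error, but one order
has to be fixed and averaging-first is the cheaper and smoother one). Peak
height is the maximum of rBC − 1 within ±2 cm⁻¹ of the nominal νᵢ:
measuring relative to unity makes a feature-free spectrum yield Δs ≈ 0, so
pure water produces the small constants kᵢ; the local-maximum search
absorbs sub-grid misalignment of line positions. The default panel
[1034, 1063, 1078] cm⁻¹ deliberately merges the fructose 1080 cm⁻¹ line
into the 1078 cm⁻¹ evaluation — the two are too close to separate at
1 cm⁻¹ sampling.

## Calibration

kᵢ is the arithmetic mean of Δs(νᵢ) over a cycle's pure-water sets, kept
cycle-local because the water level demonstrably drifts between cycles
(residue carry-over in the flow cell); `evaluate_cycle` therefore
re-estimates k from the evaluated cycle's own water flushes while keeping
the trained polynomial bases. Each wavenumber is fitted independently
(three univariate fits per analyte) by ordinary least squares with equal
weights on the concentration points; an order-o fit demands at least o
distinct positive concentrations and otherwise raises an error instructing
order reduction rather than silently regularising.

## Inversion

Multi-start local descent (trust-region reflective, analytic Jacobian)
over the box [−0.2·c_max, 1.5·c_max]²: starts at the four box corners, the
centre, and a closed-form guess from the linear terms of the bases. The box
extends below zero so the unconstrained minimiser is reachable before
clipping, and 50% above the calibration ceiling so mild extrapolation does
not pin estimates to the boundary. The solver is validated against an
exhaustive 0.01 g/l grid search over [0, 60]²: its objective must never
exceed the grid's. If the Jacobian at the solution has condition number
above 1e8 the estimate carries an `ill_conditioned` flag (collinear basis
rows cannot separate the analytes; the flag, not a failure, because the
clipped point estimate may still be usable).

Error metrics pool per-analyte absolute errors: every evaluated set
contributes |ĉ_g − c_g| and |ĉ_f − c_f| (water sets are scored against
0 g/l on both), and e_mean / e_rms / e_max are taken over the pooled
collection — 66 values for a standard 33-set experiment. The pooling rule
is isolated in `summarize_errors` so alternative conventions (per-set
Euclidean error, analyte-bearing sets only) are one-line changes.

## Synthetic data

The simulator generates reflectance(ν) = plasmon(ν)·(1 + Σᵢ hᵢ Lᵢ(ν)) + ε
with hᵢ = kᵢ + φᵢ(c_g) + ψᵢ(c_f), a broad Lorentzian plasmon (centre
1060 cm⁻¹, HWHM 150 cm⁻¹, amplitude 0.9) and narrow vibrational lines
(HWHM 2.5 cm⁻¹) at 1034, 1063, 1078 and 1080 cm⁻¹ — four lines although
the panel evaluates three, reproducing the 1078/1080 overlap problem. The
default truth coefficients put peak modulations at 50 g/l at a few percent
of reflectance with water constants near 0.01, monotone on the calibrated
range; replicate noise is i.i.d. Gaussian with SD 0.002 (0.2% of unit
reflectance), chosen so that after 30-replicate averaging the water-set
Δs dispersion is comparable to the spread of the water constants
themselves. The standard experiment is 3 cycles × 11 sets × 30 replicates
(990 spectra) on a 900–1200 cm⁻¹ grid at 1 cm⁻¹; water flushes open,
close, and separate all analyte sets. The mixed cycle's concentration
pairs — (10,10), (25,25), (50,10), (10,50), (25,10) g/l — are a documented
stand-in respecting the 60 g/l maximum total.

Two deliberate design choices:

- **Multiplicative imprint.** Because the lines multiply the plasmon curve,
  dividing by the true plasmon recovers 1 + Σ hᵢLᵢ exactly in the
  noiseless limit, giving every pipeline stage an analytic ground truth.
- **Gaussian lineshapes by default.** Gaussian tails vanish below machine
  precision outside the [1000, 1100] cm⁻¹ exclusion window, so the data the
  baseline smoother actually weighs is analyte-independent and the fitted
  baseline is identical across solution conditions. That is what makes the
  zero-noise end-to-end recovery exact (e_rms ~ 1e−13 g/l): the
  ALSS baseline introduces a fixed per-wavenumber offset and scale that
  the calibration absorbs into k̂ᵢ and the fitted coefficients. A
  `lorentzian` lineshape variant is available; its heavier tails leak
  outside the window, couple the baseline weakly to concentration, and
  degrade the exactness to a realistic systematic — useful for robustness
  studies, not for oracle tests. True SEIRA lineshapes are asymmetric
  (Fano-type); neither variant models that.
- The exact-recovery configuration (`SimTruth.separated()`) additionally
  drops the 1080 cm⁻¹ interferent: with overlapping lines the peak argmax
  can migrate between grid points as concentrations change, and the
  effective concentration→height map then leaves the additive-polynomial
  family that "exact" presupposes. The 4-line default is used everywhere
  realism matters.

What passing simulation tests does *not* show about real measurements: no
drift or residue carry-over between sets (the reason k is cycle-local is
real data, not the simulator), no Fano asymmetry, no wavenumber-correlated
noise, no detector nonlinearity. Recovery numbers on synthetic data
characterise the algorithm under its own assumptions, not instrument
performance.

## Problem sizes

Default test and acceptance runs use the full standard experiment (33 sets,
990 spectra of 301 points); a handful of structural tests shrink replicate
counts to 1–5 since replicate multiplicity is irrelevant to what they
check. The inversion-oracle comparison uses 50 random instances against a
6001² exhaustive grid, evaluated blockwise via the separable structure of
the objective.

## Known limitations

- λ is grid-spacing dependent (index-based differences); resampled data
  needs re-tuning.
- The polynomial order interface accepts orders 1–3 only; arbitrarily
  shaped bases (exponential, spline) would require generalising `fit_basis`
  and the model serialisation.
- No uncertainty quantification on the concentration estimates; the
  objective value and the ill-conditioning flag are the only quality
  signals.
- Concentrations below 10 g/l are extrapolation territory for the default
  calibration designs.
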