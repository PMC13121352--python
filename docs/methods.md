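# Methods

## Models

**Soil physical state.** All mass↔volume conversions take water density as
1.0 g cm⁻³. Total porosity comes from the saturation-mass route
TP = (m_sat − m_dry)/V when both masses are recorded, else from the
particle-density identity TP = 1 − BD/PD (PD defaults to 2.96 Mg m⁻³, the
solid-phase density of the very clayey Oxisol the defaults describe; the
Proctor maximum bulk density defaults to 1.53 Mg m⁻³). Each derived record
states which route was used. Volumetric water content is θv = w·BD,
air-filled porosity TP − θv, saturation degree S = 100·θv/TP, and degree of
compactness DC = 100·BD/BD_Proctor — the latter adopted as the operational
definition because it reproduces the reference whole-percent values (72% at
BD 1.10, 82% at 1.26). θv may exceed TP by up to a configurable tolerance
(default 0.02 m³ m⁻³) before a record is rejected; any excess is flagged
as over-saturation rather than silently truncated, since real tables carry
measurement noise. Elongation rate is the mean primary-root length of the
(up to two) seedlings divided by the growth duration in days (default 87 h).

**Penetration resistance.** Qp = a·BD^b·w^c with w *gravimetric*
(kg kg⁻¹) by default: the published per-structure coefficient sets are only
consistent with gravimetric water contents in the 0.2–0.45 kg kg⁻¹ range,
although power-law formulations elsewhere sometimes use volumetric θ; a
`water_content_variable` field records the choice. Fitting is
Levenberg–Marquardt on the MPa scale, initialised at the exact OLS solution
of log Qp = log a + b·log BD + c·log w. That log-linear solution is also
the test oracle: on noise-free data the two must agree to solver tolerance.
Identifiability requires ≥ 6 samples with ≥ 2 distinct BD and w values.
Standard errors come from the Jacobian at the optimum; R² is reported both
in the ratio convention 1 − SSE/SS_reg used alongside the published
parameter tables and as the conventional 1 − SSE/SST (`r2_classic`).

**Elongation surface.** Re(Qp, S) = a·exp(−½[((S−x₀)/b)² + ((Qp−y₀)/c)²]).
x₀ and y₀ are unconstrained in sign — the packed-structure optimum lies at
negative Qp, i.e. outside the physically reachable quadrant, and
constraining it would make that fit unreachable. Because both published
optima sit outside the observable data cloud, the amplitude a trades off
against (y₀, c) along a nearly flat cost valley: very different parameter
vectors produce almost identical surfaces over the data hull. Consequences
adopted here:

- fits use seeded multi-start (default 20 starts; amplitude in
  [max Re, 10·max Re], x₀ within the S range ± one range-width, y₀ from
  min Qp − 3 range-widths up to max Qp, widths from the data spread), with
  a cheap exploration pass (tolerance 1e-8, 400 evaluations) followed by a
  tight polish (1e-10) of the best candidate;
- among candidates tied within 0.1% in cost, the least-extrapolated
  optimum (closest to the data bounding box, distances normalised by the
  data ranges) is preferred, so reported optima stay interpretable;
- a polish stopping on its evaluation budget rather than the gradient test
  is accepted when its cost has not increased — in a flat valley the
  gradient test may simply never trigger;
- recovery of fitted surfaces is judged on predicted values over the data
  hull (max |ΔRe|), not on raw parameter equality, and the optimum
  coordinates are assessed for bias against their Monte-Carlo spread
  rather than per-fit linearised standard errors, which understate
  uncertainty along the valley.

Re is strictly positive and may exceed 1 near a fitted peak; clamping to
[0, 1] is available but off by default, and comparison grids flag nodes
with Re > 1. Relative elongation is obtained from absolute rates either by
the per-group maximum (default; its maximum output is exactly 1) or by an
explicit reference rate — the normalisation the original analysis used is
not recoverable, so neither mode hard-codes a denominator. Stress
reductions are 100·(1 − Re(to)/Re(from)) along one axis; structure
contrasts default to the studied window Qp ∈ [0.5, 4] MPa, S ∈ [50, 90]%.

**Evaluation.** RMSE, CRM = (ΣO − ΣP)/ΣO, Pearson r with population
(1/n) standard deviations in numerator and denominator (the ratio is then
convention-independent), and the classic 0–1 Willmott index
d = 1 − Σ(P−O)²/Σ(|P−Ō|+|O−Ō|)². Undefined metrics (zero variance, zero
observed sum, zero potential error) are reported as missing and flagged,
never as 0. The fit/validation split is stratified by matric potential —
an unstratified 70/30 draw could strip whole hydric levels from either
set — with largest-remainder allocation so the overall fit count equals
round(0.7·n) (77/33 for 110 samples) while every stratum stays within one
sample of its own 70% target; strata smaller than two go wholly to the fit
set with a warning semantic rather than an error.

## Synthetic experiment generator

The generator is the package's stand-in for the undeposited field data and
defines the conditions under which the pipeline is validated: 110 Field
columns (bulk density truncated-normal, mean 1.18, sd 0.10, bounds
[1.00, 1.45] Mg m⁻³ — a wide compactness range) and 90 Packed columns (six
levels 1.02–1.42 Mg m⁻³ × 3 replicates), each equilibrated at one of five
matric potentials {−10, −60, −100, −1000, −5000} hPa, i.e. 22 and 18
columns per potential respectively. Water content comes from a synthetic
van Genuchten curve (θr 0.25, θs 0.65, α 0.10 hPa⁻¹, n 1.25); the real
study published no retention data, so these are package choices, exposed
in config and selected so that the saturation cloud spans the studied
50–90% window and sits near 78% at −60 hPa and ~92% at −10 hPa, as a
structured clayey Oxisol with early-draining macropores would. Each row's
θs is capped at its own porosity 1 − BD/PD so S ≤ 100% by construction.
True resistance comes from the per-structure Busscher truth (published
parameter sets by default), true relative elongation from the truth
surface; noise is additive Gaussian on measured Qp (sd 0.10 MPa, floored
at 1 kPa) and on Re (sd 0.05, truncated at 0) — the simplest model
consistent with the scatter such experiments show. Re converts to rates
via a reference of 4.83 cm d⁻¹, inferred from paired published
(relative; absolute) values rather than stated anywhere. Dry and saturated
masses are generated consistently with the particle-density porosity, so
both porosity routes agree exactly on synthetic tables.

What the generator does **not** emulate: within-sample seedling variation,
depth profiles of resistance, retention hysteresis or structure-specific
retention (per-structure offsets default to zero), heteroscedastic or
non-Gaussian noise, and any biological mechanism (hypoxia, biopore
recolonisation). Passing recovery tests therefore demonstrate that the
estimation chain is consistent and calibrated under these idealised
conditions, not that the fitted models describe any particular field soil.

## Recovery protocol and problem sizes

`recovery_experiment` runs, per replicate: generate → 70/30 stratified
split within structure → Busscher fit on measured Qp → calculated Qp from
that fit → surface fit → validation metrics on the held-out 30%, plus the
maximum deviation between fitted and truth surfaces over the replicate's
own (Qp, S) cloud. Replicate seeds are spawned from the config seed. The
shipped studies use the full 200-column design with 20 replicates for the
noise-calibration checks and single replicates for noise-free closure;
noise-free closure is exact to machine precision, and at Re-noise sd 0.05
the mean validation RMSE tracks the injected sd within a few percent.

## Numerical choices and degenerate inputs

Busscher convergence tolerance 1e-10 on parameter change, ≤ 200 iterations;
surface polish tolerance 1e-10. Degenerate designs (constant regressor,
too few distinct stress levels, < 6 resp. < 10 rows) raise typed errors
rather than returning garbage fits; w ≤ 0 in the power law raises a domain
error naming the singularity; an all-zero rate vector with no reference
raises rather than dividing by zero. Reported tables round Re to 2
decimals and percentages to whole percent, matching the precision of the
reference values; internal computation is double precision throughout.

## Known limitations

- Parameters of the elongation surface other than the fitted values at
  observable stress levels should not be interpreted individually; the
  amplitude in particular is not comparable across structures.
- The Busscher water-content variable defaults to gravimetric; feeding
  volumetric contents without switching the config will bias the exponents.
- The pipeline's default normalisation (per-structure maximum rate) makes
  the fitted amplitude scale with the best-performing sample; use the
  reference mode for cross-experiment comparability.
- The generator's retention curve is synthetic; absolute saturation values
  in simulations carry no field meaning.
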