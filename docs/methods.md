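# Methods

## Problem and data model

A moisture sorption isotherm relates the equilibrium moisture content
(EMC, `X_eq`, % dry basis) of a hygroscopic material to the water activity
`a_w` of the surrounding air at fixed temperature. The package analyses
tabular sorption records — one `(sample, mode, T, a_w, X_eq)` observation
per row — grouped into per-temperature isotherm series. The packaged
reference dataset covers five sweet-cherry cultivars, desorption and
adsorption, at 30/40/50 °C, with six salt-fixed water activities per
temperature (KOH up to BaCl₂·2H₂O, `a_w` ≈ 0.057–0.898). Moisture is
stored in % dry basis exactly as tabulated; temperatures in °C. Kelvin
conversion (`T + 273.15`) and fractional moisture happen only inside the
thermodynamic operations.

## Isotherm models

Three classical equations, all passing through the origin:

- **GAB** (3 parameters): `X_eq = A·B·C·a_w / [(1 − B·a_w)(1 − B·a_w + C·B·a_w)]`
  with `A = X_m` the monolayer moisture (% d.b.), `B = K ∈ (0,1)` the
  multilayer factor and `C` the Guggenheim energy constant. This is the
  standard denominator; it is the form whose θ/a_w integral yields the
  closed-form spreading pressure below, and whose amplitude admits the
  monolayer reading used for surface areas. (Typeset variants with a
  `1 − B·a_w − B·C·a_w` second factor degenerate to a two-parameter
  hyperbola under least squares and place a pole inside (0, 1) for steep
  isotherms, which would break the spreading-pressure integral; they were
  therefore rejected.)
- **Peleg** (4): `X_eq = A·a_w^C + B·a_w^D`. No ordering constraint is
  imposed on the exponents; the optimizer may find either branch.
- **Enderby** (4): `X_eq = [A/(1 − B·a_w) + C/(1 − D·a_w)]·a_w`, read as the
  sum of two hyperbolic terms times `a_w` — the only four-parameter parse
  of the printed expression valid on the whole activity range.

All inversions and integrations are capped at `a_w = 0.95`: beyond the
last design point the fitted curve is extrapolation.

## Fitting protocol

Parameters minimise the plain (unweighted) sum of squared deviations, via
bounded trust-region least squares (`scipy.optimize.least_squares`,
`trf`), tolerances 1e−10, evaluation budget 5000 per start. Because the
objective is multimodal, a fixed data-adaptive start grid is used
(deterministic multi-start; identical input ⇒ identical output):

- GAB: `A ∈ {x̂, x̂/2, 2x̂}` with `x̂` the observed moisture nearest
  `a_w = 0.32`; `B ∈ {0.5, 0.7, 0.9}`; `C ∈ {1, 5, 20}`.
- Peleg: `A = x̂`, `B = x_last − x̂`, `C ∈ {0.5, 1}`, `D ∈ {2, 5}`.
- Enderby: `A = C = x̂(0.3)/2`; `B, D ∈ {0.3, 0.7, 0.9}`.

Bounds: GAB `A ∈ (0, 10⁴]`, `B ∈ (0, 1)`, `C ∈ (0, 10⁶]`; Peleg all
positive with exponents ≤ 50; Enderby `B, D ∈ (0, 1)` with signed
amplitudes. The upper caps are numerical necessities of the bounded
optimizer, far outside any physical moisture value. Some steep isotherms
drive the GAB optimum onto the BET-saturated ridge (`C → ∞`) or the
degenerate low-`C` ridge (`A → ∞`, `A·C` finite); on a ridge the
amplitude is not statistically identifiable and the reported `A` (and any
monolayer-derived quantity) should be read with that caveat. Runs that
exhaust the evaluation budget without formally converging are kept as
fallback candidates but flagged unconverged.

Goodness of fit: `r = sqrt(Σ(X_pred − X̄_exp)² / Σ(X_exp − X̄_exp)²)`
clipped to [0, 1] (the square root of the regression-to-total
sum-of-squares ratio, the convention of the sorption literature), and the
mean relative error `MRE = (100/N)·Σ|X_exp − X_pred|/X_exp`, with
zero-moisture points excluded from the MRE. A fit is acceptable when
MRE ≤ 10 %. Model selection ranks converged fits by `r` (compared to
3 decimals) and breaks ties by lower MRE; the overall winner across a
dataset is the modal per-series winner, ties broken by lower mean MRE.

## Thermodynamic properties

At constant moisture, the Clausius–Clapeyron relation gives
`ln a_w = −(q_st/R)(1/T) + ΔS/R`. For each moisture level on a grid
(default 10–30 % d.b. in 1 % steps, bracketing the 14–24 % band where the
curves vary most sharply), the water activity at each temperature is
obtained by numerically inverting the fitted GAB isotherm (bracketed root
finding to ~1e−15; model inverses are used rather than raw-data
interpolation because only six raw points exist per series), and an OLS
line of `ln a_w` on `1/T` yields the **net** isosteric heat
`q_st = −R·slope` (kJ/mol; the latent heat of pure water is not added)
and differential entropy `ΔS = R·intercept` (J mol⁻¹ K⁻¹), with
`R = 8.314 J mol⁻¹ K⁻¹`. Grid points not attainable at every temperature
are dropped with a warning.

Gibbs free energy: `ΔG = R·T·ln a_w`. Polynomial smoothing of
`q_st(X_eq)` and `ΔS(X_eq)` is cubic by default (degree configurable); the
smooths are reporting artifacts only — downstream regressions use the raw
grid values.

**Enthalpy–entropy compensation:** OLS of `q_st` (J/mol) on `ΔS` across
the grid. Slope = isokinetic temperature `T_β` (K); intercept = `ΔG_β`
(J/mol). The process is spontaneous iff `ΔG_β < 0`. Compensation is
deemed credible when `T_β` differs from the harmonic mean temperature
`T_hm = n/Σ(1/T_i)` by more than 0.1 % (the simple inequality test; a
Krug-style confidence band is out of scope).

## Surface properties

Spreading pressure `π(a_w) = (k_B·T/A_m)·∫₀^a_w θ(u)/u du` with
`θ = X_eq/X_m`, `k_B = 1.380×10⁻²³ J/K`, `A_m = 1.06×10⁻¹⁹ m²`. Under GAB
the integrand is `B·C/[(1 − B·u)(1 − B·u + C·B·u)]`, whose antiderivative
gives the closed form `π = (k_B·T/A_m)·ln[(1 − B·a_w + C·B·a_w)/(1 − B·a_w)]`.
An adaptive-quadrature evaluation of the defining integral serves as an
independent oracle; the two agree to 1e−8 relative over broad parameter
sweeps (a central correctness property of the module). Curves are
reported on `a_w ∈ {0.05, …, 0.90}`.

Sorption surface area: `S₀ = M_m/PM_H₂O · N₀ · A_H₂O = 3.5×10³·M_m`
(m²/g dry solid) with `M_m = A/100` the fractional GAB monolayer.

**Optimal storage humidity:** each desorption isotherm is smoothed by a
least-squares cubic `X_eq = c₃a³ + c₂a² + c₁a + c₀`; the inflection
`a_w = −c₂/(3c₃)` marks the curvature change between the two sigmoid
limbs and is reported (with the moisture the cubic predicts there) as the
storage optimum. The reported pair uses the highest-temperature
desorption series and is flagged `method_inferred`: which
temperature/mode underlies the published single pair per cultivar is not
derivable, so these pairs are comparison references, not strict targets.

## Synthetic data generator

Emulates the static-gravimetric design: GAB truth with amplitude
decreasing in temperature (defaults `A = 12/9/7` % d.b. at 30/40/50 °C,
`B = 0.85`, `C = 8` — a typical type-II sugar-rich-fruit configuration),
design activities equal to the salt-reference values per temperature, and
multiplicative Gaussian noise (`σ = 0.02` by default, the relative
repeatability of a sorption balance), truncated at ±3σ and floored at
0.1 % d.b. so small moistures stay positive. Fixed seed ⇒ byte-identical
output. The generator does **not** emulate hysteresis (desorption and
adsorption would be generated independently), inter-replicate drift, or
temperature-dependent design activities beyond the tabulated salts — so
passing recovery tests demonstrate estimator correctness under the
assumed noise model, not robustness to structured measurement error in
real gravimetric data.

The recovery study (200 replicates at σ = 0.02 by default) refits each
replicate and reruns the downstream pipeline, reporting bias, RMSE and
median absolute relative error for the GAB parameters and for `q_st` at
18 % d.b., `T_β` and `S₀`; since `S₀ = 35·A`, its relative error equals
the amplitude's exactly.

## Numerical choices and degenerate inputs

- Root finding: Brent's method on (0, 0.95]; targets outside the
  attainable moisture range raise and are excluded from grids.
- `r` is clipped to [0, 1]; a zero total sum of squares yields `r = 1`.
- Compensation requires ≥ 3 grid points and a non-degenerate ΔS spread.
- Cubic storage fits require ≥ 4 points and a non-vanishing cubic term.
- All report CSVs print 4-decimal floats; the JSON summary retains full
  precision; reruns are byte-identical.

## Known limitations

- On the packaged cherry dataset, several printed summary statistics of
  the original study are not reproducible from the printed isotherm
  table itself: the tabulated low-activity moistures bound the GAB
  amplitude from below at roughly three times the value the printed
  surface areas imply, and the best attainable mean relative errors for
  some series exceed the printed ones. The pipeline reports what the
  data actually yield; the acceptance suite records the disagreements
  rather than masking them.
- Parameter uncertainty is not quantified (no confidence intervals on
  fitted parameters or derived thermodynamic quantities).
- Hysteresis is summarised only pointwise (desorption minus adsorption
  moisture); no loop-area statistic is computed.
- Problem sizes used throughout (6 points per isotherm, 3 temperatures,
  21-point isosteric grid, 200 recovery replicates) mirror the study
  design and keep the full analysis in the minutes range on one CPU.
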