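# Methods

## The model

`esrkit` estimates the 1-hour Westergren erythrocyte sedimentation rate
(ESR) from a 5-second optical aggregation measurement and the hematocrit.
The physical backbone is Stokes' law for a sedimenting particle, modified
in three ways:

1. **Hindered settling.** In a concentrated suspension the settling
   velocity is reduced by the Richardson–Zaki factor
   `phi(Ht) = (1 − Ht)^n`, with `n = 4.65` in the low-Reynolds-number
   regime relevant to blood.
2. **Aggregation kinetics.** Red cells form rouleaux and then
   three-dimensional aggregates; the effective particle radius grows as
   `Ragg(t) = Ref (1 + alpha (1 − exp(−t/lambda)))` (Oka's saturating
   model), where `alpha` is the dimensionless aggregate size parameter
   and `lambda` [s] the growth time constant.  The interface velocity is
   `v(t) = v_Stokes · phi(Ht) · (Ragg(t)/Ref)^2`, which integrates in
   closed form to the lag/constant-phase distance

   ```
   h(t) = v_Stokes · phi · [ (1+a)^2 t − 2a(1+a) L (1 − e^{−t/L})
                             + (a^2 L / 2)(1 − e^{−2t/L}) ]
   ```

   (`a = alpha`, `L = lambda`).  This expression is certified in the test
   suite against adaptive quadrature of the velocity over an 81-point
   parameter grid to a relative tolerance of 1e−8 — that check also
   pins down the coefficients, which are easy to mistype.
3. **Packing phase.** Beyond the empirical transition time
   `tau = 10.317 · Ve^−0.57` (Ve in mm/min, tau in min) the deposited
   cells slow the interface, which relaxes exponentially toward the
   maximum settling distance `h_inf = 102 (1 − 0.8 Ht) alpha^0.2` [mm].
   The packing branch is anchored at the instantaneous velocity at tau,
   making the assembled curve value- and slope-continuous there (tested
   to 1e−9 mm and 1e−6 mm/min).

**Unit regimes.** The Stokes kernel is evaluated in SI (m, s); the
empirical transition/packing/`h_inf` relations are evaluated in clinical
units (mm/min, min, mm) — their coefficients are only meaningful on that
scale (e.g. `h_inf ≈ 70–100` must be mm on a 200-mm tube).  All
conversions happen at the `build_curve` boundary. `g = 9.81 m/s²` is
adopted; the remaining constants are literature values
(`rho_e = 1100`, `rho_p = 1025` kg/m³, `Ref = 3.084e−6` m,
`mu_p = 1.64e−3` Pa·s).

## The optical side

A syllectogram is the transmitted-light intensity after abrupt flow
cessation; it dips to a minimum `I_MIN` (complete dispersion) and rises
as aggregation clears the optical path.  The aggregation index over a
window of T seconds is the area ratio `AI_T = A/(A+B)` between the curve
and its bounding rectangle `[I_MIN, I_MAX] × [0, T]`.  Conventions:

- `I_MIN` is the single sample at the detected start (`detect_start`:
  global minimum in the first 2 s, earliest index on ties).  No local
  averaging is applied — averaging a rising curve at its boundary biases
  `I_MIN` upward far more than noise biases it downward.
- `I_MAX` is the **mean over the final 100 ms of the window** (default
  `window_end` mode), so `AI_T` is computable from a T-second record.
  The alternative `trace_end` mode references the end of the full record
  instead; it is exposed because the area definition is ambiguous in
  that respect, and the two differ systematically (the full-record
  reference deflates windowed AIs).  All calibration constants in this
  package refer to the `window_end` convention.
- Trapezoidal integration on the recorded 10-ms grid; `A + B` then
  telescopes exactly to `(I_MAX − I_MIN)·T`, which is asserted.
- Two detectors are averaged; a disagreement above 0.10 sets a QC flag
  (bubble artefact heuristic).  On noisy traces with an *unknown* start,
  the argmin selection gives `I_MIN` a small negative bias; traces whose
  acquisition is synchronized to flow stop should set `t0_index`
  explicitly, as the synthetic generator does.

The hematocrit correction `HAI = AI − k (Ht − 0.40)` (default
`k = 0.284`) removes the near-linear crowding contribution of the
hematocrit to the AI, referencing everything to Ht 0.40.

## Calibration chain and its fits

The forward pipeline is
`(AI5, Ht) → HAI5 → Vs → (alpha, Ve) → lambda → curve → ESR_1h` with

- `Vs = a (HAI5 − b)^4 + c` [m/s], `a = 0.0541`, `b = 0.426`; `c` is
  always the computed Stokes velocity, never fitted or stored.  Below
  the physiological floor `b` the (even) quartic would rise again, so
  `Vs` clamps to `c` with a warning.  The quartic is used because `Vs`
  scales as the square of the aggregate radius and the size parameter
  is, empirically, quadratic in HAI5.
- `alpha = sqrt(Vs/c) − 1`, `Ve = Vs · phi(Ht)`.
- `lambda = d·HAI5 + e·Ht + f` [min], `d = −0.816`, `e = 0.887`,
  `f = 0.357`, floored at 1 s (the plane goes negative for extreme
  inputs).

Fitting (`ESREstimator.fit` / the `fit_*` functions): `k` is the mean
over fibrinogen levels of the within-level OLS slope of AI5 on Ht;
`(a, b)` by nonlinear least squares with `c` fixed, performed in
Stokes-velocity units (`y = Vs/c`) because the raw targets are ~1e−6 m/s
and an unscaled fit stalls far from the optimum; `d` is the mean of the
per-Ht λ-vs-HAI5 slopes at Ht 0.25 and 0.30 (where settling is fast
enough for λ to be reliable), then `(e, f)` by OLS of `λ − d·HAI5` on
Ht.  Ordinary least squares throughout; the loss/weighting of the
original fits is not documented anywhere, so the plainest choice is
used.  On noiseless synthetic cohorts all six constants are recovered to
better than 1e−6 relative.

## Westergren analysis

- `wg_esr_1h`: the 60-min reading, linearly interpolated when the export
  has no exact 60-min row.
- `extract_ve` (auto mode): a two-stage reproducible stand-in for the
  manual practice of choosing the constant-velocity range.  Stage 1
  scans candidate windows (starts 1–25 min, ends 5–60 min, ≥5 readings)
  and keeps the R²-maximizing one (ties prefer the widest).  Stage 2
  refits over `[1, min(max(tau, 6), 60)]` min with tau recomputed from
  the current slope, iterated to a fixed point.  The refinement matters
  for fast settlers: at Ve > 3.5 mm/min the constant phase ends before
  5 min, and any fixed late window lands in the packing phase and
  underestimates Ve by tens of percent.
- `fit_lambda`: 1-D bounded least squares over λ ∈ [1, 600] s between
  the forward curve and the readings at t ≤ min(tau, 60) min, equal
  weights.  Samples with Ve < 0.1 mm/min are excluded: the 0.5-mm scale
  resolution dominates their early readings.  The λ search range covers
  the seconds-to-minutes scale on which the kinetics saturate; beyond
  t ≫ λ the curve is insensitive to λ.

## Synthetic cohort generator

`SyntheticSpec` reproduces the calibration study design: 2 donors ×
4 hematocrit levels (0.25/0.30/0.35/0.40) × 4 fibrinogen levels = 32
samples.  Each donor × fibrinogen cell draws one `alpha` (fibrinogen
level maps to a quartile of `alpha_range`, emulating fibrinogen-driven
aggregability) shared by its four hematocrit samples — the same plasma
drives aggregation at every hematocrit, which is also what makes the
AI-vs-Ht slope exactly `k` and the calibration exactly recoverable.
Generation inverts the calibration chain (`alpha → Vs → HAI5 → AI5`,
`Ve = Vs·phi`, true ESR from the forward curve), so ground truth is
exact at the AI level.

Defaults and why:

- `alpha_range = (0.5, 15.0)`.  Inverting the `Vs` regression at the
  calibrated constants over the clinically observed range (Ve up to
  ~4 mm/min, 1-h ESR up to ~100 mm) gives aggregate size parameters up
  to ~15; the lower edge produces slow settlers that trip the
  0.1-mm/min exclusion, as a few samples in a real cohort do.
- `lambda_mode = "regression"`: the time constant follows
  `d·HAI5 + e·Ht + f`, making the cohort coherent with the calibration
  (and exactly recoverable when noiseless); `"uniform"` draws λ
  independently from `lambda_range_s` for sensitivity studies.
- Noise defaults: 8 ADC counts of Gaussian intensity noise (modest
  electronic noise on a 12-bit scale), 0.5-mm reading quantization (the
  Westergren protocol resolution), ±0.1 mm uniform visual jitter, and
  0.01 SD of AI repeatability noise for table-level cohorts.
- The syllectogram family is a two-timescale saturating rise: a fast
  rouleaux component `1 − e^{−t/1s}` plus a slow component
  `(1 − e^{−t/6s})^2` whose sigmoidal onset lets windowed AI5 fall
  below 0.5 (a purely concave rise cannot).  The fast/slow amplitude
  split is solved numerically (Brent) so that `compute_ai` at 5 s hits
  the row's AI5 to 1e−3.  The family is a test harness with plausible
  shape, not a physiological model.

**What passing tests show — and do not.**  The synthetic study shows the
pipeline is internally consistent (exact inverse round trips, exact
calibration recovery, ESR recovery r > 0.95 under study-like noise) and
that every algorithmic step behaves as specified.  It does not show
clinical accuracy: real syllectograms have drift, bubbles and
temperature effects, real sedimentation deviates from the three-phase
model (notably the packing coefficients at high hematocrit), and the
generator's noise is by construction the noise the analysis assumes.

## Numerical choices and degenerate inputs

- Ties in start detection resolve to the earliest index; constant traces
  warn and return index 0.
- Degenerate traces (`I_MAX ≤ I_MIN`) raise instead of returning a
  meaningless ratio.
- `h_inf → 0` as `alpha → 0`, which would place the packing target above
  the front; `alpha < 0.01` triggers a validity warning, and the
  no-aggregation path never reaches the packing phase within 60 min for
  physiological hematocrits (tau > 100 min), so the curve stays in the
  analytic lag regime there.
- The quartic `Vs` fit runs in `Vs/c` units with tight tolerances; the
  sigmoid comparison fit (`fit_puccini`) is seeded from the observed
  half-height time.
- All randomness flows from one seeded `numpy` generator per entry
  point; identical seeds give byte-identical outputs.

## Known limitations

- **λ identifiability.**  With 0.5-mm readings at ≥1-min intervals, the
  lag-phase displacement signal (~`Ve·λ`) for λ of a few seconds is
  below the reading resolution, so re-fitted λ values on quantized
  series scatter widely (the predicted-vs-refitted λ correlation on the
  synthetic study is seed-dependent, ~0.35–0.7).  λ is reliable on
  near-noiseless curves (recovered to 1%) and for slower-settling,
  larger-λ samples.
- The transition-time and `h_inf` coefficients are fixed empirical
  values; no refitting procedure is provided, and they are known to be
  imperfect at high hematocrit in the packing phase.
- The windowed `I_MAX` convention is a documented choice; calibrations
  are not transferable between the `window_end` and `trace_end`
  conventions.
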