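# Methods

This note documents the models, numerical choices and limitations behind
`lysetrack`. It states how quantities are computed; every empirical claim
here is one the test suite itself computes.

## Signal model

A chromatogram is a uniformly sampled 280 nm absorbance trace,
`t = 0` at injection, nominally 5 Hz over 300 s (1500 samples). Grid
uniformity is enforced at load time with a relative spacing tolerance of
1e-6; anything worse is rejected rather than silently resampled, because
the alignment step assumes that one sample is one fixed time quantum.
`resample_to_grid` (linear interpolation, never extrapolating) exists for
the rare case of mixed acquisition rates.

## Alignment

Retention jitter between injections is modelled as a per-trace integer
sample shift. The reference is the elementwise arithmetic mean of all
traces in the set; each trace is then shifted by the integer
`s* = argmax_{|s| <= max_shift} corr(shift(x, s), reference)` with Pearson
correlation on the mean-subtracted compared window. Design choices:

* **Integer shifts only.** Sub-sample interpolation would change peak
  shapes and break the exact shift-recovery oracle; integration windows
  are tens of samples wide, so sub-sample residuals are immaterial there.
* **Edge replication** fills vacated samples, so no missing values reach
  the integrators. The affected margins are at the trace (or interval)
  ends, far from the peaks in a well-designed method.
* **Tie-breaking**: candidates are scanned in order of increasing `|s|`
  (negative before positive at equal magnitude) and only a strictly larger
  correlation replaces the incumbent — deterministic, least-intervention,
  and a no-op on an already aligned set. A zero-variance trace aligns with
  shift 0 and a warning.
* **Whole-trace by default**; independent per-interval shifting is
  available for runs whose FT and EL regions drift differently. Each
  interval must contain at least `2*max_shift + 1` samples.

Note that alignment is toward the *mean* of the set: for a pair
consisting of a trace and its 2-sample-delayed copy the recovered shifts
are `(+1, -1)`, not `(0, -2)`. Symmetric jitter therefore cancels; a
common systematic offset of all traces is deliberately not corrected
(it cancels in the ratio statistics).

**Resolution limit.** The exhaustive correlation argmax is the matched
filter, i.e. the maximum-likelihood estimator of an integer delay in
white noise. Its single-sample exactness degrades as peaks broaden: the
correlation drop between adjacent shifts scales as `(dt/sigma)^2`, so for
the simulator's default peaks (sigma 8–10 s at 5 Hz) and noise at 5 % of
peak height the exact-recovery probability is about 93 % (errors are
±1 sample, symmetric). Noiseless shifts within the search window are
always recovered exactly. Sharper peaks (sigma below ~5 s) restore
near-certain exactness; this is a property of the estimation problem, not
of the implementation.

## Integration and recovery statistics

ROIs are half-open `[start_s, end_s)` windows in seconds; an ROI may end
up to one sample spacing past the last sample (the natural half-open
cover of the grid). Integration is the composite trapezoid rule over the
samples inside the window plus linearly interpolated boundary values —
exact for piecewise-linear signals and within 1e-3 relative of a 1000×
finer Riemann sum for smooth peaks at 5 Hz (asserted in tests). Optional
baseline handling subtracts, per ROI, the straight line through the trace
values at the ROI endpoints; it is **off by default** since the
anion-exchange method's wash steps keep the baseline low. Negative areas
are clipped to zero with a warning — protein amounts cannot be negative,
and the clip only triggers when a window contains essentially noise.

Two normalizations coexist on purpose:

* `relative_recovery_eq2` (start-anchored span): forced to 0 % / 100 % at
  the first/last cycle, invariant under positive affine transforms of the
  area series. Undefined when first and last areas coincide.
* `normalize_end_anchored`: `value_i / value_last * 100`, invariant under
  positive scaling only. This is the convention of comparison tables in
  which the untreated sample shows its pre-released protein share
  (typically 10–15 %) and interior cycles may exceed 100 % by noise.

Viability-type signals use the mirrored `normalize_start_anchored`
(untreated = 100 %). `build_comparison` applies end-anchoring to protein
methods and start-anchoring to viability methods; columns are invariant
under per-method rescaling of the raw inputs, so unit choices are
irrelevant. The anchor is the *last cycle*, not the maximum — a noisy
intermediate cycle can therefore exceed 100 %, which is faithful to the
convention rather than a bug.

Biomass from optical density uses the fixed linear correlation
`DCW [g/L] = 0.451 * OD600` with an inverse helper; per-biomass
normalization (`auc / biomass`) makes runs at different cell densities
comparable before model fitting.

## Reference-analytics reductions

* **CFU**: `colonies / plated_volume * 10^(-dilution_exp)`; plate
  selection uses the standard 30–300 countable window, preferring counts
  near 100, ties toward the higher dilution. The rule is a configuration
  point, not biology.
* **Flow cytometry**: viable = total-membrane-dye events (RH414) minus
  depolarized-dead events (DiBAC4(3)); gating is assumed done upstream.
* **Dielectric spectroscopy**: mean over the logged window of
  (1 MHz capacitance − 10 MHz capacitance); at least 3 min of logging is
  enforced.

## Screening model

The design is a full factorial (pressure 500/1000/1500 bar × biomass
10/55/100 g DCW/L × cycles 0/1/2/3 = 36 runs, generation order
lexicographic). Factors are coded affinely to [-1, +1]; the symmetric
three-level factors code to {-1, 0, +1}, the four cycle levels to
{-1, -1/3, +1/3, +1}, and the coded main-effect columns of the full
factorial are mutually orthogonal.

The model family is intercept + linear main effects + all two-factor
interactions (switchable off) — the customary screening set; quadratic
terms are excluded because a screening, not an optimization, design is
being analyzed. Fitting is OLS (via statsmodels). Rank deficiency is
detected before fitting and reported with the names of the aliased terms
(QR column pivoting). Model quality:

* `R2 = 1 - SSE/SStot` (centered total sum of squares);
* `Q2 = 1 - PRESS/SStot` with `PRESS = sum_i (e_i / (1 - h_i))^2`, the
  closed-form leave-one-out residuals; the test suite verifies this
  against explicit n-fold refitting. Since `1 - h_i <= 1`,
  `PRESS >= SSE` and `Q2 <= R2` always. Saturated fits (leverage 1) get a
  warning and drop the undefined terms from PRESS.
* Two-sided p-values from the t distribution on `n - p` residual degrees
  of freedom.

`predict_surface` evaluates the fitted model over a 2-D grid with the
remaining factors fixed, warning (not failing) on extrapolation beyond
the coded range. The default contour slice is cycles × biomass at fixed
pressure, since pressure main effects are typically insignificant in this
range.

## Synthetic data

The simulator emulates exactly the features the pipeline must be robust
to, and nothing more:

* two Gaussian peaks (FT: center 60 s, sigma 8 s, area 400 mAU·s at full
  load; EL: 200 s, sigma 10 s, 600 mAU·s) whose areas scale linearly with
  the released-protein fraction;
* a linear baseline drift (default 1 mAU across the run), white Gaussian
  detector noise (default sd 0.2 mAU, about 1 % of the EL peak height)
  and a uniform integer retention jitter (default ±3 samples);
* cumulative release following geometric survival,
  `f(n) = f0 + (1 - f0)(1 - (1 - e)^n)`, with default per-cycle
  efficiency `e = 0.85` (one pass at 1500 bar releases ~85 %, saturating
  thereafter) and pre-lysed fraction `f0` to emulate freeze–thaw damage
  (`f0` doubled doubles the untreated sample's area).

All randomness flows from explicit per-call seeds (numpy `SeedSequence`
spawning for multi-trace experiments); identical seeds give bit-identical
traces. What the simulator does **not** model — peak tailing, carryover,
detector saturation, pressure- or biomass-dependent kinetics, product
degradation — bounds what passing tests demonstrate: the pipeline's
correctness on well-behaved two-peak runs, not robustness to pathological
chromatography.

`fit_disruption_kinetics` inverts the release model by bounded
least squares over `(e, f0, total-protein scale)`; on noise-free series
the per-cycle efficiency is recovered to well within 0.02 for
`e` in [0.5, 0.95].

## Problem sizes used in the test suite

Tests run the pipeline at the instrument's native scale (1500-sample
traces): 20-seed end-to-end replicates for the recovery-band check,
50 seeded shift recoveries, 100 random peaks against the fine-grid
integration oracle, and 200 replicates of the 36-run screening fit for
the null-pressure p-value calibration. The whole suite completes in a few
seconds.

## Known limitations

* Integer-sample alignment cannot beat the matched-filter resolution
  limit described above; broad peaks plus heavy noise yield occasional
  ±1 sample residuals (immaterial for window integration, but real).
* The end-anchored convention is undefined for experiments whose final
  cycle releases no protein; the tool errors rather than guessing.
* AUC is relative, not absolute, protein: no extinction-coefficient
  calibration is attempted.
* The CFU plate-selection rule and the FT/EL window proposal
  (deepest-valley split of the mean reference) are pragmatic conventions,
  both overridable by configuration.
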