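# Methods

## Model structure and assumptions

The package models a closed two-species iron redox loop. Total iron is
fixed (2 mM by default) and partitioned at all times between Fe²⁺ and
Fe³⁺; only (reducer density, oxidizer density, Fe²⁺) are integrated and
Fe³⁺ is derived as `fe_total − fe2`, so iron conservation holds exactly
rather than to solver tolerance. The model assumes a well-mixed batch
culture, no signalling delays, and no explicit resource limitation:
stationary phase enters only through the time dependence of the
per-cell rate coefficients.

Each coefficient is a *rate block*, `amplitude / (4PL-shaped
denominator)`, moving smoothly from `amplitude/early_denom` at t = 0 to
`amplitude/late_denom` as t → ∞. With a large denominator ratio the
transition in time occurs near `half_time · ratio^(−1/exponent)`, i.e.
well before the nominal half-time — a property worth keeping in mind
when reading parameter files.

The oxidizer's growth is driven by `fe_total − fe2`, the Fe³⁺-position
term of the printed equation system. This is arguably in tension with
the biology (the organism oxidizes Fe²⁺, so one might expect Fe²⁺ to
drive its growth); the package implements the equations as printed and
does not expose an inverted variant, because the packaged parameters
were designed and validated only for the printed form.

Two further structural consequences matter for users:

* **No intrinsic saturation.** The Fe²⁺ production term does not shut
  off as Fe²⁺ approaches the pool size, and consumption does not stop
  at zero. Admissible trajectories are those whose parameters keep Fe²⁺
  inside [0, fe_total]; the simulator clamps small excursions in
  post-processing and flags any clamp above 10⁻⁶ mM in the trajectory
  metadata.
* **Autocatalytic coupling.** Fe²⁺ feeds reducer growth, which feeds
  Fe²⁺ production. Parameter sets with simultaneous strong growth and
  strong late production are unstable (finite-time blow-up). The fitter
  treats failed integrations as large finite residuals so optimization
  retreats from such regions instead of aborting.

## Default parameter set

No numeric rate constants are available for the co-culture system, so
the package ships a reference set (`redoxlan.defaults`) designed around
the documented dynamics: Fe²⁺ rises from 0 to an interior maximum of
0.76 mM mid-incubation of a 96-h run and declines thereafter; both
densities grow monotonically from a 0.01 OD₆₀₀ inoculum (1 % transfer
of an OD 0.8 seed culture) to order-1 OD₆₀₀.

The design separates the dynamics into phases so that the autocatalytic
loop stays weak: reducer Fe²⁺ production is strong early
(1.348 mM OD⁻¹ h⁻¹) and shuts down ~2000-fold around 30 h, before the
reducer population is large; reducer growth (0.155 h⁻¹ per mM Fe²⁺)
runs until ~58 h, after production has stopped, so late growth no
longer feeds back into the pool; oxidizer consumption is negligible
early and ramps 30-fold to 0.03 mM OD⁻¹ h⁻¹ between ~22 and 50 h,
producing the decline phase without driving Fe²⁺ negative by 96 h.
Growth coefficients decay late (100-fold and 25-fold) to give
stationary phase. The single numerically tuned constant is the
production amplitude J_S, solved by bisection against the 0.76 mM peak
(`scripts/derive_default_parameters.py`); all other constants are round
design values.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with the Dormand–Prince
  RK45 pair, rtol 1e-8 / atol 1e-10 by default. Halving tolerances
  moves the default trajectory by < 1e-5 on every channel.
* 4PL fitting: trust-region reflective least squares. Initialization
  when none is given: A ← earliest value, B ← latest value, C ← time of
  closest approach to the midpoint, D ← 2. Default bounds keep
  C ∈ (0, 10·t_max] and D ∈ (0, 20] to prevent divergence on flat
  data. Constant data are flat in (C, D); the fit returns the canonical
  tie-break C = median(times), D = 1, flagged `degenerate`.
* Co-culture fitting: free parameters are addressed by letter symbol
  (E_S, …, N_R); each observed channel is standardized by its observed
  range (not variance — more robust on 9-point series) before residual
  pooling. Bounds are multiplicative around the initialization
  (×1/3 … ×3 by default). Loss is unweighted least squares.
* The full 20-constant joint fit on a single-condition time course is
  ill-posed. The intended workflow fixes the Fe-rate blocks from
  monoculture pre-fits and frees growth parameters; the recovery
  experiment defaults to freeing the two growth amplitudes (E_S, E_R),
  which are well identified by the OD channels.
* Calibration: raw intensities are log₁₀-transformed before fitting;
  zero or negative intensities are rejected rather than offset-shifted.
  Inverse predictions outside the convention range are clipped and
  flagged, not rejected, since noise can push readouts slightly past
  the calibrated endpoints. The ratio convention defaults to percent
  (0–100): the reference slope 0.01764 spans a plausible log-intensity
  range (2.126–3.890) only on that scale; the fraction convention is
  selectable.
* Correlation p-values use the t transform with n−2 degrees of freedom;
  no multiple-testing correction is applied.

## Synthetic data

The generator emulates the study's measured channels: Fe²⁺ (mM),
per-species OD₆₀₀, raw nanoprobe luminescence, and a
phenanthroline-style absorbance channel. Concentration and OD channels
carry additive Gaussian noise; raw intensity carries multiplicative
log-normal noise (positive, spans a decade); absorbance is an affine
map of Fe²⁺ (0.35 AU/mM + 0.02 AU, round plate-reader-scale values)
with additive noise. Noisy Fe²⁺ is truncated into [0, fe_total] with
the truncation count logged; OD channels are left untruncated.

Default noise magnitudes — od_sd 0.02, fe2_sd 0.08 mM, lum_cv 5 %,
abs_sd 0.01 AU — are calibrated so the recovery experiment lands at the
fidelity levels the validation targets (median fitted-trajectory
correlation ≈ 0.90+ on Fe²⁺, ≈ 0.99+ on OD); true replicate noise
magnitudes were not available to estimate. The default sampling grid is
0–96 h every 12 h.

What passing tests do *not* show about real data: the generator draws
noise from the same model family the fitter assumes (no model
misspecification), uses a single condition (no initial-iron titration),
and treats per-species OD as directly observable, whereas a real
co-culture yields one total OD₆₀₀ unless species are resolved by
plating, FISH or flow cytometry. Recovery results are therefore a
best-case bound.

## Problem sizes

The recovery experiment uses 25 seeds, 9 time points and 2 free
parameters; the calibration recovery uses 100 replicates of 6-point
curves; the refit oracle sweeps 50 random 4PL truths. These sizes give
stable medians while keeping the full suite fast.

## Known limitations

* Monotone rate blocks cannot represent rise-then-fall per-cell rates;
  the decline of the Fe²⁺ pool must come from population growth.
* The model is valid only while Fe²⁺ stays within the pool bounds; the
  simulator clamps and flags, but does not project, out-of-range
  states.
* Three-species consortium dynamics, electron-shuttle amendments,
  inhibitor effects and product (lycopene) yield are out of scope; no
  equations are defined for them here.
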