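# Methods

## The interference model

`rfdmodel` implements a theoretical dose-response model for the acute
interference of aerobic exercise with rate of force development (RFD). RFD
is taken as the initial slope of an isometric mid-thigh-pull (IMTP)
force-time curve, in N·s⁻¹ — the standard force-plate measure of explosive
strength in weightlifters. The predicted RFD after a single aerobic bout of
duration *d* minutes is

    RFD_aerobic(d) = RFD0 * [1 - kappa * (1 - exp(-alpha * (d - d0)+))]

with `(x)+ = max(x, 0)`. The model's assumptions, in plain terms:

- **Duration is the dose.** The aerobic bout's duration is the only driver;
  intensity, modality (the model is framed around running) and individual
  variability are not modeled.
- **RFD is the sensitive quantity.** Aerobic work is assumed to degrade the
  fast neural contribution to force production; peak force is untouched.
- **Loss saturates.** The decline is exponential in duration: steep below
  ~10 min, approaching a ceiling thereafter. `kappa` caps the maximal
  fractional loss; `alpha` sets how fast the cap is approached; `d0` is a
  short grace period with no predicted decline.
- **Acute only.** The prediction describes an IMTP performed shortly
  (within ~1-2 h) after the bout. Recovery kinetics, repeated bouts and
  chronic training adaptation are outside the model.

The model is not calibrated against experimental data (none exist for this
population); it is a coach-tunable projection, and every numerical claim in
this package is a property of the closed form, not of any athlete.

### Parameters

| name    | units  | default | role |
|---------|--------|---------|------|
| `rfd0`  | N·s⁻¹  | 15000   | baseline peak RFD; 15000 represents a highly trained weightlifter. Scales predictions linearly; percent loss is independent of it. |
| `kappa` | —      | 0.8     | maximal fractional loss (at most 80% of baseline RFD can be lost); the large-duration floor is `rfd0*(1-kappa)`. |
| `alpha` | min⁻¹  | 0.3     | rate constant; at 0.3 the loss reaches ~73% of baseline by 10 min and is within 0.5% of the cap by 20 min. |
| `d0`    | min    | 2       | onset delay; `d <= d0` predicts no change (the positive-part operator zeroes the exponent). |
| `d_max` | min    | 60      | supported duration domain. Longer durations are accepted with an `ExtrapolationWarning` rather than an error: the closed form is well defined and 60 min marks the simulated range, not a mathematical bound. Negative durations are rejected. |

Parameters are validated once, at construction of `InterferenceParams`
(errors name the offending field); all operations are pure functions of
validated parameters, and everything in `model.py` and `sensitivity.py` is
deterministic IEEE-double arithmetic.

### Linear comparison variant

The linear variant used for model comparison is not part of the prediction
equation; it is constructed to share the nonlinear model's endpoints:
`rfd0` at `d0`, descending along the chord to the floor `rfd0*(1-kappa)` at
`d_max`, clamped outside. This makes the two shapes directly comparable.
One subtlety: the exponential has not *reached* the floor at `d_max` — it
sits above it by the terminal gap `rfd0*kappa*exp(-alpha*(d_max-d0))`
(0.33 N·s⁻¹ at the defaults, larger for small `alpha`). The "exponential
below its chord" bound therefore holds up to that gap, which is how the
tests state it.

### Display rounding

Predicted RFD is conventionally reported to the nearest integer N·s⁻¹ and
percent loss to the nearest integer percent (athlete-profile examples to
1 decimal). Full double precision is always retained internally and in
CSV/JSON output; rounded values are derived properties. Two rows of the
conventional reference table are known rounding inconsistencies of the
source table rather than of the model: the closed form gives 3002.698 N·s⁻¹
at d=30 (rounds to 3003, printed 3002) and 47.47% at d=5 (rounds to 47,
printed 48). Tests compare rounded values within ±1 in the last digit at
those rows and exactly elsewhere.

## Simulated force-time curves

`forcetime.py` generates IMTP-like traces whose initial slope equals a given
RFD, so interference predictions can be visualized as a flattening curve
family. The functional form is a mono-exponential rise to a plateau,

    F(t) = F_peak * (1 - exp(-(RFD / F_peak) * t)),

chosen as the simplest saturating curve whose analytic derivative at t=0 is
exactly the supplied RFD. Defaults: plateau 4000 N (a strong athlete's IMTP
peak force), 5 s trial sampled at 1 kHz (typical force-plate configuration).
Aerobic exercise scales the slope only; the plateau is shared across the
family by default (a `peak_scale` knob exists for exploring a lowered peak,
but nothing in the model predicts one). What the simulator does *not*
emulate: neuromuscular drive dynamics, onset-detection ambiguity, drift,
filtering artifacts — so round-trip tests validate the estimator's
arithmetic, not its behavior on real plate data.

Optional measurement noise is additive zero-mean Gaussian force noise
(default SD 0; 20 N is used in tests as a plausible plate-noise scale) from
`numpy.random.default_rng` under an explicit integer seed; identical
parameters and seed give bit-identical curves.

### RFD estimation from a sampled curve

`estimate_rfd_from_curve` returns the ordinary least-squares slope of force
against time over `[0, window]` (default window 0.02 s), the conventional
initial-slope read-off. On the mono-exponential form this estimator is
biased low by approximately `(rfd / F_peak) * window / 2`, because the curve
bends away from its tangent inside the window:

- noiseless, `rfd=15000`, default plateau: bias is −1.9% at `window=0.01`
  and −3.7% at `window=0.02`. Accuracy tests therefore use a window small
  relative to the curvature time constant `F_peak / rfd` (the property test
  uses `window <= 0.03 * F_peak / rfd`, keeping bias under 2% across
  rfd ∈ [1000, 20000]).
- with 20 N noise at 1 kHz and `window=0.02` the sampling SD of the slope is
  ≈ 720 N·s⁻¹ (4.8% of 15000), so a *single* noisy estimate is
  noise-dominated and can miss by >10%. Accuracy under noise is therefore
  assessed on the mean over 200 independent noise realizations (within 5% of
  the generating RFD; the observed systematic part is the −3.7% curvature
  bias), while a single-trial check uses the simulation-derived
  |bias| + 3·SD ≈ 18% band.

Curve import/export is two-column CSV text (`time_s,force_N`, one header
line) written with shortest-round-trip `repr` formatting, so a written curve
re-parses bit-exactly.

## Sensitivity sweeps

`sweep_alpha` and `sweep_kappa` vary exactly one parameter over a grid,
holding the rest at the base parameter set, and evaluate predicted RFD and
percent loss over a duration grid. Default grids — α ∈ {0.05, 0.1, 0.2,
0.3, 0.5}, κ ∈ {0.2, 0.4, 0.6, 0.8, 1.0} — bracket the weightlifter
defaults (0.3, 0.8) and are representative rather than canonical. Sweep
rows are computed by the same `predict_rfd` code path as single predictions
(tests assert bit-equality), and serialize to a long-format table
(`varied_name, varied_value, duration_min, rfd, percent_loss`). Joint α×κ
grids are deliberately not a default output: one-knob families are what a
coach can actually read.

## Configuration and CLI

The `rfdmodel` CLI is a thin layer over the library — no numeric logic lives
in it. Parameters resolve with precedence flag > TOML config file >
default; config files are flat TOML with the parameter names as keys, and
unknown keys warn rather than error so files can carry annotations.
Diagnostics go to standard error, data to standard output or `--output`, so
piped CSV stays clean; identical invocations produce byte-identical output.
Three athlete profiles ship with the package (group-average IMTP baselines
of 16652 and 7663 N·s⁻¹ for national-caliber male and female weightlifters,
plus the 15000 N·s⁻¹ conceptual default) and can be selected with
`--profile` in place of `--rfd0`.

## Numerical notes and limitations

- All model quantities are closed-form; no optimization, integration or
  fitting is performed anywhere, and the only randomness in the package is
  the seeded curve noise.
- `d` exactly at `d0` is the identity case (positive part is 0), and the
  prediction is continuous there.
- Degenerate settings behave as limits: `kappa=0` or `alpha=0` predict no
  change at any duration; `d_max == d0` collapses the linear variant to a
  step at `d0`.
- The package cannot tell a coach whether the model is *right* — no
  empirical validation exists. It guarantees only that the stated equation,
  its tabulated consequences and its simulated curves are computed
  correctly and reproducibly.
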