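# Methods

## The measurement being modelled

An optical stretcher holds a suspended cell in a dual-beam laser trap and
applies a contact-free surface stress along the beam axis. In a step-stress
creep experiment the stretching power is switched on abruptly, held for the
stretch duration `T`, and switched back to trapping power, after which the
cell relaxes. Phase-contrast video of the cell is segmented per frame and
the long axis `L(t)` and short axis `S(t)` of an ellipse fit are recorded,
together with orientation and relative brightness.

Two dimensionless deformation signals are derived per cell:

- **relative deformation** `d(t) = (L(t) − L0)/L0`, the fractional
  elongation of the long axis, with `L0` the mean long axis over the
  pre-stretch (trap-only) baseline window;
- **elliptic deformation** `ε(t) = [L(t)/S(t)]/e0 − 1`, the change of the
  axis ratio against the resting shape `e0 = mean(L/S)` over the baseline.
  The elliptic signal captures the Poisson effect — the short axis
  contracts while the long axis elongates — and therefore dissociates from
  pure elongation. Normalising by `e0` and subtracting 1 makes every curve
  start at ≈0; the raw axis ratio would carry the resting-shape offset into
  every downstream statistic.

## Kelvin–Voigt model with active contractility

The cell is modelled as a Kelvin–Voigt solid — spring (Young's modulus `E`,
Pa) in parallel with a dashpot (viscosity `η`, Pa·s), relaxation time
`τ = η/E` — extended by an activity parameter `a` (Pa/s): the cell
contracts against the optical load, modelled as a linear decrease of the
effective step stress,

```
η γ′(t) + E γ(t) = max(σ0 − a·t, 0),    γ(0) = 0.
```

On the unclamped range the closed form is

```
γ(t) = (σ0/E)(1 − e^{−t/τ}) − (a/E)[t − τ(1 − e^{−t/τ})],
```

and past the clamp time `t_c = σ0/a` the strain decays freely,
`γ(t) = γ(t_c) e^{−(t−t_c)/τ}`. The clamp encodes that contraction cannot
reverse the sign of the applied optical stress in this linear model. After
the step the trapping power only holds the cell; the trapping stress is
approximated as zero, so relaxation is `γ(T+Δt) = γ(T) e^{−Δt/τ}`. Both
closed forms are verified against an independent numerical initial-value
solver to <1e−8 absolute over a grid E ∈ [10, 1000] Pa, τ ∈ [0.1, 10] s,
a ∈ [0, 0.5] Pa/s.

The step stress and peak stretching force scale linearly with laser power,
anchored at 0.38 Pa and 80 pN per 400 mW (both coefficients configurable).

### Fitting

`fit_kv` performs trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) of the forward model to the
stretch-phase samples, for both signals × both windows (full stretch and
first 2 s) × both models (passive, active) — eight fits per cell, all
exported as features. Bounds are E ∈ (0, 1e6] Pa, τ ∈ (1e−3, 1e3] s,
a ∈ [0, 10] Pa/s; initialisation E0 = σ0/γ(T), τ0 = 0.3·T, a0 = 0, with two
additional starts (a fast-relaxing one, and one with a nonzero activity
head start) because the clamped active model has local minima; the lowest-
cost solution wins. The fit error is the RMS residual. Curves with no
measurable deformation, or fits pushed to the E bound, are flagged
non-converged and carry NaN parameters into an explicit missing-value mask
— never silent defaults. The per-cell `E`, `τ`, `a` quoted in summaries
come from the active fit of the relative-deformation signal over the full
window.

### Derived labels and scalars

- **Shape restoration** `R = d(T) − d(T + 1.5 s)`, sampled at the nearest
  frames (no interpolation, mirroring the frame-based measurement).
  Positive `R` means elastic recoil toward the resting shape; `R ≈ 0`
  means viscous, dissipative behaviour. For a passive cell
  `R = γ(T)(1 − e^{−1.5/τ})`.
- **Activity label**: a cell is *active* when the fitted `a` strictly
  exceeds 0.001 Pa/s; below that the contraction signal vanishes in the
  random noise of the fit. Non-converged fits give *undetermined*.

## Synthetic cohorts

The generator draws per-cell ground truth from per-class distributions and
pushes it through the same forward model the fitter assumes:

- log-normal `E`, `η`, radius (strictly positive, right-skewed, the usual
  shape of cell-mechanical parameters);
- zero-inflated log-normal activity: `a = 0` with probability
  1 − active_fraction, log-normal otherwise;
- normal resting ellipticity (clipped at 1) and brightness;
- the short axis co-varies as `S(t) = S0 (1 − ν d(t))` with a class-specific
  effective Poisson ratio ν ∈ [0, 0.5], so elliptic and relative
  deformation can dissociate between classes;
- i.i.d. Gaussian noise (default sd 0.05 µm) added per frame to both axis
  lengths;
- frame rate defaults to 30 Hz and a 1 s trap-only baseline precedes the
  step; both are configurable.

Every output is a pure function of (config, seed); seeds are split with
`numpy.random.SeedSequence` so population sampling, protocol assignment and
measurement noise come from independent streams.

### The "clinical-cohort" preset

`clinical_cohort_config()` encodes the emulated study conditions: two classes,
measured with the clinical three-power protocol set (400/800/1200 mW,
i.e. 0.38/0.76/1.14 Pa, 1 s baseline + 10 s stretch + 2 s relaxation, one
power chosen uniformly at random per cell) —

| parameter | PBMC-like | CTC-candidate-like |
|---|---|---|
| E median (log-sd) | 30 Pa (0.6) | 50 Pa (0.6) |
| η median (log-sd) | 75 Pa·s (0.7), τ ≈ 2.5 s | 30 Pa·s (0.7), τ ≈ 0.6 s |
| radius median (log-sd) | 5 µm (0.25) | 8 µm (0.30) |
| Poisson coupling ν | 0.45 | 0.2 |
| active fraction | 0.375 | 0.375 |
| activity median (active cells) | 0.08 Pa/s | 0.08 Pa/s |

The stiffnesses put median relative deformations in the observed
few-percent range (PBMC ≈ 0.02–0.03 at the middle power); the combined
stiffness and coupling gaps give the PBMC class about twice the
end-of-stretch elliptic deformation of the CTC class; the τ gap makes the
CTC class restore shape faster (higher `R`). The wide log-normal spreads
reflect the order-of-magnitude within-class heterogeneity real
optical-stretcher cohorts show, which is also what keeps the two classes
broadly overlapping — a classifier on this preset scores well above chance
but far from perfectly, as on real blood-derived cohorts. Brightness,
resting ellipticity and rotation rate are deliberately identically
distributed in both classes: no class difference in them is reported for
clinical cohorts, so giving them gaps would manufacture spurious
discriminative features. An active fraction of 0.375 corresponds to an
active:non-active ratio of 0.6. A `separation` factor scales the radius,
stiffness and coupling gaps multiplicatively for classifier stress tests.

The shape-restoration gap is deliberately modest (median ratio ≈ 1.2);
with a few hundred cells per class its class medians occasionally invert
from one seed to the next, and its KS comparison is not significant at
every laser power — the effect is a tendency, not a separator.

What the generator does **not** emulate: blood-sample debris, erythrocytes
and cell clusters; out-of-plane rotation; optical-force physics (stress is
a scalar input); nonlinear or power-law rheology; donor-level structure
(cells are i.i.d. within a class). Passing tests therefore demonstrate the
pipeline's correctness and calibration on Kelvin–Voigt-faithful data, not
performance on real blood samples.

### Rendering and tracking

`render_frames` draws one filled, rotated ellipse per frame over a noisy
background (pixel-center convention, origin top-left). `trace_axes`
segments each frame (Otsu threshold, largest connected object with a
contrast guard of 4 robust sigma over background so pure-noise frames fail
detection), fits a least-squares ellipse to the contour, and measures
relative brightness as mean interior intensity over median background.
Isolated detection failures (runs of ≤2 frames) are linearly interpolated;
traces with >10% failed frames are flagged invalid. The rendered→tracked
round trip recovers axes to well under 2% relative error at default
signal-to-noise.

"Degree of rotation" is the cumulative absolute orientation change during
the stretch phase with 180°-wrap unwrapping — the in-plane component of
tumbling, which is what 2-D imaging can measure. It is invariant under a
global orientation offset, but is ill-defined for near-circular cells,
whose fitted orientation is arbitrary.

## Features and classification

The default schema has 45 features: morphology (effective radius, area,
relative brightness, resting ellipticity, rotation degree), end-of-stretch
relative and elliptic deformation, the full fit grid (E, η, τ, fit error,
plus a for active fits, per signal × window), shape restoration and laser
power. Schemas are JSON-serialisable and user-extensible; column order is
exactly schema order.

Classification is a random forest (500 Gini trees, sqrt-features per
split by default) evaluated with repeated stratified k-fold
cross-validation (5 folds × 10 repeats by default). Masked features are
imputed with the training-fold median plus a missing indicator, inside each
fold, so no information leaks from held-out cells. Sensitivity is the
recall of the positive class (CTC candidates), specificity the recall of
the other class. Permutation importance is measured on a stratified
held-out split (mean accuracy drop over 10 permutations), with ties broken
by feature name for deterministic ranks. `progressive_input` evaluates
cumulative feature-group prefixes on identical folds, so each added group
is a paired comparison. The split unit is the cell; cohorts here have no
donor structure, but on real data a donor-grouped split is the
leakage-safe alternative.

Calibration-heavy checks (classifier null and separated cohorts, the
acceptance script, the end-to-end pipeline tests) use 200 trees, 5 × 2
folds and cohorts of 250–1000 cells per class; the library defaults are
unchanged.

## Statistics

Distribution comparisons are two-sample Kolmogorov–Smirnov tests with the
asymptotic p-value (sample sizes in scope are hundreds to thousands, where
the exact method is impractical), starred as * p<0.05, ** p<0.01,
*** p<0.001. The scalar tested per metric is the value at the last
stretch-phase frame for both deformations, and `R` for restoration. No
multiple-testing correction is applied by default (raw p-values are
reported); a Bonferroni option would be a one-line wrapper and is
deliberately not wired into the tables. Under the null the rejection rate
at α = 0.05 is calibrated to [0.035, 0.065] for n = 100 per sample. Fold
enrichment of a case proportion over a control proportion is reported as
the exact ratio plus an integer-rounded headline.

## Numerical choices and degenerate inputs

- Relative/elliptic baselines are means over the pre-stretch window (a
  single-frame baseline would inject one frame's noise into every sample).
- Phase marks are computed from protocol timing with half-frame tolerance;
  shape restoration requires ≥1.5 s of relaxation and errors otherwise.
- After noise injection the per-frame long/short ordering is restored by
  taking max/min, and the short axis is floored at 1 nm.
- Flat or zero-stress curves are non-converged by construction, not fitted.
- KS tests require ≥2 finite values per sample; masked (NaN) features are
  dropped before testing; medians are computed on unmasked values only.
- All stochastic procedures take explicit integer seeds; classifier seeds
  are reduced modulo 2³¹ for scikit-learn.

## Known limitations

- **Activity resolution.** With 0.05 µm axis noise at 30 Hz over a 10 s
  step, the standard error of the fitted activity is of order 3×10⁻³ Pa/s
  — above the 0.001 Pa/s labelling threshold. Truly active cells
  (a ≈ 0.08 Pa/s) are detected essentially always, but a substantial
  fraction of passive cells fit a spurious small activity, so the measured
  active:non-active ratio overstates the ground-truth 0.6 and the measured
  per-class activity medians sit below the true active-cell median. This
  is a property of the measurement, not the estimator: initialising the
  fit at the true parameters does not improve it. Resolving activity at
  the threshold would need roughly tenfold lower axis noise or a
  correspondingly longer/denser recording.
- **τ at low power.** Relaxation-time recovery degrades for stiff,
  fast-relaxing cells at the lowest power (smallest strains); median
  relative errors land around 12–16% across the pooled clinical cohort —
  again a noise floor, unchanged when the optimiser is started at the
  true parameters.
- The elliptic/relative dissociation achievable with linear Poisson
  coupling is bounded by (1+ν_max)/(1+ν_min) ≈ 1.2, so the ≈2× elliptic
  split between classes necessarily rides partly on a stiffness gap; the
  two classes' relative-deformation medians differ by ≈1.7× in the preset.
- **Size importance is split by construction.** The effective radius is
  exactly √(area/π), so radius and area are monotone-equivalent columns;
  tree ensembles substitute one for the other freely and permutation
  importance divides and damps the cell-size signal between them. The
  rheological fit features, spread over many non-identical columns, do not
  suffer exact substitution, so they tend to out-rank radius in marginal
  importance even when radius is the strongest single separator. Rankings
  over correlated features should be read with this in mind (grouping
  correlated features before permuting is the standard remedy).
- The exact feature list of the emulated study is hosted externally and
  not enumerated in its text; the shipped 45-feature schema covers every
  named feature family but is not a feature-for-feature replica, and
  classifier scores on synthetic cohorts are not comparable to scores
  measured on real cells.
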