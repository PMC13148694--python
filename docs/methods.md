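# Methods

This note documents the statistical model, the synthetic-data generator,
the parameter choices, the numerical decisions, and the known limits of
the emulation. Everything here is reproducible from the package alone.

## 1. The calibration model

### 1.1 Form

For observation *i* (one participant × protocol condition × device ×
placement stratum), with `A_i` the steady-state activity counts per minute
and `MET_i` the steady-state energy expenditure:

```
sqrt(MET_i) = β0 + β1·sqrt(A_i) + Σ_s [ γ_s·d_si + δ_s·d_si·sqrt(A_i) ] + ε_i
```

where `d_si` indicates membership of non-reference stratum *s*. The
reference stratum is the hip-worn GT3X+; the other three strata (ActTrust
hip, ActTrust wrist, GT3X+ wrist) each get an intercept offset `γ_s` and a
slope offset `δ_s`. The square-root transform linearises the
counts-to-METs relationship and stabilises the variance: MET scatter grows
with intensity, while sqrt-MET scatter is approximately constant.

The working equation of stratum *s* is `√MET = b0_s + b1_s·√A` with
`b0_s = β0 + γ_s`, `b1_s = β1 + δ_s` (offsets zero for the reference). Its
2×2 covariance is `A Σ Aᵀ`, where Σ is the OLS coefficient covariance
`σ̂²(XᵀX)⁻¹` and A holds the two combination vectors.

Estimation is ordinary least squares via `statsmodels.OLS` on a manually
constructed design matrix with canonical column order (`const`,
`sqrt_activity`, then one dummy and one interaction per non-reference
stratum). Rank deficiency is detected up front (QR diagonal) and reported
with the offending column names.

### 1.2 Cut-points and their uncertainty

The counts/min at which stratum *s* predicts a MET boundary
`M ∈ {3, 6, 9}` is the inverse of the working equation:

```
g(b0, b1; M) = ((√M − b0) / b1)²       (requires b1 > 0 and √M ≥ b0)
```

Uncertainty propagates by the delta method with gradient

```
∂g/∂b0 = −2(√M − b0)/b1²
∂g/∂b1 = −2(√M − b0)²/b1³
SE(g)  = sqrt(gradᵀ · Cov(b0, b1) · grad)
```

and a normal-quantile interval `g ± z·SE`, truncated below at zero
counts. `cutpoint_se_bootstrap` cross-checks the delta SE by drawing
(b0, b1) from their estimated bivariate normal and re-inverting; draws
with `b1 ≤ 0` or `b0 > √M` (where the inversion is undefined) are
excluded. At study-scale coefficient precision (CV(b1) < 10%) the two
routes agree within a fraction of a percent; the acceptance suite enforces
5%.

The inversion is exactly consistent with prediction:
`predict_met(eq, invert_cutpoint(eq, M)) = M` to float precision, so
classifying counts by cut-points and classifying predicted METs by the MET
boundaries are the same partition (this identity is tested directly).

### 1.3 Evaluation

- **Intensity classes.** light [0, 3), moderate [3, 6), vigorous [6, 9),
  very vigorous [9, ∞) METs; boundaries are left-closed (a value on the
  boundary belongs to the higher class), applied identically on the MET
  and the counts side.
- **One-vs-rest metrics.** sensitivity, specificity and balanced accuracy
  from the 4×4 confusion matrix; AUC by the Mann–Whitney rank formulation
  on the continuous predicted-MET score. The score direction is chosen
  per class (AUC = max(a, 1−a), the usual ROC "direction auto"
  convention): a monotone score ranks the lowest band *below* the rest.
  Interior-band AUCs are structurally depressed for any monotone score —
  a middle band cannot be separated from both sides by one threshold
  direction — which is exactly the published pattern (terminal classes
  near 1, interior classes far lower).
- **ANOVA.** one-way over the 20 condition × stratum cells on the
  sqrt-count scale: df_between = 19; η² = SS_between/SS_total; Tukey HSD
  (statsmodels) for all pairwise cell contrasts.
- **Agreement.** Bland–Altman bias and 1.96-SD limits of agreement between
  predicted and measured METs per stratum, with a proportional-bias slope
  test; residual diagnostics via Q–Q pairs, Shapiro–Wilk (subsampled at
  4,999) and Breusch–Pagan against the model design.

## 2. The synthetic-data generator

The generator's defaults *are* the study conditions; they were chosen from
the published table and physiological reference values before the test
thresholds were frozen, and are not tuned to outcomes.

### 2.1 Latent-intensity construction

One shared VO₂ measurement must be consistent with four different
per-stratum count scales. The generator therefore draws, per participant
× condition, a latent sqrt-MET intensity

```
u = sqrt(met_by_speed(v)) + τ(v)·z ,   z = ρ·a_i + sqrt(1−ρ²)·w
```

with `a_i` a persistent participant effect, `w` a condition-level draw,
`ρ = 0.6`, and `τ(v) = 0.02 + 0.016·v` (km/h) the between-subject spread.
Each stratum's steady-state counts then sit **exactly on its true line**:
`√cpm_s = max(0, (u − b0_s)/b1_s)`, with (b0_s, b1_s) the published
coefficients. The measured MET adds calorimetry noise on the y side only:
`√MET = u + ε`, `ε ~ N(0, 0.15)`.

Because the x values are exact and all error is in y, OLS recovery is
unbiased and nominal CI coverage holds — which is what the coverage
acceptance test verifies. In the default observation-level mode ε is
drawn independently per row; a `"shared"` mode reuses one ε across the
four strata of a cluster, mirroring the physical single-measurement
situation (under the saturated interaction model the per-stratum estimates
use disjoint rows, but shared residuals make rows correlated and dummy
contrasts over-cover, so the independent mode is the default for
statistical contracts).

Parameter values and their provenance:

- `met_by_speed = {0: 1.6, 3: 2.8, 5: 3.8, 7: 7.0, 9: 9.5}` — compendium-
  typical treadmill values; rest is the measured standing rate through the
  3.5 ml/kg/min convention (young adults rest above 1.0 MET by that
  convention, consistent with zero-count predictions b0² ≈ 1.1–1.5 from
  the published equations); 7 km/h is at the walk/run transition and
  9 km/h interpolates the running compendium entries.
- `τ(v)` gives ≈10% between-subject CV in MET at 9 km/h (typical
  running-economy variability) and a tight rest cluster.
- `residual_sd_sqrt_met = 0.15` on the sqrt scale reproduces study-like
  R² ≈ 0.95 at n = 56.
- Cohort demographics: sex-specific normal age/height/mass (male
  28.3 ± 4.6 y, 172 ± 6.2 cm, 78.2 ± 11.9 kg; female 26.8 ± 5.0 y,
  160 ± 7.3 cm, 59.9 ± 9.4 kg), ages clipped to the recruited 18–35 band.

### 2.2 Raw-signal emulation

The full-fidelity path generates tri-axial acceleration and runs it
through each device's counting chain:

- **Gait waveform.** per-axis sums of the step-frequency fundamental
  (`f0 = 1.4 + 0.16·v` Hz) plus two harmonics, hip dominated by the
  vertical axis and wrist by arm swing, random phases, 0.005 g sensor
  noise; at rest a 0.7 Hz postural-sway term (inside both passbands).
- **Device chains.** 4th-order zero-phase Butterworth band-pass
  (GT3X+: 0.25–2.5 Hz at 30 Hz, ±6 g clip; ActTrust: 0.5–2.7 Hz at 25 Hz,
  0.03 g deadband + ±4 g clip), then 1-s epochs: VM = Euclidean norm of
  per-axis rectified integrals (GT3X+), PIM = integral of the filtered
  norm (ActTrust). Count scales (1000 / 2500 counts per g·s) are explicit
  configuration chosen so calibrated amplitudes stay in the physiologic
  0.1–3 g range — not estimates of vendor constants.
- **Amplitude calibration.** to place a series at a target counts/min, a
  noise-free 60-s probe with the same seed (hence identical phases) is
  refined by three fixed-point iterations, exploiting the chain's
  linearity in amplitude away from the deadband/clip limits.
- **Breaths.** gamma-distributed inter-breath gaps (rate 12 + 2.8·v per
  min), first-order on-kinetics (τ = 30 s) truncated to an exact plateau
  from 160 s — so the central window [180 s, 420 s) is strictly steady and
  the noise-free round trip is exact — multiplicative 5% CV noise, and
  errant breaths (probability 0.01, scaled ×U(2.2, 4)) for the cleaning
  rule to find.
- **Dataset layout.** plain CSVs (per-stratum epoch files with ISO
  timestamps, per-condition breath files, participants table), a truth
  sidecar for parameter-recovery tests, and a SHA-256 manifest;
  byte-identical for identical inputs.

### 2.3 Preprocessing rules

- **Errant breaths.** breath *i* is removed iff it deviates more than
  3 sample SDs (ddof = 1) from the mean of breaths {i−2, i−1, i+1, i+2},
  in a single pass over the original series (removals do not re-enter
  reference windows); the first/last two breaths are always retained;
  series with < 5 breaths are returned unchanged with a warning. The rule
  intentionally also removes a few percent of legitimate breaths from
  heavy-tailed neighbourhoods; this is harmless to steady-state means and
  is counted in the run log.
- **Steady state.** central 4 of 10 minutes, half-open [start+180,
  start+420). METs: inter-breath-interval-weighted mean of VO₂/kg/3.5.
  Counts: mean of the four 1-minute epoch sums, minutes rescaled for
  small gaps, NaN (→ row dropped and counted) above 5% missingness.

## 3. Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  integer(-list) seeds; dataset writing uses per-series seed tuples
  `[seed, participant, condition, stratum, stream]`, so any series can be
  regenerated in isolation.
- Normal (z) interval multipliers by default; Student-t available via
  `use_t` (df from the fit). At n_obs ≈ 1120 the difference is < 0.2%.
- Delta-method intervals are truncated at zero counts; covariance
  validation accepts any finite symmetric PSD matrix (including the
  zero matrix → zero-width interval) and rejects NaN/asymmetric/indefinite
  input.
- CSV artefacts use fixed float formats so identical configs produce
  byte-identical files.

## 4. Known limitations

- **Device physics vs latent lines.** at rest, sensor noise (GT3X+) and
  the 0.03 g deadband (ActTrust) put a floor/ceiling on achievable counts;
  at 9 km/h the GT3X+ 2.5 Hz corner attenuates the 2.8 Hz step fundamental
  and the 3 g amplitude cap binds, so raw-path counts undershoot the
  latent target by ~5–8% at top speed. End-to-end raw-path tests therefore
  assert monotonicity and qualitative recovery; exact statistical
  contracts (oracle equivalence, coverage) run on the observation-level
  generator, which is the model's own data-generating process.
- **Interior-class AUC.** with a monotone score the moderate/vigorous
  one-vs-rest AUCs are structurally ≈0.5–0.8; this mirrors the published
  evaluation and is not a defect of the classifier.
- **Clamping at rest.** participants whose latent intensity falls below a
  stratum's intercept produce zero counts (the max(0, ·) clamp); with the
  default spreads this is rare and its bias on recovered offsets is below
  the n = 56 sampling noise (the coverage test passes at nominal level).
- The generator emulates treadmill locomotion only; free-living movement,
  non-ambulatory activity and device-wear artefacts are out of scope.
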