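# Methods

## Odor activity values and the OIRS scale

All intensity modelling runs through the odor activity value
OAV = C/C_thr (dimensionless; numerically the dilution-to-threshold ratio)
and its natural logarithm. Natural log is used throughout — the worked
tangent examples only close numerically under a fixed base, and lnOAV is the
named variable of the model. Concentrations and thresholds are mass
concentrations in mg/m³. The optional conversion to ppb is ideal-gas:
ppb = (µg/m³ ÷ MW) × RT/P, with the reference state fixed at 20 °C and
101.325 kPa (molar volume 24.055 L/mol) because that state reproduces the
paired (mg/m³, ppb) values of the packaged threshold table; the table itself
never states a temperature convention.

Odor intensity lives on the OIRS scale [1, 8]. Raw assessor ratings sit on
the half-step grid {1.0, 1.5, …, 8.0}; panel means are unconstrained reals
in [1, 8]. Measured-OI design bands are half-open, lower-inclusive:
low [1, 2.5), middle [2.5, 4.5), high [4.5, 7]. The source convention writes
the band edges ambiguously ("1–2.5", "2.5–4.5"); the half-open reading is a
package decision, fixed and tested. Values above the 7.0 design ceiling are
classified high with an `above-design-range` warning rather than rejected.

## The mixture model

A binary sample with supra-threshold components (both lnOAV > 0 — the
normalization weights are undefined otherwise, and sub-threshold samples are
outside the model's design space) maps to the mixing proportion
x = lnOAV_a/(lnOAV_a + lnOAV_b) and per-unit intensity
OI_m = OI/(lnOAV_a + lnOAV_b). The mixture curve y = f(x) is a quadratic
fitted by unweighted ordinary least squares; the polynomial order is fixed
at 2 (no model selection), and the fit requires ≥ 4 points on ≥ 3 distinct
proportions. Partial odor intensities come from the tangent at (x, f(x)):

    OI_a,m = (1 − x)·f′(x) + f(x)        OI_b,m = −x·f′(x) + f(x)

These are the intercepts of the tangent line on the x = 1 and x = 0 axes,
and algebraically the marginal contributions: ∂OI/∂lnOAV_a = OI_a,m when OI
is written as (lnOAV_a + lnOAV_b)·f(x). The prediction
OI = OI_a,m·lnOAV_a + OI_b,m·lnOAV_b is computed by both routes (summation
rule and direct curve evaluation) and cross-checked to 1e-9 on every call.
Partial intensities may be negative (hypo-additivity) and are never floored.
The hard domain for x is (0, 1); outside the calibrated design range
[0.1, 0.9] the package warns (`extrapolation`) but does not block — a
component below ~20% of the total barely influences mixture OI, so the
design never probes there.

Component "a" is always the first column of the input; every output is
order-covariant, and the swap symmetry (x → 1 − x, partials exchange,
prediction invariant) is enforced by tests.

### Confidence bands

Fitted models store the inverse normal matrix, residual sd (n − 3
denominator) and n, sufficient for pointwise mean-response confidence bands
ŷ(x) ± t_{1−α/2, n−3}·s·√(vᵀ(XᵀX)⁻¹v) and per-coefficient t intervals. The
default level is 0.90. The pointwise mean-response band is the standard
reading of the dashed intervals in this kind of regression display; no
simultaneous (Scheffé/Working–Hotelling) band is offered. The packaged
extended model is literature-fixed — coefficients only, no residual
information — and refuses to produce bands rather than fabricating them.

### The extended curve and report rounding

The packaged extended model y = 2.20x² − 2.20x + 1.32 (symmetric about
x = 0.5) predicts binary aldehyde mixtures without a panel. Its validation
set (21 samples: 9 from the calibration aldehyde pairs, 12 from four pairs
outside calibration) ships as a packaged CSV holding the component lnOAVs,
panel-measured OI, and the originally reported partials and predictions.

Reported predictions follow a two-stage rounding: to 2 decimals, then to 1,
ties away from zero. This is deliberate: the original reported values were
evidently produced from intermediates held at two decimals (e.g. a
prediction of 1.5495 was reported as 1.6), and only this convention
reproduces every reported per-sample prediction and the section mean
predictive coefficients (1.03 calibration / 0.93 transfer). Plain 1-decimal
rounding and full precision are available as evaluation modes
(`rounding="decimal1" | "none"`; CLI `--no-round`); both give a calibration
mean of 1.02. Ratios use the reported measured OI as denominator; records
without a positive measurement are excluded with a logged
`excluded-record` warning.

One validation cell is knowingly not reproduced: the first calibration row
reports OI_a,m = 1.32, but the tangent construction on its lnOAV pair
(2.18, 0.56) gives 1.23, and only 1.23 is consistent with the row's own
reported prediction of 2.6. The reported 1.32 appears to be a transcription
slip (it duplicates the curve's constant term); the acceptance test asserts
the discrepancy explicitly. Four further partial-intensity cells in the
validation table differ from recomputation in the last printed digit only
(< 0.008); the tests require sub-last-digit agreement there rather than
exact rounded equality, since no uniform rounding rule reproduces those
printed digits.

## Individual response

Single-odorant OI is linear in lnOAV over the working range; the package
fits it by unweighted OLS (panel means have similar precision by design) and
reports slope, intercept and residual sd (n − 2). Pooling points across
odorants is the caller's choice — chemically similar odorants (e.g. the
straight-chain aldehydes) empirically share one line, but the package does
not force pooling. Predictions outside [1, 8] carry a below/above-scale
flag and are never clamped silently.

## Panel and design simulator

The simulator emulates the sensory protocol: each of n assessors (default
8) rates true OI plus Gaussian noise, rounded to the half-step grid and
clamped to [1, 8]; the panel mean is the measured OI. Defaults:

- `rating_sd = 0.2` OIRS per assessor. The observed repeat-evaluation
  envelope is ±0.4 on panel means; sd 0.2 puts ~95% of 8-assessor panel
  means inside that envelope. The sd may instead be a function of true OI
  (rating precision improves with intensity), default constant.
- Grid ties round away from the nearer scale bound (3.25 → 3.5,
  5.25 → 5.0), biasing ties toward the scale interior; the protocol is
  silent on ties and this rule keeps boundary clamping symmetric.
- The mixture design draws 24 samples — 8 per measured-OI band, proportions
  uniform in [0.1, 0.9], true OI uniform within each band capped at 7.0 —
  and inverts true OI through the truth curve into component lnOAVs and
  thence concentrations. All randomness flows from one generator seeded by
  a single integer.

What the simulator does not model: assessor identity and covariates,
fatigue, inter-assessor correlation, odor type/hedonics, and any real
psychophysical departure from "linear in lnOAV plus noise". Recovery and
coverage results on simulated data therefore validate the estimators under
the stated noise model, not panel behaviour in the field.

Numerical note: with zero rating noise the panel mean is pure half-step
quantization (error ≤ 0.25 OIRS). That error does not vanish per sample, so
noiseless round-trip recovery of curve coefficients converges only as the
design grows (≈0.15 typical max coefficient error at 24 samples, < 0.1 at
960); the tests check convergence rather than exact recovery at 24. Bias of
the fitted coefficients is negligible (< 0.01) already at 24 samples when
averaged over replicate designs, and 90% coefficient intervals attain
nominal coverage within binomial tolerance over 100 replicates of the
24-sample, 8-assessor, sd 0.2 reference conditions (the problem sizes used
throughout the recovery tests).

## Files and formats

CSV dialects are UTF-8, comma-separated, header required, `.` decimal
separator; readers reject malformed numerics with line numbers rather than
coercing. Models serialize to JSON losslessly (including band information)
with an explicit format version; mismatched versions are refused. The
prediction report prints partials at 2 decimals and OI at 1 — report
precision lives only in writers, never in memory. Every CLI run writes a
manifest (command, input digests, seed, version, timestamp, outputs);
reruns from identical inputs are byte-identical on all numeric outputs.
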