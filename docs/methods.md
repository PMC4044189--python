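# Methods

This note documents the models, the generator, the numerical choices
and the limitations of the `glasscoherence` pipeline. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus model

A pattern is parameterized by `GlassPatternSpec`. The dot total is
`density × side²` forced to the nearest even number (dots come in
pairs), so the dipole count is `round(density × side² / 2)`; at the
default density 25 dots/deg² on a 14.4° square this is 2592 dipoles
(5184 dots). The signal-dipole count is `round(coherence × n)` with
round-half-to-even (unbiased over coherences). Signal orientations
follow the polar rule — starburst = `atan2(y, x) mod π`, circular =
that + π/2 — and noise orientations are uniform on [0, π); orientations
live on the half-circle because a dipole is an unordered dot pair.

Placement decisions where the geometry was open:

- The placement region is a square of side equal to the aperture outer
  diameter (14.4°); the annulus acts purely as a contrast envelope
  applied afterwards. Dipoles straddling an aperture edge are
  attenuated by the envelope, not re-drawn.
- The aperture envelope is 0 for r ≤ 0.75° (inner radius), rises as a
  raised cosine over [0.75°, 1.5°], is 1 on the plateau, and falls over
  [6.45°, 7.2°], keeping the outer extent at the stated 14.4° diameter.
- The 0.14° separation is between the two dots: dots sit at ±0.07°
  from the dipole center along its orientation.
- Overlapping dots accumulate additively and the image is clipped to
  [0, 1], matching display saturation; a dipole's two Gaussian dots
  (σ = 0.025°) have amplitude polarity × 0.5 about the 0.5 background.
- Rasterization warns when σ spans less than one pixel (the default is
  40 px/deg, i.e. σ = 1 px). Noise orientations are unconstrained —
  nothing excludes angles incidentally close to the polar rule.
- Fixation digits are not rendered; the behavioral task is simulated
  abstractly (target/non-target status is all the analysis uses).

## Design

`counterbalanced_orders` builds a Williams row-complete arrangement for
even n (first row 0, 1, n−1, 2, n−2, …; subsequent rows add 1 mod n)
and randomizes it by symbol relabeling, row shuffling and global
reversal — each output is a valid solution, drawn from a randomized
subset rather than uniformly over all solutions. For odd n no single
set of n sequences covers every ordered pair once (exhaustively
verified for n = 3 in the tests), and the function raises.
"Preceded by" is read as immediate stimulus-to-stimulus adjacency
within a sequence; the blank block after each sequence breaks the
chain. Condition-to-sequence assignment is re-randomized per run while
preserving the Williams structure. The within-block 1 Hz refresh and
random circular/starburst assignment are stimulus metadata only; in the
BOLD model each block is a single boxcar.

## Hemodynamic and noise model

The canonical response is the double-gamma difference
`Γpdf(t; 6, 1) − (1/6) Γpdf(t; 16, 1)`, truncated at 32 s (peak ≈ 5 s,
undershoot ≈ 15 s). Regressors are unit boxcars convolved at 0.1 s
resolution and sampled at volume onsets; the regressor scale cancels
between generation and fitting, so injected amplitudes are recovered in
their own units.

Node noise is ARMA(1,1): innovations filtered by
`x_t = a x_{t−1} + e_t + b e_{t−1}` with a 200-sample burn-in. Per-run
drift is a Legendre expansion P₀–P₃ with per-node random coefficients;
motion is six standardized random-walk series with configurable
coupling (default 0: pure nuisance columns).

## Synthetic cohort — what it emulates and what it does not

Defaults: 6 participants × 12 runs × 171 volumes at TR 2 s; per area
and hemisphere 50 responsive + 10 non-responsive (zero-amplitude)
nodes; node meridian distances uniform on [0°, 90°].

Generator parameter choices (units of psc are percent of the 1000 a.u.
baseline):

| parameter | default | rationale |
|---|---|---|
| baseline | 1000 a.u. | typical EPI intensity scale; arbitrary since psc is scale-free |
| visual response | 1.0 psc all conditions | plausible stimulus-vs-blank block response; makes nodes selectable |
| coherence effects | +{0, 0, 0.153, 0.101, 0.185, 0.246} psc full-vs-zero for {V1, V2, V3, hMT+, DRA, VRA}, linear through coherence {0, ⅓, ⅔, 1} | the injected ground truth |
| ARMA (a, b) | (0.4, −0.2) | lag-1 autocorrelation ≈ 0.21, typical of TR = 2 s BOLD |
| innovation sd | 5 a.u. (0.5%) | node-level noise giving realistic single-run effect SNR |
| participant jitter sd | 0.08 psc per condition | predicted SEM of a full-vs-zero difference = 0.08·√2/√6 ≈ 0.046 psc, matching the 0.042–0.067 psc range the group-level analysis is meant to exhibit |
| drift coefficient sds | (0, 4, 2, 1) a.u. | slow drifts a few tenths of a percent of baseline |

The generator reproduces the statistical structure the analysis
assumes — HRF-convolved boxcars, Legendre drift, ARMA(1,1) noise,
between-participant amplitude variability. It does **not** emulate
spatially correlated noise, physiological fluctuations, motion
artifacts coupled to the true motion parameters, HRF variability across
areas/participants, non-responsive-but-negatively-responding nodes, or
any image-space (voxel/NIfTI) representation. Passing tests therefore
validate the analysis chain under its own assumptions; they say nothing
about robustness to model misspecification in real data.

## GLM

Condition regressors span runs as single columns (4 total) and drift is
per-run (48 columns), matching the protocol's 58-regressor design;
censoring drops the first 3 volumes of each run from data and design
(2016 rows, 168 per run). Motion columns are standardized per run.

ARMA(1,1) estimation is per node, by minimizing the conditional sum of
squared innovations (the conditional Gaussian likelihood) over the
stationary/invertible region with Nelder–Mead, initialized by moment
matching on the lag-1/lag-2 autocorrelations. Two numerical guards:

- The CSS surface is exactly flat along the common-factor line
  b = −a (the filter cancels), so near-white residuals are otherwise
  unidentified; a small ridge penalty `3×10⁻³ · Σx² · (a² + b²)` breaks
  the tie toward (0, 0). The bias this introduces at realistic (a, b)
  is well below the estimator's sampling error (cross-checked against
  exact-ML ARMA in the tests).
- Near-constant residuals fall back to (0, 0) with a warning.

Whitening applies the innovation filter `[1, −a]/[1, b]` per run to
data and design; with (a, b) = (0, 0) this is the identity and the fit
equals OLS. The psc baseline is the mean of the fitted drift-only
timecourse (dominated by the P₀ intercept) — the only reading that
yields a baseline in signal units. The responsiveness contrast is the
unweighted sum of the four condition betas, tested one-sided;
Benjamini–Hochberg selection runs within each participant ×
hemisphere group at q = 0.001.

## Trend inference

Contrast vectors are built by exact rational Gram–Schmidt on levels
0..k−1 and reduced to primitive integers (sign: last entry positive),
reproducing the standard tables. The permutation test shuffles each
participant's four values independently each iteration (the literal
within-participant exchangeability null), uses the add-one estimate
p = (1 + count)/(N + 1) with ties counting as extreme (conservative),
and doubles the directional tail (capped at 1) rather than using
|null| ≥ |obs|. Consequently 2/(N+1) ≤ p ≤ 1. A zero observed
coefficient returns p = 1. The group coefficient is the mean of
per-participant contrasts (identical to a contrast of group means for
balanced data). The meridian-distance analysis bins nodes at
{0, 22.5, 45, 67.5, 90}° and repeats the averaging + test per bin,
flagging a bin as missing if any participant contributes no nodes.

## Behavioral analysis

Digit events at 3 Hz; each is a target with probability 1/20 (ten
digits × two polarities, two targets). Hits occur at target + lag with
probability `hit_rate`; false alarms are per-non-target-event with
probability `false_alarm_rate`. Trains are discretized into 100 ms
bins. Lags are 0.0–1.4 s inclusive: a bin width of 0.1 s on "0 to
1.5 s" admits 16 values, but the analysis has 15 lag levels, so the
grid stops at 1.4 s. A bin's condition is the block active at the
*target* bin. Correlations are Pearson on binary series (phi), with
zero-variance restrictions reported missing.

The two-way repeated-measures ANOVA partitions SS explicitly
(participants random; each fixed effect tested against its interaction
with participants). Because a pooled error is also common — and yields
the (14, 280) shape for the lag effect with 6 participants, 4
conditions and 15 lags — the table additionally reports a
clearly-labeled pooled-error variant for the lag effect, with error SS
= (lag × participant) + residual. The partition is cross-checked
against pingouin in the tests.

## Pipeline and reproducibility

All randomness descends from one seed through named `SeedSequence`
substreams (stimulus, design, cohort, behavior, permutation), so
changing the draw count in one stage cannot perturb another. `run-all`
echoes its config into the output directory; tables are deterministic
byte-for-byte given a config.

## Problem sizes in the test suite

Tests run at desk scale, chosen as package defaults for quick
iteration: the permutation-calibration study uses 500 null cohorts of
6 participants × 2 runs × 10 flat-profile nodes with 10³ permutations
(the add-one two-tailed test is expected to be slightly conservative;
the check is the 95% binomial band around α = 0.05); parameter
recovery uses all six areas at 4 + 1 nodes per hemisphere. The
per-condition recovery check uses a Monte-Carlo SE from the error SD
pooled across areas and conditions (a 6-participant per-condition SD
estimate is too noisy to control 24 simultaneous comparisons) at 3 SEs,
with the aggregate per-area bias held to 2 SEs. The acceptance script
averages three cohort seeds for the recovered V3 difference.

## Known limitations

- GLS uses the conditional (innovation-filter) approximation rather
  than exact initial-condition whitening or REML variance components.
- The permutation test's doubling of the directional tail can exceed
  the exact two-sided level for asymmetric nulls (by design, matching
  the analysis convention it implements).
- The behavioral simulator draws a single fixed response lag per run
  configuration; real response-time jitter would widen the lag profile.
- No plotting utilities; outputs are TSV/JSON for external tooling.
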