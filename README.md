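# glasscoherence

A self-contained pipeline for a polar Glass-pattern coherence fMRI
block-design experiment: stimulus synthesis, first-order counterbalanced
block design, a synthetic multi-participant BOLD cohort, a prewhitened
GLM with percent-signal-change conversion, orthogonal-polynomial trend
inference by permutation testing, and the accompanying fixation-task
behavioral analysis.

It is aimed at vision scientists and methodologists who want a fully
inspectable, seeded implementation of this analysis chain — to study its
statistical behavior (calibration, parameter recovery, sensitivity) on
simulated cohorts with known ground truth, or to reuse the individual
pieces (stimulus generator, Williams counterbalancing, ARMA(1,1)
prewhitening, within-participant permutation trend tests).

## The experiment and the model

**Stimuli.** A polar Glass pattern is a field of dot pairs (*dipoles*)
placed uniformly over a square region at 25 dots/deg². A proportion
*c* (the *coherence*: 0, 0.33, 0.66 or 1) of dipoles is oriented by a
polar rule relative to fixation — tangential (*circular* form) or radial
(*starburst*) — while the rest take random orientations. Dots are
Gaussian profiles (σ = 0.025°) separated by 0.14°, full increments or
decrements from a mean-luminance background, shown inside a 1.5–14.4°
annulus with 0.75° raised-cosine contrast ramps.

**Design.** Blocks of 16 s; four stimulus conditions plus blank. Each
run holds four sequences of (4 stimulus blocks + blank), arranged so
that every condition immediately follows every other exactly once per
run (a row-complete Williams arrangement), plus a 6 s lead-in and an
appended blank: 342 s = 171 volumes at TR = 2 s; 12 runs per
participant, 6 participants.

**Analysis.** Per cortical-surface node, the signal is modeled as

```
y = X β + ε,    ε ~ ARMA(1,1)
```

where X holds one boxcar ⊛ double-gamma HRF regressor per condition
(spanning runs), per-run Legendre drift P₀–P₃, and six motion nuisance
columns — 2016 retained volumes × 58 regressors after censoring the
first 3 volumes of each run. The fit is two-pass: OLS, ARMA(1,1)
estimation on the residuals, then GLS via innovation filtering.
Condition betas become percent signal change, psc = 100·β/baseline,
with the baseline the mean fitted drift timecourse. Stimulus-responsive
nodes (one-sided all-stimulus > 0 contrast, Benjamini–Hochberg at
q = 0.001 per hemisphere) are averaged within each visual area and each
participant's mean across conditions is subtracted.

The coherence response function of each area is summarized by
orthogonal polynomial contrasts (linear [−3,−1,+1,+3], quadratic
[+1,−1,−1,+1], cubic [−1,+3,−3,+1]); significance comes from 10⁴
permutations in which each participant's four condition values are
independently shuffled, with the directional tail probability doubled
(two-tailed). The synthetic cohort injects flat coherence responses in
V1/V2 and linear ones in V3, hMT+, DRA and VRA with full-versus-zero
differences of 0.153, 0.101, 0.185 and 0.246 psc.

## Worked example

```python
from glasscoherence import (CohortConfig, simulate_cohort, fit_cohort,
                            orthogonal_contrasts, permutation_trend_test,
                            substream)

config = CohortConfig(areas=("V1", "V3"), nodes_per_area_hemi=10,
                      nonresponsive_per_area_hemi=2)
cohort = simulate_cohort(config, substream(5, "cohort"))
fit = fit_cohort(cohort, whiten=True, q=0.001)
print("design matrix:", fit.design_shape)

linear = orthogonal_contrasts(4).linear
for area in ("V1", "V3"):
    mat = fit.area_matrices[area]
    res = permutation_trend_test(mat, linear, 10_000,
                                 substream(5, "permutation"))
    diff = (mat.values["c100"] - mat.values["c0"]).mean()
    print(f"{area}: linear coeff = {res.coefficient:+.3f}, "
          f"p = {res.p_two_tailed:.4f}, full-vs-zero = {diff:+.3f} psc")
```

prints

```
design matrix: (2016, 58)
V1: linear coeff = -0.074, p = 0.6015, full-vs-zero = -0.026 psc
V3: linear coeff = +0.494, p = 0.0118, full-vs-zero = +0.151 psc
```

The design matrix has the protocol's exact dimensions. The flat V1
profile yields a small linear coefficient and a non-significant
permutation p; the V3 area, whose injected linear effect is 0.153 psc
full-versus-zero, recovers a difference of +0.151 psc and a clearly
significant positive linear trend.

A command-line surface wraps the same stages:

```sh
glasscoherence make-stimuli --coherence 0.66 --form circular --seed 1 --out-dir stimuli
glasscoherence make-design --n-runs 12 --seed 1 --out-dir design
glasscoherence run-all --seed 1 --out-dir out
```

`run-all` writes events TSVs, node/area psc tables, the area ×
{linear, quadratic, cubic} trend table, the behavioral ANOVA and a
`report.json` with all seeds and stage summaries.

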