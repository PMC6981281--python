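# Methods

## The cell-death cycle model

`necrokinetics` models the kinetics of *active neuronal necrosis* — single
dying neurons counted per 143 μm × 143 μm microscopy field in the cortex of
amyloid-pathology mouse models. The model assumes that cell death proceeds
in regular cycles of length *p* days, beginning at an onset time *t₀*, and
that during each cycle a constant fraction *r* of the residual neuron
population dies. With *N* neurons per field at onset, the population
entering cycle *k* is

    N_k = N (1 − r)^(k−1),        k = 1, 2, …

and the number of deaths during cycle *k* — what a snapshot of the field
shows as active necrosis — is

    D_k = N r (1 − r)^(k−1) = N_k − N_{k+1}.

Calendar time is mapped to a **continuous** cycle index

    k(t) = (t − t₀)/p + 1,        t ≥ t₀,

so the expected count decays geometrically and smoothly after onset and is
exactly zero before it. The fractional-cycle convention matters: with the
reference fitted parameter set (N = 30.3 cells/field, r = 0.141, p = 31 d,
t₀ = 31 d) it yields 3.706 cells/field at day 60, whereas integer-stepped
cycles would hold the day-31 value until day 62. Times before `onset_days`
return a NaN sentinel from `cycles_at_time` and zero expected necrosis.

Assumptions worth keeping in mind: the death ratio is constant over the
whole course (no age-dependent hazard), fields are homogeneous and
independent, and the model describes expected counts only — the
distribution around the mean is left to the noise model of the generator.

## Parameters

| parameter     | meaning                               | units  | domain      | default grid        |
|---------------|---------------------------------------|--------|-------------|---------------------|
| `n0`          | neurons per field at onset            | cells  | > 0         | 5–60, step 0.1      |
| `r`           | per-cycle death ratio                 | —      | 0 ≤ r < 1   | 0.01–0.6, step 0.001|
| `period_days` | cycle length *p*                      | days   | > 0         | 5–90, step 1        |
| `onset_days`  | first detectable necrosis *t₀*        | days   | ≥ 0         | 0–90, step 1        |

`n0` is real-valued: it is an expected count per field, and the reference
fit (30.3) is itself fractional.

## Fitting

The objective is the unweighted sum of squared differences between the
per-time-point **mean** count and the model curve (`sse_objective`);
weighting by the number of fields per time point is available but off by
default, since the design is balanced in the intended use.

`fit_model` minimises this objective exhaustively over the Cartesian
product of the parameter grids. Because the SSE is a quadratic in `n0`
for fixed (r, p, t₀), the search profiles `n0` analytically: only the grid
values bracketing the unconstrained quadratic minimiser are scored, and
they are scored with the plain sum-of-squares expression, so the selected
point is exactly the brute-force grid minimum at a fraction of the cost
(the equivalence is asserted against a literal brute force in the test
suite). Ties in SSE are broken toward the lexicographically smallest
(r, period, onset, n0), making the search deterministic. An optional
refinement stage (`refine=True`) then runs bounded coordinate-wise
minimisation of each parameter within the interval spanned by its grid
neighbours, cycling until the largest relative change in a sweep falls
below `refine_tol` (default 1e-6); a refined point is accepted only if it
lowers the SSE, so refinement never degrades the fit, and it cannot leave
the grid hull. All-zero count tables leave `r` unidentified: the fit
short-circuits, pins `r` at the grid's lower bound and sets
`degenerate=True` rather than guessing.

### Identifiability and the detection-anchored estimator

On a design whose sampled ages all lie at or after onset, the model mean
reduces to a two-parameter exponential

    μ(t) = B e^{−s t},   s = −ln(1 − r)/p,   B = n0 r e^{s t₀},

so only (s, B) are identified and the four parameters trade off along an
exact two-dimensional ridge: any (r, p) pair with the same decay rate s,
compensated by (n0, t₀) in the amplitude, fits equally well. A free
four-parameter grid fit of such data returns an essentially arbitrary
point on that ridge (we verified this directly: across simulated
replicates the free fit scatters over r ≈ 0.1–0.33 and p ≈ 30–85 with no
tendency toward the generating values). No estimator can do better from
the decay alone; the period must come from additional structure.

`fit_detection_anchored` supplies that structure from the model itself:
detectable necrosis begins one cycle after initiation, so the onset is
estimated as the earliest sampled age with a positive mean count, the
period is tied to the onset, and only (n0, r) are grid-searched. Under
this estimator the simulation study below recovers n0 and r to a few
percent, and the period estimate is the data-derived detection boundary.
Both modes remain available (`fit` CLI: `--mode anchored|free`); the free
mode is appropriate only when the design brackets the onset or the period
is known.

### Bootstrap

`bootstrap_ci` resamples **fields within each time point** with
replacement (fields are the replicate unit of the count tables; animal
identity is not part of the data structure, so animal-level clustering is
not modelled), refits each replicate over the same grid, and reports
percentile intervals. The resampling and refits are driven by one seeded
`numpy.random.Generator`, making intervals bit-reproducible; the seed is
recorded in the returned object and in every written report. In a
simulation at the reference parameters (30 fields per age, 200
experiments, B = 200), nominal 95% intervals for r covered the truth in
95% of runs — this is recomputed, not quoted, by the test suite.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, so every stage runs without external inputs.

* **Count time courses** (`generate_necrosis_counts`): independent draws
  per field around the model mean. Poisson by default — active necrosis
  events are rare in a 143 μm field, and rare-event counts are the natural
  Poisson regime. A negative-binomial option (gamma–Poisson mixture,
  variance μ + μ²/θ) is provided because animal-to-animal variation
  plausibly overdisperses real counts. The emulated design is the study's:
  five ages at 31/92/184/368/552 days (1–18 months), 30 fields per age,
  small integer counts peaking near 2–6 months.
* **Biomarker cohorts** (`generate_biomarker_groups`): log-normal
  concentrations per diagnostic group — concentrations are positive and
  right-skewed. The default cohort mirrors the four-group CSF-HMGB1
  structure (nc 19, dc 11, MCI 21, AD 56 subjects); group locations are
  calibrated on the log scale so the closed-form binormal AUCs
  Φ(Δμ/√(σ₀²+σ₁²)) reproduce the reported discrimination (MCI vs nc
  0.861, MCI vs dc 0.931, MCI vs AD 0.809) at a concentration scale
  inside the assay's 100–5000 pg/mL working range. `binormal_auc` exposes
  the closed form so any target separation can be dialled in.
* **Correlated pairs** (`generate_correlated_pair`): standard bivariate
  normal with exact population correlation ρ, for exercising Pearson
  analyses.

What the generators do **not** emulate: within-animal correlation of
fields (the count tables carry no animal identity, so independence is
assumed and stated), assay-level effects (calibration curves, CV%,
detection limits), and any longitudinal within-subject structure in the
cohorts. Passing tests therefore demonstrate correctness of the methods
under the stated sampling model, not robustness to clustered or
assay-censored real data.

## Statistical toolkit

* **Rank-sum test**: midranks for ties; U reported for the first sample.
  For untied data with n·m ≤ 400 the two-sided p comes from the exact
  null distribution, built by the shift-algorithm dynamic programme
  (identical to enumerating all C(n+m, n) assignments, which the tests do
  literally as an oracle). Otherwise a normal approximation with
  tie-corrected variance and a 0.5 continuity correction is used. Results
  are labelled `"exact"` or `"normal"`; exact enumeration under ties is
  not implemented (the tied permutation distribution is data-dependent,
  and the tie-corrected asymptotic is standard practice there).
* **Bonferroni**: adjusted p = min(1, m·p); in `compare_groups`, m is the
  number of pairwise comparisons actually performed and is recorded in
  the output table.
* **ROC/AUC**: empirical curve over all distinct thresholds with the
  `score ≥ threshold`, cases-score-higher orientation; endpoints (0,0)
  and (1,1) always included; AUC below 0.5 is reported as-is. The
  rank-based AUC equals the trapezoidal area of the curve and the
  pairwise concordance probability (ties counted half) exactly.
* **Pearson correlation**: product-moment formula, optional two-sided p
  via the t transform with n−2 degrees of freedom; constant input is an
  error rather than a silent NaN.
* **Box summaries**: quartiles by linear interpolation between order
  statistics (one fixed, documented convention); whiskers at the most
  extreme observations within 1.5×IQR Tukey fences.

## Problem sizes and numerical choices

The recovery experiment (analysis/03 and the acceptance machinery) uses
11 independent seeds of the 5-age × 30-field design and reports medians —
enough replicates for a stable median while keeping every fit exact over
the 551 × 591 anchored grid. The coverage study uses 200 experiments ×
200 bootstrap replicates. Grid SSEs are compared exactly (no tolerance);
ties are resolved lexicographically as above; `searchsorted` bracket
candidates are widened by one grid step on each side so floating-point
rounding cannot skip the true minimiser.

## Known limitations

* The period is only identifiable through the detection boundary; if the
  first sampled age lies well after true onset, the anchored period
  estimate is biased toward that age. Sampling before onset tightens it.
* The model has no spatial structure and no distinction between necrosis
  morphologies (single-cell events only).
* Percentile bootstrap intervals inherit grid discretisation at very
  coarse grids; the default r step (0.001) is far below the interval
  width in the intended designs.
* Likelihood-based (Poisson/NB regression) fitting is deliberately out of
  scope; the estimator is least squares on means.
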