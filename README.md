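# necrokinetics

Kinetics of active neuronal necrosis in amyloid-pathology brains:
a discrete-cycle population model, grid-search parameter estimation with
bootstrap uncertainty, seeded synthetic data, and the group-discrimination
statistics used around CSF biomarker cohorts.

## The problem

In amyloid mouse models and human prodromal Alzheimer's disease, single
dying neurons ("active necrosis") can be counted per microscopy field
(143 μm × 143 μm) at successive ages. The counts rise to a peak in the
preclinical window and then decline — the natural kinetics of a shrinking
susceptible population. This package is for analysts who want to fit
those kinetics, predict counts at unmeasured ages, and run the companion
cohort statistics (rank-sum tests with Bonferroni correction, ROC/AUC,
Pearson correlation, box summaries) on biomarker concentrations such as
CSF HMGB1.

## The model

Cell death proceeds in cycles of length *p* days starting at onset *t₀*;
each cycle kills a constant fraction *r* of the residual population. With
*N* neurons per field at onset:

- residual neurons entering cycle *k*:  N_k = N (1 − r)^(k−1)
- deaths during cycle *k* (the observed count):  D_k = N r (1 − r)^(k−1)
- continuous time-to-cycle map:  k(t) = (t − t₀)/p + 1 for t ≥ t₀

Expected necrosis is zero before onset and decays geometrically after it.
Fitting minimises the sum of squared differences between per-age mean
counts and the curve over exhaustive parameter grids (exact, deterministic,
with an optional local refinement); uncertainty comes from a field-level
percentile bootstrap. Because the post-onset mean is a two-parameter
exponential, the default estimator anchors the onset at the first age with
a positive mean count and ties the period to it — see `docs/methods.md`
for the identifiability analysis.

## Worked example

```python
import necrokinetics as nk

params = nk.DeathModelParams(n0=30.3, r=0.141, period_days=31, onset_days=31)
print(round(nk.active_necrosis_at(params, 60.0), 3))   # 3.706

tc = nk.generate_necrosis_counts(params, [31, 92, 184, 368, 552],
                                 n_fields=30, seed=1)
fit = nk.fit_detection_anchored(tc)
print(fit.params)
# DeathModelParams(n0=27.2, r=0.162, period_days=31.0, onset_days=31.0)
print(round(float(nk.predict_at(fit, 60.0)), 3))       # 3.735
```

The first number is the model's closed-form prediction at day 60 from the
reference parameter set: 3.706 cells per field. The last two lines fit a
synthetic 30-fields-per-age Poisson time course generated from those same
parameters and predict day 60 from the fit (3.735 here) — the kind of
unmeasured-age prediction the model is for.

The same flow is available from the shell:

```sh
necrokinetics simulate --seed 1 --out counts.csv
necrokinetics fit --input counts.csv --out-dir fit --bootstrap 200 --predict-time 60
necrokinetics predict --report fit/fit_report.json --time 60
necrokinetics biomarker --out-dir bio --seed 7        # synthetic CSF cohort
```

and as narrated analysis drivers writing tables under `results/`:

```sh
python analysis/01_simulate_timecourse.py   # study-condition count table
python analysis/02_fit_necrosis_model.py    # fit + bootstrap + day-60 prediction
python analysis/03_parameter_recovery.py    # 11-seed recovery experiment
python analysis/04_biomarker_cohort.py      # cohort tests, ROC/AUC, boxes
```

For example, `03_parameter_recovery.py` prints:

```
recovery over 11 seeds (median estimate, true value, rel. error):
  n0             30.500    30.300    0.7%
  r               0.147     0.141    4.3%
  period_days    31.000    31.000    0.0%
```

— the median refitted initial count, death ratio and period across 11
independently simulated time courses, against the generating values.

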