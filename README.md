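# tugait

Faller identification from a single waist-worn triaxial accelerometer
recorded while a person performs three consecutive Timed-Up-and-Go (TUG)
trials: the plain test, a dual-task manual variant (carrying a cup of
water, TUG-M) and a dual-task cognitive variant (serial subtraction,
TUG-C).  In healthy, active older adults the stopwatch times of these
tests do not separate fallers from non-fallers; the spectral content of
the acceleration signal does.  `tugait` is for researchers in gait and
fall-risk analysis who want that pipeline as a tested, reusable library
with a command-line front end and a synthetic-data generator, so every
stage can be exercised without access to a clinical cohort.

## Method

All analysis runs on the orientation-independent magnitude
`s(t) = sqrt(x(t)^2 + y(t)^2 + z(t)^2)` — the sensor's attitude on the
belt is not controlled — optionally low-pass filtered with a zero-phase
Butterworth filter.  A rolling-median activity detector splits the
recording into the three trials; the concatenated trials ("s") and the
individual trials ("t", "m", "c") each contribute ten spectral features
computed from the one-sided power spectrum `S(w)`:

- **PSE** (power spectral entropy): `f1 = -sum_w S(w) * log(S(w) + eps)`,
  `eps = 0.001`, a complexity/energy summary of the gait spectrum;
- **PSPF 1–3**: frequencies of the three highest spectral peaks
  (gait harmonics), successive peaks found by argmax with an exclusion
  band around peaks already found;
- **PSP 1–3**: the spectral power at those frequencies;
- **WPSP 1–3**: `WPSP_i = PSPF_i * PSP_i`.

That is 40 features per subject.  Distance features
`d_j(a, b) = |f_j^a - f_j^b|` between pairs of sources quantify how a
dual task reshapes the spectrum.  Features are screened with two-sided
Mann-Whitney U tests (faller vs non-faller), significant ones are fused
by the normalised average (min-max to [0, 1], then the per-subject
mean), and each candidate variable is evaluated by ROC analysis with
faller as the positive class: trapezoidal AUC, a stratified-bootstrap
95% CI, and sensitivity, specificity and f1-score at the
equal-error-rate cut-off (the threshold where the sensitivity and
specificity curves cross), reported both as a raw score and as a
probability through a univariate logistic map.

## Worked example

Draw an 18 + 18 cohort of the four discriminative distance features from
the reference group statistics, screen, fuse and evaluate:

```python
from tugait import CohortSpec, fuse_average, generate_feature_cohort, roc_analysis, utest_screen
from tugait.synthetic import REFERENCE_GROUP_STATS

distance_rows = {k: REFERENCE_GROUP_STATS[k] for k in
                 ("d_pse_s_c", "d_psp_1_s_c", "d_pspf_1_t_m", "d_wpsp_1_m_c")}
table = generate_feature_cohort(CohortSpec(features=distance_rows, n_pos=18, n_neg=18, seed=1))

for r in utest_screen(table):
    print(f"{r.feature:15s} fallers {r.mu_pos:7.3f} +- {r.sd_pos:.3f}   "
          f"non-fallers {r.mu_neg:7.3f} +- {r.sd_neg:.3f}   p={r.p_value:.4f}")

fused = fuse_average(table, table.feature_names)
res = roc_analysis(fused.values.to_numpy(), table.data["group"], n_boot=2000, seed=1)
print(f"\nfused distance variable: AUC={res.auc:.3f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"sens={res.sens:.2f}, spec={res.spec:.2f}, f1={res.f1:.2f}, "
      f"prob cut-off={res.prob_cutoff:.2f}, value cut-off={res.value_cutoff:.3f}")
```

prints

```
d_psp_1_s_c     fallers   0.024 +- 0.009   non-fallers   0.039 +- 0.008   p=0.0000
d_pse_s_c       fallers   6.284 +- 2.325   non-fallers   8.908 +- 2.163   p=0.0026
d_wpsp_1_m_c    fallers   0.375 +- 0.242   non-fallers   0.790 +- 0.641   p=0.0142
d_pspf_1_t_m    fallers  18.792 +- 5.223   non-fallers  19.335 +- 3.754   p=0.5418

fused distance variable: AUC=0.926 (95% CI 0.83-0.99), sens=0.83, spec=0.83, f1=0.83, prob cut-off=0.62, value cut-off=0.508
```

Three of the four distance features separate the groups individually
(p < 0.05); fusing them lifts discrimination well above any single
feature, with sensitivity = specificity at the equal-error cut-off.
(At n = 18 per group a single simulated cohort is noisy; the average AUC
over many replicates sits near 0.82, see below.)

The raw-signal pipeline runs the same way from the shell:

```sh
tugait simulate --out-dir cohort --n-fallers 18 --n-non-fallers 18 --seed 0
tugait segment  --recordings-dir cohort --metadata cohort/metadata.csv --out segments.csv
tugait features --recordings-dir cohort --metadata cohort/metadata.csv \
                --segments segments.csv --out features.csv
tugait analyze  --features features.csv --out-dir analysis
tugait report   --analysis-dir analysis
```

or in one step from a YAML config via `tugait run --config config.yaml`.

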