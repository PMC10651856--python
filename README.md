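# ovupredict

Ovulation-day prediction from combined hormone and ultrasound monitoring,
with the statistical machinery needed to evaluate such a rule and a
calibrated synthetic cohort generator to exercise it.

## The problem

Timing ovulation precisely matters for natural-cycle frozen embryo
transfer, insemination and natural family planning. The most reliable
direct sign is the disappearance (rupture) of the leading ovarian follicle
on transvaginal ultrasound, which defines the ovulation day D(0); days
around it are written D(−k)/D(+k). Serum LH, estrogen (E2) and
progesterone (P4) each carry timing information — the LH surge usually
peaks at D(−1), estrogen peaks at D(−2) and then falls in two phases, and
progesterone rises monotonically through the window — but no single marker
is both sensitive and specific enough on its own.

## The decision rule

`predict_day(current, previous, config, prior_follicle_documented)`
assigns one of five labels from a single visit:

**Follicle present**

1. estrogen strictly below the previous measurement (taken ≤ 2 days
   earlier) → **D(−1)** — any estrogen decrease with the follicle still
   present is followed by rupture the next day;
2. otherwise P4 ≥ 2 nmol/L **and** LH ≥ 40 IU/L → **D(−1)**;
3. otherwise → **D(−2) or earlier**.

**Follicle absent** (requires earlier documented follicle development)

4. P4 ≤ 5 nmol/L → **D(0)**;
5. P4 > 9 nmol/L → **D(+1) onward**;
6. P4 in (5, 9] nmol/L → **indeterminate** (the rule declines to call a
   day).

Around the rule the package provides:

- `cycle_data` — the longitudinal data model (visits, cycles, datasets),
  CSV I/O, retrospective D(0) annotation and day-offset alignment;
- `synthetic_cycles` — a generator of monitoring cohorts calibrated to
  published per-day hormone summaries and structural event frequencies
  (LH-peak day displacement, late estrogen drop, sharp ≥ 50% fall);
- `trajectory_stats` — per-day mean ± SEM summaries, within-cycle
  relative-change statistics, box-plot five-number summaries with
  1.5×/3× IQR fences;
- `diagnostics` — 2×2 tables, sensitivity/specificity/PPV/NPV/accuracy
  with 95% CIs (Clopper–Pearson exact; standard-logit for predictive
  values), Bayes-rule reconstruction of predictive values from
  (sens, spec, prevalence), empirical ROC curves with Mann–Whitney AUC and
  Hanley–McNeil CIs, and cutoff selection (sens×spec or Youden);
- `validation` — the end-to-end harness: apply the rule at every true
  D(−1) and D(0) visit of a cohort and report accuracies and the
  indeterminate fraction.

## Worked example

```python
from ovupredict import (
    default_simulation_params, simulate_cohort,
    validate_preovulatory, validate_postovulatory,
    per_day_summary, evaluate_marker, Marker, MarkerRule,
)

params = default_simulation_params()
cohort = simulate_cohort(params, n_cycles=118, rng_seed=1)

row = {r.day_offset: r for r in per_day_summary(cohort, "estrogen")}[-2]
print(f"E2 at D(-2): {row.mean:.1f} +/- {row.sem:.1f} pmol/L (n={row.n})")

drop = evaluate_marker(
    cohort, MarkerRule(Marker.E_CHANGE, "any_decrease"),
    positive_offset=-1, negative_offset=-2,
)
print(f"any E2 decrease, D(-1) vs D(-2): sens "
      f"{drop.metrics.sensitivity.percent:.1f}%, "
      f"spec {drop.metrics.specificity.percent:.1f}%")

pre = validate_preovulatory(cohort)
post = validate_postovulatory(cohort)
print(f"pre-ovulatory accuracy {pre.accuracy_percent:.1f}% "
      f"({pre.n_correct}/{pre.n_eligible})")
print(f"post-ovulatory: {post.indeterminate_percent:.1f}% indeterminate, "
      f"{post.accuracy_percent:.1f}% of determinate calls correct")
```

prints

```
E2 at D(-2): 1421.7 +/- 42.7 pmol/L (n=118)
any E2 decrease, D(-1) vs D(-2): sens 84.7%, spec 100.0%
pre-ovulatory accuracy 93.2% (110/118)
post-ovulatory: 48.3% indeterminate, 100.0% of determinate calls correct
```

The per-day mean recovers the calibration target (1378 ± 66 pmol/L at
D(−2)) within sampling noise; the 100% specificity of the
estrogen-decrease marker is structural — in the generator, as in the
monitored cycles it emulates, an estrogen fall with the follicle still
present is always followed by rupture at the next visit. The
pre-ovulatory accuracy reflects the ~19% of cycles whose estrogen drop
appears only on the rupture day, partly rescued by the P4+LH branch; the
high indeterminate fraction at D(0) reflects the genuine P4 overlap
between D(0) and later days.

The same pipeline is available from the shell:

```bash
ovupredict simulate --n-cycles 118 --seed 1 --out cohort.csv
ovupredict predict  --input cohort.csv --out predictions.csv
ovupredict report   --n-cycles 118 --seed 1 --out report/
```

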