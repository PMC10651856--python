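# Methods

## Data model and day alignment

A monitoring visit records serum LH (IU/L), estrogen (pmol/L),
progesterone (nmol/L), the leading-follicle mean diameter (mm) and
endometrial thickness (mm). Cycle day 1 is the onset of menstrual
bleeding. The ovulation day D(0) is assigned retrospectively to the first
visit at which a previously documented leading follicle is no longer
visualized; no sub-day interpolation is attempted even though rupture
occurred at some point in the preceding 24 h, because the clinical rule
operates on the same visit grid. A prior follicle of at least 14 mm
(configurable) is required before an absent-follicle visit may be labelled
D(0); this guards against mistaking the loss of a small non-dominant
follicle for ovulation. Analyses use the window D(−3)..D(+3).

Missing hormone values propagate as "unavailable" to downstream rules —
never as zero. The follicle field distinguishes *present* (a diameter),
*absent* (ultrasound performed, no follicle: the rupture signal) and *not
assessed*; in CSV an empty field means absent once a follicle was
documented earlier in the cycle, and the literal `NA` means not assessed.
An absent-follicle visit with no earlier visualized follicle cannot be
distinguished from "not assessed" in CSV; it is written as an empty field
and reads back as not assessed, which is the conservative interpretation.

## The decision rule

The combined rule is a fixed-order branch structure (estrogen decrease →
P4+LH → fall-through when the follicle is present; the three progesterone
zones when it is absent). Boundary conventions are taken literally: P4 ≥ 2
and LH ≥ 40 inclusive, P4 ≤ 5 inclusive toward D(0), P4 > 9 strict toward
D(+1) onward; an estrogen value equal to the previous one counts as
"unchanged", not as a decrease. The estrogen comparison uses the most
recent prior measurement no older than 2 days (the monitoring cadence);
an older or missing comparison skips the first branch and flags the
result. The LH threshold in the combined branch is 40 IU/L — the value
the algorithm itself uses — even though 35 and 60 IU/L are the thresholds
whose operating characteristics are tabulated for LH alone; all
thresholds are exposed in `RuleConfig`. Each branch carries the certainty
figure reported for it in the development cohort as opaque text; whether
the 95% figure of the P4+LH branch is a predictive value or an accuracy
is not stated in the source, so no probabilistic meaning is attached.

The `DAY_MINUS_2_OR_EARLIER` label is deliberately open-ended: the
fall-through branch cannot distinguish D(−2) from earlier monitoring
days, and the label avoids overclaiming.

## Synthetic cohort generator

The generator emulates a 118-cycle development cohort of healthy
normo-ovulatory volunteers. Its defaults are the cohort's published
per-day summaries and event frequencies; they are study conditions, not
free dials.

**Marginals.** Each (measure, day-offset) cell is a log-normal truncated
to the cell's published range, with log-scale spread matched to the
coefficient of variation implied by sd = SEM·√n (per-day n row: 54, 64,
118, 118, 55, 42, 8). Hormones are positive and right-skewed, which the
log-normal captures; the published tables state no distribution. The
log-scale location is then solved numerically (Brent root find on the
closed-form truncated-log-normal mean) so that the *truncated*
distribution's mean equals the published mean exactly. Plain moment
matching before truncation would shift realized means wherever the bounds
carry weight — most visibly for progesterone at D(−1), whose published
SEM (0.9 at n = 118, sd ≈ 9.8) is far wider than its printed range
(1.6–5.6 nmol/L) and is likely a typo; the exact-mean construction makes
the calibration robust to such inconsistencies. Two published LH ranges
are internally impossible (D(−1) "89.0–120.0" excludes its own mean of
51.9; D(0) "73.8–60.8" is inverted) and are replaced by wide plausible
bounds (10–120 and 3–75 IU/L).

**Structure.** Within each simulated cycle:

- estrogen rises strictly into its D(−2) peak, falls at D(−1) except in a
  fraction of cycles (default 19%) where the first decrease appears only
  at D(0), and falls by ≥ 50% from D(−2) to D(0) in a configurable
  fraction (default 85%);
- LH attains its per-cycle maximum at D(−1) except in a fraction
  (default 5.9%) where the peak is at D(−2);
- progesterone is nondecreasing across the whole window;
- the follicle reaches ≥ 16 mm by D(−1) and is absent from D(0) onward.

The first three event frequencies are hit, wherever achievable, by
Gaussian-copula couplings between the two cells that define each event:
the copula correlation is solved (Gauss–Hermite quadrature plus Brent)
so the event emerges at exactly its configured probability while both
day marginals remain exact. This is what makes the calibration-recovery
tests honest: designated-peak swapping or coin-conditioned resampling —
the more obvious constructions — distort the day marginals by several
sampling standard errors at cohort scale. For degenerate or extreme
parameter settings (zero variances, probabilities outside the achievable
range) the sampler falls back to explicit conditional enforcement, which
honours the event at the cost of some marginal distortion; structure
takes precedence over bounds in those corner cases. The pre-peak
estrogen days share one latent quantile (comonotone), which guarantees
the strict rise; progesterone days likewise share one latent, with a
running-maximum guard securing monotonicity.

Within-cycle coherence for LH and endometrium comes from a per-(cycle,
hormone) multiplicative log-scale random effect (`within_cycle_level_sd`,
default 0.15, a documented free parameter — the between/within variance
decomposition is not recoverable from per-day summaries alone). The
LH-peak day and the estrogen-drop timing are coupled only through their
shared calibration, i.e. effectively independent; their joint
distribution is not reported.

Cycle geometry: the follicular-phase length (mean 14.4, sd 2.2, range
9–23 days) sets the D(0) cycle day; the luteal length (13.5 ± 2.2, 9–21)
completes the cycle length, clipped to 17–38 days. Follicle diameters
walk backwards from ~20 mm at D(−1) at 1–2.5 mm/day. By default every
cycle carries all seven window days; the published per-day attrition
pattern (monitoring often started after D(−3), few cycles followed to
D(+3)) is available as `cohort_attrition()` and is applied as contiguous
truncation of follow-up so that per-day inclusion rates match the n row.

**What the generator does not emulate:** anovulatory or PCOS cycles,
intra-day hormone kinetics, assay error as a separate layer (folded into
the per-cell sd), and realistic between-visit measurement autocorrelation
beyond the structural couplings — the pre-peak estrogen rise, being
comonotone, has much less pair-to-pair spread than real data. Passing
tests therefore demonstrate that the pipeline's statistics and the rule's
structural claims behave correctly on data with the published marginal
and event structure; they do not re-establish the rule's clinical
accuracy, which was measured on real cycles that are not distributed.

## Statistics

Per-day summaries use the n−1 sample sd; SEM at n = 1 is reported as 0
with a logged warning. Relative changes are computed per pair and then
averaged (the pairing "Cases" counts of the published change table imply
per-pair computation), with the earlier value as denominator. Quartiles
default to linear interpolation between order statistics, with the SPSS
weighted-average convention selectable; outlier fences are inclusive
(≥ 1.5×IQR beyond the quartiles, extremes at 3×IQR), and with zero IQR
only values off the degenerate box are flagged.

Confidence intervals: Clopper–Pearson exact for sensitivity, specificity
and accuracy; standard-logit for PPV/NPV (falling back to the exact
interval at boundary counts); both switchable. The AUC is the
Mann–Whitney statistic (ties ½), computed as the trapezoid area under the
full empirical curve, with a Hanley–McNeil normal-approximation CI.
Cutoff selection scans all thresholds and breaks ties toward higher
specificity, then the more conservative threshold.

The balanced-prevalence (0.5) reconstruction of predictive values from
(sensitivity, specificity) by Bayes' rule reproduces every published
cutoff row's PPV/NPV/accuracy to the printed decimal (±0.1, one ulp at
the printed precision, absorbing the source's own input rounding) — the
published contrasts compare equal-sized day classes, so balanced
prevalence is their implicit convention.

## Validation harness

Eligibility is parameterized as "has the required visits": pre-ovulatory
validation needs documented D(−1) and D(0), post-ovulatory a D(0) visit
with the follicle newly absent. "Repeat test needed" is operationalized
as fall-through-branch firings at the true D(−1). The real retrospective
validation accuracies reported for the rule (97.9% pre-ovulatory, 91.8%
among determinate post-ovulatory calls) come from clinical
natural-cycle FET data that are not available; the harness reports the
synthetic analogues and the package treats the real figures as context,
not as assertable targets. On default synthetic cohorts the pre-ovulatory
accuracy lands near 92% — the estrogen-drop branch catches the ~81% of
cycles whose drop precedes rupture, and the P4+LH branch rescues roughly
half of the remainder — and the D(0) indeterminate fraction lands near
48%, close to the 46% observed clinically, because D(0) progesterone is
centred almost exactly on the 5 nmol/L boundary.

## Problem sizes

Test and acceptance runs use cohorts of 118 (the development-cohort
size), 500 (validation-scale checks and the acceptance script) and 2000
cycles (frequency-convergence checks at 4-sd binomial tolerance); a
2000-cycle simulation takes under a second, so the whole suite runs in a
few seconds.
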