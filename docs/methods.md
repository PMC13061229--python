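# Methods

This note documents the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## The orienting-response statistic

Each stimulus presentation is scored from the RR-interval stream around its
onset.  The **pre window** is the last five complete RR intervals whose
later beat falls at or before the onset; the **post window** is the first
five whose earlier beat falls at or after it.  An interval that straddles
the onset mixes pre- and post-stimulus physiology and belongs to neither
window.  Boundary ties are deterministic: an interval ending exactly at the
onset is pre, one beginning exactly at the onset is post.

With `M1` and `SD` the mean and sample standard deviation (divisor k−1) of
the pre window and `M2` the mean of the post window,

```
OR = (M1 − M2) / SD
```

classified by strict inequalities: acceleration if `OR > 2`, deceleration
if `OR < −2`, otherwise unnoticed.  `|OR|` exactly 2 is unnoticed.  The
sample (rather than population) SD is the statistical default for a
five-observation estimate; the choice is isolated in one function.

**Validity rules.**  A presentation is *invalid* (excluded from both the
numerator and denominator of every rate) when

- either window has fewer than five intervals inside `max_span_ms`
  (default 15 000 ms per side — five beats at extreme bradycardia still
  fit, while windows can never bridge a recording gap such as sleep or
  electrode loss);
- any window interval lies outside the plausible range 300–2000 ms
  (heart rate above 200 or below 30 bpm), the automated surrogate for
  visual artifact inspection — explicit and configurable;
- the pre window has zero variance (OR undefined).

**Null distribution.**  For i.i.d. Gaussian RR intervals with no stimulus
effect, `M1 − M2 ~ N(0, 2σ²/5)` independently of `SD` (mean and SD of a
Gaussian sample are independent), so `OR = √(2/5)·t₄` and

```
P(|OR| > 2) = 2·SF_t(4)(√10) ≈ 0.0341
```

This closed form anchors the Monte-Carlo acceptance checks and quantifies
the contamination floor of every apparency value: roughly 3.4 % of null
presentations are classified salient, ~1.7 % per direction.

## Apparency aggregation

Apparency for a participant × sound × scope cell is
`100 · n_salient / n_valid`; acceleration, deceleration and unnoticed
percentages are defined analogously and sum to exactly 100 before
rounding.  Scopes are the period (the 14-hour exposure day), the daypart
(daytime = segments A and C, 8:00–15:00; evening = B and D, 16:00–23:00),
a single segment, or everything.  Cells with zero valid presentations are
flagged undefined and excluded from downstream tests with a logged count.

Per-sound ratio tables pool raw counts across participants
(`100 · Σ counts / Σ valid`), not averages of per-participant percentages;
the participant-mean variant is available as a sensitivity option.

**Bathing hour.**  The protocol bathes participants 21:00–22:00 on the
evening day carrying segment B, so that hour has no usable recordings.
Its presentations are reconstructed by duplicating the same participant's
22:00–23:00 measurements (onsets shifted back one hour, provenance-flagged),
keeping per-period denominators at 14.  The original protocol describes
the replacement only as "interpolation"; duplication is the simplest
reading that preserves the printed presentation count, and the rule can be
disabled.

**Rounding.**  Internal values are never rounded; printed tables round to
one decimal, half-up.  Because each of the three direction percentages can
round by up to 0.05, a rounded row sums to 99.9, 100.0 or 100.1.

## Crossover screening

Reproducibility of each sound is assessed on completers of both periods
(those with usable recordings in each).  Per participant and sound, using
14-hour apparency per period:

- carryover statistic = apparency(P1) + apparency(P2) (range 0–200);
- period statistic = (apparency(P1) − apparency(P2)) / 2.

Each statistic is compared between the two randomization groups with
Welch's unequal-variance t-test, two-tailed, with Welch–Satterthwaite
fractional degrees of freedom and difference oriented Group 2 − Group 1.
A sound significant on either test at α = 0.05 is excluded.  No
multiplicity correction is applied across the 16 per-sound tests —
screening is deliberately conservative toward exclusion — and reports note
this.  Under homogeneity each sound survives with probability ≈ 0.95² per
the two (nearly independent) tests.

The orientation of the period statistic ((P1 − P2)/2 vs (P2 − P1)/2) is a
convention only — it flips group-mean signs but not the p-value.  Both are
supported; (P1 − P2)/2 is the default.

## Randomized-trial analyses (Period 2)

- **Populations.**  ITT = all randomized participants with any Period-2
  data; PPS = ITT minus participants whose Period-2 entries required
  imputation.  Membership is input metadata, never inferred.
- **Imputation.**  Each missing participant × sound apparency cell is
  filled with the median of that participant's available Period-2
  sound-level apparencies (midpoint at even counts) — within-participant,
  within-period, so no information leaks across periods or participants.
  A participant with nothing to impute from is an error.
- **ANOVA.**  One-way fixed effects on participant × sound apparency
  values grouped by sound, one observation per participant per sound, no
  repeated-measures term: an 18 × 11 design gives df (10, 187) and a
  16 × 11 design df (10, 165), which is the only structure consistent with
  those shapes.  Effect size η² = SS_between / SS_total, identically
  F·df_b / (F·df_b + df_w).
- **Diurnal contrast.**  Per sound, a paired t-test on per-participant
  (daytime, evening) apparency with difference oriented daytime − evening
  and Cohen's `d_z = |t|/√n` (the within-pair effect size, not the
  pooled-SD variant; both of the trial's printed t/d pairs satisfy this
  identity at n = 18).  Identical sides give t = 0, p = 1, d = 0; a
  constant non-zero difference is flagged degenerate.

## Synthetic experiments

The generator reproduces the study conditions end to end; its defaults are
the protocol's stated values wherever the protocol states one.

| parameter | default | rationale |
| --- | --- | --- |
| participants | 22 | the trial's enrolment |
| randomization | 1:1 permuted blocks of 4 and 6 | stated design |
| presentations | 16 sounds once per hour, 2 × 7-hour segments/day | stated design |
| inter-onset gap | uniform 225 ± 30 s | stated design |
| baseline RRI | 850 ms | resting heart rate ~70 bpm, healthy young adults |
| beat-to-beat noise SD | 25 ms | conventional short-term HRV (SDNN) magnitude |
| AR(1) coefficient | 0 | i.i.d. noise, so the closed-form null holds exactly; tunable to study autocorrelation effects |
| diurnal drift | 0 ms (sinusoidal amplitude) | off by default |
| p_acc, p_dec | 0.12 each | near the trial's observed per-direction rates |
| response shift | 100 ms over exactly 5 post-onset beats | rectangular shift aligned with the OR window, so E[OR] ≈ δ/σ ≈ 4 |

The five-beat rectangular response makes injected effects analytically
mappable to OR: the expected value is δ/σ up to the small-sample
reciprocal-SD factor E[σ/S] = √2·Γ(3/2)/Γ(2) ≈ 1.2533 at k = 5.

Gap sampling honours both stated properties — every gap in [195, 255] s
and all 16 onsets inside their hour — by redrawing the 15 inter-onset gaps
until the train fits (acceptance probability ≈ 0.9995) and placing it with
a uniform lead-in.  Rescaling gaps to fit instead would violate the gap
bounds by up to ~12 %.

Recordings cover waking windows only (arrival 11:00 Day 1; sleep
23:30–7:30; departure 23:00 Day 3).  The trial-shaped missingness scenario
removes Period 1 for two participants per group (equipment failure),
removes Period 2 entirely for two per group (withdrawal), and deletes six
scattered Period-2 sound cells for two further Group-2 participants,
yielding the trial's population sizes: 14 crossover completers, 18 ITT,
16 PPS.

All randomness flows from one root seed through spawned generators;
identical seed + config gives byte-identical output bundles.

**What the simulation does not model:** respiratory sinus arrhythmia or
any structured HRV beyond AR(1); habituation across the 14 presentations
of a sound; circadian heart-rate modulation (unless the drift amplitude is
set); inter-participant variability in noise level or responsiveness; and
any acoustic property of the stimuli — outcomes are drawn per presentation
with sound-independent probabilities.  Passing tests therefore establish
the correctness and calibration of the *statistical machinery* (rates,
tests, populations, determinism), not that real listeners behave like the
model.

## Numerical and scale choices

- Time is milliseconds since midnight of Day 1 of the current period;
  segment A/B sit on Day 2 and C/D on Day 3 (consistent with bathing at
  21:00 of the B evening), configurable.
- CSV floats are written with 17 significant digits and parsed in
  round-trip mode, so writer/reader pairs are exact.
- Welch's test with zero variance in both groups: equal means → t = 0,
  p = 1; unequal means → flagged degenerate.  ANOVA on identical values is
  degenerate (0/0).
- Monte-Carlo test tolerances are 3 standard errors at the stated
  replicate counts (10⁵ for the null rate; the full 18-participant
  experiment, ~7800 valid presentations, for parameter recovery).
- Problem sizes used by the test suite and acceptance script — 2–22
  simulated participants, 10⁵ null presentations, 2000 ANOVA replicates —
  were chosen so the whole suite completes in well under a minute of
  simulation time while keeping Monte-Carlo error far below the
  tolerances.

## Known limitations

- The original trial's per-participant supplementary datasets are not
  redistributable, so the printed Welch/ANOVA statistics can only be
  replicated when the user supplies those files (see
  `tests/test_acceptance.py`); the published tables alone underdetermine
  the per-participant values.
- Whether the five post-stimulus intervals should anchor at the stimulus
  file onset or after the 1.5-s stimulus envelope is not specified by the
  protocol; the onset anchor is the stimulus-file onset, and a shifted
  anchor can be emulated by offsetting event onsets.
- The bathing-hour "interpolation" is implemented as duplication of the
  following hour; any smoother definition would need the original
  system's documentation.
- Apparency values are percentages of 14 trials and hence coarsely
  discrete; the ANOVA and t-tests treat them as continuous, as in the
  original analysis.
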