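# Methods

This note records the models behind `cyclewell`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate about real monitoring data.

## Cycle segmentation and phase windows

A cycle onset is a declared-bleeding day whose 14 preceding calendar days
contain no declared bleeding. The 14-day lookback keeps a one-day gap in a
self-reported menses run (a skipped questionnaire, a light day) from
splitting one menses into two onsets; it also means cycles shorter than 15
days cannot be detected, which is below the physiological range of
interest. A complete cycle spans one onset to the day before the next;
trailing days after the last onset are unlabelled, and an athlete who never
bleeds yields no cycles and therefore drops out of phase-based analyses
automatically (amenorrhea handling). `bleed_length` counts bleeding days in
the first 10 days of the cycle, again tolerating gaps.

Predicted ovulation uses the calendar rule P.O = L − 14 (a fixed luteal
length of 14 days), clamped to at least `bleed_length + 1`. The six phases
of a cycle of length L are, with precedence menses > premenstrual >
late-follicular > early-luteal > mid-follicular > mid-luteal:

| phase           | days                         | default window |
|-----------------|------------------------------|----------------|
| menses          | 1 .. bleed_length            | bleeding run   |
| mid-follicular  | bleed_length+1 .. P.O−4      | remainder      |
| late-follicular | P.O−3 .. P.O                 | 4 d            |
| early-luteal    | P.O+1 .. P.O+4               | 4 d            |
| mid-luteal      | P.O+5 .. L−4                 | remainder      |
| premenstrual    | L−3 .. L                     | 4 d            |

All window lengths and the luteal constant are configurable
(`PhaseWindows`). The defaults are pinned by the salivary sampling
convention: on a 28-day cycle, day 8 must be mid-follicular, day 14
late-follicular and day 24 mid-luteal. Note the geometry: under the
L − 14 rule the mid-follicular window can only contain day 8 when
L ≥ 26, and day L − 4 is definitionally mid-luteal (it is day
P.O + 10, the progesterone peak) — a premenstrual window of 5+ days would
break the day-24 anchor. Cycles shorter than 21 days are not rejected;
their windows are rescaled proportionally to L/28 (with a warning), since
field data contain irregular cycles that are deliberately retained.

Pill regimens count regimen day 1 as the first pill-pause day. Days
1..pause are the withdrawal `pause`; monophasic packs have one active
phase; bi-/triphasic packs are split after active day 10 into `phase1` and
`phase2` when the true dose-change boundary is unknown (overridable per
athlete). On real calendars the regimen is anchored to the withdrawal-bleed
onset, assumed to begin on pause day 2 (`onset_pause_day`), consistent with
withdrawal bleeding typically starting one to three days into the break.

The hormone cross-check is deliberately qualitative: per-phase mean
estradiol and progesterone must show a strict progesterone peak in the
mid-luteal phase, a strict estradiol peak in the late-follicular phase and
joint minima in the mid-follicular phase. Ties fail; missing phases render
a check indeterminate rather than failed.

## Top-quintile enrichment

*Binarization.* The "top days" of athlete a for variable v are those whose
score strictly exceeds the ⌈0.8·n⌉-th order statistic of the athlete's own
n non-missing values. With heavily tied 1–10 Likert data, the strict
inequality guarantees at most 20% of days are ever flagged, whatever the
tie structure; interpolated quantile definitions do not. Athletes with
fewer than 5 values for a variable are skipped (warning) for that variable
only. The quantile order is configurable.

*Normalization.* Phase exposure is grossly unequal (menses ≈ 5 days,
mid-luteal ≈ 6+, premenstrual 4, and response rates differ per athlete),
so raw flag counts confound exposure with enrichment. Per athlete the
per-phase flag rate (flags / observed days in the phase, cycles pooled) is
computed; rates are averaged across athletes — athletes with no exposure to
a phase contribute nothing to that phase — and rescaled so the counts sum
to the raw flag total. This makes the statistic exposure-invariant (two
athletes with identical rate profiles but different follow-up lengths give
the same answer) while keeping the chi-square total on the natural count
scale. When exposures are equal the construction reduces exactly to raw
counts. Averaging per athlete-cycle instead is available (`by_cycle=True`),
as is the raw-count variant (`normalize=False`) for sensitivity analysis;
neither changes the default.

*Test and flags.* Observed per-phase counts are tested against the discrete
uniform 1/k (E = ΣO/k, df = k − 1, upper-tail chi-square p). Pearson
residuals (O_p − E)/√E are read only when the omnibus test is significant
at α = 0.05: |r| > 1.96 flags at α = 0.05, 1.64 < |r| ≤ 1.96 at α = 0.1
(two-sided standard-normal quantiles). The α = 0.1 flags are gated on the
same α = 0.05 omnibus test — a single gate keeps the two flag grades
nested. No multiple-testing correction is applied across variables by
default (`bonferroni=True` adjusts the gate). Simulation at the default
cohort size (below) puts the realized type-I rate of the omnibus test
slightly below nominal (≈ 3%), the mild conservatism expected when the
quintile threshold is estimated from the same data and per-athlete flag
totals are fixed by construction.

## Proportional-odds menses model

For ordered categories 1..m (Likert 1–10, or CR10 RPE values ranked by
their observed distinct values, which handles half-points transparently):

P(Y ≤ j | x) = logistic(θ_j − βx),  θ_1 < … < θ_{m−1},  x ∈ {0, 1}

with x = 1 on bleeding days and days missing the outcome dropped listwise.
β < 0 moves probability mass toward low scores on menses days. Priors are
flat (improper) on the order-constrained region.

*Sampler.* Because the single covariate is binary, the likelihood depends
on the data only through the m × 2 category-by-status table; the sampler
works from these sufficient statistics, so cost is independent of the
number of days. Component-wise random-walk Metropolis acts directly on
(θ, β), rejecting order-violating proposals; two additional joint
"location" moves per sweep (shift all θ together; shift θ and β together)
cross the posterior's common-shift correlation directions, which
single-component moves traverse slowly. A pure log-increment
parameterization of θ was rejected: it mixes poorly when an extreme
category is sparse, because moving the first cutpoint alone then requires a
coordinated two-component move. Per-chain, per-move step sizes adapt toward
a 44% acceptance rate during burn-in only and are frozen afterwards, so the
retained draws come from a fixed, valid kernel. Chains start at the
empirical cumulative-logit cutpoints with N(0, 0.1) jitter. Defaults: 4
chains, 1,000 burn-in, 1,000 retained draws per chain (burn-in is the
stated convention; the retained-draw count is this package's choice).

*Diagnostics and summaries.* R̂ is the split-chain Gelman–Rubin factor
√(((n−1)/n·W + B/n)/W) on split halves; values ≥ 1.1 trigger a warning
(rank-normalization postdates the convention adopted here and is not
applied). The 75% highest-density interval is the narrowest window of
⌈0.75·n⌉ consecutive sorted draws (earliest on ties) — adequate for the
unimodal posteriors that arise here, with no kernel density estimation.
Per-category probabilities are computed per draw and summarised by
posterior mean and 75% HDI; each status column's means sum to 1 exactly.

## Correlation screen

Spearman ρ = Pearson correlation of average-tie ranks, computed per
variable pair on pairwise-complete observations (the variables' missingness
is very uneven: coach scores cover ~10% of days). Two-sided p-values use
the t approximation t = ρ√((n−2)/(1−ρ²)) for n ≥ 30 and a seeded
10,000-draw permutation test below that; cells with fewer than 4 complete
pairs or zero rank variance are indeterminate (NaN, never significant).
Daily symptom burden enters as the count of distinct declared symptoms. No
multiple-testing correction (raw α = 0.05 per pair).

## Synthetic cohort generator

The generator produces the structure the analyses assume, not any real
athlete's values: 6 naturally cycling athletes + 1 amenorrheic + 5 pill
users (one monophasic, three biphasic, one triphasic; 21 active + 7 pause
days), 150 days of follow-up (≈ 4–5 complete cycles of 28 ± 2 days,
truncated to 22–35), ~5-day menses, 78% daily response, coach scores on
~10% of days coupled (r ≈ 0.7) to the athlete's own performance rating.

Scores are latent-Gaussian-then-discretized: latent = baseline (6.5) +
athlete effect (SD 0.7) + shared day factor (SD 0.8, couples the wellness
variables) + phase effect + sleep/symptom terms + noise (SD 1.5), rounded
and clipped to 1..10. Both downstream analyses are mildly misspecified for
this generative model, which is realistic. The effect preset
(`midcycle_effect_preset`) plants a mid-cycle boost (+1.5 latent points
late-follicular, +1.0 early-luteal) and a menses/premenstrual deficit
(−1.5/−1.0) for mood, fitness and self-rated performance, a premenstrual
sleep-quality dip, and for pill users a pause deficit and phase-2 boost in
self-rated performance; symptom probability rises from a 0.12/day baseline
to 0.45 in menses/pause and 0.30 premenstrually. Magnitudes are tunable
defaults, not estimates of any published effect. RPE is drawn independently
of phase and status, so the ordinal model should find nothing — the
built-in negative control. `null_cohort` zeroes all phase effects and
symptom-rate differences for type-I-error studies.

Hormone draws at cycle days 8/14/24 ± 2 are lognormal with (μ, σ)
moment-matched to the published per-phase means/SDs (estradiol 2.5 ± 1.5,
6.9 ± 4.2, 6.0 ± 3.8 pg/mL; progesterone 38.1 ± 31.3, 42.8 ± 56.9,
81.85 ± 35.7 pg/mL for mid-follicular/late-follicular/mid-luteal; pill
phases 1.6 ± 0.3 / 1.8 ± 0.9 and 20.4 ± 7.6 / 29.6 ± 10.9). Lognormal
support matches the positivity and right skew of salivary assays.
Withdrawal bleeding is placed on pause days 2–5 so the binary scheme is
exercised in both groups. Identical config + seed reproduces byte-identical
CSV output.

What the generator does **not** emulate: anovulatory cycles, luteal-phase
defects or intra-cycle hormone dynamics (no LH surge); training-load
periodization, travel or competition stress; informative missingness
(days are missed at random, whereas real athletes may skip questionnaires
on bad days); learning/drift in scale usage; and any real cohort's values.
Passing tests therefore demonstrate statistical correctness and power under
a plausible data-generating process, not field validity.

## Validation problem sizes and numerical choices

The acceptance-level checks run at these sizes, chosen to make Monte Carlo
noise small relative to the margins being tested: type-I error on 2,000
phase-null cohorts (6 athletes, ~5 cycles, 78% response); effect recovery
on 500 preset cohorts; ordinal recovery on 100 fits of n = 800 days with
true β ∈ {−1, 0, 1}; hormone ordering on 200 seeds × 1,000 draws per phase
(at the default cohort's ~25 draws per phase the ordering check fails in
roughly a third of seeds from sampling noise alone — the large-n check
verifies the configured means, the cohort-scale check only illustrates).
Oracle agreement (chi-square, Spearman, ordinal likelihood) is exercised on
hundreds of random instances at 1e-10/1e-12 tolerances against independent
implementations.

Numerical conventions: chi-square p-values from the upper tail
(`scipy.stats.chi2.sf`); expected counts strictly positive or the residual
step errors; proposals with non-finite likelihood are rejected rather than
clamped; HDI ties broken toward the earliest window; bedtime encoded as
minutes after 12:00 noon so late-night values stay monotone for rank
statistics (a wrap-around clock breaks them).

## Known limitations

- Calendar-only ovulation prediction: no LH, basal body temperature or
  hormone-informed ovulation detection; anovulatory cycles are invisible.
- The six-phase windows are convention-anchored, not individually verified;
  short cycles (< 21 d) use proportional scaling, a pragmatic fallback.
- The ordinal model pools days across athletes with no per-athlete random
  effect and assumes proportional odds; it quantifies association, not
  causation, between menstrual status and scores.
- The enrichment chi-square treats normalized counts as multinomial; the
  realized type-I rate is mildly conservative (≈ 3% at nominal 5% for the
  default cohort size).
- Symptom vocabulary is open; analyses treat symptom codes as unordered
  labels with no severity weighting beyond the daily count.
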