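# Methods

This note documents the models behind `hstsim`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic cohort does
and does not say about real patients.

## Scale grid and domain conventions

The hearing-scale grid is fixed as S*k* = 5·*k* dB HL for *k* = 1..20,
anchored on S5 = 25 dB HL and S17 = 85 dB HL with adjacent scales 5 dB
apart. Levels at or below 5 dB HL clamp to S1 (a screening floor; there is
no S0), and levels above S20 = 100 dB HL have no scale: an ear that fails
every scale is recorded as `NO_RESPONSE`. For difference arithmetic
`NO_RESPONSE` enters as the surrogate index 21 — one step past S20 — which
preserves ordering without inventing a dB value; every result that used the
surrogate is flagged (`involves_no_response`).

Siegel grading of a PTA uses the inequality form of the printed integer
ranges (≤25 → 1, ≤45 → 2, ≤75 → 3, ≤90 → 4, else 5) so that non-integer
PTAs (means of four thresholds) are always classified; the five intervals
partition [−10, 120] dB HL exactly.

## Virtual listener

The listener answers each tone with probability
`p(L) = γ + (1 − γ − λ) · logistic((L − t)/s)` — threshold `t` per ear and
frequency, spread `s` (default 3 dB), guess rate `γ` and lapse rate `λ`
(defaults 0.02 each). These defaults are conventional psychoacoustics
values, not estimates from any dataset; no published false-alarm or lapse
behaviour exists for this screening population, so they are deliberately
configurable. The logistic (rather than cumulative-normal) form was chosen
for its closed-form CDF; at these slopes the two are indistinguishable to
the procedures simulated here. Deterministic mode is the step-function
limit (`heard ⇔ L ≥ t`, boundary inclusive), which makes every adaptive
procedure exactly analyzable and is the mode used for oracle tests. Each
listener owns one seeded random stream advanced once per presentation, so
responses are reproducible given the seed and presentation order and
independent across listeners.

## HST engine

Only the descent rule of the scale test is fully specified by the
procedure it models (descend one scale after an all-correct block of four
tones, fixed order 1/2/4/0.5 kHz). The engine adopts the minimal symmetric
completion: ascend one scale on any miss, and stop once the boundary is
bracketed — an all-correct block at *k* with a missed block on record at
*k*−1, or *k* = 1 all-correct. A miss at S20 with no all-correct block
anywhere gives `NO_RESPONSE`. Further conventions:

- **Within-block short-circuit.** A block stops at its first miss; the
  all-correct requirement is already violated and the remaining tones carry
  no information for the search.
- **No response caching.** A revisited scale is re-tested in full, as a
  live app would; caching would silence stochastic variability.
- **No confirmation re-test** of the final boundary by default
  (`confirm_repeats = 0`), favouring screening speed; confirmations, when
  enabled, re-run the winning block and resume the search on failure.
- **Presentation cap** `max_presentations = 120`, sized so that every
  deterministic run completes (a full ascent S1→S20 with the miss always on
  the block's last tone needs 84 presentations); only oscillating
  stochastic listeners hit the cap, and such runs are flagged invalid
  rather than guessed at.
- Ear order defaults to right-then-left; tone duration (1.5 s) and
  inter-stimulus interval (2–3 s) are logged metadata — simulated time is
  not modelled.

For a deterministic listener the result has a closed form,
`clamp(ceil(max_f t_f / 5), 1, 20)` (or `NO_RESPONSE` if the worst
threshold exceeds 100 dB HL), which the tests verify against the adaptive
engine over randomized audiograms, along with independence from the start
scale.

**Upward shift of stochastic outcomes.** Because a scale passes only when
*all four* tones are heard, the block pass probability at per-tone
probability *p* is ≈ *p*⁴(1−λ)⁴: a block is an even-money bet only once
*p* ≈ 0.84, roughly one 5-dB scale above the single-tone midpoint at the
default slope. The stochastic scale distribution therefore centres at or
one scale above the deterministic result — an intrinsic property of
worst-of-four screening, not a bug — and the tests assert centring within
one scale accordingly. The same mechanism explains why measured scale dB
runs systematically above PTA (an average) in screened cohorts: the scale
tracks the worst frequency plus the all-correct penalty.

## Conventional audiometry

The modified Hughson-Westlake staircase is simulated with textbook
defaults where the clinical description leaves them open: start 30 dB HL,
no familiarization phase, descend 10 dB on every response, ascend 5 dB on
every non-response, threshold = lowest level with ≥2 responses out of up to
3 ascending presentations. Equipment bounds are [−10, 120] dB HL;
repeated misses at 120 return a flagged ceiling, repeated responses at −10
a flagged floor. For deterministic listeners the procedure provably
returns the true threshold rounded up to the 5-dB grid (verified over a
1-dB sweep), so exam PTA is within 5 dB of true PTA.

1 kHz is measured twice per ear; the ear is unreliable if the runs differ
by more than 10 dB. The PTA uses the *first* 1 kHz run — the retest is a
reliability check, not an average. Unreliable ears are reported and
flagged; downstream analyses exclude them only when configured to
(`exclude_unreliable`, default off: include and flag).

## Calibration numerics

dB HL ↔ dB SPL conversion is additive through a RETSPL table. No
transducer constants ship with the package — the default table is the
identity so pure simulations stay in dB HL; real tables load from CSV.
The ascending search rises in 1-dB steps from 10 dB below a known
threshold to the first response. The 2-down/1-up staircase steps 1 dB,
stops after 3 reversals by default, and estimates the threshold as the
mean of the reversal levels (standard staircase practice; a last-*k*
variant is available via `discard_reversals`).

Levitt's transformed up-down theory places the 2-down/1-up asymptote at
the level where the response probability is 1/√2 ≈ 0.707. A 3-reversal
track is dominated by its initial ascent and measures the transient, so
the convergence tests probe the *asymptote* with a longer track (20
reversals, first 4 discarded) and verify the mean estimate lands within
0.5 dB of the 70.7% point over thousands of seeded runs; the short default
remains what a quick calibration session would run. Channel-balance and
device-difference checks are plain max-per-frequency comparisons against
1 dB and 1.5 dB limits over user-supplied output tables; acoustic
measurement hardware is out of scope.

## Screening workflow

Triage groups ears by the worse scale (≤S5, S6–S10, >S10). Referral fires
when the worse scale exceeds S10 **or** the interaural difference reaches
5 scales; the diagnostic screen is positive when the difference reaches the
cutoff (5/6/7 scales analysed, 5 preferred as the highest-sensitivity
rule). Both rules use the inclusive ≥ form: the analysed cutoffs are
defined inclusively (5 scales ⇔ 25 dB), and the referral rule follows the
same convention so that every screen-positive subject at cutoff ≥5 is also
referred. The impaired ear is the one with the worse HST scale, ties
broken by higher PTA, then right.

`run_screening` examines every subject with the conventional exam by
default, because a gold-standard call is needed for the whole analysis set
(as when a validation study administers both tests to everyone); setting
`exam_referred_only` restores the literal triage flow, with non-referred
subjects falling back to their true audiogram for the gold call so records
remain analysable. Subjects labelled with bilateral or conductive loss are
excluded from the analysis set (flagged, never silently dropped);
conductive loss is a cohort label only — the generator does not model
air-bone gaps.

## Validity statistics

Confidence intervals for proportions are exact Clopper-Pearson intervals
from beta quantiles. Wilson score intervals do **not** reproduce the
package's reference interval bounds (e.g. 14/21 gives a 45.4% lower bound
where the exact interval gives 43.0%), which is how the interval method was
identified; statsmodels' `proportion_confint(method="beta")` serves as an
independent oracle in the tests. Correlation CIs use the Fisher transform
with the normal quantile and √(n−3); ANOVA is classical fixed-effects
(not Welch). Percent comparisons round half-up to 1 decimal.

`reconstruct_counts` recovers the integer 2×2 table behind published
rounded percentages by exhaustive search, scoring each candidate by the
maximum absolute deviation of its four metrics from the printed values and
requiring a unique minimizer within 0.1 percentage points (the printed
precision). Closest-match is used instead of strict re-rounding because a
published row can carry a one-digit rounding slip in a single cell (the
package's reference row prints an NPV of 82.3 where the uniquely
consistent table, 14/17, gives 82.35 → 82.4) while every interval bound
still identifies the counts exactly. With a 0.1-point tolerance the three
reference rows reconstruct uniquely with deviations ≈ 0.05 and the nearest
runner-up at ≥ 0.87.

## Synthetic cohort

The generator emulates the *structure* of a tertiary-referral SSNHL
cohort, not any patient-level data:

- **Stratified categorical assignment** (largest remainder) for sex, the
  worst-ear Siegel-grade mixture (8/9/49/18/16%) and gold positivity
  (67/88), so headline proportions are exact at the default n = 88; ages
  are N(46, 14.7²) truncated to [18, 90].
- **Impaired ear**: grade → target PTA uniform within the grade interval →
  per-frequency thresholds = target + shape + jitter (σ = 3 dB),
  re-centred so the PTA hits the target exactly. Grade intervals follow
  the printed boundaries; the unprinted outer ends use 5 dB HL (screening
  floor) and 115 dB HL (profound-loss cap). Loss shapes mix 70% flat and
  30% down-sloping (+10/+20 dB at 2/4 kHz before re-centring) — invented,
  configurable; real sudden-loss audiograms vary more.
- **Contralateral ear**: per-frequency N(15, 7²) truncated to [−10, 60].
  Gold positivity is assigned to the subjects with the highest impaired-ear
  PTA (severity and interaural gap are strongly coupled in unilateral
  sudden loss); when a contralateral draw contradicts the assigned label
  the ear is re-targeted to a gap ≥ 32 dB (positives) or 10–28 dB
  (negatives — an elevated contralateral ear, as in presbycusis). The
  truth label is always recomputed from the final PTAs, never asserted.
- The resulting mixture mean of the impaired-ear PTA is ≈ 65 dB HL with
  SD ≈ 25, close to the ~67 dB referral-cohort reference; at n = 2000 the
  seeded sample mean lands within 3 dB of it.

**What passing tests do and do not show.** The generator's two classes are
cleaner than real life: contralateral ears are either near-normal or
shifted wholesale, interaural gaps avoid a neighbourhood of the 30-dB
boundary except through jitter, and there is no conductive pathology,
fluctuating attention, or tester error. Pipeline results on synthetic
cohorts therefore demonstrate *internal consistency* (the procedures
measure what they claim, monotonicity of the cutoff trade-off, correlation
of scale with PTA > 0.8) — they do not estimate real-world operating
characteristics, and the reference validity percentages are reproduced
from their published tables, not re-derived from simulation.

## Problem sizes and determinism

Test and acceptance runs use 1,000 random audiograms for the HST oracle
check, a 1-dB sweep for the clinical staircase, 2,000 seeded staircase
tracks for the Levitt asymptote, 5,000 replicates for interval coverage,
and a 2,000-subject deterministic-listener cohort for the end-to-end
pipeline — sizes at which every Monte-Carlo margin used is several
standard errors wide while the whole suite stays in the seconds range.
All randomness flows from named seeds (one per listener, one per cohort),
so identical configurations reproduce byte-identical outputs; the CLI
writes a manifest (config + seed + version) with every run.

## Known limitations

- The ascent rule and the behaviour of the real app below its start scale
  are assumptions (symmetric single-scale steps), as is the single joint
  scale for all four frequencies.
- The staircase estimator ("after 3 reversals") is taken as the mean of
  reversal levels; a final-level convention would differ by ≲ 1 step.
- Psychometric parameters are conventions; no human variability data are
  fitted.
- Bone conduction, masking, conductive mechanics, speech audiometry and
  audio playback are out of scope.
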