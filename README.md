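# hstsim

Simulation and diagnostic-validity toolkit for hearing-scale screening of
sudden sensorineural hearing loss (SSNHL).

## The problem

SSNHL is an otologic emergency: a sensorineural loss of ≥30 dB over
consecutive frequencies arising within 72 hours. Outcomes depend on how fast
treatment starts, but the gold-standard exam — pure-tone audiometry in a
soundproof booth by an audiologist — is rarely available in primary or
urgent care. A smartphone-based *Hearing Scale Test* (HST) addresses this
by summarizing each ear's hearing on a grid of 20 scales 5 dB apart
(S*k* ⇔ 5·*k* dB HL, so S5 = 25 dB HL and S17 = 85 dB HL): starting at S5,
four pure tones (1, 2, 4, then 0.5 kHz) are played per scale, the level
descends one scale only after all four are heard, and the result is the
*minimum audible scale* — the lowest scale with an all-correct block.
Because SSNHL is almost always unilateral, the screen is the **interaural
scale difference** Δ = scale(impaired) − scale(contralateral) compared to a
cutoff (5 scales ⇔ 25 dB); using a between-ear difference also cancels
ambient-noise effects. The gold standard is an interaural pure-tone-average
difference ≥ 30 dB, with PTA = mean air-conduction threshold at
0.5/1/2/4 kHz and severity staged by the modified Siegel grades.

`hstsim` makes this whole screening chain *simulatable and testable*: a
psychometric virtual listener answers tone presentations, the adaptive HST
engine and the modified Hughson-Westlake clinical staircase run against it,
a triage layer applies the referral and decision rules, and a statistics
layer computes sensitivity / specificity / PPV / NPV with exact
Clopper-Pearson 95% CIs, Pearson correlations with Fisher-z CIs, one-way
ANOVA, and the reconstruction of integer 2×2 tables from published rounded
percentages. A seeded cohort generator emulates the referral population in
which the approach was validated (n = 88, 50% female, mean age 46, worst-ear
Siegel-grade mixture 8/9/49/18/16%, ~67/88 gold-standard positives).

## The statistics at the core

For a confusion table (TP, FN, FP, TN) against the PTA gold standard:

- sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
  NPV = TN/(TN+FN), each with the exact two-sided binomial interval from
  beta quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k).
- Pearson r with CI tanh(atanh r ± z₀.₉₇₅/√(n−3)).
- The published validity row for the 5-scale cutoff in the reference
  referral cohort — sensitivity 95.5% (87.5–99.1), specificity 66.7%
  (43.0–85.4) — is recovered exactly by reconstructing the unique integer
  table (64, 3, 7, 14) from the rounded percentages and recomputing the
  exact intervals.

## Worked example

Exact intervals from a known confusion table (TP=64, FN=3, FP=7, TN=14):

```bash
$ hstsim validate --counts 64 3 7 14
 cutoff_scales  cutoff_db  sensitivity  sensitivity_lo  sensitivity_hi  specificity  ...
             0          0         95.5            87.5            99.1         66.7  ...
```

i.e. 64/67 gold-positives were screen-positive (sensitivity 95.5%, exact
95% CI 87.5–99.1%) and 14/21 gold-negatives screen-negative (specificity
66.7%, CI 43.0–85.4%).

Full simulated chain — generate a seeded 88-subject cohort, run the HST and
the conventional exam on every virtual listener, triage, and tabulate
validity at cutoffs 5/6/7:

```bash
$ hstsim reproduce --seed 7 --n 88 --out demo
 cutoff_scales  cutoff_db  sensitivity  sensitivity_lo  sensitivity_hi  specificity  specificity_lo  specificity_hi   ppv  ppv_lo  ppv_hi   npv  npv_lo  npv_hi
             5         25        100.0            94.6           100.0         76.2            52.8            91.8  93.1    84.5    97.7 100.0    79.4   100.0
             6         30        100.0            94.6           100.0         90.5            69.6            98.8  97.1    89.9    99.6 100.0    82.4   100.0
             7         35        100.0            94.6           100.0        100.0            83.9           100.0 100.0    94.6   100.0 100.0    83.9   100.0
outputs in demo/
```

Each row is one scale-difference cutoff: as the cutoff rises the screen
gets stricter, so sensitivity can only fall and specificity only rise.
(This synthetic cohort separates the two classes more cleanly than real
patients do — see `docs/methods.md` for what the generator does and does
not emulate.) The output directory holds the cohort tables
(`audiograms.csv`, `demographics.csv`, `truth.csv`), per-subject screening
records, the validity table, and a `manifest.json` that makes the run
byte-for-byte reproducible.

Library use mirrors the CLI:

```python
from hstsim import CohortConfig, generate_cohort, run_screening
from hstsim import confusion_from_records, diagnostic_metrics

cohort = generate_cohort(CohortConfig(n=88, seed=7))
records = run_screening(cohort, cutoffs=(5, 6, 7))
print(diagnostic_metrics(confusion_from_records(records, 5)).sensitivity)
```

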