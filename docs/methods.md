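# Methods

## Problem and model

A short food questionnaire (SFQ) records how often a child consumed each of
a small set of food groups; a weighed food diary (FD) records every eating
occasion (EO) — food code, description, cooking method, day, meal and
amount in grams. `dietmap` maps each diary food code onto at most one SFQ
group and quantifies what share of habitual consumption the SFQ fails to
capture.

Every food code receives a verdict: **covered** (maps fully onto an SFQ
group), **partially covered** (a fraction in (0, 1), introduced by manual
overrides or group-level estimation), or **non-covered**. Merging the diary
with the verdict table yields the augmented database, and per subject `s`
and survey day `d` the two coverage ratios

    freq_ratio(s, d)   = Σ_EO (1 − c_i) / N_{sd}
    amount_ratio(s, d) = Σ_EO a_i (1 − c_i) / Σ_EO a_i

where `c_i` is the coverage fraction of occasion `i`'s food code, `a_i` its
amount in grams and `N_{sd}` the number of occasions that day. Survey days
are treated as mutually independent. The sample summary is the mean (and
SD) of these subject-day ratios; a pooled variant (grand totals divided)
is exposed separately because the two definitions differ whenever day
sizes vary.

## Mapping protocol

Steps are applied strictly in order; the first match wins:

1. **Exact name** — normalized food name equals a group label or include
   phrase. Normalization lowercases, maps punctuation to spaces, splits on
   whitespace, and optionally removes stopwords (default: none).
2. **Exact description** — same test on the food description.
3. **Fuzzy** — similarity `1 − d(a, b) / max(|a|, |b|)` with `d` the
   Levenshtein distance on normalized strings (edlib-backed), maximized
   over all labels and include phrases; accepted at ≥ `fuzzy_threshold`
   (default 0.85). Ties break by similarity, then SFQ-definition order.
4. **Token search** — each token of the name, then of the description and
   cooking method, looked up in the groups' include keywords; a group is
   vetoed when any input token appears in its exclude keywords (this is
   what keeps "fruit juices" out of a fresh-fruit group).

No match ⇒ non-covered. Fuzzy and token verdicts carry `needs_review=True`
— a stand-in for the human annotator who verified each automatic step in
the original protocol; a manual-override channel (`match_step=manual`)
replaces algorithmic verdicts and represents the final nutritionist check.
Two independently produced tables are compared with `compare_mappings`,
which counts codes whose (status, target group) differ.

The 0.85 threshold with review band (0.85, 0.95) was chosen so that a
single-character typo in a label of eight or more characters still matches
while unrelated labels do not, and borderline matches are flagged. Raising
the threshold can only remove fuzzy matches, never create coverage.

Group-level partial coverage (`assign_partial_fraction`) reports the
non-covered share of one catalogue group either count-based (unmapped
member codes / all member codes) or consumption-weighted when a diary is
supplied; both are exposed because published partial-coverage figures do
not state which denominator was used.

## Statistical testing

The ratio distributions are displayed with a Gaussian-kernel density using
boundary reflection at 0 and 1 (mirror images at −v and 2−v), Silverman
bandwidth by default; the estimate is non-negative and integrates to 1
within grid error.

Day-of-week structure is tested with a two-sided Wilcoxon rank-sum test of
each weekday's subject-day ratios against all other weekdays pooled
(a leave-one-day-out reading; an all-pairwise variant is available). The
statistic is the rank sum of the single-day sample with mid-ranks for
ties. The null distribution comes from

- **exact enumeration** of all C(n+m, n) assignments when feasible,
- **Monte-Carlo permutation** (default, `n_perm=9999`, seeded) with the
  add-one estimator `p = (1 + #extreme) / (1 + n_perm)`, or
- the tie-corrected **normal approximation** for large samples.

Raw p-values are reported at α = 0.01 without multiplicity adjustment,
mirroring the original analysis; Holm-adjusted values are emitted
alongside.

## Synthetic study conditions

The source microdata are access-restricted, so the generator emulates
their published structure with planted ground truth:

- **Scale**: 1,652 food codes in 77 catalogue groups; 15 SFQ groups (8
  healthy, 7 unhealthy, shipped as `data/preschool_sfq.csv`); 126 subjects × 4
  consecutive diary days with a guaranteed weekend day.
- **Mappability**: 19 of the 77 groups are truly non-covered and named
  after the survey's reported most-consumed non-covered items (breakfast
  cereals, fruit juices, sugars/syrups, ...); the remaining 58 are tied
  cyclically to SFQ groups, their food names built from the questionnaire's
  own phrases in four rotating forms that exercise every matching step.
  `typo_rate` (default 0) applies single-character substitutions/deletions
  to those names to stress the fuzzy step.
- **Consumption**: each occasion is non-covered with probability
  `target_noncov_freq` (default 0.44, the reported sample mean);
  non-covered groups are drawn proportional to their reported EO counts,
  mappable groups by their configured weights.
- **Occasion counts**: negative-binomial per subject-day (truncated at 1)
  with mean 17 and dispersion 8. The mean is derived from the published
  summary statistics: a daily non-covered frequency ratio with mean 0.44
  and SD 0.12 implies p(1−p)/N ≈ 0.12², i.e. N ≈ 17 diary entries per day.
- **Amounts**: per-occasion lognormal with moments matched to the
  configured (mean, SD) per group — reported (g/day, SD) pairs for the
  non-covered groups, and a spread averaging 92 g for mappable groups
  chosen once so the designed non-covered *amount* share at
  `target_noncov_freq=0.44` is ≈ 0.34, the reported value. Lognormality
  enforces positivity; only means/SDs are published, not distributions.

`ground_truth_coverage` recomputes the designed non-covered fractions by
direct recounting of diary rows against the planted labels, independently
of the pipeline, and serves as the recovery oracle: with `typo_rate=0` the
pipeline's subject-day ratios equal it exactly.

What the generator does **not** emulate: day-of-week effects (weekday
ratios are i.i.d. by design, so day tests are calibrated on planted shifts
rather than on default data), under-reporting and social-desirability
bias, within-subject correlation across days, nutrient composition, and
the true (unpublished) distribution of codes across groups. Passing
recovery tests therefore demonstrates the pipeline's correctness on data
with the published structure, not the field performance of the matching
heuristics on real free-text food names.

## Numerical choices and degenerate inputs

- Similarity of two empty normalized strings is defined as 1.0.
- Quartiles use linear interpolation; SD/SEM use the n−1 denominator and
  are reported missing for n = 1.
- A zero-intake subject-day keeps its row with a flagged missing amount
  ratio and is excluded (and tallied) in amount-ratio aggregation.
- Complete ties in the rank test give p = 1.
- All randomness flows from one top-level seed; per-stage seeds are
  derived deterministically, so a resolved config reproduces every CSV
  byte-identically.
- Problem sizes in the test and acceptance simulations (e.g. 500 null
  datasets at 50 observations per weekday, permutation `n_perm=999` there)
  are the package's chosen simulation scale; they keep Monte-Carlo error
  well inside the asserted tolerances.

## Known limitations

- The matching heuristics are tuned for short English label vocabularies;
  no multilingual or semantic (embedding-based) matching.
- Partial coverage is modelled at code/group granularity, not at recipe or
  ingredient level.
- The day-of-week test treats subject-days as exchangeable units; repeated
  measures on the same subject are not modelled (days are treated as
  independent by design).
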