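# Methods

## The assessment model

A confidence-weighted true-false (CTF) instrument presents *n* true/false
statements; the respondent picks one of four categories per item — a
true/false direction crossed with confident/unsure. Reducing each
response to its two bits (confident?, correct?) gives per-phase counts
`cc, ci, uc, ui` (confident/unconfident × correct/incorrect) that carry
all the metacognitive information the indices use.

Content scores weight confidence into correctness. Only the endpoints of
the per-item point scale are pinned down by the construct (confident
correct = 4, confident incorrect = 0, maximum 4·n); the interior values
are a declared mapping. The default, `(4, 3, 1, 0)` over
(confident-correct, unsure-correct, unsure-incorrect,
confident-incorrect), is symmetric about 2, strictly monotone in
response quality, and is exposed as a configurable 4-vector
(`points` in `RunConfig` / the scoring functions) so alternative
published mappings can be swapped in without touching the pipeline.

The five calibration indices are functions of the counts alone:
`AC = (cc+ui)/n`, `BS = (ci−uc)/n` (identically confidence rate minus
accuracy rate, so positive = overconfident), `CCP = cc/(cc+uc)`,
`CIP = ci/(ci+ui)`, `DIS = CCP − CIP`. On an all-correct phase CIP has a
zero denominator (and DIS with it); such values are carried as NaN and
excluded pairwise from downstream tests with logged counts. Imputing 0
or 1 instead would manufacture bias in exactly the indices under study,
so it is never done. Indices are kept at full precision internally and
rounded (2 decimals) only at report time.

## Cohort assembly

Inputs are a JSON item bank and a long CSV of responses
(`participant_id, phase, attempt_time, item_id, choice`). Attempt times
may be integers or ISO-8601 timestamps; they are compared after parsing,
never lexically. Phase labels pre/pretest and post/posttest are
normalized case-insensitively.

Learners retaking a posttest (e.g. to clear a course pass mark) would
otherwise inflate the measured gain, so only the chronologically first
posttest attempt enters the analysis. Two attempts sharing a timestamp
are a hard error rather than a silent tie-break — any deterministic
tie-break would quietly change scores. The paired cohort then keeps only
complete cases: both phases present with exactly one response per item.
No imputation is attempted; every exclusion is logged once with its
reason, and cohort assembly is invariant to input row order.

## Inference

Scores on a 20-item instrument live on coarse grids, so the Wilcoxon
signed-rank test uses midranks with the tie-corrected variance
`n(n+1)(2n+1)/24 − Σ(t³−t)/48` and the normal approximation without
continuity correction. Zero differences are discarded by default
(classic Wilcoxon); the Pratt rule is available via
`zero_method="pratt"` since the choice is a convention, not a fact about
the data. Fewer than five nonzero differences raises an error pointing
to the exact-test regime — at that size the normal approximation is
meaningless (the test suite bounds its error against the exhaustive 2^n
permutation distribution at n ≤ 10: ≤ 0.12 absolute on two-sided p for
distinct differences; with heavy ties at such tiny n the approximation
degrades further, which is precisely why the error exists).

The sign convention puts z negative when posttest values systematically
exceed pretest values, so improvement prints as negative z. Effect sizes
are Rosenthal correlations `r = z/√N` with N the pairs actually analyzed
for that row (after pairwise exclusion), labelled weak (|r| < 0.30),
moderate (0.30–0.59) or strong (≥ 0.60) — the unique simple thresholding
consistent with the labels in the reference results this package
reproduces.

Per-item change in binary correctness uses McNemar's test in its plain
chi-square form `(b−c)²/(b+c)` on the discordant counts, 1 df, no
continuity correction (b+c = 0 yields statistic 0, p = 1). No
multiple-testing adjustment is applied across items, matching the
reporting convention of the reference analysis. The per-item
confident-incorrect change is `100·(post−pre)/pre` on the percentage of
"confident" answers in the wrong direction; it is undefined (NaN) when
the pretest percentage is zero, and scale-invariant between proportions
and percentages.

## The synthetic cohort generator

No participant-level CTF datasets of this kind are public, so the
pipeline is validated on simulated cohorts with known truth. The
generator draws, per participant, a pretest correctness probability
`p_i ~ Beta(a, b)` mapped to ability `θ_i = logit(p_i)`; per item, a
difficulty offset `d_j ~ N(0, σ_d)`. Correctness of (i, j) is Bernoulli
`expit(θ_i − d_j)` at pretest and `expit(θ_i + δ − d_j)` at posttest
(δ = `knowledge_effect`, in log-odds). Confidence is then Bernoulli with
probability γ_cc (if correct) or γ_ci (if incorrect), each with separate
pre and post values — conditionally independent of item identity given
correctness, the simplest structure that can move every index the
pipeline computes. Optional posttest dropout and retakes complete the
design; retakes get strictly later integer timestamps and an
`attempt_gain` log-odds correctness bonus, so using any attempt but the
first measurably inflates scores — making the first-attempt rule's
effect observable in tests. Everything is drawn from one
`numpy.random.default_rng(seed)` stream; the same config yields
byte-identical files on disk.

Defaults mirror a realistic 307-learner continuing-education cohort on a
20-item bank with 13 false-keyed items: Beta(6, 4) ability (pretest
binary accuracy near 60%), δ = 0.5 (posttest near 72%), γ_cc 0.40 → 0.85
and γ_ci 0.20 → 0.75 across phases (median CCP/CIP near 0.36 → 0.88 and
0.14 → 0.80), σ_d = 0.5, no dropout or retakes unless requested.

What the generator does *not* emulate: item-specific confidence habits,
participant-level confidence heterogeneity beyond the correct/incorrect
split, learning during the test, demographic covariates, or the
incentive structure behind retakes. Passing tests therefore demonstrate
that the pipeline recovers known structure under this model — not that
the model captures every feature of real learner data.

## Validation strategy and problem sizes

- Worked examples with hand-computable answers (score extremes, counted
  profiles, discordant-pair arithmetic) are frozen into unit tests.
- The signed-rank test is cross-checked against an independent library
  implementation and against the exact permutation distribution at
  n ≤ 10; McNemar against an independent library implementation and
  published statistic→p pairs.
- Parameter recovery: at n = 1000 participants × 20 items, cohort-mean
  CCP/CIP estimate γ_cc/γ_ci to within ±0.03 (binomial SE ≈ 0.004, so
  the tolerance is generous but honest about grid effects).
- Type-I error: 200 null-configured replicates at n = 500 keep the
  pipeline's signed-rank rejection count inside the central 99.9%
  binomial band at α = 0.05. These sizes keep the full suite around a
  minute while leaving Monte-Carlo error well below the tolerances.

## Known limitations

- CCP/CIP are ratio estimates over at most n items; with few correct (or
  few incorrect) answers they are noisy, and their cohort means are
  means of ratios, unbiased only conditional on a nonzero denominator.
- The intermediate CTF point values (3 and 1) are a declared convention;
  analyses sensitive to the interior of the scale should vary the
  4-vector.
- The normal-approximation signed-rank p is unreliable below ~10
  effective pairs even with tie correction; the package refuses rather
  than approximates there.
- Percent-change on the confident-incorrect category explodes for small
  pretest percentages (and is undefined at zero) — report it alongside
  the absolute percentages, never alone.
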