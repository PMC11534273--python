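# ctfmeta

Scoring and metacognitive analysis of **confidence-weighted true-false
(CTF)** knowledge assessments delivered in a paired pre-post design.

CTF items combine an ordinary true/false statement with the respondent's
rated confidence, giving four response categories per item ("I am
confident this is true", "I believe this is true, but I am unsure", and
the two false-direction counterparts). Beyond measuring content
knowledge, the format measures *metacognition* — whether learners know
what they know. `ctfmeta` is written for education researchers and
evaluators (e.g. of continuing medical education or academic-detailing
courses) who collect such assessments before and after an intervention
and want a reproducible path from raw responses to a full results table.

## What it computes

Per participant and phase, with `cc/ci/uc/ui` the counts of
confident-correct, confident-incorrect, unconfident-correct and
unconfident-incorrect answers over *n* items:

- **Content scores** — summed CTF score (4 confident-correct,
  3 unsure-correct, 1 unsure-incorrect, 0 confident-incorrect per item;
  configurable), percent CTF score, and binary percent correct.
- **Calibration indices** — absolute accuracy `AC = (cc + ui)/n`;
  bias `BS = (ci − uc)/n` (confidence rate minus accuracy rate;
  positive = overconfident); `CCP = cc/(cc + uc)` and
  `CIP = ci/(ci + ui)` (probability of confidence given a correct or
  incorrect answer; undefined ratios stay missing, never imputed);
  discrimination `DIS = CCP − CIP`.
- **Paired inference** — Wilcoxon signed-rank tests with midranks and
  tie-corrected variance (z < 0 when posttest exceeds pretest), Rosenthal
  effect sizes `r = z/√N`, and per-item McNemar tests
  `(b − c)²/(b + c)` on binary correctness, all without continuity
  correction.
- **Item tables** — per-item CTF category percentages at both phases,
  binary margins, and the percent change in confident-incorrect answers.

A synthetic cohort generator (latent logistic ability, per-item
difficulty, phase-specific confidence rates, posttest retakes and
dropout) provides fully specified test beds; the chronologically first
posttest attempt is always the one analyzed.

## Worked example

```sh
ctfmeta simulate --out demo --seed 3
ctfmeta analyze --bank demo/bank.json --responses demo/responses.csv --out demo/report
```

prints `n=307; wrote demo/report/summary.csv and items.csv`. The summary
table (selected columns) reads:

```
   measure  pre_median  post_median      z p_display     r   effect
   ctf_sum       48.00        56.00 -11.64     <.001 -0.66   strong
binary_pct       60.00        70.00  -9.91     <.001 -0.57 moderate
        ac        0.55         0.70  -8.68     <.001 -0.50 moderate
        bs       -0.30         0.10 -15.10     <.001 -0.86   strong
       ccp        0.40         0.85 -15.13     <.001 -0.86   strong
       cip        0.17         0.78 -14.70     <.001 -0.84   strong
       dis        0.21         0.09   5.99     <.001  0.34 moderate
```

Read: after the simulated intervention the median CTF score rises from
48 to 56 and binary accuracy from 60% to 70% (negative z = posttest
higher). Calibration improves (AC up, bias moves from underconfident
−0.30 to +0.10), and confidence rises on correct *and* incorrect
answers (CCP 0.40→0.85, CIP 0.17→0.78), which is exactly why DIS —
how well confidence separates right from wrong — drops. `items.csv`
holds the per-item distributions, McNemar statistics and
confident-incorrect change column; `run.log` records every excluded
participant and pairwise exclusion.

Python API: `ctfmeta.simulate_cohort`, `select_first_posttest`,
`build_paired_cohort`, `score_cohort`, `profile_cohort`,
`prepost_summary`, `item_report` compose the same pipeline in-process.

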