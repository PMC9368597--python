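# Methods

This note documents the models and procedures implemented in `ohpp`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data results do and do not show about
real corpora.

## Restriction-sentence extraction

OHPP sentences are parsed with a closed lexicon (8 anatomical regions,
left/right/both markers, MN/SN cues, two process-only phrases), not a
learned model: the vocabulary is tiny, closed, and written by a small set of
physicians, so rules are auditable and fail loudly. The lexicon lives in an
editable YAML data file (`src/ohpp/data/lexicon.yaml`) with Portuguese and
English keywords active simultaneously.

Normalisation lower-cases, strips non-word symbols, collapses whitespace and
preserves diacritics; it is idempotent. Matching is fuzzy: tokens of ≥ 5
characters tolerate one edit (Levenshtein, via `edlib`) against a keyword;
shorter tokens must match exactly. The 5-character bound keeps short
function words and the 4-letter cues ("must", "pode") exact — a one-edit
tolerance there would let unrelated words flip a protection level.

Laterality resolution walks region mentions left to right and attaches the
nearest unconsumed side marker, preferring the backward span (English places
the adjective before the noun) and falling back to a short forward window
(Portuguese places it after; "fingers of both hands" also resolves
forwards). "Both", or left+right jointly before a region, expand to both
sides; a plural region word with no marker defaults to both sides. The MN/SN
cue is accepted at either end of the sentence; with several mid-sentence
cues each cue governs the phrase after it. A sentence with a cue but no
recognisable content is returned flagged `unparsed` — never silently
dropped. When MN and SN are both extracted for one part within an
appointment, MN (the stronger protection) wins.

**Known limitation:** the original keyword list and misspelling tolerance of
the source protocol are not public; this lexicon and the one-edit bound are
replacements. Transposition typos count as two edits and are not absorbed.

## Severity scoring

Each appointment's sentences form two pools:
`pool_c = (#part-bearing sentences of category c) × weight_c` with operative
per-sentence weights **MN = 1.0, SN = 2.5**. Process-only sentences
(vibration tools, manual material handling) never enter the pools. The
often-quoted opening ratio "SN = 1, MN = 0.5" contradicts the published
pools (2 MN sentences → 2; 2 SN sentences → 5) and is treated as a remark on
relative severity, not as the operative weights; both readings are
documented here because they cannot be reconciled.

Three allocation modes exist because the published worked example is not
reproducible under any single rule:

- `sentence` (default): share = pool / #sentences, split evenly over the
  sentence's parts. Conserves pools exactly (Σ part scores = pool_MN +
  pool_SN); this self-consistency is why it is the default.
- `slot`: share = pool / #part-slots in the category, then split within the
  sentence.
- `paper_compat`: MN by `sentence`, SN by `slot` — the only combination that
  reproduces every printed worked-example value (shoulders/fingers 0.5,
  trunk 5/3 → 1.66 truncated to two decimals, wrists 5/6 → 0.8 at one
  decimal). Offered for fidelity, without a claim about intent.

Scores are stored at full precision; display truncates (1.66 is 5/3
truncated, not rounded). The total is the plain sum of per-part scores on
the 0–10 Work Ability Index scale: total ≤ 7 → poor, 8–10 → good, values
strictly between 7 and 8 round half-up before classification, values outside
[0, 10] are errors.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis needs, with
one RNG stream per channel (demography, restrictions, text noise, intervals)
so changing one rate leaves other draws unchanged. Defaults, chosen once:

- **Demography:** P(female) = 0.233; seniority truncated normal per gender
  (F: 13.95 ± 7.78 years on [4, 27]; M: 18.62 ± 8.33 on [4, 29]); six
  production areas (Assembly 0.38, Body Construction 0.20, Paint 0.14,
  Metal Stamping 0.12, Quality Assurance 0.09, Special Projects 0.07 —
  plausible decreasing weights, as only the area names are public).
- **Timelines:** appointments per worker follow a truncated geometric law
  (ratio 1/2) over {1..7, 9, 10} with probability 0 at exactly 8 visits.
- **Restrictions:** 0–3 part-bearing sentences per appointment
  (P = .05/.45/.30/.20), distinct regions weighted so shoulders and elbows
  are restricted most often (as in published per-part record counts for this
  industry), 30% bilateral, plus a 15% chance of one process-only sentence.
  Distinct regions and ≤ 2 parts per sentence keep every positive per-part
  score inside [0.5, 2.5], within the published descriptive envelope
  [0.19, 5.33].
- **Text noise:** per-channel probabilities (cue-at-end 0.05, per-token
  misspelling 0.02 — one random edit, including transpositions — extra
  spaces 0.05, non-word symbols 0.05, capitalisation errors 0.05). With all
  probabilities zero, rendering is the canonical template and extraction
  round-trips the ground truth exactly.
- **Interval model:** `weeks = max(min_interval, β₀ − Σ_p β_p·score_p + ε)`,
  `ε ~ N(0, σ)`, with β₀ = 64 weeks (a zero-severity worker is recalled in
  roughly 1.2 years), a dominant shoulder-right effect β = 8 weeks per score
  unit, β = 1 elsewhere, σ = 3 weeks, floor 1 week. Higher severity brings
  the next appointment forward; the sign convention matches the reported
  directionality of shoulder-right severity. All β values are calibration
  choices of the generator, not estimates.

**What passing tests show — and do not.** The generator produces clean
timelines with a known, essentially linear signal plus independent Gaussian
noise. Real OHPP corpora have scheduling constraints, policy-driven recall
intervals, physician idiosyncrasies, censoring by turnover, and correlated
multi-part injuries; none of that is emulated. Green tests therefore verify
the machinery (extraction, scoring arithmetic, leakage-safe evaluation,
attribution identities, recovery of a planted effect), not clinical
performance on real data.

## Feature records and evaluation protocol

A worker with n appointments contributes n−1 records: current per-part
scores plus encoded worker attributes (area, function, schedule, gender as
stable sorted-vocabulary integer codes; seniority in years), with targets
read at the following appointment. The interval target is whole weeks
between consecutive dates (days/7, rounded half-up). The last appointment is
right-censored and simply dropped — no survival modelling — and
single-appointment workers contribute nothing.

Splits and cross-validation folds group by **worker**: record-level
splitting would leak a worker's own history into the test side. The splitter
shuffles workers by seed and fills the test side to the target record
fraction (realised fraction within one worker's appointments of the
target); folds are assigned greedily, largest worker first, to the smallest
fold. Per-part severity models train only on records where the part is
currently scored (> 0): a part with no restriction history carries no signal
for its next severity, and this mirrors how per-part record counts are
tabulated.

## Built-in boosted trees

Least-squares gradient boosting: start at the target mean, stagewise add
depth-limited axis-aligned regression trees fit greedily to the residuals
(exhaustive SSE split search), prediction = initial + rate × Σ trees.
Defaults: 300 trees, depth 3, learning rate 0.05, min 5 records per leaf, no
row subsampling. With rate ≤ 1 and full sampling the training loss is
provably non-increasing; with rate 1, depth ≥ log₂ n and leaf size 1 the
ensemble interpolates distinct points — both asserted as tests. A constant
target yields zero trees and a warning. Trees are flattened to arrays with
globally rebased child indices; batch prediction runs through a numba kernel
when numba is importable (a pure-numpy reference path is kept and tested for
equality), because exact Shapley explanation evaluates the model on millions
of hybrid rows.

The external comparators (decision tree, random forest, gradient boosting,
and optionally xgboost/lightgbm) are thin registry adapters; the bench runs
with the built-in learner alone, and a failing adapter is recorded as a
failed row rather than aborting the bench. Hyperparameters are fixed,
documented defaults — no tuning.

Metrics: RMSLE = √mean((log1p(ŷ) − log1p(y))²) with negative predictions
clipped to 0 (with a warning); MAE; R² = 1 − SS_res/SS_tot, NaN with a
warning when the truth is constant. RMSLE's log scale damps large-interval
outliers relative to raw RMSE, which is the reason it headlines the bench.

## Shapley attributions

The value function is interventional: v(S) = mean prediction over a
background sample with the features in S replaced by their values at the
explained point. This is model-agnostic by construction; tree-specific fast
paths would be an optimisation, not a contract. The base value is v(∅), the
mean prediction over the background — it equals the training-target mean
only for calibrated models, a deliberate, documented difference from using
the target mean directly. The background defaults to a seeded 50–100-row
training subsample.

Exact mode enumerates all 2^m coalitions (limit m ≤ 15, i.e. 32 768 value
evaluations) and satisfies efficiency — base + Σφ = f(x) — to numerical
precision; it is tested against an independent m!-ordering brute-force
oracle. Sampled mode averages marginal contributions over seeded random
permutations, reports per-feature Monte-Carlo standard errors, and then
closes the small residual by distributing it proportionally to |φ| so the
additive identity holds exactly on the reported numbers (the adjustment is
well inside the standard errors at practical permutation counts).
Downstream, `summary_data` ranks features by mean |φ| (ties alphabetical)
and `decision_path` produces the cumulative base-to-prediction walk behind
decision plots.

## Pipeline and reports

`run_pipeline` chains simulate → extract → score → features/split → train →
explain → report, writing every artifact plus a manifest with the seed, row
counts and content hashes (no timestamps, so a rerun with the same seed is
byte-comparable). Severity shares normalise summed **predicted** per-part
severities to percentages within strata — gender, seniority bands [1, 10),
[10, 20), [20, ∞) with boundaries assigned upward, and production area — a
flag switches to observed scores for diagnostics. Stratum percentages are
data-dependent and only their normalisation and binning contracts are
testable.

## Problem sizes used in the test and acceptance suites

Synthetic cohorts of 120–450 workers (≈ 200–1200 appointments, ≈ 400
feature records at 450 workers) keep the full suite within a few minutes on
one core while leaving the measured properties (round-trip exactness,
calibration confidence intervals, planted-model recovery at test R² ≥ 0.7
over five seeds, Shapley identities at 1e−9/1e−12) comfortably away from
their thresholds. The parameter-recovery suite sets the interval noise to
σ = 1 week — the "small noise" regime in which recovery is the stated
property; at the realistic default σ = 3 the irreducible noise floor caps
even the true model near R² ≈ 0.67, which says nothing about the learner.
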