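# ohpp — Occupational Health Protection Profile analytics

Occupational physicians in industrial plants record workers' activity
restrictions as free text ("Must not perform tasks that involve movements
above both shoulders."). These Occupational Health Protection Profiles
(OHPPs) carry, per sentence, a protection level — **MN** ("Must Not use",
the more severe) or **SN** ("Should Not use") — and one or more of 14 body
parts (neck, trunk, and left/right shoulder, elbow, wrist, fingers, knee,
foot). `ohpp` turns such corpora into quantitative occupational-health
analytics for ergonomists, occupational physicians and health-surveillance
teams:

1. **Extraction** — rule-based, bilingual (Portuguese/English) parsing of
   restriction sentences into a fixed 28-flag table (`<Part>_MN`,
   `<Part>_SN`), robust to clerical noise (misspellings, extra spaces,
   symbols, capitalisation errors, the MN/SN cue displaced to the sentence
   end) via bounded edit-distance keyword matching.
2. **Severity scoring** — per-category score pools (part-bearing MN
   sentences × 1.0; SN sentences × 2.5) allocated down to body parts,
   yielding per-part Functional Work Ability (FWA) severities and a total on
   the 0–10 Work Ability Index scale with categories good (8–10) / poor (0–7).
3. **Prediction** — a self-contained least-squares gradient-boosted
   regression-tree learner (plus scikit-learn/xgboost/lightgbm adapters)
   predicting (i) the weeks to a worker's next medical appointment and
   (ii) the next visit's per-part severity, evaluated with RMSLE, R² and MAE
   on worker-disjoint splits and 10-fold worker-disjoint cross-validation.
4. **Explanation** — model-agnostic Shapley attributions satisfying the
   additive identity `f(x) = base value + Σ φ_j` exactly (coalition
   enumeration up to 15 features, seeded permutation sampling beyond), plus
   the data behind summary, force, bar and decision plots and stratified
   severity-share reports (gender / seniority band / production area).

Real OHPP databases are proprietary; a seeded **synthetic corpus generator**
with full ground truth (demographics, timelines, text noise, and a planted
`weeks = max(min, β₀ − Σ β_p·score_p + ε)` interval model) makes every stage
testable end to end.

## Worked example

```python
from ohpp import (Lexicon, ScoringConfig, allocate_scores, build_profile,
                  category_pools)

sentences = [
    "Must not perform tasks that involve movements above both shoulder line",
    "Should not perform tasks that involve performing flexion/rotation movements of the trunk",
    "Must not perform tasks that imply performing tasks using tools with associated vibration",
    "Should not perform tasks that involve performing left and right wrist rotation movements",
    "Must not perform tasks that involve performing tasks that require force "
    "with application point on the fingers of both hands",
]
profile = build_profile(sentences, Lexicon.default())
print(category_pools(profile.sentence_fragments))
scores = allocate_scores(profile.sentence_fragments,
                         ScoringConfig(allocation_mode="paper_compat"))
print({k: round(v, 2) for k, v in scores.items() if v > 0})
```

prints

```
(2.0, 5.0)
{'Trunk': 1.67, 'ShoulderL': 0.5, 'ShoulderR': 0.5,
 'WristL': 0.83, 'WristR': 0.83, 'FingersL': 0.5, 'FingersR': 0.5}
```

Two MN sentences carry body parts (the vibration-tools restriction is
process-only and excluded), so the MN pool is 2 × 1.0 = 2; two SN sentences
give 2 × 2.5 = 5. In paper-compat mode the MN pool splits per sentence, then
per part (0.5 to each shoulder and each finger region), while the SN pool
splits over the three SN part slots (trunk 5/3 ≈ 1.67, displayed truncated
as 1.66; each wrist 5/6 ≈ 0.83, displayed rounded as 0.8). The `sentence`
mode (default) applies one self-consistent rule and conserves the pools
exactly; see `docs/methods.md` for why both exist.

The `examples/` directory holds one short script per capability: corpus
simulation, extraction + scoring, the prediction bench, Shapley
explanations, and stratified severity shares. A thin CLI mirrors the
pipeline stages:

```bash
ohpp simulate --seed 1 --n-workers 300 --out run/
ohpp extract --in run/corpus.jsonl --out run/profiles.csv
ohpp run-all --seed 1 --n-workers 300 --out run/
```

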