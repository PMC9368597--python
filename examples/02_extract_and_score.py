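"""Parse one appointment's restriction sentences and severity-score them.

This is the published worked example: five restrictions, two of which name
Must-Not protections with body parts, two Should-Not, and one process-only
(vibration tools) that legitimately carries no body part. Pools are
(2 MN sentences x 1.0, 2 SN sentences x 2.5) = (2, 5); paper-compat
allocation reproduces the printed per-part values.
"""

from ohpp import Lexicon, ScoringConfig, allocate_scores, build_profile, category_pools, total_score, wai_category

sentences = [
    "Must not perform tasks that involve movements above both shoulder line",
    "Should not perform tasks that involve performing flexion/rotation movements of the trunk",
    "Must not perform tasks that imply performing tasks using tools with associated vibration",
    "Should not perform tasks that involve performing left and right wrist rotation movements",
    "Must not perform tasks that involve performing tasks that require force "
    "with application point on the fingers of both hands",
]

profile = build_profile(sentences, Lexicon.default())
print("extracted flags:", sorted(k for k, v in profile.flags.items() if v))

pool_mn, pool_sn = category_pools(profile.sentence_fragments)
print(f"severity pools: MN={pool_mn}, SN={pool_sn}")

scores = allocate_scores(profile.sentence_fragments, ScoringConfig(allocation_mode="paper_compat"))
print("per-part severity (paper-compat):",
      {k: round(v, 2) for k, v in scores.items() if v > 0})

total = total_score(scores)
print(f"total severity {total:.2f} -> work-ability category: {wai_category(min(total, 10))}")
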