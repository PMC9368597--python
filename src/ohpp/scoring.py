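"""Per-body-part Functional Work Ability severity scoring.

An appointment's restriction sentences are turned into a per-part severity
score by (1) building one score pool per protection category — MN ("Must
Not") and SN ("Should Not") — as the number of part-bearing sentences in
that category times a per-sentence weight, and (2) allocating each pool down
to body parts. Process-only sentences (no body part recorded) never enter
the pools.

Operative per-sentence weights are MN = 1.0 and SN = 2.5: two MN sentences
yield a pool of 2, two SN sentences a pool of 5. (A commonly quoted opening
ratio "SN = 1, MN = 0.5" describes relative severity, not the operative
weights; only 1.0/2.5 reproduces the published pools. Both readings are
documented in the methods note.)

Three allocation modes are provided because the published worked example is
not reproducible under a single rule:

``sentence``
    per-sentence share = pool / (number of sentences in the category); each
    sentence's share splits evenly over its parts. Conserves the pools
    exactly — this is the default.
``slot``
    per-sentence share = pool / (total number of part slots in the
    category); again split evenly within the sentence.
``paper_compat``
    MN allocated by the ``sentence`` rule, SN by the ``slot`` rule — the
    only combination that reproduces the published example (shoulders and
    fingers 0.5, trunk 5/3 -> 1.66 truncated, wrists 5/6 -> 0.8), offered
    for fidelity without a claim about intent.

The total score lives on the 0-10 Work Ability Index scale with the two
published categories: good (8-10) and poor (0-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .bodyparts import PART_NAMES, BodyPart, ProtectionLevel
from .extraction import Fragment, ProtectionProfile

__all__ = [
    "ScoringConfig",
    "ScoredProfile",
    "category_pools",
    "allocate_scores",
    "total_score",
    "wai_category",
    "score_profile",
    "scores_to_frame",
    "truncate",
]

ALLOCATION_MODES = ("sentence", "slot", "paper_compat")


@dataclass(frozen=True)
class ScoringConfig:
    mn_sentence_weight: float = 1.0
    sn_sentence_weight: float = 2.5
    allocation_mode: str = "sentence"
    good_range: tuple[int, int] = (8, 10)
    poor_range: tuple[int, int] = (0, 7)

    def __post_init__(self) -> None:
        if self.mn_sentence_weight <= 0 or self.sn_sentence_weight <= 0:
            raise ValueError("sentence weights must be positive")
        if self.allocation_mode not in ALLOCATION_MODES:
            raise ValueError(
                f"unknown allocation_mode {self.allocation_mode!r}; expected one of {ALLOCATION_MODES}"
            )
        if not (self.poor_range[1] < self.good_range[0] and self.poor_range[0] <= self.poor_range[1]):
            raise ValueError("poor/good ranges must be disjoint and ordered")


@dataclass
class ScoredProfile:
    """Severity scores for one appointment: 14 per-part scores, their total,
    and the Work Ability Index category of the total."""

    scores: dict[str, float]
    total: float
    wai: str
    worker_id: str = ""
    date: str = ""
    metadata: dict = field(default_factory=dict)


def _sentences_with_parts(fragments_by_sentence: list[list[Fragment]], level: ProtectionLevel):
    """Part lists of sentences in a category that name at least one part."""
    out: list[list[BodyPart]] = []
    for frags in fragments_by_sentence:
        parts = [p for fr in frags if fr.level is level for p in fr.parts]
        if parts:
            out.append(parts)
    return out


def category_pools(
    fragments_by_sentence: list[list[Fragment]], config: ScoringConfig | None = None
) -> tuple[float, float]:
    """Score pools (pool_MN, pool_SN).

    pool = (number of sentences in the category carrying >= 1 body part)
    x (category per-sentence weight). Process-only and unparsed sentences
    contribute nothing.
    """
    config = config or ScoringConfig()
    n_mn = len(_sentences_with_parts(fragments_by_sentence, ProtectionLevel.MN))
    n_sn = len(_sentences_with_parts(fragments_by_sentence, ProtectionLevel.SN))
    return n_mn * config.mn_sentence_weight, n_sn * config.sn_sentence_weight


def _allocate_category(
    sentences: list[list[BodyPart]], pool: float, rule: str, scores: dict[str, float]
) -> None:
    if not sentences or pool == 0:
        return
    if rule == "sentence":
        share = pool / len(sentences)
        for parts in sentences:
            for p in parts:
                scores[p.name] += share / len(parts)
    elif rule == "slot":
        n_slots = sum(len(parts) for parts in sentences)
        share = pool / n_slots
        for parts in sentences:
            for p in parts:
                scores[p.name] += share / len(parts)
    else:  # pragma: no cover - guarded by ScoringConfig
        raise ValueError(f"unknown allocation rule {rule!r}")


def allocate_scores(
    fragments_by_sentence: list[list[Fragment]], config: ScoringConfig | None = None
) -> dict[str, float]:
    """Allocate the category pools over the 14 body parts.

    Parts hit by several sentences accumulate additively. Returns a full
    14-entry mapping (unrestricted parts score 0).
    """
    config = config or ScoringConfig()
    mode = config.allocation_mode
    pool_mn, pool_sn = category_pools(fragments_by_sentence, config)
    mn_sentences = _sentences_with_parts(fragments_by_sentence, ProtectionLevel.MN)
    sn_sentences = _sentences_with_parts(fragments_by_sentence, ProtectionLevel.SN)

    scores = {name: 0.0 for name in PART_NAMES}
    mn_rule = "sentence" if mode in ("sentence", "paper_compat") else "slot"
    sn_rule = "slot" if mode in ("slot", "paper_compat") else "sentence"
    _allocate_category(mn_sentences, pool_mn, mn_rule, scores)
    _allocate_category(sn_sentences, pool_sn, sn_rule, scores)
    return scores


def total_score(scores: dict[str, float]) -> float:
    """Plain sum of the 14 per-part scores."""
    return float(sum(scores.values()))


def wai_category(total: float) -> str:
    """Work Ability Index category of a total severity score.

    good (8-10) / poor (0-7); a fractional total strictly between 7 and 8 is
    rounded half-up to the nearer integer before classification. Values
    outside [0, 10] are outside the scale and raise.
    """
    if math.isnan(total) or total < 0 or total > 10:
        raise ValueError(f"total score {total} outside the 0-10 Work Ability Index scale")
    if 7 < total < 8:
        total = math.floor(total + 0.5)
    return "poor" if total <= 7 else "good"


def score_profile(profile: ProtectionProfile, config: ScoringConfig | None = None) -> ScoredProfile:
    """Score one extracted appointment profile."""
    config = config or ScoringConfig()
    scores = allocate_scores(profile.sentence_fragments, config)
    total = total_score(scores)
    return ScoredProfile(
        scores=scores,
        total=total,
        wai=wai_category(total) if total <= 10 else "poor",
        worker_id=profile.worker_id,
        date=profile.date,
        metadata={
            "area": profile.area,
            "function": profile.function,
            "schedule": profile.schedule,
            "seniority_years": profile.seniority_years,
            "gender": profile.gender,
        },
    )


def truncate(value: float, decimals: int) -> float:
    """Round toward zero at a given decimal place (display convention:
    5/3 prints as 1.66 at two truncated decimals)."""
    factor = 10**decimals
    return math.trunc(value * factor) / factor


_META = ("worker_id", "date", "area", "function", "schedule", "seniority_years", "gender")


def scores_to_frame(scored: list[ScoredProfile]) -> pd.DataFrame:
    """Flat score table: metadata, the 14 per-part scores, total, category."""
    rows = []
    for s in scored:
        row = {"worker_id": s.worker_id, "date": s.date}
        row.update(s.metadata)
        row.update({name: s.scores[name] for name in PART_NAMES})
        row["total"] = s.total
        row["wai_category"] = s.wai
        rows.append(row)
    cols = list(_META) + list(PART_NAMES) + ["total", "wai_category"]
    return pd.DataFrame(rows, columns=cols)
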