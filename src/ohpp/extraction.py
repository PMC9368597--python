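"""Rule-based extraction of (body part, protection level) pairs from
restriction sentences.

Occupational physicians write restrictions as free text ("Must not perform
tasks that involve movements above both shoulders."). Real corpora carry
clerical deviations: stray symbols, doubled spaces, misspellings, erratic
capitalisation, and the MN/SN cue written at the end of the sentence rather
than its start. The parser here is deliberately lexicon-driven — no learned
NER — because the vocabulary is tiny and closed: 8 anatomical regions,
left/right/both laterality markers, and two protection cues.

Matching is fuzzy: tokens of five or more characters tolerate one edit
(insertion, deletion or substitution) against a lexicon keyword; shorter
tokens must match exactly. Laterality resolution walks region mentions left
to right, attaching the nearest unconsumed side marker, looking backwards
first (English puts the adjective before the noun) and forwards within a
short window otherwise (Portuguese puts it after; "fingers of both hands"
also resolves forwards).

Sentences that name a protection level but no recognisable body content are
never silently dropped — they come back flagged ``unparsed`` for manual
review. Process-only restrictions (vibration tools, manual material
handling) are a recognised special case that legitimately carries no body
part.
"""

from __future__ import annotations

import importlib.resources
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd
import yaml

from .bodyparts import (
    BODY_PARTS,
    FLAG_COLUMNS,
    SIDED_REGIONS,
    UNSIDED_REGIONS,
    BodyPart,
    ProtectionLevel,
    Side,
)

__all__ = [
    "EmptySentenceError",
    "Lexicon",
    "Fragment",
    "ProtectionProfile",
    "normalize_sentence",
    "extract_protections",
    "build_profile",
    "profiles_to_frame",
    "extract_corpus",
]


class EmptySentenceError(ValueError):
    """Raised when a sentence is empty or whitespace-only."""


_WS = re.compile(r"\s+")
_NONWORD = re.compile(r"[^\w\s]+", re.UNICODE)


def normalize_sentence(raw: str) -> str:
    """Lower-case, strip non-word symbols and collapse whitespace.

    Diacritics are preserved (the source language is Portuguese). The
    operation is idempotent. Raises :class:`EmptySentenceError` on empty or
    whitespace-only input.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise EmptySentenceError("empty or whitespace-only sentence")
    text = unicodedata.normalize("NFC", raw).lower()
    text = _NONWORD.sub(" ", text)
    text = _WS.sub(" ", text).strip()
    if not text:
        raise EmptySentenceError("sentence contains no word characters")
    return text


def _fuzzy_eq(token: str, keyword: str) -> bool:
    """Exact match, or one edit for tokens/keywords of 5+ characters."""
    if token == keyword:
        return True
    if len(token) < 5 or len(keyword) < 5:
        return False
    return edlib.align(token, keyword, task="distance", k=1)["editDistance"] != -1


_PLURAL_EXCEPTIONS = {"feet", "pés"}


def _is_plural(keyword: str) -> bool:
    return keyword.endswith("s") or keyword in _PLURAL_EXCEPTIONS


class Lexicon:
    """Keyword tables for parsing plus templates for rendering.

    Loaded from YAML; both languages' keywords are active simultaneously so
    mixed corpora parse without a language switch.
    """

    def __init__(self, spec: dict):
        self.spec = spec
        langs = ("en", "pt")
        self.level_cues: dict[ProtectionLevel, list[list[str]]] = {
            ProtectionLevel[name]: [spec["levels"][name][lg].split() for lg in langs]
            for name in spec["levels"]
        }
        self.region_keywords: dict[str, str] = {}  # keyword -> region
        for region, by_lang in spec["regions"].items():
            for lg in langs:
                for kw in by_lang.get(lg, []):
                    self.region_keywords[kw] = region
        self.side_keywords: dict[str, str] = {}  # keyword -> left|right|both
        for side, by_lang in spec["sides"].items():
            for lg in langs:
                for kw in by_lang.get(lg, []):
                    self.side_keywords[kw] = side
        self.carriers: set[str] = {kw for lg in langs for kw in spec.get("carriers", {}).get(lg, [])}
        self.process_keywords: list[list[str]] = [
            kw.split() for lg in langs for kw in spec.get("process_keywords", {}).get(lg, [])
        ]

    @classmethod
    def default(cls) -> "Lexicon":
        ref = importlib.resources.files("ohpp") / "data" / "lexicon.yaml"
        return cls(yaml.safe_load(ref.read_text(encoding="utf-8")))

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        return cls(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    # --- rendering side (used by the synthetic corpus generator) ---------
    def sentence_template(self, language: str) -> str:
        return self.spec["sentence_prefix"][language]

    def level_phrase(self, level: ProtectionLevel, language: str) -> str:
        return self.spec["level_phrases"][level.value][language]

    def body_phrase(self, region: str, lat: str, language: str) -> str:
        return self.spec["phrases"][language][region][lat]

    def process_phrase(self, key: str, language: str) -> str:
        return self.spec["process_phrases"][key][language]

    # --- matching helpers -------------------------------------------------
    def match_region(self, token: str) -> str | None:
        for kw, region in self.region_keywords.items():
            if _fuzzy_eq(token, kw):
                return region
        return None

    def match_region_plural(self, token: str) -> bool:
        for kw in self.region_keywords:
            if _fuzzy_eq(token, kw) and _is_plural(kw):
                return True
        return False

    def match_side(self, token: str) -> str | None:
        for kw, side in self.side_keywords.items():
            if _fuzzy_eq(token, kw):
                return side
        return None

    def is_carrier(self, token: str) -> bool:
        return any(_fuzzy_eq(token, kw) for kw in self.carriers)

    def _seq_match(self, tokens: Sequence[str], i: int, phrase: Sequence[str]) -> bool:
        if i + len(phrase) > len(tokens):
            return False
        return all(_fuzzy_eq(tokens[i + k], w) for k, w in enumerate(phrase))

    def find_level_cues(self, tokens: Sequence[str]) -> list[tuple[int, int, ProtectionLevel]]:
        """All (start, end, level) cue spans, non-overlapping, left to right."""
        cues: list[tuple[int, int, ProtectionLevel]] = []
        i = 0
        while i < len(tokens):
            hit = None
            for level, phrases in self.level_cues.items():
                for phrase in phrases:
                    if self._seq_match(tokens, i, phrase):
                        hit = (i, i + len(phrase), level)
                        break
                if hit:
                    break
            if hit:
                cues.append(hit)
                i = hit[1]
            else:
                i += 1
        return cues

    def has_process_keyword(self, tokens: Sequence[str]) -> bool:
        return any(
            self._seq_match(tokens, i, phrase)
            for phrase in self.process_keywords
            for i in range(len(tokens))
        )


@dataclass
class Fragment:
    """One protection statement: a level plus the body parts it covers.

    ``parts`` is empty for process-only restrictions; ``unparsed`` marks a
    sentence (or a region mention) the rules could not resolve, kept for
    manual review rather than dropped.
    """

    level: ProtectionLevel | None
    parts: list[BodyPart] = field(default_factory=list)
    process_only: bool = False
    unparsed: bool = False
    note: str = ""


def _resolve_segment(tokens: list[str], lexicon: Lexicon, level: ProtectionLevel) -> Fragment:
    region_hits = [
        (i, lexicon.match_region(t))
        for i, t in enumerate(tokens)
        if not lexicon.is_carrier(t) and lexicon.match_region(t) is not None
    ]
    if not region_hits:
        if lexicon.has_process_keyword(tokens):
            return Fragment(level, [], process_only=True)
        return Fragment(level, [], unparsed=True, note=" ".join(tokens))

    side_hits = {
        i: lexicon.match_side(t) for i, t in enumerate(tokens) if lexicon.match_side(t) is not None
    }
    consumed: set[int] = set()
    parts: list[BodyPart] = []
    notes: list[str] = []
    unparsed = False

    region_positions = [i for i, _ in region_hits]
    for k, (pos, region) in enumerate(region_hits):
        if region in UNSIDED_REGIONS:
            parts.append(BodyPart(region))
            continue
        back_start = region_positions[k - 1] + 1 if k > 0 else 0
        back = {i: s for i, s in side_hits.items() if back_start <= i < pos and i not in consumed}
        fwd_stop = region_positions[k + 1] if k + 1 < len(region_hits) else len(tokens)
        fwd_stop = min(fwd_stop, pos + 5)
        fwd = {i: s for i, s in side_hits.items() if pos < i < fwd_stop and i not in consumed}

        sides = _pick_sides(pos, back, fwd)
        if sides is None:
            if lexicon.match_region_plural(tokens[pos]):
                sides, marker_idx = ["left", "right"], []
            else:
                unparsed = True
                notes.append(f"unresolved laterality for {region!r}")
                continue
        else:
            sides, marker_idx = sides
        consumed.update(marker_idx)
        for s in sides:
            parts.append(BodyPart(region, Side.LEFT if s == "left" else Side.RIGHT))

    seen: set[BodyPart] = set()
    uniq = [p for p in parts if not (p in seen or seen.add(p))]
    return Fragment(level, uniq, unparsed=unparsed, note="; ".join(notes))


def _pick_sides(
    pos: int, back: dict[int, str], fwd: dict[int, str]
) -> tuple[list[str], list[int]] | None:
    """Choose laterality from marker candidates around a region mention.

    Preference order: an explicit "both" anywhere; left+right jointly in the
    backward span ("left and right wrist"); otherwise the nearest unconsumed
    marker, backward winning ties.
    """
    for cand in (back, fwd):
        both_idx = [i for i, s in cand.items() if s == "both"]
        if both_idx:
            return ["left", "right"], both_idx
    back_sides = set(back.values())
    if {"left", "right"} <= back_sides:
        return ["left", "right"], list(back.keys())
    best: tuple[int, int, str] | None = None  # (distance, idx, side)
    for i, s in back.items():
        d = pos - i
        if best is None or d < best[0]:
            best = (d, i, s)
    for i, s in fwd.items():
        d = i - pos
        if best is None or d < best[0]:
            best = (d, i, s)
    if best is None:
        return None
    return [best[2]], [best[1]]


def extract_protections(sentence: str, lexicon: Lexicon | None = None) -> list[Fragment]:
    """Parse one normalized sentence into protection fragments.

    The MN/SN cue may sit at the start or the end of the sentence; with
    several mid-sentence cues, each cue governs the phrase that follows it.
    """
    lexicon = lexicon or Lexicon.default()
    tokens = sentence.split()
    cues = lexicon.find_level_cues(tokens)
    if not cues:
        return [Fragment(None, [], unparsed=True, note=sentence)]

    cue_idx = {i for s, e, _ in cues for i in range(s, e)}
    if len(cues) == 1:
        body = [t for i, t in enumerate(tokens) if i not in cue_idx]
        return [_resolve_segment(body, lexicon, cues[0][2])]

    fragments: list[Fragment] = []
    for j, (start, end, level) in enumerate(cues):
        stop = cues[j + 1][0] if j + 1 < len(cues) else len(tokens)
        seg = tokens[end:stop]
        if not seg and end == len(tokens):
            # trailing cue: applies to the text before the first cue, if any
            seg = tokens[: cues[0][0]]
        if not seg:
            fragments.append(Fragment(level, [], unparsed=True, note="cue without content"))
            continue
        fragments.append(_resolve_segment(seg, lexicon, level))
    return fragments


@dataclass
class ProtectionProfile:
    """One appointment flattened to the 28-flag schema plus metadata.

    Where both MN and SN were extracted for the same part within one
    appointment, MN (the stronger protection) wins and the SN flag is 0.
    """

    worker_id: str = ""
    date: str = ""
    area: str = ""
    function: str = ""
    schedule: str = ""
    seniority_years: float = float("nan")
    gender: str = ""
    flags: dict[str, int] = field(default_factory=dict)
    sentence_fragments: list[list[Fragment]] = field(default_factory=list)
    unparsed: list[str] = field(default_factory=list)

    def parts_at(self, level: ProtectionLevel) -> list[BodyPart]:
        return [p for p in BODY_PARTS if self.flags.get(f"{p.name}_{level.value}", 0) == 1]


def build_profile(
    sentences: Iterable[str],
    lexicon: Lexicon | None = None,
    *,
    metadata: dict | None = None,
) -> ProtectionProfile:
    """Extract all sentences of one appointment and merge into 28 flags."""
    lexicon = lexicon or Lexicon.default()
    flags = {c: 0 for c in FLAG_COLUMNS}
    all_fragments: list[list[Fragment]] = []
    unparsed: list[str] = []
    for raw in sentences:
        norm = normalize_sentence(raw)
        frags = extract_protections(norm, lexicon)
        all_fragments.append(frags)
        for fr in frags:
            if fr.unparsed:
                unparsed.append(norm if not fr.note else fr.note)
            if fr.level is None:
                continue
            for part in fr.parts:
                flags[f"{part.name}_{fr.level.value}"] = 1
    # MN dominates SN for the same part
    for part in BODY_PARTS:
        if flags[f"{part.name}_MN"] and flags[f"{part.name}_SN"]:
            flags[f"{part.name}_SN"] = 0
    meta = metadata or {}
    return ProtectionProfile(
        worker_id=str(meta.get("worker_id", "")),
        date=str(meta.get("date", "")),
        area=str(meta.get("area", "")),
        function=str(meta.get("function", "")),
        schedule=str(meta.get("schedule", "")),
        seniority_years=float(meta.get("seniority_years", float("nan"))),
        gender=str(meta.get("gender", "")),
        flags=flags,
        sentence_fragments=all_fragments,
        unparsed=unparsed,
    )


_META_COLUMNS = ("worker_id", "date", "area", "function", "schedule", "seniority_years", "gender")


def profiles_to_frame(profiles: Sequence[ProtectionProfile]) -> pd.DataFrame:
    """Flat table: metadata columns followed by the ordered 28 flags."""
    rows = []
    for p in profiles:
        row = {c: getattr(p, c) for c in _META_COLUMNS}
        row.update({c: p.flags.get(c, 0) for c in FLAG_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(FLAG_COLUMNS))


def extract_corpus(
    corpus_path: str | Path,
    lexicon: Lexicon | None = None,
) -> tuple[list[ProtectionProfile], pd.DataFrame]:
    """Run extraction over a JSON-lines corpus (one appointment per line).

    Each line must carry a ``sentences`` list plus appointment metadata.
    Returns the profiles and the flat 28-flag table.
    """
    lexicon = lexicon or Lexicon.default()
    profiles = []
    with open(corpus_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            profiles.append(build_profile(rec["sentences"], lexicon, metadata=rec))
    return profiles, profiles_to_frame(profiles)
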