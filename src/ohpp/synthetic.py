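"""Seeded synthetic Occupational Health Protection Profile corpora.

Real OHPP databases are proprietary occupational-health records, so the
pipeline ships a generator that emulates their statistical structure and
carries full ground truth: worker demographics (23.3% female; per-gender
seniority distributions of an automotive plant), production areas, worker
timelines whose appointment-count histogram decays with the number of visits
(with no worker at exactly 8 visits), restriction sentences rendered through
the same bilingual templates the extractor parses, clerical text noise
(misspellings, extra spaces, non-word symbols, capitalisation errors, the
MN/SN cue displaced to the end of the sentence), and a planted linear
interval model

    weeks_to_next = max(min_interval, beta0 - sum_p beta_p * score_p + eps),
    eps ~ Normal(0, sigma),

so that higher severity shortens the time to the next medical appointment,
with the shoulder-right coefficient dominant. Each random channel
(demography, restrictions, text noise, intervals) has its own stream:
changing one noise rate leaves every other draw unchanged.

Region frequencies are weighted so shoulders and elbows are restricted most
often, as in published per-part record counts for this industry.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bodyparts import PART_NAMES, BodyPart, ProtectionLevel, Side, SIDED_REGIONS, UNSIDED_REGIONS
from .extraction import Fragment, Lexicon
from .scoring import ScoringConfig, allocate_scores

__all__ = [
    "ConfigError",
    "SeniorityParams",
    "NoiseParams",
    "IntervalModel",
    "GeneratorConfig",
    "GroundTruthAppointment",
    "generate_cohort",
    "render_sentence",
    "sample_interval",
    "corpus_to_jsonl",
    "corpus_to_frame",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class SeniorityParams:
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class NoiseParams:
    p_label_at_end: float = 0.05
    p_misspell_token: float = 0.02
    p_extra_space: float = 0.05
    p_nonword_symbol: float = 0.05
    p_caps_error: float = 0.05


@dataclass(frozen=True)
class IntervalModel:
    """Planted time-to-next-appointment model, in weeks."""

    beta0: float = 64.0
    beta: dict = field(
        default_factory=lambda: {"ShoulderR": 8.0, **{p: 1.0 for p in PART_NAMES if p != "ShoulderR"}}
    )
    sigma: float = 3.0
    min_interval: float = 1.0


_DEFAULT_AREAS = {
    "Assembly": 0.38,
    "Body Construction": 0.20,
    "Paint": 0.14,
    "Metal Stamping": 0.12,
    "Quality Assurance": 0.09,
    "Special Projects": 0.07,
}

# truncated-geometric appointment-count law (ratio 1/2) with no mass at 8
def _default_count_dist() -> dict[int, float]:
    ks = [1, 2, 3, 4, 5, 6, 7, 9, 10]
    w = np.array([0.5 ** (k - 1) for k in ks])
    w /= w.sum()
    return {k: float(p) for k, p in zip(ks, w)} | {8: 0.0}


_REGION_WEIGHTS = {
    "shoulder": 0.30,
    "elbow": 0.20,
    "wrist": 0.15,
    "trunk": 0.10,
    "fingers": 0.10,
    "neck": 0.05,
    "knee": 0.05,
    "foot": 0.05,
}

_FUNCTIONS = (
    "assembly operator",
    "machine operator",
    "team leader",
    "maintenance technician",
    "quality inspector",
)
_SCHEDULES = ("day", "2-shift", "3-shift", "night")
_SCHEDULE_W = (0.2, 0.4, 0.3, 0.1)
#: number of part-bearing restriction sentences per appointment
_N_SENTENCE_DIST = {0: 0.05, 1: 0.45, 2: 0.30, 3: 0.20}
_P_BILATERAL = 0.3
_P_PROCESS_SENTENCE = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    n_workers: int = 300
    seed: int = 0
    p_female: float = 0.233
    seniority_params: dict = field(
        default_factory=lambda: {
            "F": SeniorityParams(13.95, 7.78, 4.0, 27.0),
            "M": SeniorityParams(18.62, 8.33, 4.0, 29.0),
        }
    )
    area_weights: dict = field(default_factory=lambda: dict(_DEFAULT_AREAS))
    appointment_count_dist: dict = field(default_factory=_default_count_dist)
    noise: NoiseParams = field(default_factory=NoiseParams)
    interval_model: IntervalModel = field(default_factory=IntervalModel)
    language: str = "en"

    def validate(self) -> None:
        if self.n_workers < 0:
            raise ConfigError("n_workers must be >= 0")
        if not 0 <= self.p_female <= 1:
            raise ConfigError("p_female must be in [0, 1]")
        for name, p in asdict(self.noise).items():
            if not 0 <= p <= 1:
                raise ConfigError(f"noise.{name} must be in [0, 1]")
        if abs(sum(self.area_weights.values()) - 1) > 1e-6:
            raise ConfigError("area_weights must sum to 1")
        if any(w < 0 for w in self.area_weights.values()):
            raise ConfigError("area_weights must be non-negative")
        dist = self.appointment_count_dist
        if abs(sum(dist.values()) - 1) > 1e-6:
            raise ConfigError("appointment_count_dist must sum to 1")
        if dist.get(8, 0.0) != 0.0:
            raise ConfigError("appointment_count_dist must assign probability 0 to k=8")
        if any(p < 0 for p in dist.values()):
            raise ConfigError("appointment_count_dist must be non-negative")
        if self.interval_model.beta0 <= 0:
            raise ConfigError("interval_model.beta0 must be > 0")
        if self.interval_model.sigma < 0:
            raise ConfigError("interval_model.sigma must be >= 0")
        if self.interval_model.min_interval < 1:
            raise ConfigError("interval_model.min_interval must be >= 1 week")
        if self.language not in ("en", "pt"):
            raise ConfigError("language must be 'en' or 'pt'")
        for g in ("F", "M"):
            if g not in self.seniority_params:
                raise ConfigError(f"seniority_params missing gender {g!r}")


@dataclass
class GroundTruthAppointment:
    worker_id: str
    date: str  # ISO date
    area: str
    function: str
    schedule: str
    seniority_years: float
    gender: str
    #: sentence-grouped truth: list of (level, [part names]); parts empty for
    #: process-only sentences
    true_protections: list
    sentences: list
    true_scores: dict
    true_interval_weeks: float | None  # None for the last appointment


# --------------------------------------------------------------------------
# sentence rendering


def _group_parts(parts: Sequence[BodyPart]) -> list[tuple[str, str]]:
    """(region, laterality-spec) groups in stable order; both sides collapse."""
    out: list[tuple[str, str]] = []
    seen_regions: list[str] = []
    for p in parts:
        if p.region not in seen_regions:
            seen_regions.append(p.region)
    for region in seen_regions:
        sides = {p.side for p in parts if p.region == region}
        if region in UNSIDED_REGIONS:
            out.append((region, "none"))
        elif sides >= {Side.LEFT, Side.RIGHT}:
            out.append((region, "both"))
        else:
            out.append((region, "left" if Side.LEFT in sides else "right"))
    return out


_SYMBOLS = "!?#*;:"
_CONJ = {"en": " and ", "pt": " e "}


def _misspell(token: str, rng: np.random.Generator) -> str:
    """One random edit (substitute, delete, insert or transpose)."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    op = rng.choice(["sub", "del", "ins", "swap"])
    i = int(rng.integers(0, len(token)))
    if op == "sub":
        c = alphabet[int(rng.integers(0, 26))]
        return token[:i] + c + token[i + 1 :]
    if op == "del" and len(token) > 1:
        return token[:i] + token[i + 1 :]
    if op == "swap" and len(token) > 1:
        i = min(i, len(token) - 2)
        return token[:i] + token[i + 1] + token[i] + token[i + 2 :]
    c = alphabet[int(rng.integers(0, 26))]
    return token[:i] + c + token[i:]


def render_sentence(
    protection_group: tuple[ProtectionLevel, Sequence[BodyPart]] | tuple[ProtectionLevel, str],
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    lexicon: Lexicon | None = None,
    language: str = "en",
) -> str:
    """Render one restriction sentence from a (level, parts) group.

    With all noise probabilities zero the output is exactly the canonical
    template. ``parts`` may instead be a process-template key
    (``vibration_tools`` or ``manual_material_handling``) for the
    process-only restrictions that legitimately carry no body part.
    """
    noise = noise or NoiseParams(0, 0, 0, 0, 0)
    rng = rng or np.random.default_rng(0)
    lexicon = lexicon or Lexicon.default()
    level, parts = protection_group

    level_phrase = lexicon.level_phrase(level, language)
    if isinstance(parts, str):
        body = lexicon.process_phrase(parts, language)
    else:
        if not parts:
            raise ValueError("empty part list is only valid for process-only template keys")
        groups = _group_parts(parts)
        body = _CONJ[language].join(lexicon.body_phrase(r, lat, language) for r, lat in groups)
    template = lexicon.sentence_template(language)

    if rng.random() < noise.p_label_at_end:
        core = template.format(level="", body=body).strip(" .").strip()
        sentence = core[:1].upper() + core[1:] + " " + level_phrase.lower() + "."
    else:
        sentence = template.format(level=level_phrase, body=body)

    tokens = sentence[:-1].split(" ")  # drop final period, re-added below
    out_tokens = []
    for tok in tokens:
        if len(tok) >= 3 and tok.isalpha() and rng.random() < noise.p_misspell_token:
            tok = _misspell(tok.lower(), rng)
        if rng.random() < noise.p_caps_error:
            tok = tok.upper() if rng.random() < 0.5 else tok.capitalize()
        if rng.random() < noise.p_nonword_symbol:
            tok = tok + _SYMBOLS[int(rng.integers(0, len(_SYMBOLS)))]
        out_tokens.append(tok)
    sep_tokens = [out_tokens[0]]
    for tok in out_tokens[1:]:
        sep_tokens.append("  " if rng.random() < noise.p_extra_space else " ")
        sep_tokens.append(tok)
    return "".join(sep_tokens) + "."


# --------------------------------------------------------------------------
# interval model


def sample_interval(
    true_scores: dict[str, float],
    interval_model: IntervalModel | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Weeks to the next appointment under the planted linear model.

    ``max(min_interval, beta0 - sum_p beta_p * score_p + eps)`` — monotone
    non-increasing in every score at fixed noise.
    """
    model = interval_model or IntervalModel()
    rng = rng or np.random.default_rng(0)
    if any(v < 0 for v in true_scores.values()):
        raise ValueError("scores must be non-negative")
    eps = float(rng.normal(0.0, model.sigma)) if model.sigma > 0 else 0.0
    drop = sum(model.beta.get(part, 0.0) * s for part, s in true_scores.items())
    return float(max(model.min_interval, model.beta0 - drop + eps))


# --------------------------------------------------------------------------
# cohort generation


def _truncnorm(rng: np.random.Generator, p: SeniorityParams) -> float:
    for _ in range(1000):
        x = rng.normal(p.mean, p.sd)
        if p.min <= x <= p.max:
            return float(x)
    return float(np.clip(rng.normal(p.mean, p.sd), p.min, p.max))


def _sample_restrictions(rng: np.random.Generator) -> list[tuple[ProtectionLevel, list[BodyPart]]]:
    ks = list(_N_SENTENCE_DIST)
    k = int(rng.choice(ks, p=[_N_SENTENCE_DIST[i] for i in ks]))
    regions = list(_REGION_WEIGHTS)
    weights = np.array([_REGION_WEIGHTS[r] for r in regions])
    chosen = rng.choice(len(regions), size=min(k, len(regions)), replace=False, p=weights / weights.sum())
    sentences = []
    for idx in chosen:
        region = regions[int(idx)]
        level = ProtectionLevel.MN if rng.random() < 0.5 else ProtectionLevel.SN
        if region in UNSIDED_REGIONS:
            parts = [BodyPart(region)]
        elif rng.random() < _P_BILATERAL:
            parts = [BodyPart(region, Side.LEFT), BodyPart(region, Side.RIGHT)]
        else:
            side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            parts = [BodyPart(region, side)]
        sentences.append((level, parts))
    return sentences


def _score_truth(restrictions: list[tuple[ProtectionLevel, list[BodyPart]]]) -> dict[str, float]:
    frags = [[Fragment(level, list(parts))] for level, parts in restrictions if parts]
    return allocate_scores(frags, ScoringConfig())


def generate_cohort(config: GeneratorConfig) -> list[GroundTruthAppointment]:
    """Generate a seeded synthetic cohort of appointment timelines.

    Deterministic given ``config.seed``; every appointment carries rendered
    sentences and full ground truth. The last appointment of each worker has
    no interval target (right-censored; downstream feature assembly drops
    it).
    """
    config.validate()
    lexicon = Lexicon.default()
    ss = np.random.SeedSequence(config.seed)
    demo_rng, restr_rng, noise_rng, int_rng = (np.random.default_rng(c) for c in ss.spawn(4))

    areas = sorted(config.area_weights)
    area_p = np.array([config.area_weights[a] for a in areas])
    counts = sorted(config.appointment_count_dist)
    count_p = np.array([config.appointment_count_dist[k] for k in counts])

    corpus: list[GroundTruthAppointment] = []
    for w in range(config.n_workers):
        worker_id = f"W{w:05d}"
        gender = "F" if demo_rng.random() < config.p_female else "M"
        seniority = round(_truncnorm(demo_rng, config.seniority_params[gender]), 1)
        area = areas[int(demo_rng.choice(len(areas), p=area_p / area_p.sum()))]
        function = _FUNCTIONS[int(demo_rng.integers(0, len(_FUNCTIONS)))]
        schedule = _SCHEDULES[int(demo_rng.choice(len(_SCHEDULES), p=np.array(_SCHEDULE_W)))]
        n_appts = int(counts[int(demo_rng.choice(len(counts), p=count_p / count_p.sum()))])
        day = _date(2019, 1, 1) + timedelta(days=int(demo_rng.integers(0, 730)))

        for j in range(n_appts):
            restrictions = _sample_restrictions(restr_rng)
            true_scores = _score_truth(restrictions)
            sentence_specs: list[tuple[ProtectionLevel, object]] = list(restrictions)
            if restr_rng.random() < _P_PROCESS_SENTENCE:
                key = "vibration_tools" if restr_rng.random() < 0.5 else "manual_material_handling"
                level = ProtectionLevel.MN if restr_rng.random() < 0.5 else ProtectionLevel.SN
                sentence_specs.append((level, key))
            sentences = [
                render_sentence(spec, config.noise, noise_rng, lexicon=lexicon, language=config.language)
                for spec in sentence_specs
            ]
            last = j == n_appts - 1
            interval = None if last else sample_interval(true_scores, config.interval_model, int_rng)
            corpus.append(
                GroundTruthAppointment(
                    worker_id=worker_id,
                    date=day.isoformat(),
                    area=area,
                    function=function,
                    schedule=schedule,
                    seniority_years=seniority,
                    gender=gender,
                    true_protections=[
                        (lvl.value, [p.name for p in parts] if not isinstance(parts, str) else [])
                        for lvl, parts in sentence_specs
                    ],
                    sentences=sentences,
                    true_scores=true_scores,
                    true_interval_weeks=interval,
                )
            )
            if not last:
                day = day + timedelta(days=int(round(interval * 7)))
    return corpus


# --------------------------------------------------------------------------
# serialization


def corpus_to_jsonl(corpus: list[GroundTruthAppointment], path: str | Path) -> None:
    """One appointment per line; ground truth travels with the text."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in corpus:
            fh.write(json.dumps(asdict(a), ensure_ascii=False) + "\n")


def corpus_from_jsonl(path: str | Path) -> list[GroundTruthAppointment]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                d["true_protections"] = [tuple(x) for x in d["true_protections"]]
                out.append(GroundTruthAppointment(**d))
    return out


def corpus_to_frame(corpus: list[GroundTruthAppointment]) -> pd.DataFrame:
    """Flat delimited view: metadata, joined sentences, true scores, interval."""
    rows = []
    for a in corpus:
        row = {
            "worker_id": a.worker_id,
            "date": a.date,
            "area": a.area,
            "function": a.function,
            "schedule": a.schedule,
            "seniority_years": a.seniority_years,
            "gender": a.gender,
            "sentences": " | ".join(a.sentences),
            "true_interval_weeks": a.true_interval_weeks,
        }
        row.update({f"true_{p}": a.true_scores.get(p, 0.0) for p in PART_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML or JSON file; unknown keys error."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = GeneratorConfig()
    known = set(cfg.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "noise" in raw:
        raw["noise"] = NoiseParams(**raw["noise"])
    if "interval_model" in raw:
        raw["interval_model"] = IntervalModel(**raw["interval_model"])
    if "seniority_params" in raw:
        raw["seniority_params"] = {g: SeniorityParams(**v) for g, v in raw["seniority_params"].items()}
    if "appointment_count_dist" in raw:
        raw["appointment_count_dist"] = {int(k): float(v) for k, v in raw["appointment_count_dist"].items()}
    cfg = replace(cfg, **raw)
    cfg.validate()
    return cfg
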