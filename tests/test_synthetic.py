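"""Synthetic OHPP corpus generator: calibration, determinism, noise channels."""

import collections
import io
import json

import numpy as np
import pytest

from ohpp.bodyparts import BodyPart, ProtectionLevel, Side
from ohpp.synthetic import (
    ConfigError,
    GeneratorConfig,
    IntervalModel,
    NoiseParams,
    corpus_to_jsonl,
    generate_cohort,
    load_config,
    render_sentence,
    sample_interval,
)

NO_NOISE = NoiseParams(0, 0, 0, 0, 0)


class TestRenderSentence:
    def test_canonical_english_template(self):
        s = render_sentence(
            (ProtectionLevel.MN, [BodyPart("shoulder", Side.LEFT), BodyPart("shoulder", Side.RIGHT)]),
            NO_NOISE,
        )
        assert s == "Must not perform tasks that involve movements above both shoulders."

    def test_canonical_portuguese_template(self):
        s = render_sentence(
            (ProtectionLevel.MN, [BodyPart("shoulder", Side.LEFT), BodyPart("shoulder", Side.RIGHT)]),
            NO_NOISE,
            language="pt",
        )
        assert s == "Não pode executar tarefas que envolvam movimentos acima de ambos os ombros."

    def test_label_at_end_moves_cue(self):
        rng = np.random.default_rng(0)
        s = render_sentence(
            (ProtectionLevel.SN, [BodyPart("elbow", Side.RIGHT)]),
            NoiseParams(p_label_at_end=1.0, p_misspell_token=0, p_extra_space=0, p_nonword_symbol=0, p_caps_error=0),
            rng,
        )
        assert s.lower().rstrip(".").endswith("should not")

    def test_empty_parts_only_for_process_templates(self):
        with pytest.raises(ValueError):
            render_sentence((ProtectionLevel.MN, []), NO_NOISE)
        s = render_sentence((ProtectionLevel.MN, "vibration_tools"), NO_NOISE)
        assert "vibration" in s

    def test_misspelling_rate_matches_binomial(self):
        """At p=0.2, the per-token misspelling fraction over 1000 sentences
        sits inside the 95% binomial interval around 0.2."""
        rng = np.random.default_rng(42)
        noise = NoiseParams(0, 0.2, 0, 0, 0)
        group = (ProtectionLevel.MN, [BodyPart("knee", Side.LEFT)])
        canonical = render_sentence(group, NO_NOISE).rstrip(".").split()
        eligible_mask = [len(t) >= 3 and t.isalpha() for t in canonical]
        changed = total = 0
        for _ in range(1000):
            noisy = render_sentence(group, noise, rng).rstrip(".").split()
            assert len(noisy) == len(canonical)
            for tok, ref, ok in zip(noisy, canonical, eligible_mask):
                if not ok:
                    continue
                total += 1
                changed += tok.lower() != ref.lower()
        p_hat = changed / total
        half = 1.96 * np.sqrt(0.2 * 0.8 / total)
        assert abs(p_hat - 0.2) < half + 1e-12


class TestSampleInterval:
    def test_zero_scores_no_noise_gives_baseline(self):
        weeks = sample_interval({"Trunk": 0.0}, IntervalModel(sigma=0.0), np.random.default_rng(0))
        assert weeks == 64.0

    def test_monotone_non_increasing_in_scores(self):
        model = IntervalModel(sigma=0.0)
        lo = sample_interval({"ShoulderR": 0.5}, model, np.random.default_rng(0))
        hi = sample_interval({"ShoulderR": 2.5}, model, np.random.default_rng(0))
        assert hi <= lo

    def test_floor_at_min_interval(self):
        model = IntervalModel(beta0=2.0, sigma=0.0, min_interval=1.0)
        assert sample_interval({"ShoulderR": 2.5}, model, np.random.default_rng(0)) == 1.0

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            sample_interval({"Trunk": -1.0}, IntervalModel(), np.random.default_rng(0))

    def test_zero_severity_cohort_mean_near_baseline(self):
        rng = np.random.default_rng(7)
        model = IntervalModel()
        draws = [sample_interval({}, model, rng) for _ in range(400)]
        se = model.sigma / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 64.0) < 4 * se


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(GeneratorConfig(n_workers=0)) == []

    def test_seeded_determinism_byte_identical(self):
        bufs = []
        for _ in range(2):
            corpus = generate_cohort(GeneratorConfig(n_workers=40, seed=3))
            buf = io.StringIO()
            for a in corpus:
                buf.write(json.dumps(a.__dict__, ensure_ascii=False) + "\n")
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_female_fraction_within_binomial_ci(self):
        corpus = generate_cohort(GeneratorConfig(n_workers=638, seed=1))
        genders = {a.worker_id: a.gender for a in corpus}
        p_hat = sum(g == "F" for g in genders.values()) / len(genders)
        half = 1.96 * np.sqrt(0.233 * 0.767 / 638)
        assert abs(p_hat - 0.233) < half

    def test_no_worker_has_eight_appointments(self, clean_cohort):
        _, corpus = clean_cohort
        counts = collections.Counter(collections.Counter(a.worker_id for a in corpus).values())
        assert counts.get(8, 0) == 0
        # histogram decays: single visits dominate
        assert counts[1] > counts[2] > counts[3]

    def test_timelines_ordered_with_interval_targets(self, clean_cohort):
        _, corpus = clean_cohort
        by_worker = collections.defaultdict(list)
        for a in corpus:
            by_worker[a.worker_id].append(a)
        for appts in by_worker.values():
            dates = [a.date for a in appts]
            assert dates == sorted(dates)
            assert appts[-1].true_interval_weeks is None
            for a in appts[:-1]:
                assert a.true_interval_weeks >= 1.0

    def test_scores_within_published_envelope(self, clean_cohort):
        _, corpus = clean_cohort
        positive = [v for a in corpus for v in a.true_scores.values() if v > 0]
        assert min(positive) >= 0.19 and max(positive) <= 5.33

    def test_jsonl_round_trip(self, tmp_path, clean_cohort):
        from ohpp.synthetic import corpus_from_jsonl

        _, corpus = clean_cohort
        path = tmp_path / "corpus.jsonl"
        corpus_to_jsonl(corpus[:50], path)
        back = corpus_from_jsonl(path)
        assert [a.true_scores for a in back] == [a.true_scores for a in corpus[:50]]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "override, field",
        [
            ({"p_female": 1.5}, "p_female"),
            ({"noise": NoiseParams(p_misspell_token=-0.1)}, "p_misspell_token"),
            ({"area_weights": {"Assembly": 0.5}}, "area_weights"),
            ({"appointment_count_dist": {1: 0.5, 8: 0.5}}, "k=8"),
            ({"interval_model": IntervalModel(beta0=-1)}, "beta0"),
            ({"interval_model": IntervalModel(min_interval=0.5)}, "min_interval"),
            ({"language": "de"}, "language"),
        ],
    )
    def test_invalid_config_names_field(self, override, field):
        import dataclasses

        cfg = dataclasses.replace(GeneratorConfig(), **override)
        with pytest.raises(ConfigError, match=field.replace("=", "=")):
            cfg.validate()

    def test_yaml_config_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_workers: 12\nseed: 9\np_female: 0.3\nnoise:\n  p_misspell_token: 0.05\n",
            encoding="utf-8",
        )
        cfg = load_config(path)
        assert cfg.n_workers == 12 and cfg.seed == 9
        assert cfg.noise.p_misspell_token == 0.05

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_wrokers: 12\n", encoding="utf-8")
        with pytest.raises(ConfigError, match="n_wrokers"):
            load_config(path)
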