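"""Normalization and rule-based protection extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohpp.bodyparts import FLAG_COLUMNS, PART_NAMES, ProtectionLevel
from ohpp.extraction import (
    EmptySentenceError,
    build_profile,
    extract_protections,
    normalize_sentence,
    profiles_to_frame,
)
from ohpp.synthetic import GeneratorConfig, NoiseParams, generate_cohort


class TestNormalize:
    def test_case_space_symbol_collapse(self):
        assert normalize_sentence("MUST   not perform tasks!!") == "must not perform tasks"

    def test_preserves_diacritics(self):
        assert normalize_sentence("Não pode executar tarefas") == "não pode executar tarefas"

    @pytest.mark.parametrize("bad", ["", "   ", "\t\n", "!!!"])
    def test_empty_inputs_rejected(self, bad):
        with pytest.raises(EmptySentenceError):
            normalize_sentence(bad)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet=st.characters(codec="utf-8", exclude_categories=("C",)), min_size=1))
    def test_idempotent(self, raw):
        try:
            once = normalize_sentence(raw)
        except EmptySentenceError:
            return
        assert normalize_sentence(once) == once


def _pairs(fragments):
    return {(p.name, f.level.value) for f in fragments for p in f.parts}


class TestExtract:
    @pytest.mark.parametrize(
        "sentence, expected",
        [
            (
                "Must not perform tasks that involve movements above both shoulders.",
                {("ShoulderL", "MN"), ("ShoulderR", "MN")},
            ),
            (
                "Should not perform tasks that involve movements of the right elbow.",
                {("ElbowR", "SN")},
            ),
            (
                "Must not perform tasks that involve movements of the left wrist and left fingers.",
                {("WristL", "MN"), ("FingersL", "MN")},
            ),
            (
                "Should not perform tasks that involve performing left and right wrist rotation movements.",
                {("WristL", "SN"), ("WristR", "SN")},
            ),
            (
                "Must not perform tasks that require force with fingers of both hands.",
                {("FingersL", "MN"), ("FingersR", "MN")},
            ),
            # Portuguese: laterality follows the noun
            (
                "Não pode executar tarefas que envolvam movimentos acima do ombro esquerdo.",
                {("ShoulderL", "MN")},
            ),
            (
                "Não deve executar tarefas que envolvam movimentos de flexão/rotação do tronco.",
                {("Trunk", "SN")},
            ),
        ],
    )
    def test_known_sentences(self, sentence, expected, lexicon):
        frags = extract_protections(normalize_sentence(sentence), lexicon)
        assert _pairs(frags) == expected
        assert not any(f.unparsed for f in frags)

    def test_process_only_yields_no_parts(self, lexicon):
        s = "Must not perform tasks that imply performing tasks using tools with associated vibration"
        frags = extract_protections(normalize_sentence(s), lexicon)
        assert len(frags) == 1
        assert frags[0].process_only and frags[0].parts == [] and not frags[0].unparsed
        assert frags[0].level is ProtectionLevel.MN

    def test_cue_at_sentence_end(self, lexicon):
        s = "Perform tasks that involve movements of the right elbow should not."
        frags = extract_protections(normalize_sentence(s), lexicon)
        assert _pairs(frags) == {("ElbowR", "SN")}

    def test_misspelled_long_tokens_still_match(self, lexicon):
        s = "Must not perform tasks that involve movements above both sholders."
        frags = extract_protections(normalize_sentence(s), lexicon)
        assert _pairs(frags) == {("ShoulderL", "MN"), ("ShoulderR", "MN")}

    def test_level_without_content_flagged_unparsed(self, lexicon):
        frags = extract_protections(normalize_sentence("Must not do the zorgon thing"), lexicon)
        assert len(frags) == 1 and frags[0].unparsed and frags[0].parts == []

    def test_no_cue_flagged_unparsed(self, lexicon):
        frags = extract_protections(normalize_sentence("movements of the right elbow"), lexicon)
        assert all(f.unparsed for f in frags)


class TestBuildProfile:
    def test_structured_example_row1(self, lexicon):
        sentences = [
            "Should not perform tasks that involve movements of the right elbow.",
            "Must not perform tasks that involve movements above both shoulders.",
        ]
        p = build_profile(sentences, lexicon)
        on = {k for k, v in p.flags.items() if v}
        assert on == {"ShoulderL_MN", "ShoulderR_MN", "ElbowR_SN"}

    def test_structured_example_row2(self, lexicon):
        sentences = [
            "Must not perform tasks that involve movements of the left wrist and left fingers.",
            "Must not perform tasks that require force with fingers of both hands.",
        ]
        p = build_profile(sentences, lexicon)
        on = {k for k, v in p.flags.items() if v}
        assert on == {"WristL_MN", "FingersL_MN", "FingersR_MN"}

    def test_process_only_profile_all_zero(self, lexicon):
        p = build_profile(
            ["Should not perform tasks that involve manual material handling."], lexicon
        )
        assert sum(p.flags.values()) == 0 and not p.unparsed

    def test_mn_wins_over_sn_for_same_part(self, lexicon):
        sentences = [
            "Should not perform tasks that involve movements of the right elbow.",
            "Must not perform tasks that involve movements of the right elbow.",
        ]
        p = build_profile(sentences, lexicon)
        assert p.flags["ElbowR_MN"] == 1 and p.flags["ElbowR_SN"] == 0

    def test_schema_fixed_and_round_trips(self, lexicon, tmp_path):
        p = build_profile(["Must not perform tasks that involve movements above both shoulders."], lexicon)
        frame = profiles_to_frame([p])
        assert list(frame.columns[-28:]) == list(FLAG_COLUMNS)
        path = tmp_path / "profiles.csv"
        frame.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert (back[list(FLAG_COLUMNS)].to_numpy() == frame[list(FLAG_COLUMNS)].to_numpy()).all()


class TestRoundTrip:
    def test_noise_free_corpus_recovers_ground_truth(self, clean_cohort, lexicon):
        """Extraction on clean rendered text reproduces the generator's truth
        with precision = recall = 1."""
        _, corpus = clean_cohort
        for a in corpus:
            p = build_profile(a.sentences, lexicon)
            got = {(part.name, fr.level.value) for frs in p.sentence_fragments for fr in frs for part in fr.parts}
            want = {(pn, lvl) for lvl, parts in a.true_protections for pn in parts}
            assert got == want
            assert not p.unparsed

    def test_f1_degrades_smoothly_with_misspelling_rate(self, lexicon):
        """Raising the token-misspelling rate from 0 to 0.1 lowers extraction
        F1 gradually — fuzzy matching leaves no cliff."""
        f1s = []
        for p_mis in (0.0, 0.03, 0.06, 0.1):
            cfg = GeneratorConfig(
                n_workers=120, seed=23, noise=NoiseParams(0, p_mis, 0, 0, 0)
            )
            corpus = generate_cohort(cfg)
            tp = fp = fn = 0
            for a in corpus:
                prof = build_profile(a.sentences, lexicon)
                got = {
                    (part.name, fr.level.value)
                    for frs in prof.sentence_fragments
                    for fr in frs
                    for part in fr.parts
                }
                want = {(pn, lvl) for lvl, parts in a.true_protections for pn in parts}
                tp += len(got & want)
                fp += len(got - want)
                fn += len(want - got)
            f1s.append(2 * tp / (2 * tp + fp + fn))
        assert f1s[0] == 1.0
        assert f1s[-1] >= 0.80
        drops = [a - b for a, b in zip(f1s, f1s[1:])]
        assert all(d <= 0.10 for d in drops), f"cliff in F1 sequence {f1s}"
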