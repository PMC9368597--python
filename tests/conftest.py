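import numpy as np
import pytest

from ohpp.extraction import Lexicon, build_profile
from ohpp.features import assemble_features, split_by_worker
from ohpp.scoring import score_profile, scores_to_frame
from ohpp.synthetic import GeneratorConfig, NoiseParams, generate_cohort


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def worked_example_sentences():
    """The five-restriction appointment used as the scoring worked example."""
    return [
        "Must not perform tasks that involve movements above both shoulder line",
        "Should not perform tasks that involve performing flexion/rotation movements of the trunk",
        "Must not perform tasks that imply performing tasks using tools with associated vibration",
        "Should not perform tasks that involve performing left and right wrist rotation movements",
        "Must not perform tasks that involve performing tasks that require force with application "
        "point on the fingers of both hands",
    ]


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free synthetic cohort: text and ground truth must round-trip."""
    cfg = GeneratorConfig(n_workers=250, seed=11, noise=NoiseParams(0, 0, 0, 0, 0))
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def feature_table(clean_cohort, lexicon):
    """Scored + assembled feature table from the clean cohort."""
    _, corpus = clean_cohort
    scored = [score_profile(build_profile(a.sentences, lexicon, metadata=a.__dict__)) for a in corpus]
    return assemble_features(scores_to_frame(scored))


@pytest.fixture(scope="session")
def split_plan(feature_table):
    return split_by_worker(feature_table, test_fraction=0.2, seed=5, k_folds=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
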