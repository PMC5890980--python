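import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from content_ehr.corpus import Corpus, PatientRecord, Visit, Vocabulary, split_corpus
from content_ehr.simulate import SimConfig, generate_de_novo


@pytest.fixture
def tiny_vocab() -> Vocabulary:
    return Vocabulary(("A", "B", "C", "D", "E"))


@pytest.fixture
def tiny_corpus(tiny_vocab) -> Corpus:
    """3 patients, 7 visits, 15 code occurrences (hand-countable)."""
    records = (
        PatientRecord(
            "p1",
            (Visit((0,), label=1), Visit((0, 1), label=0)),
            (True, True),
        ),
        PatientRecord(
            "p2",
            (Visit((1, 2, 3), label=0), Visit((0, 2), label=1), Visit((4,), label=0)),
            (True, True, True),
        ),
        PatientRecord(
            "p3",
            (Visit((0, 1, 2, 3), label=1), Visit((3, 4), label=0)),
            (True, True),
        ),
    )
    return Corpus(tiny_vocab, records)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated corpus with splits, for fit/predict/embedding tests."""
    config = SimConfig(
        n_patients=60, vocab_size=30, n_topics=4, mean_visits=8.0,
        mean_codes_per_visit=2.5, seed=11,
    )
    corpus, truth = generate_de_novo(config)
    return split_corpus(corpus, (40, 10, 10), seed=12), truth


def random_record(rng: np.random.Generator, n_codes: int, n_visits: int,
                  all_masked: bool = False) -> PatientRecord:
    visits, mask = [], []
    for t in range(n_visits):
        codes = tuple(
            rng.choice(n_codes, size=rng.integers(1, min(4, n_codes) + 1),
                       replace=False)
        )
        masked = True if (all_masked or t == 0) else bool(rng.random() < 0.8)
        label = int(rng.random() < 0.5) if masked else None
        visits.append(Visit(codes, label=label))
        mask.append(masked)
    return PatientRecord("r", tuple(visits), tuple(mask))
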