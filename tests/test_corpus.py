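import numpy as np
import pytest
from hypothesis import given, strategies as st

from content_ehr.corpus import (
    Corpus,
    CorpusFormatError,
    PatientRecord,
    Visit,
    Vocabulary,
    build_labels,
    corpus_stats,
    read_corpus,
    split_corpus,
    write_corpus,
)


# ---------------------------------------------------------------------------
# serialization


@pytest.mark.parametrize("dialect", ["jsonl", "flat"])
def test_round_trip_identity(tiny_corpus, dialect, tmp_path):
    path = tmp_path / f"corpus.{dialect}"
    write_corpus(tiny_corpus, path, dialect)
    back = read_corpus(path, dialect)
    assert back.vocabulary.codes == tiny_corpus.vocabulary.codes
    assert back.records == tiny_corpus.records


def test_read_builds_vocabulary_in_first_appearance_order(tmp_path):
    path = tmp_path / "c.jsonl"
    path.write_text(
        '{"pid":"p","visits":[{"t":null,"loc":null,"codes":["A"],"label":null},'
        '{"t":null,"loc":null,"codes":["A","B"],"label":null}]}\n'
    )
    corpus = read_corpus(path)
    assert corpus.vocabulary.codes == ("A", "B")
    rec = corpus.records[0]
    assert rec.n_visits == 2
    assert [v.n_codes for v in rec.visits] == [1, 2]


def test_empty_corpus_round_trip(tiny_vocab, tmp_path):
    path = tmp_path / "empty.jsonl"
    write_corpus(Corpus(tiny_vocab, ()), path)
    assert read_corpus(path).records == ()


def test_repeated_writes_are_byte_identical(tmp_path):
    rng = np.random.default_rng(3)
    vocab = Vocabulary(tuple(f"C{i}" for i in range(20)))
    records = []
    for i in range(100):
        visits = tuple(
            Visit(tuple(rng.choice(20, size=rng.integers(1, 5), replace=False)),
                  time=int(t * 10), label=int(rng.random() < 0.5))
            for t in range(rng.integers(1, 6))
        )
        records.append(PatientRecord(f"p{i}", visits, (True,) * len(visits)))
    corpus = Corpus(vocab, tuple(records))
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_corpus(corpus, p1)
    write_corpus(corpus, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.jsonl"
    path.write_text('{"pid":"ok","visits":[]}\nnot json at all\n')
    with pytest.raises(CorpusFormatError, match=":2"):
        read_corpus(path)


def test_unknown_code_with_fixed_vocabulary_names_the_code(tmp_path, tiny_vocab):
    path = tmp_path / "c.flat"
    path.write_text("p1\t1,A ZZZ\n")
    with pytest.raises(CorpusFormatError, match="ZZZ"):
        read_corpus(path, "flat", vocabulary=tiny_vocab)


def test_flat_dialect_unlabeled_marker(tmp_path):
    path = tmp_path / "c.flat"
    path.write_text("p1\t-,A B;1,B\n")
    rec = read_corpus(path, "flat").records[0]
    assert rec.visits[0].label is None
    assert rec.label_mask == (False, True)


# ---------------------------------------------------------------------------
# label construction


def _ip(day, dur=0):
    return dict(time=day, location="inpatient", duration_days=dur)


def test_single_inpatient_visit_is_negative():
    rec = PatientRecord("p", (Visit((0,), **_ip(0)),), (False,))
    out = build_labels(rec)
    assert out.visits[0].label == 0
    assert out.label_mask == (True,)


def test_readmission_window_right_endpoint_is_closed():
    # discharge day 10; next admission day 40 is exactly 30 days later -> positive
    rec = PatientRecord(
        "p", (Visit((0,), **_ip(0, dur=10)), Visit((1,), **_ip(40))), (False, False)
    )
    assert build_labels(rec).visits[0].label == 1
    # admission day 41 -> negative
    rec2 = PatientRecord(
        "p", (Visit((0,), **_ip(0, dur=10)), Visit((1,), **_ip(41))), (False, False)
    )
    assert build_labels(rec2).visits[0].label == 0


def test_non_inpatient_visits_are_masked_out_and_inert():
    with_out = PatientRecord(
        "p",
        (
            Visit((0,), **_ip(0)),
            Visit((1,), time=5, location="outpatient"),
            Visit((2,), **_ip(20)),
        ),
        (False,) * 3,
    )
    without = PatientRecord(
        "p", (Visit((0,), **_ip(0)), Visit((2,), **_ip(20))), (False,) * 2
    )
    a = build_labels(with_out)
    b = build_labels(without)
    assert a.label_mask == (True, False, True)
    assert a.visits[0].label == b.visits[0].label == 1
    assert a.visits[2].label == b.visits[1].label == 0
    assert a.visits[1].label is None


def test_build_labels_requires_timestamps():
    rec = PatientRecord("p", (Visit((0,), location="inpatient"),), (False,))
    with pytest.raises(ValueError, match="timestamp"):
        build_labels(rec)


# ---------------------------------------------------------------------------
# splitting


def test_split_cardinalities_and_determinism(small_sim):
    corpus, _ = small_sim
    base = Corpus(corpus.vocabulary, corpus.records)
    for seed in (0, 1, 99):
        out = split_corpus(base, (40, 10, 10), seed)
        tags = list(out.split)
        assert tags.count("train") == 40
        assert tags.count("validation") == 10
        assert tags.count("test") == 10
    a = split_corpus(base, (30, 20, 5), 7)
    b = split_corpus(base, (30, 20, 5), 7)
    assert a.split == b.split
    assert a.split.count(None) == 5  # unassigned remainder


def test_split_all_train(tiny_corpus):
    out = split_corpus(tiny_corpus, (3, 0, 0), 0)
    assert set(out.split) == {"train"}


def test_split_oversized_errors(tiny_corpus):
    with pytest.raises(ValueError, match="split sizes"):
        split_corpus(tiny_corpus, (3, 1, 0), 0)


@given(st.integers(0, 2**31 - 1))
def test_split_partitions_are_disjoint_and_exhaustive(seed):
    vocab = Vocabulary(("A",))
    records = tuple(
        PatientRecord(f"p{i}", (Visit((0,), label=0),), (True,)) for i in range(17)
    )
    out = split_corpus(Corpus(vocab, records), (9, 5, 3), seed)
    assert sorted(out.split) == sorted(["train"] * 9 + ["validation"] * 5 + ["test"] * 3)


# ---------------------------------------------------------------------------
# statistics


def test_stats_hand_count(tiny_corpus):
    s = corpus_stats(tiny_corpus)
    assert (s.n_patients, s.n_visits, s.n_events) == (3, 7, 15)
    assert s.avg_visits_per_patient == pytest.approx(7 / 3)
    assert s.avg_events_per_patient == pytest.approx(5.0)
    assert s.n_unique_codes == 5


def test_stats_one_patient():
    vocab = Vocabulary(("A", "B"))
    corpus = Corpus(
        vocab,
        (PatientRecord("p", (Visit((0,)), Visit((0, 1))), (False, False)),),
    )
    s = corpus_stats(corpus)
    assert (s.n_patients, s.n_visits, s.n_events) == (1, 2, 3)
    assert s.avg_visits_per_patient == 2.0
    assert s.avg_events_per_patient == 3.0
    assert s.n_unique_codes == 2


def test_stats_empty_corpus_errors(tiny_vocab):
    with pytest.raises(ValueError, match="empty"):
        corpus_stats(Corpus(tiny_vocab, ()))


@given(st.integers(0, 10_000))
def test_stats_arithmetic_invariants_on_random_corpora(seed):
    rng = np.random.default_rng(seed)
    C = int(rng.integers(2, 10))
    vocab = Vocabulary(tuple(f"C{i}" for i in range(C)))
    records = []
    for i in range(int(rng.integers(1, 6))):
        visits = tuple(
            Visit(tuple(rng.choice(C, size=rng.integers(1, C + 1), replace=False)))
            for _ in range(rng.integers(1, 5))
        )
        records.append(PatientRecord(f"p{i}", visits, (False,) * len(visits)))
    s = corpus_stats(Corpus(vocab, tuple(records)))
    assert s.avg_visits_per_patient == pytest.approx(s.n_visits / s.n_patients)
    assert s.avg_events_per_patient == pytest.approx(s.n_events / s.n_patients)
    assert s.n_unique_codes <= vocab.size
    assert s.n_events >= s.n_visits  # every visit has >= 1 code here
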