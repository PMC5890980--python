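"""Longitudinal EHR visit-sequence data model and serialization.

A patient record is an ordered sequence of visits; each visit is a *set* of
medical event codes (diagnoses, labs, medications) drawn from a fixed
vocabulary, optionally timestamped (integer days from the first visit) and
located (inpatient / outpatient / other).  The supervised target is a per-visit
binary 30-day readmission label; a per-visit mask says which visits carry a
supervised label (only inpatient discharges, when labels are built from
timestamps).

Two plain-text dialects are supported:

``jsonl``
    one patient per line:
    ``{"pid": str, "visits": [{"t": int|null, "loc": str|null,
    "codes": [str], "label": 0|1|null}]}``.
``flat``
    one patient per line: ``pid<TAB>visit;visit;...`` where each visit is
    ``label,code code code`` and the label may be ``-`` for unlabeled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Vocabulary",
    "Visit",
    "PatientRecord",
    "Corpus",
    "CorpusStats",
    "read_corpus",
    "write_corpus",
    "build_labels",
    "split_corpus",
    "corpus_stats",
]


class CorpusFormatError(ValueError):
    """Raised when an input file does not conform to its dialect."""


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional code <-> index map fixing the input dimension C."""

    codes: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {c: i for i, c in enumerate(self.codes)}
        if len(index) != len(self.codes):
            raise ValueError("vocabulary contains duplicate codes")
        object.__setattr__(self, "_index", index)

    @property
    def size(self) -> int:
        return len(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def lookup(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"code {code!r} not in vocabulary") from None

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def hash(self) -> str:
        """SHA-256 over the ordered code list; used to pair checkpoints with corpora."""
        return hashlib.sha256("\n".join(self.codes).encode()).hexdigest()


@dataclass(frozen=True)
class Visit:
    """One healthcare encounter: a set of code indices, kept as a sorted tuple."""

    codes: tuple[int, ...]
    time: int | None = None
    location: str | None = None
    label: int | None = None
    duration_days: int = 0

    def __post_init__(self) -> None:
        codes = tuple(sorted(set(int(c) for c in self.codes)))
        object.__setattr__(self, "codes", codes)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.duration_days < 0:
            raise ValueError("duration_days must be non-negative")

    @property
    def n_codes(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    visits: tuple[Visit, ...]
    label_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "visits", tuple(self.visits))
        object.__setattr__(self, "label_mask", tuple(bool(m) for m in self.label_mask))
        if len(self.visits) < 1:
            raise ValueError(f"patient {self.patient_id}: needs at least one visit")
        if len(self.label_mask) != len(self.visits):
            raise ValueError(f"patient {self.patient_id}: mask length != visit count")
        times = [v.time for v in self.visits if v.time is not None]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"patient {self.patient_id}: times must be non-decreasing")
        for v, m in zip(self.visits, self.label_mask):
            if m and v.label is None:
                raise ValueError(
                    f"patient {self.patient_id}: masked-in visit has no label"
                )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class Corpus:
    vocabulary: Vocabulary
    records: tuple[PatientRecord, ...]
    split: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.split is not None:
            object.__setattr__(self, "split", tuple(self.split))
            if len(self.split) != len(self.records):
                raise ValueError("split tags must align with records")
        C = self.vocabulary.size
        for rec in self.records:
            for v in rec.visits:
                if v.codes and (v.codes[0] < 0 or v.codes[-1] >= C):
                    raise ValueError(
                        f"patient {rec.patient_id}: code index out of range [0, {C})"
                    )

    def subset(self, tag: str) -> tuple[PatientRecord, ...]:
        """Records carrying the given split tag."""
        if self.split is None:
            raise ValueError("corpus has no split tags; call split_corpus first")
        return tuple(r for r, t in zip(self.records, self.split) if t == tag)


@dataclass(frozen=True)
class CorpusStats:
    n_patients: int
    n_visits: int
    n_events: int
    avg_visits_per_patient: float
    avg_events_per_patient: float
    n_unique_codes: int


# ---------------------------------------------------------------------------
# serialization


def _visit_to_json(visit: Visit, vocab: Vocabulary) -> dict:
    d: dict = {
        "t": visit.time,
        "loc": visit.location,
        "codes": [vocab.codes[i] for i in visit.codes],
        "label": visit.label,
    }
    if visit.duration_days:
        d["dur"] = visit.duration_days
    return d


def read_vocabulary(path: str | Path) -> Vocabulary:
    """Read an explicit vocabulary file: one code per line, line order = index."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return Vocabulary(tuple(line.strip() for line in lines if line.strip()))


def read_corpus(
    path: str | Path,
    dialect: str = "jsonl",
    vocabulary: Vocabulary | None = None,
) -> Corpus:
    """Read a corpus file.

    When ``vocabulary`` is omitted it is built from all codes in order of first
    appearance; with an explicit vocabulary an unseen code is an error.
    """
    path = Path(path)
    if dialect == "jsonl":
        raw = _read_jsonl(path)
    elif dialect == "flat":
        raw = _read_flat(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if vocabulary is None:
        seen: dict[str, int] = {}
        for _, visits, _ in raw:
            for _, _, codes, _, _ in visits:
                for c in codes:
                    if c not in seen:
                        seen[c] = len(seen)
        vocabulary = Vocabulary(tuple(seen))

    records = []
    splits = []
    any_split = False
    for pid, visits, split_tag in raw:
        vs = []
        mask = []
        for t, loc, codes, label, dur in visits:
            try:
                idx = tuple(vocabulary.lookup(c) for c in codes)
            except KeyError as e:
                raise CorpusFormatError(f"patient {pid}: {e.args[0]}") from None
            vs.append(Visit(idx, time=t, location=loc, label=label, duration_days=dur))
            mask.append(label is not None)
        records.append(PatientRecord(pid, tuple(vs), tuple(mask)))
        splits.append(split_tag)
        any_split = any_split or split_tag is not None
    return Corpus(vocabulary, tuple(records), tuple(splits) if any_split else None)


def _read_jsonl(path: Path):
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                pid = obj["pid"]
                visits = [
                    (
                        v.get("t"),
                        v.get("loc"),
                        list(v["codes"]),
                        v.get("label"),
                        int(v.get("dur", 0)),
                    )
                    for v in obj["visits"]
                ]
            except (json.JSONDecodeError, KeyError, TypeError) as e:
                raise CorpusFormatError(f"{path}:{lineno}: malformed line ({e})") from None
            out.append((pid, visits, obj.get("split")))
    return out


def _read_flat(path: Path):
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'pid<TAB>visits', got {len(parts)} fields"
                )
            pid, visits_field = parts
            visits = []
            for vfield in visits_field.split(";"):
                head, _, codes_field = vfield.partition(",")
                if not _:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: visit {vfield!r} lacks 'label,codes'"
                    )
                if head == "-":
                    label = None
                elif head in ("0", "1"):
                    label = int(head)
                else:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: bad label {head!r} (expected 0, 1 or -)"
                    )
                codes = [c for c in codes_field.split(" ") if c]
                visits.append((None, None, codes, label, 0))
            out.append((pid, visits, None))
    return out


def write_corpus(corpus: Corpus, path: str | Path, dialect: str = "jsonl") -> None:
    """Write a corpus; the output is byte-stable and readable by :func:`read_corpus`."""
    path = Path(path)
    vocab = corpus.vocabulary
    lines = []
    for i, rec in enumerate(corpus.records):
        if dialect == "jsonl":
            obj: dict = {
                "pid": rec.patient_id,
                "visits": [_visit_to_json(v, vocab) for v in rec.visits],
            }
            if corpus.split is not None and corpus.split[i] is not None:
                obj["split"] = corpus.split[i]
            lines.append(json.dumps(obj, separators=(",", ":"), sort_keys=False))
        elif dialect == "flat":
            vs = []
            for v in rec.visits:
                head = "-" if v.label is None else str(v.label)
                vs.append(head + "," + " ".join(vocab.codes[c] for c in v.codes))
            lines.append(rec.patient_id + "\t" + ";".join(vs))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    Path(path).write_text("\n".join(vocab.codes) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# label construction


def build_labels(
    record: PatientRecord,
    window_days: int = 30,
    inpatient_location: str = "inpatient",
) -> PatientRecord:
    """Construct 30-day readmission labels from timestamps and visit locations.

    An inpatient visit is labeled positive iff another inpatient visit *starts*
    within ``(discharge, discharge + window_days]`` where
    ``discharge = time + duration_days``; the closed right endpoint means a
    readmission exactly ``window_days`` after release counts.  Only inpatient
    visits are supervised (mask true); other visits get mask false and no label.
    """
    if any(v.time is None for v in record.visits):
        raise ValueError(
            f"patient {record.patient_id}: visits lack timestamps; "
            "use a pre-labeled input instead of build_labels"
        )
    inpatient_starts = [
        v.time for v in record.visits if v.location == inpatient_location
    ]
    visits = []
    mask = []
    for v in record.visits:
        if v.location != inpatient_location:
            visits.append(replace(v, label=None))
            mask.append(False)
            continue
        discharge = v.time + v.duration_days
        readmit = any(
            discharge < s <= discharge + window_days for s in inpatient_starts
        )
        visits.append(replace(v, label=int(readmit)))
        mask.append(True)
    return PatientRecord(record.patient_id, tuple(visits), tuple(mask))


# ---------------------------------------------------------------------------
# splitting and statistics


def split_corpus(
    corpus: Corpus, sizes: tuple[int, int, int], seed: int
) -> Corpus:
    """Assign disjoint train/validation/test tags at the patient level."""
    n_train, n_val, n_test = sizes
    total = n_train + n_val + n_test
    if total > len(corpus.records):
        raise ValueError(
            f"requested split sizes sum to {total} but corpus has "
            f"{len(corpus.records)} records"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus.records))
    tags: list[str | None] = [None] * len(corpus.records)
    for pos, idx in enumerate(order):
        if pos < n_train:
            tags[idx] = "train"
        elif pos < n_train + n_val:
            tags[idx] = "validation"
        elif pos < total:
            tags[idx] = "test"
    return Corpus(corpus.vocabulary, corpus.records, tuple(tags))


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Descriptive statistics: patients, visits, events, per-patient averages."""
    n_patients = len(corpus.records)
    if n_patients == 0:
        raise ValueError("empty corpus: averages undefined")
    n_visits = sum(r.n_visits for r in corpus.records)
    n_events = sum(v.n_codes for r in corpus.records for v in r.visits)
    unique: set[int] = set()
    for r in corpus.records:
        for v in r.visits:
            unique.update(v.codes)
    return CorpusStats(
        n_patients=n_patients,
        n_visits=n_visits,
        n_events=n_events,
        avg_visits_per_patient=n_visits / n_patients,
        avg_events_per_patient=n_events / n_patients,
        n_unique_codes=len(unique),
    )
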