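"""Synthetic EHR generation.

Two generators:

``subsample_combine``
    the benchmark-style procedure applied to an existing corpus: per record
    keep a random 30-50% of visits (order preserved), permute records, pair
    them, align the second member's event times to the first, and merge the
    two visit streams into one synthetic patient.  Halves the record count.

``generate_de_novo``
    a fully generative simulator with known ground truth, emulating the scale
    of a real claims cohort (hundreds of codes, ~80 visits and ~230 events per
    patient).  Each patient draws a context vector theta* ~ N(0, I_K); visits
    draw codes from a mixture of sparse topic-code distributions weighted by
    softmax(theta*).  Readmission risk combines a *global* component (a fixed
    linear functional of theta*) and a *local* component (a damped random walk
    driven by the "acute" codes in recent visits):

        p*_t = sigmoid(bias + gw * <w_g, theta*> + lw * s_t),
        s_t  = damping * s_{t-1} + (acute_t - E[acute]).

    Because both components are functions of the generated codes/context, a
    model can in principle recover them; the stored p*_t give the Bayes
    ROC-AUC, an upper bound on any model's test performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, PatientRecord, Visit, Vocabulary

__all__ = ["SimConfig", "GroundTruth", "subsample_combine", "generate_de_novo"]


@dataclass
class SimConfig:
    """De novo simulator configuration.

    Defaults emulate the scale of the benchmark synthetic cohort: a 618-code
    vocabulary, ~80 visits and ~2.9 events per visit per patient.  The risk
    weights set the strength of the patient-level (global) and recent-visit
    (local) components; ``label_bias`` shifts overall prevalence (the default
    -1.0 yields a realistic ~30% visit-level readmission rate under the
    default weights).
    """

    n_patients: int = 3000
    vocab_size: int = 618
    n_topics: int = 10
    mean_visits: float = 80.0
    mean_codes_per_visit: float = 2.86
    global_weight: float = 2.0
    local_weight: float = 1.0
    label_bias: float = -1.0
    acute_fraction: float = 0.1
    local_damping: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "vocab_size", "n_topics"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mean_visits", "mean_codes_per_visit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("global_weight", "local_weight", "label_bias"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 < self.acute_fraction <= 1.0:
            raise ValueError("acute_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """True per-patient context vectors and per-visit readmission probabilities."""

    theta: dict[str, np.ndarray] = field(default_factory=dict)
    probs: dict[str, np.ndarray] = field(default_factory=dict)

    def pooled(self, records) -> tuple[np.ndarray, np.ndarray]:
        """True probabilities and observed labels pooled over the given records."""
        p, y = [], []
        for rec in records:
            p.extend(self.probs[rec.patient_id])
            y.extend(v.label for v in rec.visits)
        return np.array(p), np.array(y)

    def write(self, path: str | Path) -> None:
        lines = ["pid\tvisit\tp_true"]
        for pid in self.probs:
            for t, p in enumerate(self.probs[pid]):
                lines.append(f"{pid}\t{t}\t{p:.10g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _sigmoid(x: float) -> float:
    return 0.5 * (1.0 + math.tanh(0.5 * x))


def generate_de_novo(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    C, K = config.vocab_size, config.n_topics
    vocab = Vocabulary(tuple(f"C{i:04d}" for i in range(C)))

    # sparse positive topic-code matrix, one per simulation, rows normalized;
    # a 2% uniform floor gives every code a base rate so the full vocabulary
    # is reachable, as in real coding systems
    n_active = max(5, C // 5)
    topics = np.zeros((K, C))
    for k in range(K):
        active = rng.choice(C, size=n_active, replace=False)
        topics[k, active] = rng.gamma(1.0, 1.0, size=n_active)
        topics[k] /= topics[k].sum()
        topics[k] = 0.98 * topics[k] + 0.02 / C

    n_acute = max(1, int(round(config.acute_fraction * C)))
    acute = np.zeros(C, dtype=bool)
    acute[rng.choice(C, size=n_acute, replace=False)] = True
    topic_acute_mass = topics @ acute.astype(float)

    # Fixed unit vector defining the global risk axis.  It must be a *contrast*
    # (zero-sum): softmax(theta) is invariant to adding a constant to theta, so
    # any component of theta along the all-ones direction is invisible in the
    # generated codes and a risk loading on it could never be recovered.
    if K > 1:
        w_g = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(K)])
        w_g /= np.linalg.norm(w_g)
    else:
        w_g = np.ones(1)

    records = []
    truth = GroundTruth()
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        theta = rng.standard_normal(K)
        pi = np.exp(theta - theta.max())
        pi /= pi.sum()
        code_dist = pi @ topics
        expected_acute = config.mean_codes_per_visit * float(pi @ topic_acute_mass)
        global_term = config.global_weight * float(w_g @ theta)

        n_visits = max(1, int(rng.poisson(config.mean_visits)))
        s = 0.0
        t_day = 0
        visits = []
        p_true = np.zeros(n_visits)
        for t in range(n_visits):
            m = max(1, int(rng.poisson(config.mean_codes_per_visit)))
            codes = rng.choice(C, size=m, replace=True, p=code_dist)
            code_set = tuple(sorted(set(int(c) for c in codes)))
            a_t = sum(1 for c in code_set if acute[c])
            s = config.local_damping * s + (a_t - expected_acute)
            p = _sigmoid(config.label_bias + global_term + config.local_weight * s)
            p_true[t] = p
            label = int(rng.random() < p)
            visits.append(Visit(code_set, time=t_day, label=label))
            t_day += 1 + int(rng.poisson(13))
        records.append(
            PatientRecord(pid, tuple(visits), tuple([True] * n_visits))
        )
        truth.theta[pid] = theta
        truth.probs[pid] = p_true
    return Corpus(vocab, tuple(records)), truth


def subsample_combine(source: Corpus, seed: int) -> Corpus:
    """Subsample 30-50% of each record's visits, pair shuffled records, and merge.

    The second member of each pair has its times shifted so its first kept
    visit aligns with the first member's first kept visit; the merged stream is
    sorted by time with a stable tie-break favoring the first member.  Labels
    and masks travel with their source visits.  Emits floor(n/2) records.
    """
    if len(source.records) < 2:
        raise ValueError("subsample_combine needs at least 2 source records")
    for rec in source.records:
        if any(v.time is None for v in rec.visits):
            raise ValueError(f"patient {rec.patient_id}: visits lack timestamps")
    rng = np.random.default_rng(seed)

    kept: list[list[tuple[Visit, bool]]] = []
    for rec in source.records:
        u = rng.uniform(0.3, 0.5)
        n_keep = math.ceil(u * rec.n_visits)
        idx = np.sort(rng.choice(rec.n_visits, size=n_keep, replace=False))
        kept.append([(rec.visits[j], rec.label_mask[j]) for j in idx])

    order = rng.permutation(len(kept))
    records = []
    for i in range(len(order) // 2):
        first = kept[order[2 * i]]
        second = kept[order[2 * i + 1]]
        offset = first[0][0].time - second[0][0].time
        stream = [(v.time, 0, j, v, m) for j, (v, m) in enumerate(first)]
        stream += [
            (v.time + offset, 1, j, v, m) for j, (v, m) in enumerate(second)
        ]
        stream.sort(key=lambda e: (e[0], e[1], e[2]))
        base = stream[0][0]
        visits = []
        mask = []
        for t_new, tag, _, v, m in stream:
            visits.append(
                Visit(
                    v.codes,
                    time=t_new - base,
                    location=v.location,
                    label=v.label,
                    duration_days=v.duration_days,
                )
            )
            mask.append(m)
        records.append(PatientRecord(f"S{i:05d}", tuple(visits), tuple(mask)))
    return Corpus(source.vocabulary, tuple(records))
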