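"""Patient-level representations and k-means phenotype clustering.

A patient is represented as the concatenation of the posterior-mean context
vector theta (dim N, the global chronic-condition summary) and the final GRU
hidden state h_T (dim D_h, the local recent-history summary).  Clustering
these vectors with k-means yields candidate phenotype subgroups; cluster
summaries report the average readmission count per patient and the top event
codes by within-cluster count, optionally omitting the globally most common
codes so cluster-specific patterns stand out.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .corpus import Corpus
from .recognition import ALL, infer_posterior, patient_counts
from .training import FitResult, _record_counts
from .model import forward

__all__ = [
    "PatientEmbedding",
    "ClusterSummary",
    "embed_patients",
    "cluster_patients",
    "summarize_clusters",
]


@dataclass(frozen=True)
class PatientEmbedding:
    patient_id: str
    vector: np.ndarray  # theta (N) concatenated with h_T (D_h)


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    n_patients: int
    avg_readmissions: float
    top_events: tuple[tuple[str, int], ...]


def embed_patients(corpus: Corpus, fit_result: FitResult) -> list[PatientEmbedding]:
    """theta = posterior mean over the full record; h_T from the forward pass."""
    if fit_result.vocab_hash and corpus.vocabulary.hash() != fit_result.vocab_hash:
        raise ValueError("corpus vocabulary does not match the fitted checkpoint")
    params = fit_result.params
    out = []
    for rec in corpus.records:
        if fit_result.rec_params is not None:
            counts = _record_counts(
                rec, params.n_codes, fit_result.config.scale_counts
            )
            theta = infer_posterior(counts, fit_result.rec_params).mu
        else:
            theta = np.zeros(params.n_topics)
        scores = forward(rec, params, theta)
        out.append(
            PatientEmbedding(rec.patient_id, np.concatenate([theta, scores[-1].hidden]))
        )
    return out


def cluster_patients(
    embeddings: list[PatientEmbedding], k: int = 20, seed: int = 0
) -> np.ndarray:
    """Seeded k-means (squared Euclidean, k-means++ init, 10 restarts)."""
    if len(embeddings) < k:
        raise ValueError(f"need at least k={k} patients, got {len(embeddings)}")
    X = np.stack([e.vector for e in embeddings])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def summarize_clusters(
    corpus: Corpus,
    assignments: np.ndarray,
    exclude_top: int = 3,
    exclude_codes: list[str] | None = None,
    n_top_events: int = 10,
) -> list[ClusterSummary]:
    """Per-cluster size, mean positive-label count, and top event codes.

    ``exclude_top`` removes the globally most frequent codes (cohort-wide
    commonalities) from every ranking; an explicit ``exclude_codes`` list
    overrides the frequency-based choice.
    """
    if len(assignments) != len(corpus.records):
        raise ValueError("assignments must cover every record")
    vocab = corpus.vocabulary
    global_counts: Counter[int] = Counter()
    for rec in corpus.records:
        for v in rec.visits:
            global_counts.update(v.codes)
    if exclude_codes is not None:
        excluded = {vocab.lookup(c) for c in exclude_codes}
    else:
        ranked = sorted(global_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        excluded = {c for c, _ in ranked[:exclude_top]}

    summaries = []
    for cid in sorted(set(int(a) for a in assignments)):
        members = [r for r, a in zip(corpus.records, assignments) if int(a) == cid]
        counts: Counter[int] = Counter()
        readmits = []
        for rec in members:
            n_pos = sum(
                1
                for v, m in zip(rec.visits, rec.label_mask)
                if m and v.label == 1
            )
            readmits.append(n_pos)
            for v in rec.visits:
                counts.update(v.codes)
        top = sorted(
            ((c, n) for c, n in counts.items() if c not in excluded),
            key=lambda kv: (-kv[1], kv[0]),
        )[:n_top_events]
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                n_patients=len(members),
                avg_readmissions=float(np.mean(readmits)),
                top_events=tuple((vocab.codes[c], n) for c, n in top),
            )
        )
    return summaries
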