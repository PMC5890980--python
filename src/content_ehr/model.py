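"""The generative network: visit embedding, GRU recurrence, topic-biased output.

Per patient the model runs a GRU over visit embeddings (local, short-term
context) and adds a per-patient Gaussian context vector theta (global,
long-term context) to every visit's output logit:

    h_t     = GRU(embed(V_{t-1}), h_{t-1})
    logit_t = Q . h_t + q0 + B_t . theta,   B_t = mean_{m in V_t} b_m
    p_t     = sigmoid(logit_t)

where b_m (a row of the C x N topic matrix B) is the latent topic vector of
code m.  The GRU-only ablation drops the B_t . theta term.  All arithmetic is
float64 NumPy; gradients are derived by hand in :mod:`content_ehr.training`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import PatientRecord, Visit

__all__ = [
    "GruWeights",
    "ContentParams",
    "VisitScore",
    "init_content_params",
    "embed_visit",
    "gru_step",
    "topic_bias",
    "forward",
    "gru_baseline_forward",
    "sigmoid",
]


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass
class GruWeights:
    """Gate weights: U_* map the input (H), W_* the previous hidden state (D_h)."""

    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_dim(self) -> int:
        return self.U_z.shape[1]


@dataclass
class ContentParams:
    """All generative-model weights.

    W_v : (C, H) code-embedding matrix; a visit embeds as the sum of its rows.
    gru : GRU gate weights over the (H -> D_h) recurrence.
    Q   : (D_h,) output weight vector with scalar bias q0 (0-d array).
    B   : (C, N) topic matrix; row m is the topic vector b_m of code m.
    """

    W_v: np.ndarray
    gru: GruWeights
    Q: np.ndarray
    q0: np.ndarray
    B: np.ndarray

    @property
    def n_codes(self) -> int:
        return self.W_v.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.W_v.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.Q.shape[0]

    @property
    def n_topics(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class VisitScore:
    logit: float
    probability: float
    hidden: np.ndarray


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    a = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-a, a, size=shape)


def init_content_params(
    n_codes: int,
    embed_dim: int = 100,
    hidden_dim: int = 200,
    n_topics: int = 50,
    rng: np.random.Generator | int | None = None,
) -> ContentParams:
    """Zero-mean uniform initialization scaled by 1/sqrt(fan_in); biases zero.

    The topic matrix B is the exception: its rows are scaled by 1/sqrt(N)
    (the dimension of the bias product B_t . theta) rather than 1/sqrt(C), so
    the context pathway contributes at a usable magnitude from the first
    updates instead of having to grow out of a near-zero saddle.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    C, H, D, N = n_codes, embed_dim, hidden_dim, n_topics
    gru = GruWeights(
        U_z=_uniform(rng, (D, H), H),
        U_r=_uniform(rng, (D, H), H),
        U_h=_uniform(rng, (D, H), H),
        W_z=_uniform(rng, (D, D), D),
        W_r=_uniform(rng, (D, D), D),
        W_h=_uniform(rng, (D, D), D),
        b_z=np.zeros(D),
        b_r=np.zeros(D),
        b_h=np.zeros(D),
    )
    return ContentParams(
        W_v=_uniform(rng, (C, H), C),
        gru=gru,
        Q=_uniform(rng, (D,), D),
        q0=np.zeros(()),
        B=_uniform(rng, (C, N), N),
    )


def zero_content_params(
    n_codes: int, embed_dim: int = 100, hidden_dim: int = 200, n_topics: int = 50
) -> ContentParams:
    C, H, D, N = n_codes, embed_dim, hidden_dim, n_topics
    z = np.zeros
    gru = GruWeights(z((D, H)), z((D, H)), z((D, H)), z((D, D)), z((D, D)), z((D, D)),
                     z(D), z(D), z(D))
    return ContentParams(z((C, H)), gru, z(D), z(()), z((C, N)))


def embed_visit(visit: Visit | tuple[int, ...], W_v: np.ndarray) -> np.ndarray:
    """Sum of the embedding rows of the codes present (W_v^T V_t for binary V_t)."""
    codes = visit.codes if isinstance(visit, Visit) else tuple(visit)
    if not codes:
        return np.zeros(W_v.shape[1])
    return W_v[list(codes)].sum(axis=0)


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, gru: GruWeights) -> np.ndarray:
    """One GRU update:

    z = sigmoid(U_z x + W_z h + b_z)        (update gate)
    r = sigmoid(U_r x + W_r h + b_r)        (reset gate)
    h~ = tanh(U_h x + r * (W_h h) + b_h)    (candidate state)
    h' = z * h + (1 - z) * h~
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))):
        raise ValueError("non-finite input to gru_step")
    z = sigmoid(gru.U_z @ x_t + gru.W_z @ h_prev + gru.b_z)
    r = sigmoid(gru.U_r @ x_t + gru.W_r @ h_prev + gru.b_r)
    h_tilde = np.tanh(gru.U_h @ x_t + r * (gru.W_h @ h_prev) + gru.b_h)
    return z * h_prev + (1.0 - z) * h_tilde


def topic_bias(visit: Visit | tuple[int, ...], B: np.ndarray) -> np.ndarray:
    """Mean of the topic rows b_m over codes in the visit; zero for an empty visit."""
    codes = visit.codes if isinstance(visit, Visit) else tuple(visit)
    if not codes:
        return np.zeros(B.shape[1])
    return B[list(codes)].mean(axis=0)


def _theta_at(theta: np.ndarray, t: int, n_topics: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        return theta
    return theta[t]


def forward(
    record: PatientRecord,
    params: ContentParams,
    theta: np.ndarray,
) -> list[VisitScore]:
    """Score every visit of a record given a context vector.

    ``theta`` is either a single (N,) vector used at every step or a (T, N)
    array of per-step context vectors (causal inference mode).  The input to
    the GRU at step t is the embedding of the *previous* visit, with V_0
    defined as the empty visit, so h_1 = GRU(0, 0) is a bias-driven start state.
    """
    theta = np.asarray(theta, dtype=float)
    N = params.n_topics
    if theta.shape[-1] != N:
        raise ValueError(f"theta has dimension {theta.shape[-1]}, expected {N}")
    if theta.ndim == 2 and theta.shape[0] != record.n_visits:
        raise ValueError("per-step theta must have one row per visit")
    h = np.zeros(params.hidden_dim)
    x = np.zeros(params.embed_dim)  # embedding of the empty visit V_0
    scores = []
    for t, visit in enumerate(record.visits):
        h = gru_step(x, h, params.gru)
        logit = float(params.Q @ h) + float(params.q0) + float(
            topic_bias(visit, params.B) @ _theta_at(theta, t, N)
        )
        scores.append(VisitScore(logit=logit, probability=float(sigmoid(logit)), hidden=h))
        x = embed_visit(visit, params.W_v)
    return scores


def gru_baseline_forward(
    record: PatientRecord, params: ContentParams
) -> list[VisitScore]:
    """GRU-only ablation: logistic regression over the hidden state, no topic bias."""
    return forward(record, params, np.zeros(params.n_topics))
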