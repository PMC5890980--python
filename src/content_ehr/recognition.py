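"""Variational recognition network q(theta | patient).

A two-layer rectified MLP maps a patient's bag-of-events count vector to the
mean and log standard deviation of a diagonal Gaussian posterior over the
N-dimensional context vector theta:

    r1 = ReLU(W_r1 p + b_r1)
    r2 = ReLU(W_r2 r1 + b_r2)
    mu = W_mu r2 + b_mu
    log_sigma = W_sigma r2 + b_sigma
    q(theta | p) = N(mu, diag(exp(log_sigma)^2))

Sampling uses the reparameterization theta = mu + exp(log_sigma) * eps with
eps ~ N(0, I), so gradients flow through mu and log_sigma.  The KL divergence
to the standard-normal prior has the closed form
0.5 * sum(mu^2 + sigma^2 - 1 - 2 log sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import PatientRecord

__all__ = [
    "RecognitionParams",
    "PosteriorGaussian",
    "init_recognition_params",
    "patient_counts",
    "infer_posterior",
    "sample_theta",
    "kl_to_prior",
    "ALL",
]

ALL = None  # sentinel for patient_counts over the whole record


@dataclass
class RecognitionParams:
    W_r1: np.ndarray
    b_r1: np.ndarray
    W_r2: np.ndarray
    b_r2: np.ndarray
    W_mu: np.ndarray
    b_mu: np.ndarray
    W_sigma: np.ndarray
    b_sigma: np.ndarray

    @property
    def n_codes(self) -> int:
        return self.W_r1.shape[1]

    @property
    def n_topics(self) -> int:
        return self.W_mu.shape[0]


@dataclass(frozen=True)
class PosteriorGaussian:
    mu: np.ndarray
    log_sigma: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)


def init_recognition_params(
    n_codes: int,
    n_topics: int = 50,
    hidden1: int = 200,
    hidden2: int = 200,
    rng: np.random.Generator | int | None = None,
    mu_gain: float = 8.0,
    sigma_bias: float = -1.0,
) -> RecognitionParams:
    """Fan-in-scaled uniform initialization, with two anti-collapse choices.

    The mu head is initialized ``mu_gain`` times larger than plain fan-in
    scaling so the posterior means start dispersed across patients at roughly
    the prior's scale — a latent pathway the output layer can latch onto
    immediately, instead of one the KL term prunes before it matures.
    ``sigma_bias`` starts the posterior spread below the prior
    (sigma = exp(-1) ~ 0.37) so early reparameterization noise does not drown
    that signal.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def u(shape, fan_in, gain=1.0):
        a = gain / np.sqrt(max(fan_in, 1))
        return rng.uniform(-a, a, size=shape)

    return RecognitionParams(
        W_r1=u((hidden1, n_codes), n_codes),
        b_r1=np.zeros(hidden1),
        W_r2=u((hidden2, hidden1), hidden1),
        b_r2=np.zeros(hidden2),
        W_mu=u((n_topics, hidden2), hidden2, mu_gain),
        b_mu=np.zeros(n_topics),
        W_sigma=u((n_topics, hidden2), hidden2),
        b_sigma=np.full(n_topics, sigma_bias),
    )


def zero_recognition_params(
    n_codes: int, n_topics: int = 50, hidden1: int = 200, hidden2: int = 200
) -> RecognitionParams:
    z = np.zeros
    return RecognitionParams(
        z((hidden1, n_codes)), z(hidden1), z((hidden2, hidden1)), z(hidden2),
        z((n_topics, hidden2)), z(n_topics), z((n_topics, hidden2)), z(n_topics),
    )


def patient_counts(
    record: PatientRecord, n_codes: int, upto_visit: int | None = ALL
) -> np.ndarray:
    """Bag-of-events count vector.

    With ``upto_visit=ALL`` every visit is counted.  In causal mode
    ``upto_visit=t`` (1-based) counts only visits 1..t-1, i.e. the visits
    strictly before the one being predicted; ``upto_visit=1`` is the empty
    prefix.  Each visit contributes at most 1 per code (codes are sets).
    """
    if upto_visit is ALL:
        included = record.visits
    else:
        if not 1 <= upto_visit <= record.n_visits:
            raise ValueError(
                f"upto_visit must be in [1, {record.n_visits}], got {upto_visit}"
            )
        included = record.visits[: upto_visit - 1]
    counts = np.zeros(n_codes)
    for v in included:
        counts[list(v.codes)] += 1.0
    return counts


def infer_posterior(counts: np.ndarray, params: RecognitionParams) -> PosteriorGaussian:
    counts = np.asarray(counts, dtype=float)
    if not np.all(np.isfinite(counts)):
        raise ValueError("non-finite counts")
    r1 = np.maximum(params.W_r1 @ counts + params.b_r1, 0.0)
    r2 = np.maximum(params.W_r2 @ r1 + params.b_r2, 0.0)
    mu = params.W_mu @ r2 + params.b_mu
    log_sigma = params.W_sigma @ r2 + params.b_sigma
    return PosteriorGaussian(mu=mu, log_sigma=log_sigma)


def sample_theta(
    post: PosteriorGaussian,
    noise: np.ndarray | int | None = None,
) -> np.ndarray:
    """Reparameterized draw theta = mu + sigma * eps.

    ``noise`` may be an explicit eps vector, an integer seed, or None for the
    mean mode (eps = 0, returning mu exactly).
    """
    if noise is None:
        return post.mu.copy()
    if isinstance(noise, (int, np.integer)):
        eps = np.random.default_rng(int(noise)).standard_normal(post.mu.shape)
    else:
        eps = np.asarray(noise, dtype=float)
    return post.mu + np.exp(post.log_sigma) * eps


def kl_to_prior(post: PosteriorGaussian) -> float:
    """Closed-form KL(q || N(0, I)) = 0.5 * sum(mu^2 + sigma^2 - 1 - 2 log sigma)."""
    s2 = np.exp(2.0 * post.log_sigma)
    return float(0.5 * np.sum(post.mu**2 + s2 - 1.0 - 2.0 * post.log_sigma))
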