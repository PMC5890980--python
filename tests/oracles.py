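"""Independent brute-force / scalar oracles used by the test suite.

Everything here is written in plain Python loops over scalars, deliberately
sharing no code with the package implementation.
"""

import math


def sig(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def gru_step_scalar(x, h_prev, U_z, W_z, b_z, U_r, W_r, b_r, U_h, W_h, b_h):
    """Four-equation GRU update evaluated coordinate by coordinate."""
    D = len(h_prev)
    z = [sig(sum(U_z[i][j] * x[j] for j in range(len(x)))
             + sum(W_z[i][j] * h_prev[j] for j in range(D)) + b_z[i])
         for i in range(D)]
    r = [sig(sum(U_r[i][j] * x[j] for j in range(len(x)))
             + sum(W_r[i][j] * h_prev[j] for j in range(D)) + b_r[i])
         for i in range(D)]
    h_tilde = [math.tanh(sum(U_h[i][j] * x[j] for j in range(len(x)))
                         + r[i] * sum(W_h[i][j] * h_prev[j] for j in range(D))
                         + b_h[i])
               for i in range(D)]
    return [z[i] * h_prev[i] + (1 - z[i]) * h_tilde[i] for i in range(D)]


def forward_scalar(visit_codes, W_v, gru_weights, Q, q0, B, theta):
    """Step-by-step logit evaluation for a whole record.

    ``visit_codes`` is a list of code-index tuples; ``gru_weights`` is the
    tuple (U_z, W_z, b_z, U_r, W_r, b_r, U_h, W_h, b_h) as nested lists.
    """
    D = len(Q)
    H = len(W_v[0])
    h = [0.0] * D
    x = [0.0] * H
    logits = []
    for codes in visit_codes:
        h = gru_step_scalar(x, h, *gru_weights)
        bt = [0.0] * len(theta)
        if codes:
            for m in codes:
                for n in range(len(theta)):
                    bt[n] += B[m][n] / len(codes)
        logit = sum(Q[i] * h[i] for i in range(D)) + q0
        logit += sum(bt[n] * theta[n] for n in range(len(theta)))
        logits.append(logit)
        x = [0.0] * H
        for m in codes:
            for j in range(H):
                x[j] += W_v[m][j]
    return logits


def mlp_posterior_scalar(counts, W_r1, b_r1, W_r2, b_r2, W_mu, b_mu, W_s, b_s):
    """Two-ReLU-layer recognition network evaluated with scalar loops."""

    def affine_relu(W, b, v):
        return [max(sum(W[i][j] * v[j] for j in range(len(v))) + b[i], 0.0)
                for i in range(len(b))]

    def affine(W, b, v):
        return [sum(W[i][j] * v[j] for j in range(len(v))) + b[i]
                for i in range(len(b))]

    r1 = affine_relu(W_r1, b_r1, counts)
    r2 = affine_relu(W_r2, b_r2, r1)
    return affine(W_mu, b_mu, r2), affine(W_s, b_s, r2)


def roc_auc_pairs(scores, labels):
    """Mann-Whitney pair counting with ties credited 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_walk(scores, labels):
    """Walk the distinct score thresholds in descending order and accumulate
    precision times recall increment."""
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValueError("at least one positive required")
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for thr in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def accuracy_count(scores, labels, threshold=0.5):
    return sum(
        1 for s, y in zip(scores, labels) if (1 if s >= threshold else 0) == y
    ) / len(scores)
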