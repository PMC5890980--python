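"""Visit-level classification metrics and repeated-run aggregation.

ROC-AUC uses the Mann-Whitney formulation (ties credited 1/2) and PR-AUC the
step-wise average-precision formulation; both delegate to scikit-learn, which
implements exactly these conventions.  ``evaluate_repeated`` re-fits the model
``n_runs`` times with consecutive seeds, micro-pools all supervised visit
predictions across test patients, and reports mean +/- sample standard
deviation per metric — the reporting format used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .corpus import Corpus
from .training import TrainConfig, _pooled_predictions, fit

__all__ = ["EvalReport", "roc_auc", "pr_auc", "accuracy", "evaluate_repeated"]

METRICS = ("pr_auc", "roc_auc", "acc")


def roc_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Average precision: sum over recall increments of precision at each step."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("pr_auc requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of points with (score >= threshold) == label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("accuracy of an empty input is undefined")
    return float(np.mean((scores >= threshold).astype(int) == labels))


@dataclass
class EvalReport:
    """Per-metric mean and sample standard deviation over repeated runs."""

    n_runs: int
    per_run: dict[str, list[float]]

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_run[metric]))

    def std(self, metric: str) -> float:
        vals = self.per_run[metric]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in METRICS:
            row = {"metric": m, "mean": self.mean(m), "std": self.std(m)}
            for i, v in enumerate(self.per_run[m]):
                row[f"run{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return "  ".join(
            f"{m}={self.mean(m):.4f}±{self.std(m):.4f}" for m in METRICS
        )


def evaluate_repeated(
    corpus: Corpus,
    config: TrainConfig,
    n_runs: int = 10,
    base_seed: int = 0,
) -> EvalReport:
    """Fit and evaluate ``n_runs`` times with seeds base_seed..base_seed+n_runs-1.

    The data split is held fixed; only initialization, shuffling, and the
    reparameterization draws vary between runs.
    """
    from dataclasses import replace

    test = corpus.subset("test")
    per_run: dict[str, list[float]] = {m: [] for m in METRICS}
    for i in range(n_runs):
        run_cfg = replace(config, seed=base_seed + i)
        result = fit(corpus, run_cfg)
        scores, labels = _pooled_predictions(
            test, result.params, result.rec_params, run_cfg
        )
        per_run["roc_auc"].append(roc_auc(scores, labels))
        per_run["pr_auc"].append(pr_auc(scores, labels))
        per_run["acc"].append(accuracy(scores, labels))
    return EvalReport(n_runs=n_runs, per_run=per_run)
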