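"""OOD detection metrics.

Conventions: a detector emits one scalar score per image with higher = more
likely OOD.  The positive class is an ID sample being *accepted* (score at or
below the threshold), the negative class is OOD.  FPR@TPR95 is then the
fraction of OOD samples wrongly accepted at the threshold that accepts 95%
of ID samples; random guessing sits at FPR ~ 0.95 and AUROC 0.5.

Fechner correlation — the mean sign-agreement of two variables' deviations
from their means — is used to audit whether two methods' per-challenge
results co-vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ScoreSet", "MetricsRow", "fpr_at_tpr", "accept_threshold", "auroc", "fechner_correlation", "evaluate_challenge"]


@dataclass
class ScoreSet:
    """Paired ID/OOD score lists; higher score = more OOD."""

    id_scores: np.ndarray
    ood_scores: np.ndarray

    def __post_init__(self) -> None:
        self.id_scores = np.asarray(self.id_scores, dtype=np.float64)
        self.ood_scores = np.asarray(self.ood_scores, dtype=np.float64)
        if self.id_scores.size == 0 or self.ood_scores.size == 0:
            raise ValueError("both score lists must be non-empty")
        if not (np.all(np.isfinite(self.id_scores)) and np.all(np.isfinite(self.ood_scores))):
            raise ValueError("scores must be finite")


@dataclass
class MetricsRow:
    fpr_at_95tpr: float
    auroc: float


def accept_threshold(id_scores: np.ndarray, tpr: float = 0.95) -> float:
    """Smallest score value tau with fraction(id_scores <= tau) >= tpr."""
    ids = np.sort(np.asarray(id_scores, dtype=np.float64))
    k = int(np.ceil(tpr * ids.size))
    return float(ids[max(k, 1) - 1])


def fpr_at_tpr(s: ScoreSet, tpr: float = 0.95) -> float:
    """False-positive rate at the given ID true-positive (acceptance) rate.

    Samples scoring exactly tau are accepted, which guarantees ID acceptance
    >= tpr on finite samples.  Lower is better; ~0.95 is random guessing.
    """
    if not 0 < tpr < 1:
        raise ValueError(f"tpr must be in (0, 1), got {tpr}")
    tau = accept_threshold(s.id_scores, tpr)
    return float(np.mean(s.ood_scores <= tau))


def auroc(s: ScoreSet) -> float:
    """Probability a random OOD score exceeds a random ID score, ties counted 1/2."""
    n_id, n_ood = s.id_scores.size, s.ood_scores.size
    ranks = rankdata(np.concatenate([s.id_scores, s.ood_scores]))
    r_ood = float(ranks[n_id:].sum())
    return (r_ood - n_ood * (n_ood + 1) / 2.0) / (n_id * n_ood)


def fechner_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean sign-agreement of deviations from the mean: (1/n) sum sign((a−ā)(b−b̄)).

    Entries where either deviation is exactly zero contribute 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(np.mean(np.sign((a - a.mean()) * (b - b.mean()))))


def evaluate_challenge(id_scores, ood_scores) -> MetricsRow:
    """Both headline metrics from one paired ID/OOD score set."""
    s = ScoreSet(id_scores=id_scores, ood_scores=ood_scores)
    return MetricsRow(fpr_at_95tpr=fpr_at_tpr(s), auroc=auroc(s))
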