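"""Agreement between realized and expected distances.

Final structures are scored with the Pearson correlation coefficient
(PCC) between the realized pairwise distances d and the expected
distances D, and the Spearman correlation coefficient (SCC), i.e. the
Pearson coefficient of the rank-transformed distances (ties receive
average ranks).  Both are computed over the masked pairs only,
consistent with the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distance import DistanceTargets
from .loss import LossSpec, loss_from_positions, pair_distances

__all__ = ["EvaluationRecord", "pearson", "spearman", "evaluate_structure"]


@dataclass(frozen=True)
class EvaluationRecord:
    scc: float
    pcc: float
    n_pairs: int
    loss_name: str
    final_loss: float


def _check_vectors(d, D) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    if d.shape != D.shape or d.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if d.size < 2:
        raise ValueError("need at least 2 paired values for a correlation")
    if np.ptp(d) == 0 or np.ptp(D) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return d, D


def pearson(d, D) -> float:
    """Product-moment correlation of two equal-length vectors."""
    d, D = _check_vectors(d, D)
    return float(stats.pearsonr(d, D).statistic)


def spearman(d, D) -> float:
    """Rank correlation: Pearson applied to average-rank transforms."""
    d, D = _check_vectors(d, D)
    return float(stats.spearmanr(d, D).statistic)


def evaluate_structure(
    positions: np.ndarray, targets: DistanceTargets, spec: LossSpec | None = None
) -> EvaluationRecord:
    """SCC/PCC/loss of an N x 3 coordinate set against its targets."""
    if spec is None:
        spec = LossSpec()
    expected = targets.pair_vector()
    if expected.size < 2:
        raise ValueError("need at least 2 masked pairs to evaluate a structure")
    realized = pair_distances(positions, targets)
    return EvaluationRecord(
        scc=spearman(realized, expected),
        pcc=pearson(realized, expected),
        n_pairs=int(expected.size),
        loss_name=spec.name,
        final_loss=loss_from_positions(positions, targets, spec),
    )
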