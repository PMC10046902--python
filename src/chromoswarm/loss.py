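"""Loss functions scoring a candidate structure against target distances.

Four selectable objectives compare the realized pairwise Euclidean
distances d_ij of a structure with the expected distances D_ij derived
from the contact matrix, over the masked (observed) unordered pairs:

    MSE   = mean((d - D)**2)
    RMSE  = sqrt(MSE)
    SSE   = sum((d - D)**2)
    Huber = mean(h(d - D)),  h(r) = r**2 / 2            if |r| <= alpha
                                    alpha * (|r| - alpha / 2)  otherwise

``ncount`` is the number of masked unordered pairs.  The integer
selector (the ``lf`` option) maps 0 -> RMSE, 1 -> MSE, 2 -> SSE,
3 -> Huber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceTargets

__all__ = ["LOSS_NAMES", "LossSpec", "realized_distances", "pair_distances", "loss_value"]

LOSS_NAMES: tuple[str, ...] = ("RMSE", "MSE", "SSE", "Huber")

#: Huber threshold between the quadratic and linear branches
DEFAULT_ALPHA = 0.5


@dataclass(frozen=True)
class LossSpec:
    """Loss selection: ``selector`` in 0..3 plus the Huber ``alpha``."""

    selector: int = 0
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.selector not in (0, 1, 2, 3):
            raise ValueError(
                f"loss selector must be in [0, 3] "
                f"(0=RMSE, 1=MSE, 2=SSE, 3=Huber), got {self.selector}"
            )
        if self.alpha <= 0:
            raise ValueError(f"Huber alpha must be positive, got {self.alpha}")

    @property
    def name(self) -> str:
        return LOSS_NAMES[self.selector]


def realized_distances(positions: np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix of an N x 3 coordinate set."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError(f"positions must be N x 3, got shape {positions.shape}")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions contain non-finite coordinates")
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def pair_distances(positions: np.ndarray, targets: DistanceTargets) -> np.ndarray:
    """Realized distances of the masked unordered pairs, in the same
    order as :meth:`DistanceTargets.pair_vector`."""
    d = realized_distances(positions)
    iu = np.triu_indices(targets.n_bins, k=1)
    sel = targets.mask[iu]
    return d[iu][sel]


def _residual_loss(residuals: np.ndarray, spec: LossSpec) -> float:
    r2 = residuals * residuals
    if spec.selector == 2:  # SSE
        return float(r2.sum())
    if spec.selector == 3:  # Huber
        a = spec.alpha
        absr = np.abs(residuals)
        h = np.where(absr <= a, 0.5 * r2, a * (absr - 0.5 * a))
        return float(h.mean())
    mse = float(r2.mean())
    return float(np.sqrt(mse)) if spec.selector == 0 else mse


def loss_value(
    realized: np.ndarray, targets: DistanceTargets, spec: LossSpec | None = None
) -> float:
    """Score a realized N x N distance matrix against the targets.

    Only masked unordered pairs contribute.  The result is >= 0 and is
    0 exactly when every masked realized distance equals its target.
    """
    if spec is None:
        spec = LossSpec()
    realized = np.asarray(realized, dtype=float)
    if realized.shape != targets.d_expected.shape:
        raise ValueError(
            f"distance matrix shape {realized.shape} does not match "
            f"targets shape {targets.d_expected.shape}"
        )
    iu = np.triu_indices(targets.n_bins, k=1)
    sel = targets.mask[iu]
    if not sel.any():
        raise ValueError("no comparable pairs: target mask is empty")
    residuals = realized[iu][sel] - targets.d_expected[iu][sel]
    return _residual_loss(residuals, spec)


def loss_from_positions(
    positions: np.ndarray, targets: DistanceTargets, spec: LossSpec | None = None
) -> float:
    """Convenience: loss of an N x 3 coordinate set."""
    return loss_value(realized_distances(positions), targets, spec)
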