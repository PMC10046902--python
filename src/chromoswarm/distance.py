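"""Interaction-frequency to expected-distance conversion.

The distance method assumes that the contact count between two chromatin
bins decays with their spatial separation, and inverts that relation as

    D_ij = 1 / IF_ij ** beta

where ``beta`` is the conversion-factor exponent.  The resulting target
distances are scale-free, so they are rescaled by a common factor such
that the largest defined target equals ``unit_scale`` (default 1.0,
matching the default particle initialization range).  Pairs with
IF == 0 carry no distance information and are masked out; the diagonal
is always masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMatrix

__all__ = ["DistanceTargets", "if_to_distance", "DEFAULT_BETA_GRID", "search_beta"]

#: candidate conversion factors for the grid search (0.1 .. 1.5 step 0.1)
DEFAULT_BETA_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 16))


@dataclass(frozen=True)
class DistanceTargets:
    """Expected pairwise distances and the mask of defined pairs."""

    d_expected: np.ndarray  # N x N, valid only where mask is True
    mask: np.ndarray        # N x N boolean, symmetric, False on diagonal
    beta: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d_expected, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if d.shape != m.shape or d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("d_expected and mask must be square matrices of equal shape")
        if np.any(np.diag(m)):
            raise ValueError("diagonal pairs must be unmasked")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
        if not np.array_equal(np.where(m, d, 0.0), np.where(m, d, 0.0).T):
            raise ValueError("d_expected must be symmetric on masked cells")
        masked = d[m]
        if masked.size and (not np.all(np.isfinite(masked)) or np.any(masked <= 0)):
            raise ValueError("masked expected distances must be finite and positive")
        object.__setattr__(self, "d_expected", d)
        object.__setattr__(self, "mask", m)

    @property
    def n_bins(self) -> int:
        return self.d_expected.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of masked unordered pairs."""
        return int(self.mask.sum()) // 2

    def pair_vector(self) -> np.ndarray:
        """Expected distances of the masked unordered pairs (i < j),
        in row-major upper-triangle order."""
        iu = np.triu_indices(self.n_bins, k=1)
        sel = self.mask[iu]
        return self.d_expected[iu][sel]


def if_to_distance(
    matrix: ContactMatrix, beta: float, unit_scale: float = 1.0
) -> DistanceTargets:
    """Convert an IF matrix into expected pairwise distances.

    For every off-diagonal pair with IF > 0, ``D = 1 / IF**beta``, then
    all defined targets are rescaled by one common factor so the largest
    equals ``unit_scale``.  Rescaling preserves all distance ratios.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if unit_scale <= 0:
        raise ValueError(f"unit_scale must be positive, got {unit_scale}")
    values = matrix.values
    mask = values > 0
    np.fill_diagonal(mask, False)
    if not mask.any():
        raise ValueError("contact matrix has no nonzero off-diagonal IF values")
    d = np.zeros_like(values)
    with np.errstate(divide="ignore"):
        d[mask] = 1.0 / values[mask] ** beta
    d[mask] *= unit_scale / d[mask].max()
    return DistanceTargets(d_expected=d, mask=mask, beta=float(beta))


def search_beta(matrix, candidates=DEFAULT_BETA_GRID, config=None, loss_spec=None):
    """Grid-search the conversion factor.

    Runs the full swarm reconstruction at each candidate ``beta`` and
    returns ``(best_beta, best_structure)`` where best is the structure
    with the highest Spearman correlation between realized and expected
    distances.  Ties break toward the smaller beta.
    """
    from .pso import SwarmConfig, run  # local import to avoid a cycle

    candidates = list(candidates)
    if not candidates:
        raise ValueError("beta candidate list is empty")
    if any(b <= 0 for b in candidates):
        raise ValueError("all beta candidates must be positive")
    if config is None:
        config = SwarmConfig()
    best = None
    for beta in sorted(candidates):
        structure = run(matrix, config=config, loss_spec=loss_spec, beta=beta)
        scc = structure.evaluation.scc
        if best is None or scc > best[2]:
            best = (beta, structure, scc)
    return best[0], best[1]
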