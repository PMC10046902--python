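"""Ground-truth structures and the contact matrices they imply.

Testing a distance-method reconstructor needs inputs whose answer is
known.  This module builds simple 3D curves (helix, circle, random
walk) and converts their pairwise distances back into an interaction
frequency matrix by inverting the distance law:

    IF_ij = (1 / d_ij) ** (1 / beta)

so that applying ``D = 1 / IF**beta`` with the same ``beta`` recovers
the true distances up to one global scale factor.  Optional
multiplicative log-normal noise emulates measurement scatter while
keeping IF positive.
"""

from __future__ import annotations

import numpy as np

from .contact_io import ContactMatrix
from .loss import realized_distances

__all__ = ["make_structure", "structure_to_if", "make_fixture", "STRUCTURE_KINDS"]

STRUCTURE_KINDS = ("helix", "circle", "random_walk")


def make_structure(kind: str, n_bins: int, seed: int = 0) -> np.ndarray:
    """Generate an N x 3 ground-truth curve.

    ``helix`` and ``circle`` are deterministic parametric curves with
    unit spacing between consecutive bins; ``random_walk`` is a seeded
    unit-step walk that resamples steps landing within 0.7 units of a
    previous bin (self-avoiding enough to keep all pairs separated).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if kind == "helix":
        # radius 1, pitch chosen so consecutive bins are ~1 apart
        t = np.arange(n_bins) * 0.7
        return np.column_stack([np.cos(t), np.sin(t), 0.5 * t])
    if kind == "circle":
        theta = 2 * np.pi * np.arange(n_bins) / n_bins
        r = n_bins / (2 * np.pi)  # unit arc length between bins
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n_bins)])
    if kind == "random_walk":
        rng = np.random.default_rng(seed)
        pts = [np.zeros(3)]
        while len(pts) < n_bins:
            for _ in range(200):
                direction = rng.normal(size=3)
                candidate = pts[-1] + direction / np.linalg.norm(direction)
                dists = np.linalg.norm(np.array(pts) - candidate, axis=1)
                if dists.min() > 0.7:
                    break
            pts.append(candidate)
        return np.array(pts)
    raise ValueError(f"unknown structure kind {kind!r}; choose from {STRUCTURE_KINDS}")


def structure_to_if(
    positions: np.ndarray,
    beta: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ContactMatrix:
    """Contact matrix implied by a structure under the distance law.

    ``IF_ij = (1 / d_ij) ** (1 / beta)``, optionally multiplied by
    ``exp(eps)`` with ``eps ~ Normal(0, noise_sd**2)`` drawn once per
    unordered pair.  Diagonal entries are 0.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    d = realized_distances(positions)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if d[off].min() <= 0:
        raise ValueError("coincident bins: zero pairwise distance implies infinite IF")
    if_mat = np.zeros_like(d)
    if_mat[off] = (1.0 / d[off]) ** (1.0 / beta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=(n, n))
        eps = np.triu(eps, k=1)
        eps = eps + eps.T  # symmetric per-pair noise
        if_mat *= np.exp(eps)
    return ContactMatrix(values=if_mat)


def make_fixture(
    kind: str = "helix",
    n_bins: int = 20,
    beta: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, ContactMatrix]:
    """Convenience: ``(true_positions, if_matrix)`` for a test scenario."""
    positions = make_structure(kind, n_bins, seed=seed)
    return positions, structure_to_if(positions, beta=beta, noise_sd=noise_sd, seed=seed)
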