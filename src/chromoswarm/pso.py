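"""Particle swarm optimization of chromosome bin coordinates.

Each particle is one candidate structure: an N x 3 matrix of bin
coordinates plus a velocity of the same shape and a memory of the best
structure it has visited.  At every iteration every coordinate cell is
updated as

    V <- w * V + c1 * R1 * (Pbest - P) + c2 * R2 * (Gbest - P)
    P <- P + V

with fresh uniform [0, 1) draws R1, R2 per cell, inertia weight w,
local (cognitive) weight c1 and global (social) weight c2.  The swarm
stops at the iteration cap or when the global best score improves by
less than the change threshold over a patience window.

The swarm is stored as stacked arrays (swarm_size, n_bins, 3) so one
iteration is a handful of vectorized operations; :class:`Particle`
views are available for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_io import ContactMatrix
from .distance import DistanceTargets, if_to_distance
from .evaluation import evaluate_structure
from .loss import LossSpec
from .structure_io import Structure

__all__ = ["SwarmConfig", "Particle", "SwarmState", "initialize_swarm", "step", "run"]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    The defaults of ``swarm_size=15``, ``max_iterations=30000``,
    ``threshold=1e-6`` and ``rand_range=1.0`` are the tool's published
    defaults.  The inertia weight decays linearly from ``w_start`` to
    ``w_end`` over the iteration budget and ``c1 = c2 = 2.0``, the
    canonical swarm settings; all are configurable.
    """

    swarm_size: int = 15
    max_iterations: int = 30000
    threshold: float = 1e-6
    rand_range: float = 1.0
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0
    patience: int = 100          # iterations per stop-check window
    stall_windows: int = 5       # consecutive sub-threshold windows before stopping
    clamp_velocity: bool = True  # clamp each velocity component to +/- rand_range

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.rand_range <= 0:
            raise ValueError("rand_range must be positive")
        if min(self.w_start, self.w_end, self.c1, self.c2) < 0:
            raise ValueError("w, c1 and c2 must be nonnegative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.stall_windows < 1:
            raise ValueError("stall_windows must be >= 1")

    def inertia_at(self, iteration: int) -> float:
        """Linearly decayed inertia weight for a given iteration."""
        if self.max_iterations <= 1:
            return self.w_start
        frac = min(iteration / (self.max_iterations - 1), 1.0)
        return self.w_start + (self.w_end - self.w_start) * frac


@dataclass(frozen=True)
class Particle:
    """Read-only view of one candidate structure in the swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    best_positions: np.ndarray
    best_score: float


@dataclass
class SwarmState:
    """The whole swarm, stacked along the first axis."""

    positions: np.ndarray       # (S, N, 3)
    velocities: np.ndarray      # (S, N, 3)
    best_positions: np.ndarray  # (S, N, 3)
    best_scores: np.ndarray     # (S,)
    global_best_positions: np.ndarray  # (N, 3)
    global_best_score: float
    iteration: int
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def swarm_size(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bins(self) -> int:
        return self.positions.shape[1]

    @property
    def particles(self) -> list[Particle]:
        return [
            Particle(
                positions=self.positions[k],
                velocities=self.velocities[k],
                best_positions=self.best_positions[k],
                best_score=float(self.best_scores[k]),
            )
            for k in range(self.swarm_size)
        ]


def _swarm_losses(
    positions: np.ndarray, targets: DistanceTargets, spec: LossSpec
) -> np.ndarray:
    """Loss of every particle, vectorized over the swarm axis."""
    iu, ju = np.triu_indices(targets.n_bins, k=1)
    sel = targets.mask[iu, ju]
    iu, ju = iu[sel], ju[sel]
    diff = positions[:, iu, :] - positions[:, ju, :]       # (S, P, 3)
    d = np.sqrt((diff * diff).sum(axis=-1))                # (S, P)
    residuals = d - targets.d_expected[iu, ju]
    r2 = residuals * residuals
    if spec.selector == 2:
        return r2.sum(axis=1)
    if spec.selector == 3:
        a = spec.alpha
        absr = np.abs(residuals)
        h = np.where(absr <= a, 0.5 * r2, a * (absr - 0.5 * a))
        return h.mean(axis=1)
    mse = r2.mean(axis=1)
    return np.sqrt(mse) if spec.selector == 0 else mse


def initialize_swarm(
    n_bins: int,
    config: SwarmConfig,
    targets: DistanceTargets,
    spec: LossSpec,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Draw initial coordinates uniform in [-rand_range, +rand_range],
    zero velocities, seed the personal and global bests."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins to form a structure")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.swarm_size, n_bins, 3)
    positions = rng.uniform(-config.rand_range, config.rand_range, size=shape)
    velocities = np.zeros(shape)
    scores = _swarm_losses(positions, targets, spec)
    k = int(np.argmin(scores))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        best_positions=positions.copy(),
        best_scores=scores,
        global_best_positions=positions[k].copy(),
        global_best_score=float(scores[k]),
        iteration=0,
        rng=rng,
    )


def step(
    state: SwarmState,
    targets: DistanceTargets,
    spec: LossSpec,
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Advance the swarm by one iteration (in place; returns the state).

    R1 and R2 are drawn per coordinate cell.  Personal and global bests
    are replaced only on strict improvement, so the global best score
    is non-increasing.
    """
    if rng is None:
        rng = state.rng
    w = config.inertia_at(state.iteration)
    shape = state.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    state.velocities *= w
    state.velocities += config.c1 * r1 * (state.best_positions - state.positions)
    state.velocities += config.c2 * r2 * (state.global_best_positions - state.positions)
    if config.clamp_velocity:
        np.clip(state.velocities, -config.rand_range, config.rand_range,
                out=state.velocities)
    state.positions += state.velocities

    scores = _swarm_losses(state.positions, targets, spec)
    improved = scores < state.best_scores
    state.best_positions[improved] = state.positions[improved]
    state.best_scores[improved] = scores[improved]
    k = int(np.argmin(state.best_scores))
    if state.best_scores[k] < state.global_best_score:
        state.global_best_score = float(state.best_scores[k])
        state.global_best_positions = state.best_positions[k].copy()
    state.iteration += 1
    return state


def run(
    matrix: ContactMatrix,
    config: SwarmConfig | None = None,
    loss_spec: LossSpec | None = None,
    beta: float = 1.0,
    targets: DistanceTargets | None = None,
) -> Structure:
    """Full reconstruction: IF -> target distances -> optimized structure.

    Iterates :func:`step` until the iteration cap is reached or the
    global best score decreases by less than ``config.threshold`` over
    ``config.stall_windows`` consecutive windows of ``config.patience``
    iterations (a swarm routinely plateaus for one window and then
    resumes improving, so a single stalled window is not convergence).
    Returns the global-best structure with its evaluation record and a
    provenance snapshot sufficient to rerun.
    """
    if config is None:
        config = SwarmConfig()
    if loss_spec is None:
        loss_spec = LossSpec()
    if targets is None:
        targets = if_to_distance(matrix, beta)
    state = initialize_swarm(targets.n_bins, config, targets, loss_spec)
    stop_reason = "max_iterations"
    window_start_score = state.global_best_score
    prev_best = state.global_best_score
    stalled = 0
    while state.iteration < config.max_iterations:
        step(state, targets, loss_spec, config)
        if state.global_best_score > prev_best + 1e-15:
            raise AssertionError("global best score increased")  # bookkeeping invariant
        prev_best = state.global_best_score
        if state.iteration % config.patience == 0:
            if window_start_score - state.global_best_score < config.threshold:
                stalled += 1
                if stalled >= config.stall_windows:
                    stop_reason = "threshold"
                    break
            else:
                stalled = 0
            window_start_score = state.global_best_score
    evaluation = evaluate_structure(state.global_best_positions, targets, loss_spec)
    provenance = {
        "beta": float(targets.beta),
        "loss": loss_spec.name,
        "alpha": loss_spec.alpha,
        "seed": config.seed,
        "swarm_size": config.swarm_size,
        "max_iterations": config.max_iterations,
        "threshold": config.threshold,
        "rand_range": config.rand_range,
        "w_start": config.w_start,
        "w_end": config.w_end,
        "c1": config.c1,
        "c2": config.c2,
        "iterations_used": state.iteration,
        "stop_reason": stop_reason,
    }
    return Structure(
        positions=state.global_best_positions.copy(),
        evaluation=evaluation,
        provenance=provenance,
    )
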