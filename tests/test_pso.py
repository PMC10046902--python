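"""Swarm initialization, the cell-wise update rule, and convergence."""

import numpy as np
import pytest

from chromoswarm import (
    LossSpec,
    SwarmConfig,
    evaluate_structure,
    initialize_swarm,
    run,
    step,
)
from chromoswarm.distance import if_to_distance
from chromoswarm.pso import SwarmState, _swarm_losses
from conftest import make_targets


class ConstantRNG:
    """Stand-in random source yielding a fixed sequence of fill values."""

    def __init__(self, *values):
        self.values = list(values)

    def random(self, shape):
        return np.full(shape, self.values.pop(0))


@pytest.fixture
def two_bin_targets():
    return make_targets(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestInitialize:
    def test_single_particle_swarm(self, two_bin_targets):
        cfg = SwarmConfig(swarm_size=1, seed=5)
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        assert state.swarm_size == 1
        assert state.global_best_score == state.particles[0].best_score

    def test_same_seed_is_bit_identical(self, two_bin_targets):
        cfg = SwarmConfig(seed=9)
        a = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        b = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        assert np.array_equal(a.positions, b.positions)
        assert a.global_best_score == b.global_best_score

    def test_coordinates_within_rand_range(self, two_bin_targets):
        cfg = SwarmConfig(swarm_size=200, rand_range=1.0, seed=0)
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        assert state.positions.size >= 1000
        assert state.positions.min() >= -1.0
        assert state.positions.max() <= 1.0

    def test_velocities_start_at_zero(self, two_bin_targets):
        state = initialize_swarm(2, SwarmConfig(seed=0), two_bin_targets, LossSpec())
        assert not state.velocities.any()

    def test_single_bin_rejected(self, two_bin_targets):
        with pytest.raises(ValueError, match="at least 2 bins"):
            initialize_swarm(1, SwarmConfig(), two_bin_targets, LossSpec())

    def test_global_best_is_swarm_minimum(self, helix20_targets):
        cfg = SwarmConfig(swarm_size=15, seed=3)
        state = initialize_swarm(20, cfg, helix20_targets, LossSpec())
        assert state.global_best_score == pytest.approx(state.best_scores.min())
        assert state.global_best_score <= state.best_scores.max()


class TestStep:
    def test_zero_coefficients_freeze_swarm(self, two_bin_targets):
        cfg = SwarmConfig(w_start=0.0, w_end=0.0, c1=0.0, c2=0.0, seed=1)
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        before = state.positions.copy()
        score = state.global_best_score
        step(state, two_bin_targets, LossSpec(), cfg)
        assert np.array_equal(state.positions, before)
        assert state.global_best_score == score

    def test_particle_at_both_bests_keeps_inertia_only(self, two_bin_targets):
        cfg = SwarmConfig(
            swarm_size=1, w_start=0.5, w_end=0.5, c1=1.0, c2=1.0,
            seed=2, clamp_velocity=False,
        )
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        state.best_positions[:] = state.positions      # personal best == P
        state.global_best_positions = state.positions[0].copy()  # global == P
        state.velocities[:] = 0.125
        step(state, two_bin_targets, LossSpec(), cfg, rng=ConstantRNG(0.7, 0.9))
        assert np.allclose(state.velocities, 0.5 * 0.125)

    def test_hand_computed_cell_update(self, two_bin_targets):
        """One cell with P=0, V=1, personal best 2, global best 3,
        w=0.5, c1=c2=1, R1=0.25, R2=0.5 must move to
        V' = 0.5*1 + 0.25*(2-0) + 0.5*(3-0) = 2.5 and P' = 2.5."""
        cfg = SwarmConfig(
            swarm_size=1, w_start=0.5, w_end=0.5, c1=1.0, c2=1.0,
            seed=0, clamp_velocity=False,
        )
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        state.positions[:] = 0.0
        state.velocities[:] = 0.0
        state.best_positions[:] = 0.0
        state.global_best_positions[:] = 0.0
        state.positions[0, 0, 0] = 0.0
        state.velocities[0, 0, 0] = 1.0
        state.best_positions[0, 0, 0] = 2.0
        state.global_best_positions[0, 0] = 3.0
        state.best_scores[:] = _swarm_losses(state.best_positions, two_bin_targets, LossSpec())
        step(state, two_bin_targets, LossSpec(), cfg, rng=ConstantRNG(0.25, 0.5))
        assert state.velocities[0, 0, 0] == pytest.approx(2.5, abs=1e-12)
        assert state.positions[0, 0, 0] == pytest.approx(2.5, abs=1e-12)

    def test_velocity_decays_geometrically_without_attraction(self, two_bin_targets):
        cfg = SwarmConfig(w_start=0.5, w_end=0.5, c1=0.0, c2=0.0, seed=4)
        state = initialize_swarm(2, cfg, two_bin_targets, LossSpec())
        state.velocities[:] = 0.8
        for k in range(1, 6):
            step(state, two_bin_targets, LossSpec(), cfg)
            assert np.allclose(np.abs(state.velocities), 0.8 * 0.5**k)

    def test_global_best_monotone_over_iterations(self, helix20_targets):
        cfg = SwarmConfig(seed=8, max_iterations=500)
        state = initialize_swarm(20, cfg, helix20_targets, LossSpec())
        best = state.global_best_score
        for _ in range(500):
            step(state, helix20_targets, LossSpec(), cfg)
            assert state.global_best_score <= best
            best = state.global_best_score


class TestRun:
    def test_single_iteration_cap(self, helix20):
        _, ifm = helix20
        s = run(ifm, config=SwarmConfig(max_iterations=1, seed=0), beta=1.0)
        assert s.provenance["iterations_used"] == 1
        assert s.provenance["stop_reason"] == "max_iterations"

    def test_huge_threshold_stops_early(self, helix20):
        _, ifm = helix20
        cfg = SwarmConfig(max_iterations=30000, threshold=1e9, seed=0)
        s = run(ifm, config=cfg, beta=1.0)
        assert s.provenance["stop_reason"] == "threshold"
        assert s.provenance["iterations_used"] == cfg.patience * cfg.stall_windows

    def test_bit_reproducible_given_seed(self, helix20):
        _, ifm = helix20
        cfg = SwarmConfig(max_iterations=300, seed=77)
        a = run(ifm, config=cfg, beta=1.0)
        b = run(ifm, config=cfg, beta=1.0)
        assert np.array_equal(a.positions, b.positions)
        assert a.evaluation == b.evaluation

    def test_recovers_helix_structure(self, helix20, fast_config):
        _, ifm = helix20
        s = run(ifm, config=fast_config, beta=1.0)
        assert s.evaluation.scc >= 0.9
        assert s.evaluation.pcc >= 0.9

    def test_if_scale_freedom(self, helix20):
        """Multiplying all IFs by a constant is absorbed by the target
        rescaling: identical seed gives the identical structure."""
        _, ifm = helix20
        from chromoswarm.contact_io import ContactMatrix

        scaled = ContactMatrix(values=ifm.values * 32.0)
        cfg = SwarmConfig(max_iterations=300, seed=5)
        a = run(ifm, config=cfg, beta=1.0)
        b = run(scaled, config=cfg, beta=1.0)
        assert a.evaluation.scc == b.evaluation.scc
        assert np.array_equal(a.positions, b.positions)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(swarm_size=0)
        with pytest.raises(ValueError):
            SwarmConfig(threshold=0)
        with pytest.raises(ValueError):
            SwarmConfig(rand_range=-1)
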