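"""Diffusion-aggregation simulator: Brownian motion, binding rules, bookkeeping."""

import math

import numpy as np
import pytest

from origamikin import (
    ObservationWindow,
    SimConfig,
    advance,
    cluster_diffusion,
    detect_and_bind,
    immobile_fraction,
    initial_state,
    run,
)
from origamikin.simulate import ConfigurationError, log_schedule


def make_state(positions, angles=None, rng_seed=0, **cfg_kwargs):
    cfg = SimConfig(rng_seed=rng_seed, **cfg_kwargs)
    positions = np.asarray(positions, dtype=float)
    if angles is None:
        angles = np.zeros(len(positions))
    from origamikin.simulate import ClusterState

    return ClusterState(positions, np.asarray(angles, dtype=float), cfg)


class TestClusterDiffusion:
    def test_inverse_n_rule(self):
        assert cluster_diffusion(1, 0.2, "inverse_n") == pytest.approx(0.2)
        assert cluster_diffusion(2, 0.2, "inverse_n") == pytest.approx(0.1)

    @pytest.mark.parametrize("scaling", ["inverse_n", "saffman_delbruck_log"])
    def test_monotone_nonincreasing_and_bounded(self, scaling):
        values = [cluster_diffusion(n, 0.2, scaling) for n in range(1, 101)]
        assert values[0] == pytest.approx(0.2)
        assert all(v <= 0.2 for v in values)
        assert all(b <= a for a, b in zip(values, values[1:]))
        assert all(v > 0 for v in values)

    def test_rejects_empty_cluster(self):
        with pytest.raises(ValueError):
            cluster_diffusion(0, 0.2)


class TestAdvance:
    def test_frozen_membrane_leaves_positions(self, rng):
        state = make_state([[1.0, 1.0], [2.0, 2.0]], D1=0.0, n_monomers=2)
        before = state.positions.copy()
        advance(state, 0.1, rng)
        assert np.array_equal(state.positions, before)

    def test_msd_matches_2d_brownian_law(self, rng):
        """Free monomers: <r^2> = 4*D*tau, checked on a 10^4-particle ensemble."""
        n, D, dt, steps = 10_000, 0.2, 0.01, 20
        state = make_state(rng.uniform(100, 200, size=(n, 2)),
                           domain_side=1e6, D1=D, n_monomers=n)
        start = state.positions.copy()
        for _ in range(steps):
            advance(state, dt, rng)
        tau = steps * dt
        msd = np.mean(np.sum((state.positions - start) ** 2, axis=1))
        assert msd == pytest.approx(4 * D * tau, rel=0.05)

    def test_rejects_nonpositive_step(self, rng):
        state = make_state([[0.0, 0.0]], n_monomers=1)
        with pytest.raises(ValueError):
            advance(state, 0.0, rng)

    def test_rigid_cluster_moves_together(self, rng):
        state = make_state([[1.0, 1.0], [1.05, 1.0]], domain_side=10.0,
                           n_monomers=2, D1=0.2)
        state.add_bond(0, 0, 1, 1)
        rel = state.positions[1] - state.positions[0]
        for _ in range(50):
            advance(state, 0.001, rng)
        assert np.allclose(state.positions[1] - state.positions[0], rel)


class TestDetectAndBind:
    def test_zero_link_rate_never_binds(self, rng):
        state = make_state(np.zeros((5, 2)), n_monomers=5, link_rate=0.0,
                           domain_side=1.0)
        for _ in range(100):
            detect_and_bind(state, 0.01, rng)
        assert state.n_clusters == 5

    def test_coincident_pair_with_huge_rate_dimerizes_immediately(self, rng):
        state = make_state([[0.5, 0.5], [0.5, 0.5]], n_monomers=2,
                           link_rate=1e9, domain_side=1.0)
        detect_and_bind(state, 0.01, rng)
        assert state.n_clusters == 1

    def test_scaffold_rule_rejects_antiparallel(self, rng):
        state = make_state([[0.5, 0.5], [0.55, 0.5]], angles=[0.0, math.pi],
                           n_monomers=2, link_rate=1e9, domain_side=1.0,
                           orientation_rule="parallel_only")
        for _ in range(50):
            detect_and_bind(state, 0.01, rng)
        assert state.n_clusters == 2

    def test_scaffold_rule_accepts_near_parallel(self, rng):
        state = make_state([[0.5, 0.5], [0.55, 0.5]], angles=[0.0, 0.2],
                           n_monomers=2, link_rate=1e9, domain_side=1.0,
                           orientation_rule="parallel_only")
        detect_and_bind(state, 0.01, rng)
        assert state.n_clusters == 1

    def test_scaffold_rule_never_branches(self, rng):
        """Linear-assembly design: every edge holds at most one partner."""
        n = 60
        state = make_state(rng.uniform(0, 2.0, size=(n, 2)),
                           angles=np.zeros(n), n_monomers=n, link_rate=50.0,
                           domain_side=2.0, orientation_rule="parallel_only",
                           capture_radius=0.3)
        for _ in range(200):
            advance(state, 0.005, rng)
            detect_and_bind(state, 0.005, rng)
        for m in state.monomers:
            assert all(len(p) <= 1 for p in m.edge_partners)

    def test_bond_symmetry_and_conservation(self, rng):
        n = 80
        state = make_state(rng.uniform(0, 3.0, size=(n, 2)), n_monomers=n,
                           link_rate=20.0, branch_probability=0.5,
                           domain_side=3.0, capture_radius=0.2)
        for _ in range(150):
            advance(state, 0.005, rng)
            detect_and_bind(state, 0.005, rng)
            assert sum(state.cluster_sizes.values()) == n
        for m in state.monomers:
            for edge in m.edge_partners:
                for j in edge:
                    assert m.id in [
                        p
                        for e in state.monomer(j).edge_partners
                        for p in e
                    ]

    def test_well_mixed_limit_matches_birth_process_oracle(self):
        """Tiny domain, all pairs always in reach: cluster-count decay must match
        a direct Gillespie simulation of the same edge-pair birth process."""
        N, link, T = 12, 0.15, 12.0
        n_rep = 60

        def simulate_mean_clusters(seed):
            cfg = dict(domain_side=0.12, n_monomers=N, D1=0.005, dt=0.05,
                       capture_radius=0.1, link_rate=link, domain=None)
            state = make_state(
                np.random.default_rng(seed).uniform(0, 0.12, size=(N, 2)),
                n_monomers=N, domain_side=0.12, D1=0.005, link_rate=link,
                capture_radius=0.1)
            rng = np.random.default_rng(seed + 1)
            t = 0.0
            while t < T:
                advance(state, 0.05, rng)
                detect_and_bind(state, 0.05, rng)
                t += 0.05
            return state.n_clusters

        def gillespie_mean_clusters(seed):
            rng = np.random.default_rng(seed)
            free = [[1, 1] for _ in range(N)]   # free slots per edge
            cluster = list(range(N))
            t = 0.0
            while t < T:
                pairs = []
                for i in range(N):
                    for j in range(i + 1, N):
                        if cluster[i] == cluster[j]:
                            continue
                        combos = sum(
                            free[i][a] * free[j][b]
                            for a in range(2) for b in range(2)
                        )
                        if combos:
                            pairs.append((i, j, combos))
                total = link * sum(c for _, _, c in pairs)
                if total == 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= T:
                    break
                weights = np.array([c for _, _, c in pairs], dtype=float)
                i, j, _ = pairs[rng.choice(len(pairs), p=weights / weights.sum())]
                ei = rng.choice([a for a in range(2) if free[i][a]])
                ej = rng.choice([b for b in range(2) if free[j][b]])
                free[i][ei] -= 1
                free[j][ej] -= 1
                old, new = cluster[j], cluster[i]
                cluster = [new if c == old else c for c in cluster]
            return len(set(cluster))

        sim = np.mean([simulate_mean_clusters(7 * k) for k in range(n_rep)])
        oracle = np.mean([gillespie_mean_clusters(1000 + k) for k in range(n_rep)])
        assert sim == pytest.approx(oracle, rel=0.12)


class TestRun:
    def base_config(self, **kw):
        defaults = dict(domain_side=5.0, n_monomers=40, dt=0.02, link_rate=1.0,
                        total_time=10.0, rng_seed=3,
                        observation_schedule=(ObservationWindow(0.0, 20, 30.0),
                                              ObservationWindow(5.0, 20, 30.0)))
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_zero_total_time_returns_initial_state_only(self):
        cfg = self.base_config(total_time=0.0, observation_schedule=())
        res = run(cfg)
        assert res.final_state.time == 0.0
        assert res.final_state.n_clusters == 40

    def test_identical_seeds_identical_trajectories(self):
        r1, r2 = run(self.base_config()), run(self.base_config())
        for w1, w2 in zip(r1.windows, r2.windows):
            assert np.array_equal(w1.positions, w2.positions)
        assert r1.size_series.equals(r2.size_series)

    def test_mean_cluster_size_nondecreasing_without_unbinding(self):
        res = run(self.base_config(link_rate=5.0))
        sizes = res.size_series.mean_cluster_size.to_numpy()
        assert np.all(np.diff(sizes) >= 0)

    def test_monomers_conserved_in_every_record(self):
        res = run(self.base_config())
        ss = res.size_series
        assert np.allclose(ss.mean_cluster_size * ss.n_clusters, 40)

    def test_step_resolution_violation_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            run(self.base_config(dt=1.0, D1=0.2, capture_radius=0.05))

    def test_window_beyond_total_time_rejected(self):
        with pytest.raises(ConfigurationError):
            run(self.base_config(
                total_time=1.0,
                observation_schedule=(ObservationWindow(5.0, 10, 30.0),)))

    def test_frames_recorded_at_schedule(self):
        cfg = self.base_config()
        res = run(cfg)
        assert len(res.windows) == 2
        assert res.windows[0].positions.shape == (20, 40, 2)
        assert not np.array_equal(res.windows[0].positions[0],
                                  res.windows[1].positions[0])


class TestImmobileFraction:
    def test_free_monomers_with_generous_threshold(self):
        state = make_state(np.random.default_rng(0).uniform(0, 5, (20, 2)),
                           n_monomers=20, D1=0.2, domain_side=5.0)
        assert immobile_fraction(state, 0.5, 1.0) == 0.0

    def test_fully_aggregated_cluster_is_immobile(self, rng):
        n = 100
        state = make_state(np.full((n, 2), 2.0), n_monomers=n, D1=0.2,
                           domain_side=5.0)
        for i in range(n - 1):
            state.add_bond(i, 0, i + 1, 1)
        assert immobile_fraction(state, 0.2, 1.0) == 1.0

    def test_half_and_half_mixture_counts_directly(self):
        """100 monomers: 50 free, 50 in one 50-mer; threshold between the two
        r.m.s. displacements -> fraction is exactly 0.5."""
        n = 100
        state = make_state(np.random.default_rng(1).uniform(0, 10, (n, 2)),
                           n_monomers=n, D1=0.2, domain_side=10.0)
        for i in range(50, n - 1):
            state.add_bond(i, 0, i + 1, 1)
        horizon = 1.0
        rms_free = math.sqrt(4 * 0.2 * horizon)
        rms_cluster = math.sqrt(4 * 0.2 / 50 * horizon)
        threshold = 0.5 * (rms_free + rms_cluster)
        assert immobile_fraction(state, threshold, horizon) == pytest.approx(0.5)

    def test_rejects_nonpositive_arguments(self):
        state = make_state([[0.0, 0.0]], n_monomers=1)
        with pytest.raises(ValueError):
            immobile_fraction(state, 0.0, 1.0)


def test_log_schedule_is_geometric_and_nonoverlapping():
    sched = log_schedule(10.0, 6000.0, 24, n_frames=64)
    starts = np.array([w.start for w in sched])
    assert len(sched) == 24
    assert starts[0] == pytest.approx(10.0)
    assert starts[-1] == pytest.approx(6000.0)
    durations = 64 / 30.0
    assert np.all(np.diff(starts) >= durations - 1e-9)
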