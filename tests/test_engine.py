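import numpy as np
import pytest

from fadsim.colorspace import angle_of, rotate_clockwise, unit_from_angle
from fadsim.engine import (
    AgentState,
    BoredomFunction,
    ConfigurationError,
    GroupSpec,
    PopulationConfig,
    apply_drift_and_bias,
    boredom_weight,
    choose_color,
    initialize_population,
    run_simulation,
    sample_partner,
    update_memory,
)
from fadsim.metrics import chance_threshold, trend_series

from conftest import reference_config


class TestBoredomWeight:
    @pytest.mark.parametrize(
        "d, x0, expected",
        [
            (0.7, 0.7, 0.5),
            (1.0, 0.7, 1.0 / (1.0 + np.exp(-6.0))),   # ~0.997527
            (0.0, 0.7, 1.0 / (1.0 + np.exp(14.0))),   # ~8.3153e-7
        ],
    )
    def test_sigmoid_values(self, d, x0, expected):
        assert boredom_weight(d, BoredomFunction(x0)) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        f = BoredomFunction(0.6)
        d = np.linspace(0, 1, 101)
        w = boredom_weight(d, f)
        assert np.all(np.diff(w) > 0)
        assert np.all((w > 0) & (w < 1))

    def test_out_of_range_difference_rejected(self):
        with pytest.raises(ValueError):
            boredom_weight(1.2, BoredomFunction(0.7))

    def test_x0_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            BoredomFunction(1.5)


class TestConfig:
    def test_group_rounding_80_20(self):
        cfg = PopulationConfig(
            n_agents=200, n_trials=1, m=12,
            groups=(GroupSpec(0.8, 0.65), GroupSpec(0.2, 0.9)),
        )
        assert cfg.group_sizes() == [160, 40]
        gids = cfg.group_ids()
        assert (gids[:160] == 0).all() and (gids[160:] == 1).all()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_agents=10, n_trials=1, m=2,
                             groups=(GroupSpec(0.5, 0.7),))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_agents=1, n_trials=1, m=2)
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_agents=10, n_trials=0, m=2)
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_agents=10, n_trials=1, m=2, update_mode="async")

    def test_roundtrip_dict(self):
        cfg = PopulationConfig(n_agents=10, n_trials=3, m=2, seed=7,
                               groups=(GroupSpec(0.5, 0.7), GroupSpec(0.5, 0.9)))
        assert PopulationConfig.from_dict(cfg.to_dict()) == cfg


class TestInitialization:
    def test_shapes_and_unit_memories(self, rng):
        cfg = PopulationConfig(n_agents=200, n_trials=1, m=12, seed=1)
        agents = initialize_population(cfg, rng)
        assert len(agents) == 200
        for a in agents[:5]:
            assert a.memory.shape == (12, 2)
            np.testing.assert_allclose(np.linalg.norm(a.memory, axis=1), 1.0, atol=1e-12)

    def test_same_seed_identical(self):
        cfg = PopulationConfig(n_agents=20, n_trials=1, m=4, seed=3)
        a1 = initialize_population(cfg, np.random.default_rng(9))
        a2 = initialize_population(cfg, np.random.default_rng(9))
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.memory, y.memory)


class TestSingleAgentOps:
    def test_choice_is_memory_sum(self):
        a = AgentState(memory=np.tile([0.0, 1.0], (5, 1)), boredom=BoredomFunction(0.7))
        np.testing.assert_allclose(choose_color(a), [0, 5])
        a2 = AgentState(memory=np.array([[0.0, 1.0], [0.0, -1.0]]),
                        boredom=BoredomFunction(0.7))
        np.testing.assert_allclose(choose_color(a2), [0, 0])
        a3 = AgentState(memory=np.array([[1.0, 0.0], [0.0, 1.0]]),
                        boredom=BoredomFunction(0.7))
        assert angle_of(choose_color(a3)) == pytest.approx(0.125)

    def test_drift_rotates_displayed_choice(self):
        a = AgentState(memory=np.zeros((1, 2)), boredom=BoredomFunction(0.7),
                       drift_deg=17.0)
        out = apply_drift_and_bias(np.array([0.0, 2.0]), a)
        np.testing.assert_allclose(
            out, 2.0 * np.array([np.sin(np.deg2rad(17)), np.cos(np.deg2rad(17))]),
            atol=1e-12)

    def test_bias_adds_40_percent_toward_subgroup_vector(self):
        a = AgentState(memory=np.zeros((1, 2)), boredom=BoredomFunction(0.7),
                       uniform_bias=True)
        out = apply_drift_and_bias(np.array([0.0, 1.0]), a, s_sub=np.array([0.0, 5.0]))
        np.testing.assert_allclose(out, [0.0, 1.4], atol=1e-12)

    def test_no_drift_no_bias_is_identity(self):
        a = AgentState(memory=np.zeros((1, 2)), boredom=BoredomFunction(0.7))
        y = np.array([0.3, -0.8])
        np.testing.assert_array_equal(apply_drift_and_bias(y, a), y)

    def test_update_memory_stores_weighted_unit_sample(self):
        a = AgentState(memory=unit_from_angle(np.array([0.0, 0.1, 0.2])),
                       boredom=BoredomFunction(0.7))
        new = update_memory(a, z=np.array([0.0, -3.0]), own_y=np.array([0.0, 1.0]))
        np.testing.assert_allclose(
            new.memory[0], (1.0 / (1.0 + np.exp(-6.0))) * np.array([0.0, -1.0]),
            atol=1e-12)
        np.testing.assert_array_equal(new.memory[1:], a.memory[:-1])
        assert new.memory.shape == a.memory.shape


class TestPartnerSampling:
    def test_two_agents_always_each_other(self, rng):
        assert sample_partner(0, [1.0, 1.0], rng) == 1
        assert sample_partner(1, [1.0, 1.0], rng) == 0

    def test_never_self(self, rng):
        draws = {sample_partner(2, np.ones(6), rng) for _ in range(200)}
        assert 2 not in draws
        assert draws == {0, 1, 3, 4, 5}

    def test_popular_agent_frequency_matches_analytics(self, rng):
        # weights {10, 1 x 20}: a non-popular sampler excludes itself,
        # leaving 19 unit weights, so it picks agent 0 with p = 10/29
        weights = np.array([10.0] + [1.0] * 20)
        n_draws = 100_000
        hits = sum(sample_partner(5, weights, rng) == 0 for _ in range(n_draws))
        p = 10.0 / 29.0
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert abs(hits - n_draws * p) < 3 * sigma


class TestTwoAgentOracle:
    """Hand-computed single step: A holds [0,1] (m=1), B holds [1,0],
    x0=0.7.  A samples B: d=0.5, w=1/(1+e^4)=0.017986..., so A's new
    memory is w*[1,0]."""

    def test_hand_computed_step(self):
        a = AgentState(memory=np.array([[0.0, 1.0]]), boredom=BoredomFunction(0.7))
        new = update_memory(a, z=np.array([1.0, 0.0]), own_y=np.array([0.0, 1.0]))
        w = 1.0 / (1.0 + np.exp(4.0))
        assert w == pytest.approx(0.01798620996, abs=1e-10)
        np.testing.assert_allclose(new.memory[0], [w, 0.0], atol=1e-12)

    def test_full_run_matches_for_both_agents(self):
        cfg = PopulationConfig(n_agents=2, n_trials=1, m=1, seed=0)
        res = run_simulation(cfg)
        # choices on trial 0 are the initial unit memories
        np.testing.assert_allclose(np.linalg.norm(res.choices[0], axis=1), 1.0,
                                   atol=1e-12)
        assert res.partners[0, 0] == 1 and res.partners[0, 1] == 0
        d01 = np.arccos(np.clip(res.choices[0, 0] @ res.choices[0, 1], -1, 1)) / np.pi
        w = 1.0 / (1.0 + np.exp(-20.0 * (d01 - 0.7)))
        assert res.sample_weights[0, 0] == pytest.approx(w, rel=1e-12)


class TestRunSimulation:
    def test_deterministic_given_seed(self):
        cfg = PopulationConfig(n_agents=10, n_trials=20, m=4, seed=42)
        r1, r2 = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(r1.choices, r2.choices)
        np.testing.assert_array_equal(r1.partners, r2.partners)

    def test_identical_memories_stay_identical(self):
        # symmetry fixed point: if all agents share one memory, all
        # choices coincide on every trial and uniformity is 1 forever
        cfg = PopulationConfig(n_agents=6, n_trials=15, m=3, seed=5)
        res = run_simulation(cfg)
        ts = trend_series(res.choices)
        assert not np.all(ts.uniformity > 0.9999)  # random init: not degenerate
        # now force identical memories through a symmetric custom run:
        # all initial angles equal is a measure-zero event for the rng,
        # so emulate by checking the invariance property directly
        from fadsim import engine as eng

        n, m, n_t = 5, 3, 10
        mem = np.tile(unit_from_angle(0.3), (n, m, 1))
        choices = []
        head = m - 1
        rngp = np.random.default_rng(0)
        for t in range(n_t):
            y = mem.sum(axis=1)
            choices.append(y.copy())
            u = rngp.random(n)
            idx = np.minimum((u * (n - 1)).astype(int), n - 2)
            ptn = idx + (idx >= np.arange(n))
            dirs = y / np.linalg.norm(y, axis=-1)[:, None]
            d = np.arccos(np.clip(np.sum(dirs * dirs[ptn], -1), -1, 1)) / np.pi
            w = 1 / (1 + np.exp(-20 * (d - 0.7)))
            head = (head + 1) % m
            mem[:, head, :] = w[:, None] * dirs[ptn]
        ts2 = trend_series(np.stack(choices))
        np.testing.assert_allclose(ts2.uniformity, 1.0, atol=1e-9)

    def test_global_rotation_equivariance(self):
        """Rotating all initial memories by a fixed angle rotates every
        recorded choice by that angle (same partner stream)."""
        cfg = PopulationConfig(n_agents=8, n_trials=12, m=3, seed=11)
        base = run_simulation(cfg)
        alpha = 53.0
        # re-run manually with rotated init, sharing the partner stream
        ss = np.random.SeedSequence(cfg.seed).spawn(3)
        rng_init, rng_partner, _ = (np.random.default_rng(s) for s in ss)
        mem = unit_from_angle(rng_init.random((8, 3)))
        mem = rotate_clockwise(mem, alpha)
        head = 2
        for t in range(12):
            y = mem.sum(axis=1)
            np.testing.assert_allclose(
                y, rotate_clockwise(base.choices[t], alpha), atol=1e-9)
            u = rng_partner.random(8)
            idx = np.minimum((u * 7).astype(int), 6)
            ptn = idx + (idx >= np.arange(8))
            dirs = y / np.linalg.norm(y, axis=-1)[:, None]
            d = np.arccos(np.clip(np.sum(dirs * dirs[ptn], -1), -1, 1)) / np.pi
            w = 1 / (1 + np.exp(-20 * (d - 0.7)))
            head = (head + 1) % 3
            mem[:, head, :] = w[:, None] * dirs[ptn]

    def test_memory_and_choice_length_bounds(self):
        cfg = PopulationConfig(n_agents=12, n_trials=30, m=5, seed=2)
        res = run_simulation(cfg)
        lengths = np.linalg.norm(res.choices, axis=-1)
        assert np.all(lengths <= 5.0 + 1e-9)
        assert np.all((res.sample_weights > 0) & (res.sample_weights < 1))


class TestRegimes:
    def test_convergence_at_low_boredom(self):
        """x0=0.5 reaches near-complete uniformity within 2000 trials."""
        hits = 0
        for seed in range(3):
            res = run_simulation(reference_config(x0=0.5, seed=seed))
            if trend_series(res.choices).uniformity.max() >= 0.99:
                hits += 1
        assert hits == 3

    def test_divergence_large_bored_population(self):
        """n=2000, x0=0.9: any collective trend is fully disrupted —
        uniformity hovers near the chance level (within a factor ~2 of
        the random-vector expectation) and never approaches the trend
        threshold of the reference population size."""
        cfg = PopulationConfig(n_agents=2000, n_trials=2000, m=12,
                               groups=(GroupSpec(1.0, 0.9),), seed=0)
        ts = trend_series(run_simulation(cfg).choices)
        from oracles import rayleigh_expected_resultant

        burn = 100
        assert ts.uniformity[burn:].mean() < 2 * rayleigh_expected_resultant(2000)
        assert ts.uniformity.max() < 0.153

    def test_max_uniformity_non_increasing_in_boredom(self):
        means = []
        for x0 in (0.5, 0.7, 0.85):
            vals = [
                trend_series(run_simulation(reference_config(x0=x0, seed=s)).choices
                             ).uniformity.max()
                for s in range(5)
            ]
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
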