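"""Replay buffer semantics and the IPF driver."""

import numpy as np
import pytest

from scorebridge import (FunctionDrift, HalfBridgeTrainConfig, IPFConfig,
                         ReplayBuffer, SDEConfig, TraceEstimatorSpec, ZeroDrift,
                         build_drift, run_ipf, sigma_heuristic, simulate_em)
from scorebridge.ipf import init_reference, refresh_buffer


def _small_config(dim=1, **kw):
    defaults = dict(
        sde=SDEConfig(sigma=1.0, dt=0.02, n_steps=10, dim=dim),
        n_ipf_iterations=2,
        n_new_trajectories=16,
        buffer_capacity=64,
        refresh_every=25,
        train=HalfBridgeTrainConfig(n_train_steps=50, batch_points=128),
        trace=TraceEstimatorSpec("exact_diagonal"),
        n_eval=64,
        rng_seed=0,
    )
    defaults.update(kw)
    return IPFConfig(**defaults)


def _ensemble(n, cfg, seed=0):
    return simulate_em(ZeroDrift(cfg.dim), np.zeros((n, cfg.dim)), cfg, rng_seed=seed)


class TestReplayBuffer:
    def test_empty_plus_batch(self):
        cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=5, dim=1)
        buf = ReplayBuffer(512)
        buf.push_ensemble(_ensemble(128, cfg))
        assert len(buf) == 128

    def test_fifo_eviction(self):
        cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=5, dim=1)
        buf = ReplayBuffer(512)
        for seed in range(4):
            buf.push_ensemble(_ensemble(128, cfg, seed))
        oldest = buf.initial_states().copy()
        buf.push_ensemble(_ensemble(128, cfg, 99))
        assert len(buf) == 512
        # the 128 oldest were evicted; remaining starts shifted accordingly
        assert np.array_equal(buf.initial_states()[:384], oldest[128:])

    def test_capacity_one(self):
        cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=5, dim=1)
        buf = ReplayBuffer(1)
        ens = _ensemble(3, cfg, 7)
        buf.push_ensemble(ens)
        assert len(buf) == 1
        assert np.array_equal(buf.initial_states()[0], ens.states[2, 0])

    def test_flat_points_uses_forward_times(self):
        cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=4, dim=1)
        buf = ReplayBuffer(8)
        buf.push_ensemble(simulate_em(ZeroDrift(1), np.zeros((2, 1)), cfg,
                                      direction="backward", rng_seed=0))
        _, T = buf.flat_points()
        assert np.allclose(np.unique(T), [0.0, 0.25, 0.5, 0.75, 1.0])
        # backward grid tau=0 is forward time 1
        assert T[0] == pytest.approx(1.0)

    def test_mixed_directions_rejected(self):
        cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=4, dim=1)
        buf = ReplayBuffer(8)
        buf.push_ensemble(_ensemble(2, cfg))
        with pytest.raises(ValueError, match="direction"):
            buf.push_ensemble(simulate_em(ZeroDrift(1), np.zeros((2, 1)), cfg,
                                          direction="backward", rng_seed=1))


def test_init_reference_zero_mode(rng):
    ref = init_reference(3, "zero_drift")
    assert np.allclose(ref(rng.normal(size=(5, 3)), 0.2), 0.0)


def test_init_reference_untrained_net_is_small(rng):
    ref = init_reference(2, "untrained_net", rng_seed=4)
    x = rng.uniform(-3, 3, size=(100, 2))
    assert np.max(np.abs(ref(x, 0.5))) <= 0.1


def test_untrained_reference_process_is_nearly_brownian():
    """Simulation under a fresh reference: endpoint variance grows by about
    sigma^2 * horizon, as for a Wiener process."""
    cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=100, dim=1)
    ref = init_reference(1, "untrained_net", rng_seed=5)
    rng = np.random.default_rng(0)
    x0 = rng.normal(0, 1, size=(5000, 1))
    ens = simulate_em(ref, x0, cfg, rng_seed=6)
    growth = ens.states[:, -1].var() - x0.var()
    assert abs(growth - 1.0) < 0.1


def test_refresh_buffer_appends_and_anchors(rng):
    config = _small_config()
    buf = ReplayBuffer(config.buffer_capacity)
    samples = rng.normal(size=(200, 1))
    refresh_buffer(buf, ZeroDrift(1), samples, config, "forward",
                   np.random.default_rng(0))
    assert len(buf) == config.n_new_trajectories
    # marginal anchoring: every start is one of the provided samples
    starts = buf.initial_states()[:, 0]
    assert np.all(np.isin(np.round(starts, 12), np.round(samples[:, 0], 12)))


def test_sigma_heuristic_covers_target_range():
    samples = np.array([[0.0], [4.0]])
    sigma = sigma_heuristic(samples, horizon=1.0)
    assert sigma == pytest.approx(2.0)
    assert sigma_heuristic(samples, horizon=0.25) == pytest.approx(4.0)


def test_run_ipf_shapes_and_determinism(rng):
    pi0 = rng.normal(-1, 1, size=(128, 1))
    pi1 = rng.normal(1, 1, size=(128, 1))
    config = _small_config()
    res1 = run_ipf(pi0, pi1, config)
    assert len(res1.diagnostics) == config.n_ipf_iterations
    for d in res1.diagnostics:
        assert d["w1_forward_end"] >= 0 and d["w1_backward_end"] >= 0
    res2 = run_ipf(pi0, pi1, config)
    assert np.array_equal(res1.forward_drift.get_flat(), res2.forward_drift.get_flat())
    assert np.array_equal(res1.backward_drift.get_flat(), res2.backward_drift.get_flat())
    assert res1.diagnostics == res2.diagnostics


def test_run_ipf_identical_marginals_near_noise_floor(rng):
    """pi0 = pi1, small sigma: almost no transport is needed, so endpoint
    W1 stays within twice the resampling noise floor."""
    base = rng.normal(0, 1, size=(512, 1))
    config = _small_config(
        sde=SDEConfig(sigma=0.2, dt=0.02, n_steps=10, dim=1),
        n_ipf_iterations=2,
        n_new_trajectories=64,
        buffer_capacity=256,
        train=HalfBridgeTrainConfig(n_train_steps=200, batch_points=256),
        n_eval=256,
    )
    res = run_ipf(base, base, config)
    floor = np.mean([
        float(np.mean(np.abs(np.sort(rng.choice(base[:, 0], 256)) -
                             np.sort(rng.choice(base[:, 0], 256)))))
        for _ in range(5)
    ])
    last = res.diagnostics[-1]
    assert last["w1_forward_end"] < 2 * floor + 0.1
    assert last["w1_backward_end"] < 2 * floor + 0.1


def test_dimension_mismatch_rejected(rng):
    config = _small_config()
    with pytest.raises(ValueError, match="dimension"):
        run_ipf(rng.normal(size=(10, 2)), rng.normal(size=(10, 1)), config)


def test_config_validation():
    with pytest.raises(ValueError, match="capacity"):
        _small_config(n_new_trajectories=128, buffer_capacity=64)
    with pytest.raises(ValueError, match="init_mode"):
        _small_config(init_mode="bogus")
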