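"""Trace estimators, the reference score-matching loss, and training."""

import numpy as np
import pytest

import scorebridge.autodiff as ad
from scorebridge import (FunctionDrift, HalfBridgeTrainConfig, ReplayBuffer,
                         TraceEstimatorSpec, build_drift, reference_score_loss,
                         trace_jacobian_exact, trace_jacobian_hutchinson,
                         trace_jacobian_stein, train_half_bridge)
from scorebridge.scorefit import Adam, cosine_lr

from conftest import stationary_ou_buffer


class LinearPhi:
    """phi(x) = A x — exact hand-computable Jacobian."""

    activation = "tanh"

    def __init__(self, A):
        self.A = np.asarray(A, dtype=float)

    def forward_t(self, x, t):
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(x)
        return ad.matmul(x, ad.Tensor(self.A.T))

    def __call__(self, x, t):
        return np.atleast_2d(x) @ self.A.T


A_TEST = np.array([[2.0, 1.0], [0.0, 3.0]])  # trace 5


class ConstantPhi:
    activation = "tanh"

    def __init__(self, c):
        self.c = np.asarray(c, dtype=float)

    def forward_t(self, x, t):
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(x)
        return ad.broadcast_to(ad.Tensor(self.c), (x.shape[0], self.c.size)) + ad.mul(x, 0.0)

    def __call__(self, x, t):
        return np.broadcast_to(self.c, (np.atleast_2d(x).shape[0], self.c.size)).copy()


def test_exact_trace_linear_constant_identity(rng):
    x = rng.normal(size=(6, 2))
    assert np.allclose(trace_jacobian_exact(LinearPhi(A_TEST), x, 0.0), 5.0)
    assert np.allclose(trace_jacobian_exact(ConstantPhi(np.ones(2)), x, 0.0), 0.0)
    x3 = rng.normal(size=(4, 3))
    assert np.allclose(trace_jacobian_exact(LinearPhi(np.eye(3)), x3, 0.0), 3.0)


def test_hutchinson_identity_map_is_exact_per_probe(rng):
    """Rademacher entries square to one: z^T I z = D for every probe."""
    x = rng.normal(size=(5, 3))
    spec = TraceEstimatorSpec("hutchinson", n_probes=1)
    est = trace_jacobian_hutchinson(LinearPhi(np.eye(3)), x, 0.0, spec, rng_seed=0)
    assert np.allclose(est, 3.0)


def test_hutchinson_unbiased_for_linear_map(rng):
    x = rng.normal(size=(4, 2))
    spec = TraceEstimatorSpec("hutchinson", n_probes=10000)
    est = trace_jacobian_hutchinson(LinearPhi(A_TEST), x, 0.0, spec, rng_seed=1)
    # z^T A z = 5 + (a12 + a21) z1 z2 = 5 + z1 z2: per-probe std exactly 1
    se = 1.0 / np.sqrt(10000)
    assert np.all(np.abs(est - 5.0) < 3 * se)


def test_stein_exact_in_expectation_for_linear_map(rng):
    x = rng.normal(size=(3, 2))
    spec = TraceEstimatorSpec("stein", n_probes=100000, stein_sigma=0.5)
    est = trace_jacobian_stein(LinearPhi(A_TEST), x, 0.0, spec, rng_seed=2)
    # var of phi(x+z)^T z / s^2 dominated by (A x)^T z / s^2 term
    se = np.linalg.norm(A_TEST @ x.T, axis=0) / (0.5 * np.sqrt(100000))
    assert np.all(np.abs(est - 5.0) < 3 * (se + 0.05))


def test_stein_identity_map_dimension(rng):
    x = rng.normal(size=(2, 4))
    spec = TraceEstimatorSpec("stein", n_probes=100000, stein_sigma=0.1)
    est = trace_jacobian_stein(LinearPhi(np.eye(4)), x, 0.0, spec, rng_seed=3)
    se = (np.linalg.norm(x, axis=1) / 0.1 + np.sqrt(2 * 4)) / np.sqrt(100000)
    assert np.all(np.abs(est - 4.0) < 3 * se)


def test_constant_field_all_estimators_zero(rng):
    x = rng.normal(size=(4, 2))
    phi = ConstantPhi(np.array([1.5, -2.0]))
    assert np.allclose(trace_jacobian_exact(phi, x, 0.0), 0.0)
    h = trace_jacobian_hutchinson(phi, x, 0.0, TraceEstimatorSpec("hutchinson", 5), 0)
    assert np.allclose(h, 0.0)
    s = trace_jacobian_stein(phi, x, 0.0, TraceEstimatorSpec("stein", 1000, stein_sigma=0.2), 0)
    assert np.abs(s).max() < 3 * np.linalg.norm(phi.c) / (0.2 * np.sqrt(1000))


def test_spec_validation():
    with pytest.raises(ValueError):
        TraceEstimatorSpec("stein")  # missing sigma
    with pytest.raises(ValueError):
        TraceEstimatorSpec("hutchinson", stein_sigma=0.1)
    with pytest.raises(ValueError):
        TraceEstimatorSpec("nope")
    with pytest.raises(ValueError):
        HalfBridgeTrainConfig(lr_start=1e-5, lr_end=1e-3)


def test_relu_rejected_by_derivative_estimators(rng):
    net = build_drift(2, overrides=dict(activation="relu"))
    with pytest.raises(ValueError, match="stein"):
        trace_jacobian_exact(net, rng.normal(size=(2, 2)), 0.0)


def test_loss_hand_examples(rng):
    zero = ConstantPhi(np.zeros(1))
    mu1 = FunctionDrift(lambda x, t: np.ones_like(np.atleast_2d(x)), 1)
    batch = {"x": rng.normal(size=(10, 1)), "t": np.zeros(10)}
    spec = TraceEstimatorSpec("exact_diagonal")
    assert reference_score_loss(zero, mu1, batch, 1.0, spec) == pytest.approx(0.0)

    # single point, D=1, phi(x)=x, mu_ref=1, sigma=1, x=0: 0 + 0 + 2 = 2
    ident = LinearPhi(np.eye(1))
    single = {"x": np.zeros((1, 1)), "t": np.zeros(1)}
    assert reference_score_loss(ident, mu1, single, 1.0, spec) == pytest.approx(2.0)

    # constant phi=(1,1), mu_ref=0: loss = ||c||^2 = 2
    c = ConstantPhi(np.ones(2))
    mu0 = FunctionDrift(lambda x, t: np.zeros_like(np.atleast_2d(x)), 2)
    batch2 = {"x": rng.normal(size=(5, 2)), "t": np.zeros(5)}
    assert reference_score_loss(c, mu0, batch2, 3.0, spec) == pytest.approx(2.0)


def test_loss_validation(rng):
    ident = LinearPhi(np.eye(1))
    mu0 = FunctionDrift(lambda x, t: np.zeros_like(np.atleast_2d(x)), 1)
    batch = {"x": rng.normal(size=(3, 1)), "t": np.zeros(3)}
    with pytest.raises(ValueError, match="sigma"):
        reference_score_loss(ident, mu0, batch, -1.0, TraceEstimatorSpec("exact_diagonal"))
    with pytest.raises(ValueError):
        reference_score_loss(ident, mu0, {"x": np.zeros((3, 1)), "t": np.zeros(2)},
                             1.0, TraceEstimatorSpec("exact_diagonal"))


@pytest.mark.parametrize("net_seed", [1, 2, 3])
def test_integration_by_parts_identity(net_seed):
    """E_N(0,I)[Tr J_phi] = E[x . phi(x)] for smooth phi; both sides are
    estimated on the same draw, so the Monte-Carlo error is the paired
    standard error of the per-point difference."""
    net = build_drift(3, overrides=dict(final_scale=0.5), rng_seed=net_seed)
    x = np.random.default_rng(777 + net_seed).standard_normal((100000, 3))
    tr = trace_jacobian_exact(net, x, 0.3)
    dot = (x * net(x, 0.3)).sum(axis=1)
    d = tr - dot
    assert abs(d.mean()) < 3 * d.std() / np.sqrt(d.size)


def test_cosine_schedule_endpoints():
    assert cosine_lr(0, 1000, 1e-3, 1e-5) == pytest.approx(1e-3)
    assert cosine_lr(999, 1000, 1e-3, 1e-5) == pytest.approx(1e-5)
    mid = cosine_lr(500, 1000, 1e-3, 1e-5)
    assert 1e-5 < mid < 1e-3


def test_adam_minimises_quadratic():
    p = ad.Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p])
    for _ in range(500):
        loss = ad.tsum(ad.mul(p, p))
        g = ad.grad(loss, [p])
        opt.step(g, 0.05)
    assert np.all(np.abs(p.data) < 1e-2)


def test_empty_buffer_raises():
    phi = build_drift(1)
    mu = FunctionDrift(lambda x, t: np.zeros_like(np.atleast_2d(x)), 1)
    with pytest.raises(ValueError, match="empty"):
        train_half_bridge(phi, mu, ReplayBuffer(8), 1.0,
                          TraceEstimatorSpec("exact_diagonal"),
                          HalfBridgeTrainConfig(n_train_steps=2))


def test_no_gradient_flows_into_reference(rng):
    """mu_ref is a constant in the loss: training must leave it untouched."""
    buf, _ = stationary_ou_buffer(n_paths=32, n_steps=20, seed=5)
    mu_net = build_drift(1, rng_seed=1)
    before = mu_net.get_flat().copy()
    phi = build_drift(1, rng_seed=2)
    cfg = HalfBridgeTrainConfig(n_train_steps=20, batch_points=64, rng_seed=3)
    train_half_bridge(phi, mu_net, buf, 1.0, TraceEstimatorSpec("exact_diagonal"), cfg)
    assert np.array_equal(mu_net.get_flat(), before)


def test_wiener_half_bridge_learns_gaussian_score():
    """mu_ref = 0 from N(0,1), sigma=1: at forward time t=1 the minimiser is
    the Brownian-smoothed score -x/2 (variance 1 + t = 2)."""
    rng = np.random.default_rng(8)
    from scorebridge import SDEConfig, simulate_em, ZeroDrift
    cfg = SDEConfig(sigma=1.0, dt=0.01, n_steps=100, dim=1)
    x0 = rng.standard_normal((512, 1))
    ens = simulate_em(ZeroDrift(1), x0, cfg, rng_seed=9)
    buf = ReplayBuffer(512)
    buf.push_ensemble(ens)
    phi = build_drift(1, rng_seed=10)
    tcfg = HalfBridgeTrainConfig(n_train_steps=1000, batch_points=1024, rng_seed=11)
    mu0 = ZeroDrift(1)
    phi, losses = train_half_bridge(phi, mu0, buf, 1.0,
                                    TraceEstimatorSpec("exact_diagonal"), tcfg)
    assert losses.shape == (1000,)
    xs = np.linspace(-2, 2, 81)[:, None]
    mse = np.mean((phi(xs, 1.0)[:, 0] - (-xs[:, 0] / 2.0)) ** 2)
    assert mse <= 0.05
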