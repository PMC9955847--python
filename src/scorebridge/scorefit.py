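"""Score matching with a reference drift: loss, trace estimators, training.

A half-bridge fits a vector field ``phi`` so that it becomes the reverse
drift of a reference process with drift ``mu_ref`` and diffusion ``sigma``.
Given points ``x`` drawn from the reference process' marginals, the cost per
point is

    ||phi||^2 + 2 mu_ref . phi + 2 sigma^2 Tr J_phi,

whose population minimiser is ``-mu_ref + sigma^2 grad log p_t`` — exactly
the reverse-time drift.  No access to the true score is needed: everything
in the loss is computable from simulated samples.

The Jacobian trace can be computed exactly (D backward passes), estimated
unbiasedly with Rademacher probes (Hutchinson; one extra derivative of the
scalar ``phi . z``), or derivative-free via Gaussian perturbations and
Stein's lemma (usable with ReLU networks, biased O(sigma_z^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "TraceEstimatorSpec", "HalfBridgeTrainConfig", "Adam", "cosine_lr",
    "trace_jacobian_exact", "trace_jacobian_hutchinson", "trace_jacobian_stein",
    "reference_score_loss", "train_half_bridge",
]


@dataclass(frozen=True)
class TraceEstimatorSpec:
    """Which Jacobian-trace estimator to use inside the loss.

    kind : {"exact_diagonal", "hutchinson", "stein"}
    n_probes : probe vectors per point (stochastic estimators)
    stein_sigma : perturbation scale sigma_z of the Gaussian probes
        (stein only; the estimator's bias vanishes as sigma_z -> 0)
    """

    kind: str = "exact_diagonal"
    n_probes: int = 1
    stein_sigma: float | None = None

    def __post_init__(self):
        if self.kind not in ("exact_diagonal", "hutchinson", "stein"):
            raise ValueError(f"unknown trace estimator {self.kind!r}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.kind == "stein":
            if self.stein_sigma is None or self.stein_sigma <= 0:
                raise ValueError("stein estimator requires stein_sigma > 0")
        elif self.stein_sigma is not None:
            raise ValueError("stein_sigma only applies to the stein estimator")


@dataclass
class HalfBridgeTrainConfig:
    """Optimiser schedule for one half-bridge (Adam, cosine-annealed lr)."""

    n_train_steps: int = 1000
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    schedule: str = "cosine"
    batch_points: int = 1024
    rng_seed: int = 0

    def __post_init__(self):
        if self.lr_end > self.lr_start:
            raise ValueError("lr_end must not exceed lr_start")
        if self.schedule != "cosine":
            raise ValueError("only the cosine schedule is supported")


def _check_differentiable(phi, spec_kind):
    act = getattr(phi, "activation", None)
    if act == "relu" and spec_kind in ("exact_diagonal", "hutchinson"):
        raise ValueError(
            "relu networks are only once differentiable; use the stein "
            "trace estimator"
        )


# -- trace estimators (traced versions return autodiff Tensors) -------------

def _trace_exact_t(phi, xt, t, y=None):
    if y is None:
        y = phi.forward_t(xt, t)
    d = xt.shape[1]
    tr = None
    for j in range(d):
        gx = ad.grad(ad.tsum(y[:, j]), [xt])[0]
        term = gx[:, j]
        tr = term if tr is None else tr + term
    return tr


def _trace_hutchinson_t(phi, xt, t, n_probes, rng, y=None):
    if y is None:
        y = phi.forward_t(xt, t)
    b, d = xt.shape
    est = None
    for _ in range(n_probes):
        z = rng.integers(0, 2, size=(b, d)).astype(np.float64) * 2.0 - 1.0
        gx = ad.grad(ad.tsum(ad.mul(y, z)), [xt])[0]
        term = ad.tsum(ad.mul(gx, z), axis=1)
        est = term if est is None else est + term
    return ad.mul(est, 1.0 / n_probes)


def _trace_stein_t(phi, xt, t, sigma_z, n_probes, rng):
    b, d = xt.shape
    est = None
    for _ in range(n_probes):
        z = rng.normal(0.0, sigma_z, size=(b, d))
        yp = phi.forward_t(xt + z, t)
        term = ad.mul(ad.tsum(ad.mul(yp, z), axis=1), 1.0 / sigma_z ** 2)
        est = term if est is None else est + term
    return ad.mul(est, 1.0 / n_probes)


_CHUNK = 8192  # bound graph memory for large evaluation batches


def _chunked_t(x, t):
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    t = np.asarray(t, dtype=np.float64)
    if t.ndim == 0:
        t = np.full(x.shape[0], float(t))
    for lo in range(0, x.shape[0], _CHUNK):
        yield x[lo:lo + _CHUNK], t[lo:lo + _CHUNK]


def trace_jacobian_exact(phi, x, t):
    """Exact ``sum_d d phi_d / d x_d`` per point, shape ``[B]``."""
    _check_differentiable(phi, "exact_diagonal")
    out = []
    for xc, tc in _chunked_t(x, t):
        xt = ad.Tensor(xc, requires_grad=True)
        out.append(_trace_exact_t(phi, xt, tc).data)
    return np.concatenate(out)


def trace_jacobian_hutchinson(phi, x, t, spec, rng_seed=0):
    """Rademacher-probe estimate ``E_z z^T J z``, unbiased for the trace."""
    if spec.kind != "hutchinson":
        raise ValueError("spec.kind must be 'hutchinson'")
    _check_differentiable(phi, "hutchinson")
    rng = np.random.default_rng(rng_seed)
    out = []
    for xc, tc in _chunked_t(x, t):
        xt = ad.Tensor(xc, requires_grad=True)
        out.append(_trace_hutchinson_t(phi, xt, tc, spec.n_probes, rng).data)
    return np.concatenate(out)


def trace_jacobian_stein(phi, x, t, spec, rng_seed=0):
    """Derivative-free estimate ``E_z phi(x+z)^T z / sigma_z^2``.

    Exact in expectation for affine ``phi`` and asymptotically unbiased as
    ``sigma_z -> 0``; needs only forward passes.
    """
    if spec.kind != "stein":
        raise ValueError("spec.kind must be 'stein'")
    rng = np.random.default_rng(rng_seed)
    out = []
    for xc, tc in _chunked_t(x, t):
        b, d = xc.shape
        acc = np.zeros(b)
        for _ in range(spec.n_probes):
            z = rng.normal(0.0, spec.stein_sigma, size=(b, d))
            yp = phi(xc + z, tc)
            acc += (yp * z).sum(axis=1) / spec.stein_sigma ** 2
        out.append(acc / spec.n_probes)
    return np.concatenate(out)


# -- loss -------------------------------------------------------------------

def _loss_t(phi, mu_ref_vals, x_np, t_np, sigma, trace_spec, rng):
    """Traced minibatch loss; ``mu_ref_vals`` is a constant array."""
    needs_x_grad = trace_spec.kind in ("exact_diagonal", "hutchinson")
    xt = ad.Tensor(x_np, requires_grad=needs_x_grad)
    y = phi.forward_t(xt, t_np)
    quad = ad.tsum(ad.mul(y, y), axis=1)
    cross = ad.mul(ad.tsum(ad.mul(y, mu_ref_vals), axis=1), 2.0)
    if trace_spec.kind == "exact_diagonal":
        tr = _trace_exact_t(phi, xt, t_np, y=y)
    elif trace_spec.kind == "hutchinson":
        tr = _trace_hutchinson_t(phi, xt, t_np, trace_spec.n_probes, rng, y=y)
    else:
        tr = _trace_stein_t(phi, xt, t_np, trace_spec.stein_sigma,
                            trace_spec.n_probes, rng)
    return ad.tmean(quad + cross + ad.mul(tr, 2.0 * sigma ** 2))


def reference_score_loss(phi, mu_ref, batch, sigma, trace_spec, rng_seed=0):
    """Empirical score-matching cost on a batch ``{x: [B,D], t: [B]}``.

    The reference drift is treated as a constant: no gradient flows into
    ``mu_ref``.  Returns the minibatch mean of the per-point cost.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_differentiable(phi, trace_spec.kind)
    x = np.atleast_2d(np.asarray(batch["x"], dtype=np.float64))
    t = np.asarray(batch["t"], dtype=np.float64)
    if t.ndim == 0:
        t = np.full(x.shape[0], float(t))
    if t.shape[0] != x.shape[0]:
        raise ValueError("batch x and t sizes disagree")
    mu_vals = np.asarray(mu_ref(x, t), dtype=np.float64)
    if mu_vals.shape != x.shape:
        raise ValueError("mu_ref output shape mismatch")
    rng = np.random.default_rng(rng_seed)
    return float(_loss_t(phi, mu_vals, x, t, sigma, trace_spec, rng).data)


# -- optimiser ---------------------------------------------------------------

def cosine_lr(step, n_steps, lr_start, lr_end):
    """Cosine annealing from ``lr_start`` to ``lr_end`` over ``n_steps``."""
    if n_steps <= 1:
        return lr_end
    frac = step / (n_steps - 1)
    return lr_end + 0.5 * (lr_start - lr_end) * (1.0 + math.cos(math.pi * frac))


class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = g.data if isinstance(g, ad.Tensor) else g
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


# -- half-bridge training ----------------------------------------------------

class TrainingDiverged(RuntimeError):
    def __init__(self, step, losses):
        super().__init__(f"non-finite loss at training step {step}")
        self.step = step
        self.losses = losses


def train_half_bridge(phi, mu_ref, buffer, sigma, trace_spec, cfg,
                      refresh_every=None, refresh_fn=None):
    """Fit ``phi`` to the reverse drift of the ``mu_ref`` process.

    Minibatches of ``(x, t)`` pairs are sampled uniformly over all
    (trajectory, time-step) entries of the replay buffer; stochastic trace
    probes are redrawn every step.  Optionally ``refresh_fn()`` is invoked
    every ``refresh_every`` steps (before sampling) so the driver can top up
    the buffer with fresh reference trajectories mid-training.

    Returns ``(phi, losses)`` where ``losses`` is the per-step loss log.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_differentiable(phi, trace_spec.kind)
    if len(buffer) == 0 and refresh_fn is None:
        raise ValueError("replay buffer is empty")

    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(phi.parameters())
    params = phi.parameters()
    losses = np.empty(cfg.n_train_steps)

    X = T = None
    for step in range(cfg.n_train_steps):
        if refresh_fn is not None and refresh_every and step % refresh_every == 0:
            refresh_fn()
            X = T = None
        if X is None:
            if len(buffer) == 0:
                raise ValueError("replay buffer is empty")
            X, T = buffer.flat_points()
        idx = rng.integers(0, X.shape[0], size=min(cfg.batch_points, X.shape[0]))
        xb, tb = X[idx], T[idx]
        mu_vals = np.asarray(mu_ref(xb, tb), dtype=np.float64)
        loss = _loss_t(phi, mu_vals, xb, tb, sigma, trace_spec, rng)
        val = float(loss.data)
        losses[step] = val
        if not np.isfinite(val):
            raise TrainingDiverged(step, losses[: step + 1])
        grads = ad.grad(loss, params)
        opt.step(grads, cosine_lr(step, cfg.n_train_steps, cfg.lr_start, cfg.lr_end))
    return phi, losses
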