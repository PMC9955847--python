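"""Trainable drift approximators.

The drift of each half-bridge is a residual multilayer perceptron taking the
state ``x`` and the normalised time ``t`` as distinct inputs.  Each block has
the shape

    h <- h + act( Linear( [LayerNorm(h), Embedding(t)] ) )

where layer normalisation is applied to the spatial features only, so the
learned time embedding is passed through untouched.  Default sizing follows
the rule of thumb of ``10 * D`` hidden units and depth ``max(2, ceil(D / 5))``.

All drift networks are parameterised by the *forward-clock* normalised time
``t in [0, 1]``; the SDE simulator converts backward grid indices to forward
time before calling a network (see :mod:`scorebridge.sde`).
"""

from __future__ import annotations

import json
import math

import numpy as np

from . import autodiff as ad

__all__ = ["DriftApproximator", "ZeroDrift", "FunctionDrift", "build_drift", "evaluate_drift"]

_ACT = {"tanh": ad.tanh, "gelu": ad.gelu, "relu": ad.relu}
_ACT_NP = {
    "tanh": np.tanh,
    "gelu": lambda z: 0.5 * z * (1.0 + _erf_np(z / math.sqrt(2.0))),
    "relu": lambda z: np.maximum(z, 0.0),
}

_LN_EPS = 1e-5


def _erf_np(z):
    from scipy.special import erf

    return erf(z)


class DriftApproximator:
    """Residual MLP vector field ``(x, t) -> R^D``.

    Parameters
    ----------
    dim : int
        Spatial dimension D.
    width, depth : int, optional
        Hidden width (default ``10 * dim``) and number of residual blocks
        (default ``max(2, ceil(dim / 5))``).
    activation : {"tanh", "gelu", "relu"}
        ``relu`` is only once differentiable; training with the exact or
        Hutchinson trace estimators requires tanh or gelu.
    time_embedding_size : int
        Width of the learned affine embedding of ``t``.
    final_scale : float
        Standard deviation of the output-layer weights; kept small so a
        freshly built network is a near-zero drift (its simulated process is
        dominated by the Wiener term, the useful IPF starting point).
    """

    def __init__(self, dim, width=None, depth=None, activation="tanh",
                 time_embedding_size=16, rng_seed=0, final_scale=1e-2):
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        if activation not in _ACT:
            raise ValueError(f"unknown activation {activation!r}")
        self.dim = int(dim)
        self.width = int(width) if width is not None else 10 * self.dim
        self.depth = int(depth) if depth is not None else max(2, math.ceil(self.dim / 5))
        self.activation = activation
        self.time_embedding_size = int(time_embedding_size)
        self.rng_seed = int(rng_seed)
        self.final_scale = float(final_scale)
        self._init_params(np.random.default_rng(rng_seed))

    def _init_params(self, rng):
        D, W, E = self.dim, self.width, self.time_embedding_size
        p = {}
        p["W_t"] = rng.normal(0.0, 1.0, size=(1, E))
        p["b_t"] = np.zeros(E)
        p["W_in"] = rng.normal(0.0, 1.0 / math.sqrt(D), size=(D, W))
        # nonzero biases keep the layer-normalised features away from the
        # degenerate all-equal configuration (whose Jacobian spikes as the
        # feature variance hits the epsilon floor)
        p["b_in"] = rng.uniform(-1.0, 1.0, size=W) / math.sqrt(D)
        for i in range(self.depth):
            p[f"gamma_{i}"] = np.ones(W)
            p[f"beta_{i}"] = np.zeros(W)
            p[f"W_{i}"] = rng.normal(0.0, 1.0 / math.sqrt(W + E), size=(W + E, W))
            p[f"b_{i}"] = rng.uniform(-1.0, 1.0, size=W) / math.sqrt(W + E)
        p["W_out"] = rng.normal(0.0, self.final_scale / math.sqrt(W), size=(W, D))
        p["b_out"] = np.zeros(D)
        self._params = {k: ad.Tensor(v, requires_grad=True) for k, v in p.items()}

    # -- parameter access --------------------------------------------------
    def parameters(self):
        return list(self._params.values())

    def named_parameters(self):
        return dict(self._params)

    def get_flat(self):
        return np.concatenate([t.data.ravel() for t in self._params.values()])

    def set_flat(self, vec):
        vec = np.asarray(vec, dtype=np.float64)
        off = 0
        for t in self._params.values():
            n = t.data.size
            t.data = vec[off:off + n].reshape(t.data.shape).copy()
            off += n
        if off != vec.size:
            raise ValueError("flat parameter vector has wrong length")

    @property
    def n_params(self):
        return int(sum(t.data.size for t in self._params.values()))

    # -- evaluation ---------------------------------------------------------
    def _prep_t(self, t, batch):
        t = np.asarray(t, dtype=np.float64)
        if t.ndim == 0:
            t = np.full(batch, float(t))
        return t.reshape(batch, 1)

    def __call__(self, x, t):
        """Fast NumPy forward pass (no graph)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.dim:
            raise ValueError(f"expected dim {self.dim}, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to drift network")
        p = {k: v.data for k, v in self._params.items()}
        act = _ACT_NP[self.activation]
        tcol = self._prep_t(t, x.shape[0])
        e = tcol @ p["W_t"] + p["b_t"]
        h = x @ p["W_in"] + p["b_in"]
        for i in range(self.depth):
            mu = h.mean(axis=1, keepdims=True)
            xc = h - mu
            var = (xc * xc).mean(axis=1, keepdims=True)
            n = xc / np.sqrt(var + _LN_EPS)
            n = n * p[f"gamma_{i}"] + p[f"beta_{i}"]
            c = np.concatenate([n, np.broadcast_to(e, (h.shape[0], e.shape[1]))], axis=1)
            h = h + act(c @ p[f"W_{i}"] + p[f"b_{i}"])
        return h @ p["W_out"] + p["b_out"]

    def forward_t(self, x, t):
        """Traced forward pass: ``x`` is an autodiff Tensor ``[B, D]``."""
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        B = x.shape[0]
        p = self._params
        act = _ACT[self.activation]
        tcol = ad.Tensor(self._prep_t(t, B))
        e = ad.matmul(tcol, p["W_t"]) + p["b_t"]
        h = ad.matmul(x, p["W_in"]) + p["b_in"]
        for i in range(self.depth):
            mu = ad.tmean(h, axis=1, keepdims=True)
            xc = h - mu
            var = ad.tmean(ad.mul(xc, xc), axis=1, keepdims=True)
            n = ad.mul(xc, ad.power(var + _LN_EPS, -0.5))
            n = ad.mul(n, p[f"gamma_{i}"]) + p[f"beta_{i}"]
            c = ad.concat([n, ad.broadcast_to(e, (B, e.shape[1]))], axis=1)
            h = h + act(ad.matmul(c, p[f"W_{i}"]) + p[f"b_{i}"])
        return ad.matmul(h, p["W_out"]) + p["b_out"]

    def jacobian(self, x, t):
        """Analytic Jacobian ``[B, D, D]`` via reverse mode (testing aid)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        B, D = x.shape
        xt = ad.Tensor(x, requires_grad=True)
        y = self.forward_t(xt, t)
        J = np.empty((B, D, D))
        for d in range(D):
            gx = ad.grad(ad.tsum(y[:, d]), [xt])[0]
            J[:, d, :] = gx.data
        return J

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        meta = dict(dim=self.dim, width=self.width, depth=self.depth,
                    activation=self.activation,
                    time_embedding_size=self.time_embedding_size,
                    rng_seed=self.rng_seed, final_scale=self.final_scale)
        np.savez(path, flat=self.get_flat(), meta=json.dumps(meta))

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            flat = f["flat"]
        net = cls(**meta)
        net.set_flat(flat)
        return net


class ZeroDrift:
    """Constant-zero vector field (the Wiener reference process)."""

    def __init__(self, dim):
        self.dim = int(dim)

    def __call__(self, x, t):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return np.zeros_like(x)


class FunctionDrift:
    """Adapter wrapping an arbitrary ``f(x, t) -> [B, D]`` callable."""

    def __init__(self, fn, dim):
        self.fn = fn
        self.dim = int(dim)

    def __call__(self, x, t):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return np.asarray(self.fn(x, t), dtype=np.float64)


def build_drift(dim, overrides=None, rng_seed=0):
    """Build a drift approximator with the default sizing rules.

    ``overrides`` may contain any :class:`DriftApproximator` constructor
    keyword (width, depth, activation, time_embedding_size, final_scale).
    """
    kwargs = dict(overrides or {})
    return DriftApproximator(dim, rng_seed=rng_seed, **kwargs)


def evaluate_drift(net, x, t):
    """Batched evaluation ``[B, D] -> [B, D]`` of any drift object."""
    out = net(x, t)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("drift produced non-finite output")
    return out
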