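"""Synthetic marginal distributions and analytic oracles.

Two families of boundary-distribution pairs mirror the package's synthetic
experiments: Gaussian-to-GMM pairs (a unimodal Gaussian flowing into a
bimodal mixture, means drawn uniformly from ``[-2.5, 2.5]`` with unit
standard deviation) and manifold targets built by concatenating classic
parametric manifolds (swiss roll, S-curve, two moons) reached from a
standard normal.  The manifold parametrisations are implemented directly
from their standard forms and standardised per dimension to unit scale,
the regime the network initialisation and diffusion heuristic presume.

The Ornstein--Uhlenbeck reverse drift in closed form serves as the analytic
oracle for everything score-related: for a forward process
``dX = -theta X dt + sigma dW`` with Gaussian initial law, the marginal
stays Gaussian and the reverse drift ``-mu + sigma^2 grad log p`` can be
written down exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarginalSpec", "gmm_pair", "manifold_pair",
    "ou_marginal_params", "ou_reverse_drift",
    "MANIFOLD_DIMS",
]

MANIFOLD_DIMS = {"swiss_roll": 3, "s_curve": 3, "moons": 2}


@dataclass
class MarginalSpec:
    """Declarative description of a marginal distribution.

    kind : {"gaussian", "gmm", "manifold_concat", "empirical"}
    parameters : kind-specific dict (means/stds/weights, manifold list +
        noise, or raw samples for "empirical")
    """

    kind: str
    dim: int
    parameters: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "gmm", "manifold_concat", "empirical"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "gmm":
            w = np.asarray(self.parameters["weights"], dtype=np.float64)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("gmm weights must sum to 1")
            if np.any(np.asarray(self.parameters["stds"]) <= 0):
                raise ValueError("gmm stds must be positive")

    def sample(self, n, rng_seed=None):
        """Draw ``n`` samples; deterministic given the seed."""
        seed = self.rng_seed if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)
        if self.kind == "gaussian":
            mean = np.asarray(self.parameters["mean"], dtype=np.float64)
            std = float(self.parameters["std"])
            return mean + std * rng.standard_normal((n, self.dim))
        if self.kind == "gmm":
            means = np.atleast_2d(np.asarray(self.parameters["means"], dtype=np.float64))
            stds = np.asarray(self.parameters["stds"], dtype=np.float64)
            weights = np.asarray(self.parameters["weights"], dtype=np.float64)
            comp = rng.choice(len(weights), size=n, p=weights)
            return means[comp] + stds[comp, None] * rng.standard_normal((n, self.dim))
        if self.kind == "manifold_concat":
            return _sample_manifolds(self.parameters["manifolds"], n, rng,
                                     self.parameters.get("noise", 0.05))
        if self.kind == "empirical":
            samples = np.atleast_2d(np.asarray(self.parameters["samples"]))
            idx = rng.choice(samples.shape[0], size=n, replace=n > samples.shape[0])
            return samples[idx].astype(np.float64)
        raise AssertionError  # pragma: no cover


def gmm_pair(dim, rng_seed=0):
    """Unimodal-Gaussian / bimodal-GMM boundary pair.

    All component means are uniform on ``[-2.5, 2.5]`` per coordinate with
    standard deviation 1.0; the mixture weights are uniform (1/2, 1/2).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(rng_seed)
    m0 = rng.uniform(-2.5, 2.5, size=dim)
    m1 = rng.uniform(-2.5, 2.5, size=(2, dim))
    sub = rng.integers(0, 2 ** 31 - 1, size=2)
    pi0 = MarginalSpec("gaussian", dim, dict(mean=m0, std=1.0), rng_seed=int(sub[0]))
    pi1 = MarginalSpec("gmm", dim,
                       dict(means=m1, stds=np.array([1.0, 1.0]),
                            weights=np.array([0.5, 0.5])),
                       rng_seed=int(sub[1]))
    return pi0, pi1


def _swiss_roll(n, rng):
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.uniform(size=n))
    y = 21.0 * rng.uniform(size=n)
    return np.column_stack([t * np.cos(t), y, t * np.sin(t)])


def _s_curve(n, rng):
    t = 3.0 * np.pi * (rng.uniform(size=n) - 0.5)
    y = 2.0 * rng.uniform(size=n)
    return np.column_stack([np.sin(t), y, np.sign(t) * (np.cos(t) - 1.0)])


def _moons(n, rng):
    n_out = n - n // 2
    t_out = np.pi * rng.uniform(size=n_out)
    t_in = np.pi * rng.uniform(size=n // 2)
    outer = np.column_stack([np.cos(t_out), np.sin(t_out)])
    inner = np.column_stack([1.0 - np.cos(t_in), 1.0 - np.sin(t_in) - 0.5])
    pts = np.vstack([outer, inner])
    return pts[rng.permutation(n)]

_MANIFOLD_FNS = {"swiss_roll": _swiss_roll, "s_curve": _s_curve, "moons": _moons}


def _sample_manifolds(manifolds, n, rng, noise):
    blocks = []
    for name in manifolds:
        if name not in _MANIFOLD_FNS:
            raise ValueError(f"unknown manifold {name!r}")
        pts = _MANIFOLD_FNS[name](n, rng)
        # standardise each coordinate to zero mean / unit scale, then jitter
        pts = (pts - pts.mean(axis=0)) / pts.std(axis=0)
        blocks.append(pts)
    out = np.concatenate(blocks, axis=1)
    if noise > 0:
        out = out + noise * rng.standard_normal(out.shape)
    return out


def manifold_pair(manifolds, n, rng_seed=0):
    """Standard-normal source / concatenated-manifold target pair.

    Each listed manifold is sampled independently per target sample and the
    coordinate blocks are concatenated (swiss_roll and s_curve contribute 3
    dimensions each, moons 2).
    """
    manifolds = list(manifolds)
    if not manifolds or n < 1:
        raise ValueError("need at least one manifold and n >= 1")
    dim = sum(MANIFOLD_DIMS.get(m, -10 ** 6) for m in manifolds)
    for m in manifolds:
        if m not in MANIFOLD_DIMS:
            raise ValueError(f"unknown manifold {m!r}")
    rng = np.random.default_rng(rng_seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=2)
    pi0 = MarginalSpec("gaussian", dim, dict(mean=np.zeros(dim), std=1.0),
                       rng_seed=int(sub[0]))
    pi1 = MarginalSpec("manifold_concat", dim,
                       dict(manifolds=manifolds, noise=0.05, n_reference=n),
                       rng_seed=int(sub[1]))
    return pi0, pi1


def ou_marginal_params(theta, sigma, init_mean, init_var, t):
    """Mean and variance of the OU marginal at forward time ``t``.

    ``m_t = m_0 e^{-theta t}``,
    ``v_t = v_0 e^{-2 theta t} + sigma^2 (1 - e^{-2 theta t}) / (2 theta)``
    (with the Brownian limit ``v_0 + sigma^2 t`` as ``theta -> 0``).
    """
    init_mean = np.asarray(init_mean, dtype=np.float64)
    if theta > 1e-12:
        decay = np.exp(-theta * t)
        m = init_mean * decay
        v = init_var * decay ** 2 + sigma ** 2 * (1.0 - decay ** 2) / (2.0 * theta)
    else:
        m = init_mean.copy()
        v = init_var + sigma ** 2 * t
    return m, float(v)


def ou_reverse_drift(theta, sigma, init_mean, init_var, x, tau):
    """Analytic reverse drift of a forward OU process, at backward time tau.

    For ``dX = -theta X dt + sigma dW`` started at ``N(m_0, v_0 I)`` the
    reverse drift at forward time ``t = 1 - tau`` is

        theta * x - sigma^2 (x - m_t) / v_t,

    i.e. ``-mu(x, t) + sigma^2 grad log p_t(x)`` with the Gaussian marginal.
    In the stationary case ``v_0 = sigma^2 / (2 theta)`` this reduces to
    ``-theta x``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    x = np.asarray(x, dtype=np.float64)
    t = 1.0 - tau
    m, v = ou_marginal_params(theta, sigma, init_mean, init_var, t)
    return theta * x - sigma ** 2 * (x - m) / v
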